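"""Univariable two-sample Mendelian randomisation estimators.

Four summary-data estimators of the causal effect of an exposure on an
outcome from harmonised per-SNP estimates (beta_exp, se_exp, beta_out,
se_out): inverse-variance weighted (IVW), MR-Egger, weighted median and
penalised weighted median.  IVW and Egger are weighted least squares with
outcome-precision weights; by default the IVW/Egger standard error carries a
multiplicative random-effects scaling floored at 1, i.e. it is inflated by
sqrt(Q / df) whenever Cochran's Q exceeds its degrees of freedom.  Binary
outcomes are on the log-odds scale, so exp(estimate) is an odds ratio per SD
of the exposure.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Union

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .sumstats import HarmonisedPairs

PairsLike = Union[HarmonisedPairs, pd.DataFrame]


class MREstimationError(ValueError):
    pass


@dataclass
class MRResult:
    """One estimator's output for one exposure-outcome pair."""

    method: str
    n_snp: int
    estimate: float
    se: float
    ci_low: float
    ci_high: float
    pvalue: float
    cochran_q: Optional[float] = None
    q_df: Optional[int] = None
    egger_intercept: Optional[float] = None
    egger_intercept_se: Optional[float] = None
    egger_intercept_pvalue: Optional[float] = None
    seed: Optional[int] = None

    @property
    def odds_ratio(self) -> tuple[float, float, float]:
        """(OR, 95% CI low, high) — meaningful for binary outcomes."""
        return (np.exp(self.estimate), np.exp(self.ci_low), np.exp(self.ci_high))

    def as_dict(self) -> dict:
        return {
            "method": self.method,
            "n_snp": self.n_snp,
            "estimate": self.estimate,
            "se": self.se,
            "ci_low": self.ci_low,
            "ci_high": self.ci_high,
            "pvalue": self.pvalue,
            "cochran_q": self.cochran_q,
            "q_df": self.q_df,
            "egger_intercept": self.egger_intercept,
        }


def _pairs_df(pairs: PairsLike) -> pd.DataFrame:
    df = pairs.kept if isinstance(pairs, HarmonisedPairs) else pairs
    need = {"beta_exp", "se_exp", "beta_out", "se_out"}
    if not need.issubset(df.columns):
        raise MREstimationError(f"pairs require columns {sorted(need)}")
    return df.reset_index(drop=True)


def _wald_result(bx, by, se_y) -> MRResult:
    est = by / bx
    se = se_y / abs(bx)  # first-order delta method
    z = est / se
    return MRResult(
        method="ivw",
        n_snp=1,
        estimate=float(est),
        se=float(se),
        ci_low=float(est - 1.96 * se),
        ci_high=float(est + 1.96 * se),
        pvalue=float(2 * stats.norm.sf(abs(z))),
        cochran_q=0.0,
        q_df=0,
    )


def _finish(method, n, est, se, q=None, q_df=None, **extra) -> MRResult:
    z = est / se
    return MRResult(
        method=method,
        n_snp=int(n),
        estimate=float(est),
        se=float(se),
        ci_low=float(est - 1.96 * se),
        ci_high=float(est + 1.96 * se),
        pvalue=float(2 * stats.norm.sf(abs(z))),
        cochran_q=q,
        q_df=q_df,
        **extra,
    )


# ---------------------------------------------------------------------------
# IVW and Egger
# ---------------------------------------------------------------------------

def ivw(pairs: PairsLike, random_effects: bool = True) -> MRResult:
    """Inverse-variance weighted estimate.

    Weighted least squares of outcome betas on exposure betas through the
    origin, weights 1/se_out^2.  With a single SNP this is the Wald ratio
    with delta-method SE.  ``random_effects`` applies the multiplicative
    scaling max(1, sqrt(Q/(L-1))) to the fixed-effect SE.
    """
    df = _pairs_df(pairs)
    L = len(df)
    if L == 0:
        raise MREstimationError("no retained SNPs")
    bx = df["beta_exp"].to_numpy(float)
    by = df["beta_out"].to_numpy(float)
    se_y = df["se_out"].to_numpy(float)
    if np.all(bx == 0):
        raise MREstimationError("all exposure betas are zero")
    if L == 1:
        return _wald_result(bx[0], by[0], se_y[0])

    w = 1.0 / se_y**2
    fit = sm.WLS(by, bx[:, None], weights=w).fit()
    est = float(fit.params[0])
    q = float(fit.ssr)  # weighted residual sum of squares = Cochran's Q
    se_fixed = float(np.sqrt(fit.cov_params(scale=1.0)[0, 0]))
    scale = max(1.0, np.sqrt(q / (L - 1))) if random_effects and L > 1 else 1.0
    return _finish("ivw", L, est, se_fixed * scale, q=q, q_df=L - 1)


def egger(pairs: PairsLike, random_effects: bool = True) -> MRResult:
    """MR-Egger regression: WLS of outcome on exposure betas with intercept.

    SNPs are re-oriented so every exposure beta is positive before fitting;
    the slope is the causal estimate and the intercept is the directional-
    pleiotropy test.
    """
    df = _pairs_df(pairs)
    L = len(df)
    if L < 3:
        raise MREstimationError(f"MR-Egger requires >= 3 SNPs, got {L}")
    sign = np.sign(df["beta_exp"].to_numpy(float))
    sign[sign == 0] = 1.0
    bx = df["beta_exp"].to_numpy(float) * sign
    by = df["beta_out"].to_numpy(float) * sign
    se_y = df["se_out"].to_numpy(float)

    w = 1.0 / se_y**2
    X = sm.add_constant(bx, has_constant="add")
    fit = sm.WLS(by, X, weights=w).fit()
    q = float(fit.ssr)
    cov_fixed = fit.cov_params(scale=1.0)
    scale = max(1.0, np.sqrt(q / (L - 2))) if random_effects else 1.0
    slope = float(fit.params[1])
    slope_se = float(np.sqrt(cov_fixed[1, 1])) * scale
    icpt = float(fit.params[0])
    icpt_se = float(np.sqrt(cov_fixed[0, 0])) * scale
    return _finish(
        "egger",
        L,
        slope,
        slope_se,
        q=q,
        q_df=L - 2,
        egger_intercept=icpt,
        egger_intercept_se=icpt_se,
        egger_intercept_pvalue=float(2 * stats.norm.sf(abs(icpt / icpt_se))),
    )


# ---------------------------------------------------------------------------
# weighted median family
# ---------------------------------------------------------------------------

def _weighted_median_point(ratios: np.ndarray, weights: np.ndarray) -> float:
    """Weighted median with midpoint convention and linear interpolation.

    The estimate is the value of the weighted empirical distribution of the
    per-SNP ratios at cumulative weight 1/2, where each ratio sits at the
    midpoint of its own weight mass.
    """
    order = np.argsort(ratios, kind="stable")
    b = ratios[order]
    w = weights[order] / weights.sum()
    cum = np.cumsum(w) - 0.5 * w
    if cum[0] >= 0.5:
        return float(b[0])
    if cum[-1] <= 0.5:
        return float(b[-1])
    k = int(np.searchsorted(cum, 0.5, side="right")) - 1
    return float(b[k] + (b[k + 1] - b[k]) * (0.5 - cum[k]) / (cum[k + 1] - cum[k]))


def _ratio_data(df: pd.DataFrame) -> tuple[np.ndarray, np.ndarray, pd.DataFrame]:
    """Per-SNP Wald ratios and their inverse-variance weights.

    Ratio variance by the first-order delta method, var = se_out^2/beta_exp^2.
    SNPs with beta_exp == 0 (ratio undefined) are dropped with a warning.
    """
    nonzero = df["beta_exp"] != 0
    if not nonzero.all():
        import logging

        logging.getLogger("tissuemr").warning(
            "dropping %d SNPs with zero exposure beta", int((~nonzero).sum())
        )
    df = df[nonzero]
    bx = df["beta_exp"].to_numpy(float)
    by = df["beta_out"].to_numpy(float)
    se_y = df["se_out"].to_numpy(float)
    ratios = by / bx
    weights = bx**2 / se_y**2  # 1 / delta-method variance
    return ratios, weights, df


def _bootstrap_se(
    df: pd.DataFrame, n_boot: int, seed: int, penalty: Optional[float]
) -> float:
    """Parametric bootstrap SE: redraw betas from their sampling distributions
    and replay the (penalised) weighted-median estimate."""
    rng = np.random.default_rng(seed)
    bx = df["beta_exp"].to_numpy(float)
    sx = df["se_exp"].to_numpy(float)
    by = df["beta_out"].to_numpy(float)
    sy = df["se_out"].to_numpy(float)
    est = np.empty(n_boot)
    for i in range(n_boot):
        bxs = rng.normal(bx, sx)
        bys = rng.normal(by, sy)
        ok = bxs != 0
        ratios = bys[ok] / bxs[ok]
        weights = bxs[ok] ** 2 / sy[ok] ** 2
        point = _weighted_median_point(ratios, weights)
        if penalty is not None:
            qi = stats.chi2.sf(weights * (ratios - point) ** 2, df=1)
            pw = weights * np.minimum(1.0, penalty * qi)
            point = _weighted_median_point(ratios, pw)
        est[i] = point
    return float(est.std(ddof=1))


def weighted_median(pairs: PairsLike, n_boot: int = 1000, seed: int = 0) -> MRResult:
    """Weighted-median estimator: consistent if SNPs contributing at least
    half the weight are valid instruments.  SE by parametric bootstrap."""
    df = _pairs_df(pairs)
    ratios, weights, df = _ratio_data(df)
    if len(df) < 3:
        raise MREstimationError(f"weighted median requires >= 3 usable SNPs, got {len(df)}")
    est = _weighted_median_point(ratios, weights)
    se = _bootstrap_se(df, n_boot, seed, penalty=None)
    res = _finish("weighted_median", len(df), est, se)
    res.seed = seed
    return res


def penalised_weighted_median(
    pairs: PairsLike, penalty: float = 20.0, n_boot: int = 1000, seed: int = 0
) -> MRResult:
    """Weighted median with heterogeneity-penalised weights.

    Each SNP's contribution to Cochran's Q about the plain weighted-median
    estimate, Q_i = w_i (ratio_i - est)^2, is converted to a one-sided
    chi-square(1) tail probability q_i; weights become w_i min(1, penalty q_i)
    and the weighted median is recomputed.  Outlying (pleiotropic) SNPs are
    down-weighted smoothly.
    """
    df = _pairs_df(pairs)
    ratios, weights, df = _ratio_data(df)
    if len(df) < 3:
        raise MREstimationError(f"penalised weighted median requires >= 3 usable SNPs")
    first = _weighted_median_point(ratios, weights)
    qi = stats.chi2.sf(weights * (ratios - first) ** 2, df=1)
    pen_w = weights * np.minimum(1.0, penalty * qi)
    est = _weighted_median_point(ratios, pen_w)
    se = _bootstrap_se(df, n_boot, seed, penalty=penalty)
    res = _finish("penalised_weighted_median", len(df), est, se)
    res.seed = seed
    return res


def all_estimators(
    pairs: PairsLike, n_boot: int = 1000, seed: int = 0, random_effects: bool = True
) -> pd.DataFrame:
    """Run IVW, Egger and both medians; long-format results table."""
    df = _pairs_df(pairs)
    out = [ivw(df, random_effects=random_effects)]
    if len(df) >= 3:
        out.append(egger(df, random_effects=random_effects))
        out.append(weighted_median(df, n_boot=n_boot, seed=seed))
        out.append(penalised_weighted_median(df, n_boot=n_boot, seed=seed))
    return pd.DataFrame([r.as_dict() for r in out])
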