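"""Summary-level simulation engine and power analysis.

Generates synthetic GWAS summary statistics directly at the summary level
(no individual-level genotypes): a pool of independent exposure loci with
per-SNP standard errors implied by allele frequency and sample size, tissue
labels and colocalization posteriors (PPA4), and matched outcome statistics
under user-chosen per-tissue causal effects.  On top of the generator sit a
power grid over (effect size, outcome sample size, variance explained), an
instrument-count strength curve, and a clearly-labelled synthetic emulation
of published tissue-partitioned instrument tables.

Outcome generative models
-------------------------
"mediated" (default): the SNP-outcome effect is
``gamma_i = sum_t theta_t * beta_i * ppa4_{i,t}`` — PPA4 is taken as the
fraction of SNP i's exposure effect mediated through tissue t, the
identifying assumption under which PPA4-weighted MVMR is consistent.
"labelled": ``gamma_i = theta_{tissue(i)} * beta_i`` for tissue-labelled
SNPs and 0 otherwise; under this model the weighted estimator is inflated by
roughly E[ppa4]/E[ppa4^2] of the own-tissue PPA4 distribution.

Determinism: every cell/replicate derives its generator from the master seed
by the documented rule ``default_rng((seed, *cell_indices, rep, stream))``.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .coloc import InstrumentSet
from .mvmr import (
    MVMRInput,
    _conditional_f_arrays,
    _mvmr_wls,
    build_weighted_design,
    conditional_f,
)
from .sumstats import SummaryStats

logger = logging.getLogger("tissuemr")

TISSUES = ("adipose", "brain")


@dataclass(frozen=True)
class TruncBeta:
    """Beta(a, b) distribution truncated to [lower, 1]."""

    a: float
    b: float
    lower: float = 0.0

    def sample(self, rng: np.random.Generator, size: int) -> np.ndarray:
        lo = stats.beta.cdf(self.lower, self.a, self.b)
        u = rng.uniform(lo, 1.0, size)
        return stats.beta.ppf(u, self.a, self.b)


@dataclass(frozen=True)
class SimulationSpec:
    """Study-design parameters for the summary-level simulation.

    Defaults reproduce the reference power study: a pool of 915 independent
    exposure loci from a GWAS of n = 700,000; effect sizes 0.1/0.125/0.15;
    outcome sample sizes 10k–100k; per-tissue variance explained 0.5%–3%;
    86 adipose-like and 140 brain-like instruments; own-tissue PPA4 from
    Beta(8,2) truncated to >= 0.8 and cross-tissue PPA4 from Beta(1,9).
    """

    n_snps_pool: int = 915
    n_exposure_gwas: int = 700_000
    effect_grid: tuple[float, ...] = (0.1, 0.125, 0.15)
    n_outcome_grid: tuple[int, ...] = (10_000, 25_000, 50_000, 75_000, 100_000)
    varexp_grid: tuple[float, ...] = (0.005, 0.01, 0.015, 0.02, 0.025, 0.03)
    n_adipose_like: int = 86
    n_brain_like: int = 140
    ppa4_own: TruncBeta = TruncBeta(8.0, 2.0, lower=0.8)
    ppa4_cross: TruncBeta = TruncBeta(1.0, 9.0)
    varexp_background: float = 0.04
    maf_range: tuple[float, float] = (0.05, 0.5)
    ppa4_threshold: float = 0.8
    outcome_model: str = "mediated"  # "mediated" | "labelled"
    n_reps: int = 200
    alpha: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_adipose_like + self.n_brain_like > self.n_snps_pool:
            raise ValueError("tissue subset counts exceed pool size")
        if any(v <= 0 or v > 0.05 for v in self.varexp_grid):
            raise ValueError("varexp values must lie in (0, 0.05]")
        if self.n_reps < 1:
            raise ValueError("n_reps must be >= 1")
        if self.outcome_model not in ("mediated", "labelled"):
            raise ValueError(f"unknown outcome_model {self.outcome_model!r}")


def _child_rng(seed: int, *indices: int) -> np.random.Generator:
    """Documented child-seed rule: master seed followed by cell indices."""
    return np.random.default_rng((int(seed), *map(int, indices)))


@dataclass
class ExposurePool:
    """Synthetic exposure GWAS pool with tissue labels and PPA4 assignments."""

    rsids: list[str]
    maf: np.ndarray
    beta_true: np.ndarray
    beta_hat: np.ndarray
    se: np.ndarray
    labels: np.ndarray  # "adipose" | "brain" | "none"
    ppa4: np.ndarray  # (P, 2) columns in TISSUES order
    n_gwas: int
    tissues: tuple[str, ...] = TISSUES

    def to_sumstats(self, trait_name: str = "exposure") -> SummaryStats:
        P = len(self.rsids)
        z = self.beta_hat / self.se
        df = pd.DataFrame(
            {
                "rsid": self.rsids,
                "chrom": [str(i % 22 + 1) for i in range(P)],
                "pos": [1_000_000 + 20_000_000 * (i // 22) for i in range(P)],
                "effect_allele": "A",
                "other_allele": "G",
                "eaf": self.maf,
                "beta": self.beta_hat,
                "se": self.se,
                "pvalue": np.clip(2 * stats.norm.sf(np.abs(z)), 1e-300, 1.0),
                "n": self.n_gwas,
            }
        )
        return SummaryStats(df=df, trait_name=trait_name, n_total=self.n_gwas)

    def instrument_sets(self, threshold: float = 0.8) -> list[InstrumentSet]:
        """Threshold-passing instruments per tissue (observed betas/SEs)."""
        sets = []
        for k, tissue in enumerate(self.tissues):
            sel = self.ppa4[:, k] >= threshold
            df = pd.DataFrame(
                {
                    "rsid": np.asarray(self.rsids)[sel],
                    "beta": self.beta_hat[sel],
                    "se": self.se[sel],
                    "gene": [f"GENE_{r}" for r in np.asarray(self.rsids)[sel]],
                    "ppa4": self.ppa4[sel, k],
                }
            )
            sets.append(InstrumentSet(tissue=tissue, df=df))
        return sets

    def ppa4_lookup(self) -> pd.DataFrame:
        """Long-format (rsid, tissue, ppa4) for cross-tissue design lookups."""
        rows = []
        for k, tissue in enumerate(self.tissues):
            rows.append(
                pd.DataFrame(
                    {"rsid": self.rsids, "tissue": tissue, "ppa4": self.ppa4[:, k]}
                )
            )
        return pd.concat(rows, ignore_index=True)

    def realised_varexp(self, tissue: str) -> float:
        k = self.labels == tissue
        return float(np.sum(2 * self.maf[k] * (1 - self.maf[k]) * self.beta_true[k] ** 2))


def _rescale_to_varexp(beta: np.ndarray, maf: np.ndarray, target: float) -> np.ndarray:
    """Scale effects so the additive variance sum(2p(1-p)beta^2) hits target."""
    current = np.sum(2 * maf * (1 - maf) * beta**2)
    return beta * np.sqrt(target / current)


def simulate_exposure_pool(
    spec: SimulationSpec,
    varexp: float,
    seed: Optional[int] = None,
    rng: Optional[np.random.Generator] = None,
) -> ExposurePool:
    """Draw one synthetic exposure GWAS pool.

    Per SNP: MAF ~ U(maf_range); tissue-labelled true effects drawn zero-mean
    normal then rescaled exactly so each tissue subset explains ``varexp`` of
    the exposure variance (the unlabelled remainder is rescaled to
    ``varexp_background``); estimated beta = true beta + noise with
    SE = 1/sqrt(2p(1-p) n_exposure_gwas); own-tissue PPA4 from ``ppa4_own``,
    cross- and unlabelled-tissue PPA4 from ``ppa4_cross``.
    """
    if rng is None:
        rng = _child_rng(spec.seed if seed is None else seed)
    P = spec.n_snps_pool
    na, nb = spec.n_adipose_like, spec.n_brain_like
    maf = rng.uniform(*spec.maf_range, P)
    labels = np.array(["adipose"] * na + ["brain"] * nb + ["none"] * (P - na - nb))

    beta_true = rng.normal(0.0, 1.0, P)
    for tissue, target in (("adipose", varexp), ("brain", varexp), ("none", spec.varexp_background)):
        k = labels == tissue
        if k.any() and target > 0:
            beta_true[k] = _rescale_to_varexp(beta_true[k], maf[k], target)
        elif k.any():
            beta_true[k] = 0.0

    se = 1.0 / np.sqrt(2 * maf * (1 - maf) * spec.n_exposure_gwas)
    beta_hat = beta_true + rng.normal(0.0, se)

    ppa4 = np.column_stack(
        [spec.ppa4_cross.sample(rng, P), spec.ppa4_cross.sample(rng, P)]
    )
    for k, tissue in enumerate(TISSUES):
        own = labels == tissue
        ppa4[own, k] = spec.ppa4_own.sample(rng, int(own.sum()))

    rsids = [f"rs{i:06d}" for i in range(P)]
    return ExposurePool(
        rsids=rsids,
        maf=maf,
        beta_true=beta_true,
        beta_hat=beta_hat,
        se=se,
        labels=labels,
        ppa4=ppa4,
        n_gwas=spec.n_exposure_gwas,
    )


@dataclass
class OutcomeSim:
    """Synthetic outcome GWAS matched to an exposure pool."""

    rsids: list[str]
    gamma_true: np.ndarray
    gamma_hat: np.ndarray
    se: np.ndarray
    n_outcome: int

    def to_sumstats(self, maf: np.ndarray, trait_name: str = "outcome") -> SummaryStats:
        z = self.gamma_hat / self.se
        P = len(self.rsids)
        df = pd.DataFrame(
            {
                "rsid": self.rsids,
                "chrom": [str(i % 22 + 1) for i in range(P)],
                "pos": [1_000_000 + 20_000_000 * (i // 22) for i in range(P)],
                "effect_allele": "A",
                "other_allele": "G",
                "eaf": maf,
                "beta": self.gamma_hat,
                "se": self.se,
                "pvalue": np.clip(2 * stats.norm.sf(np.abs(z)), 1e-300, 1.0),
                "n": self.n_outcome,
            }
        )
        return SummaryStats(df=df, trait_name=trait_name, n_total=self.n_outcome)


def simulate_outcome(
    pool: ExposurePool,
    theta: Sequence[float],
    n_outcome: int,
    seed: Optional[int] = None,
    rng: Optional[np.random.Generator] = None,
    model: str = "mediated",
) -> OutcomeSim:
    """Generate outcome summary statistics under per-tissue causal effects.

    ``theta`` gives one causal effect per tissue (TISSUES order).  True
    SNP-outcome effects follow the chosen generative model (module
    docstring); estimates add noise with SE = 1/sqrt(2p(1-p) n_outcome).
    """
    theta = np.asarray(theta, float)
    if theta.shape != (len(pool.tissues),):
        raise ValueError(f"theta must have {len(pool.tissues)} entries")
    if rng is None:
        rng = _child_rng(0 if seed is None else seed)
    if model == "mediated":
        gamma = (pool.beta_true[:, None] * pool.ppa4) @ theta
    elif model == "labelled":
        gamma = np.zeros_like(pool.beta_true)
        for k, tissue in enumerate(pool.tissues):
            own = pool.labels == tissue
            gamma[own] = theta[k] * pool.beta_true[own]
    else:
        raise ValueError(f"unknown outcome model {model!r}")
    se = 1.0 / np.sqrt(2 * pool.maf * (1 - pool.maf) * n_outcome)
    gamma_hat = gamma + rng.normal(0.0, se)
    return OutcomeSim(
        rsids=list(pool.rsids),
        gamma_true=gamma,
        gamma_hat=gamma_hat,
        se=se,
        n_outcome=n_outcome,
    )


# ---------------------------------------------------------------------------
# replication engine
# ---------------------------------------------------------------------------

def replicate_mvmr(
    spec: SimulationSpec,
    theta: Sequence[float],
    varexp: float,
    n_outcome: int,
    n_reps: int,
    cell_indices: tuple[int, ...] = (),
) -> pd.DataFrame:
    """Repeatedly simulate → select instruments → weighted MVMR.

    Each replicate draws a fresh pool, selects instruments at
    ``spec.ppa4_threshold``, builds the PPA4-weighted design from observed
    exposure betas, fits the multivariable IVW model and computes conditional
    F.  Returns one row per (rep, tissue) with estimate, se, pvalue,
    conditional_f, n_snp.  Uses the same numerical cores as
    :func:`tissuemr.mvmr.mvmr_ivw`.
    """
    rows = []
    for rep in range(n_reps):
        rng = _child_rng(spec.seed, *cell_indices, rep)
        pool = simulate_exposure_pool(spec, varexp, rng=rng)
        out = simulate_outcome(
            pool, theta, n_outcome, rng=rng, model=spec.outcome_model
        )
        sel = (pool.ppa4 >= spec.ppa4_threshold).any(axis=1)
        X = pool.beta_hat[sel, None] * pool.ppa4[sel]
        w = 1.0 / out.se[sel] ** 2
        est, se, q, q_df = _mvmr_wls(X, out.gamma_hat[sel], w)
        fstats = _conditional_f_arrays(X, pool.se[sel])
        pvals = 2 * stats.norm.sf(np.abs(est / se))
        for k, tissue in enumerate(pool.tissues):
            rows.append(
                {
                    "rep": rep,
                    "tissue": tissue,
                    "estimate": est[k],
                    "se": se[k],
                    "pvalue": pvals[k],
                    "conditional_f": fstats[k],
                    "n_snp": int(sel.sum()),
                }
            )
    return pd.DataFrame(rows)


def power_grid(spec: SimulationSpec) -> pd.DataFrame:
    """Rejection rates over the (effect, n_outcome, varexp) grid.

    For each cell the same per-tissue effect is applied to both tissues.
    Returns one row per (effect, n_outcome, varexp, tissue): rejection rate
    at ``spec.alpha``, mean estimate, empirical SE, mean conditional F,
    n_reps.  Fully deterministic given ``spec.seed``.
    """
    rows = []
    grid = itertools.product(
        enumerate(spec.effect_grid),
        enumerate(spec.n_outcome_grid),
        enumerate(spec.varexp_grid),
    )
    for (ie, effect), (inn, n_out), (iv, varexp) in grid:
        reps = replicate_mvmr(
            spec,
            theta=(effect,) * len(TISSUES),
            varexp=varexp,
            n_outcome=n_out,
            n_reps=spec.n_reps,
            cell_indices=(ie, inn, iv),
        )
        for tissue, sub in reps.groupby("tissue"):
            rows.append(
                {
                    "effect": effect,
                    "n_outcome": n_out,
                    "varexp": varexp,
                    "tissue": tissue,
                    "rejection_rate": float((sub["pvalue"] < spec.alpha).mean()),
                    "mean_estimate": float(sub["estimate"].mean()),
                    "empirical_se": float(sub["estimate"].std(ddof=1)),
                    "mean_conditional_f": float(sub["conditional_f"].mean()),
                    "n_reps": spec.n_reps,
                }
            )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# instrument-strength curve & synthetic instrument tables
# ---------------------------------------------------------------------------

def instrument_strength_curve(
    sets: Sequence[InstrumentSet],
    exposure: SummaryStats,
    counts: Sequence[int],
    n_samples: int = 100,
    seed: int = 0,
    ppa4_lookup: Optional[pd.DataFrame] = None,
) -> pd.DataFrame:
    """Mean conditional F when sampling a fixed number of instruments per tissue.

    For each count, draws that many instruments per tissue without
    replacement ``n_samples`` times and averages the conditional F over
    draws.  At the full set size the draw is the identity, so the value is
    the deterministic conditional F of the complete sets.
    """
    sizes = {s.tissue: len(s) for s in sets}
    for c in counts:
        if c > min(sizes.values()):
            raise ValueError(f"count {c} exceeds available instruments {sizes}")
    rows = []
    for ci, count in enumerate(counts):
        fsums = {s.tissue: [] for s in sets}
        n_draws = 1 if all(count == len(s) for s in sets) else n_samples
        for draw in range(n_draws):
            rng = _child_rng(seed, ci, draw)
            subsets = [
                InstrumentSet(
                    tissue=s.tissue,
                    df=s.df.iloc[np.sort(rng.choice(len(s), count, replace=False))],
                )
                for s in sets
            ]
            inp = build_weighted_design(subsets, exposure, ppa4_lookup=ppa4_lookup)
            for tissue, f in conditional_f(inp).items():
                fsums[tissue].append(f)
        for tissue, vals in fsums.items():
            rows.append(
                {
                    "count": count,
                    "tissue": tissue,
                    "mean_conditional_f": float(np.mean(vals)),
                    "n_samples": len(vals),
                }
            )
    return pd.DataFrame(rows)


def synthetic_instrument_tables(
    n_per_tissue: tuple[int, int] = (86, 140),
    mean_abs_beta: tuple[float, float] = (0.0148, 0.0149),
    n_gwas: int = 681_275,
    maf_range: tuple[float, float] = (0.05, 0.5),
    ppa4_own: TruncBeta = TruncBeta(8.0, 2.0, lower=0.8),
    ppa4_cross: TruncBeta = TruncBeta(1.0, 9.0),
    seed: int = 0,
    tissues: tuple[str, str] = TISSUES,
) -> tuple[list[InstrumentSet], SummaryStats, pd.DataFrame]:
    """SYNTHETIC stand-in for published tissue-partitioned instrument tables.

    Emulates the statistical structure of real adipose/brain BMI instrument
    sets: per-tissue counts, exposure-GWAS sample size, MAF-implied standard
    errors, threshold-passing own-tissue PPA4 and small cross-tissue PPA4.
    Absolute effects are half-normal draws rescaled exactly to the requested
    per-tissue mean |beta|.  Returns (instrument sets, exposure table,
    cross-tissue PPA4 lookup).  This is generated data, not the published
    tables themselves.
    """
    rng = _child_rng(seed)
    sets, exp_rows, lookup_rows = [], [], []
    counter = 0
    for k, tissue in enumerate(tissues):
        n = n_per_tissue[k]
        maf = rng.uniform(*maf_range, n)
        beta = np.abs(rng.normal(0.0, 1.0, n))
        beta *= mean_abs_beta[k] / beta.mean()  # exact mean-|beta| match
        beta *= rng.choice([-1.0, 1.0], n)
        se = 1.0 / np.sqrt(2 * maf * (1 - maf) * n_gwas)
        own = ppa4_own.sample(rng, n)
        cross = ppa4_cross.sample(rng, n)
        rsids = [f"rs{counter + i:06d}" for i in range(n)]
        counter += n
        sets.append(
            InstrumentSet(
                tissue=tissue,
                df=pd.DataFrame(
                    {
                        "rsid": rsids,
                        "beta": beta,
                        "se": se,
                        "gene": [f"GENE_{r}" for r in rsids],
                        "ppa4": own,
                    }
                ),
            )
        )
        other = tissues[1 - k]
        lookup_rows.append(pd.DataFrame({"rsid": rsids, "tissue": other, "ppa4": cross}))
        z = beta / se
        exp_rows.append(
            pd.DataFrame(
                {
                    "rsid": rsids,
                    "chrom": "1",
                    "pos": np.arange(counter - n, counter) * 20_000_000 + 1,
                    "effect_allele": "A",
                    "other_allele": "G",
                    "eaf": maf,
                    "beta": beta,
                    "se": se,
                    "pvalue": np.clip(2 * stats.norm.sf(np.abs(z)), 1e-300, 1.0),
                    "n": n_gwas,
                }
            )
        )
    exposure = SummaryStats(
        df=pd.concat(exp_rows, ignore_index=True),
        trait_name="synthetic_bmi",
        n_total=n_gwas,
    )
    return sets, exposure, pd.concat(lookup_rows, ignore_index=True)
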