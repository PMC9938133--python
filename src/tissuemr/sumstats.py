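"""Reading, validation, filtering, clumping and harmonisation of GWAS/eQTL
summary statistics.

Every downstream stage (colocalization, univariable MR, tissue-partitioned
MVMR) consumes the containers defined here.  A summary-statistics table is a
pandas DataFrame with canonical column names plus trait metadata; per-SNP
fields follow the usual GWAS conventions (beta in SD units for quantitative
traits, log-odds for binary traits; 1-based coordinates; a single genome
build per run).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger("tissuemr")

#: canonical column names every table must carry
CORE_COLUMNS = ("rsid", "effect_allele", "other_allele", "beta", "se", "pvalue")
#: canonical optional columns
OPTIONAL_COLUMNS = ("chrom", "pos", "eaf", "n", "gene_id")

#: genome-wide significance threshold used for instrument discovery
GENOME_WIDE_P = 5e-8

_COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}


class SumstatsError(ValueError):
    """Raised on malformed summary-statistics input."""


@dataclass(frozen=True)
class GenomicRegion:
    """1-based inclusive genomic interval on one chromosome."""

    chrom: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise SumstatsError(f"region start {self.start} > end {self.end}")

    def contains(self, chrom, pos) -> bool:
        return str(chrom) == str(self.chrom) and self.start <= pos <= self.end


#: extended major-histocompatibility-complex region excluded from instrument
#: discovery because of its long-range LD structure
HLA_REGION = GenomicRegion("6", 25_000_000, 35_000_000)


@dataclass
class SummaryStats:
    """One trait's per-SNP association estimates plus trait metadata.

    ``df`` columns: rsid, effect_allele, other_allele, beta, se, pvalue and
    optionally chrom, pos, eaf, n, gene_id.  Unique by
    (rsid, effect_allele, other_allele).
    """

    df: pd.DataFrame
    trait_name: str = "trait"
    trait_type: str = "quantitative"  # "quantitative" | "binary"
    n_total: Optional[int] = None
    n_case: Optional[int] = None
    n_control: Optional[int] = None

    def __post_init__(self) -> None:
        if self.trait_type not in ("quantitative", "binary"):
            raise SumstatsError(f"unknown trait_type {self.trait_type!r}")
        missing = [c for c in CORE_COLUMNS if c not in self.df.columns]
        if missing:
            raise SumstatsError(f"missing canonical columns: {missing}")

    def __len__(self) -> int:
        return len(self.df)

    @property
    def has_positions(self) -> bool:
        return "chrom" in self.df.columns and "pos" in self.df.columns

    def with_df(self, df: pd.DataFrame) -> "SummaryStats":
        return replace(self, df=df.reset_index(drop=True))

    def restrict(self, rsids: Sequence[str]) -> "SummaryStats":
        """Subset to the given rsids, preserving row order."""
        keep = self.df["rsid"].isin(set(rsids))
        return self.with_df(self.df.loc[keep])

    def in_region(self, region: GenomicRegion) -> "SummaryStats":
        if not self.has_positions:
            raise SumstatsError("table lacks chrom/pos columns")
        m = (self.df["chrom"].astype(str) == str(region.chrom)) & (
            self.df["pos"].between(region.start, region.end)
        )
        return self.with_df(self.df.loc[m])


@dataclass
class HarmonisedPairs:
    """Exposure/outcome estimates expressed on the exposure effect allele.

    One row per requested exposure SNP with columns: rsid, effect_allele,
    other_allele, beta_exp, se_exp, eaf_exp, beta_out, se_out, eaf_out,
    orientation ("kept" | "flipped" | "dropped"), reason (why a SNP was
    dropped, or "proxy-substituted" for retained proxy lookups) and
    proxy_rsid.
    """

    df: pd.DataFrame
    exposure_name: str = "exposure"
    outcome_name: str = "outcome"

    @property
    def kept(self) -> pd.DataFrame:
        """Retained rows only (orientation is kept or flipped)."""
        return self.df[self.df["orientation"] != "dropped"].reset_index(drop=True)

    @property
    def n_kept(self) -> int:
        return int((self.df["orientation"] != "dropped").sum())

    def write_tsv(self, path) -> None:
        self.df.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# reading & validation
# ---------------------------------------------------------------------------

def _normalise_chrom(c) -> str:
    s = str(c).strip()
    if s.lower().startswith("chr"):
        s = s[3:]
    return s.upper() if s.upper() == "X" else s


def validate_records(df: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Split a canonical-column DataFrame into valid rows and an exclusion log.

    Returns (clean, excluded) where ``excluded`` carries a ``reason`` column.
    Row order is preserved; duplicate rsids keep the smallest p-value.
    """
    df = df.copy()
    reasons = pd.Series(pd.NA, index=df.index, dtype="object")

    for col in ("beta", "se", "pvalue"):
        df[col] = pd.to_numeric(df[col], errors="coerce")
    for col in ("eaf", "pos", "n"):
        if col in df.columns:
            df[col] = pd.to_numeric(df[col], errors="coerce")
    if "chrom" in df.columns:
        df["chrom"] = df["chrom"].map(_normalise_chrom)
    for col in ("effect_allele", "other_allele"):
        df[col] = df[col].astype(str).str.upper().str.strip()

    def flag(mask: pd.Series, reason: str) -> None:
        new = mask & reasons.isna()
        reasons[new] = reason

    flag(~np.isfinite(df["se"]) | (df["se"] <= 0), "non-positive SE")
    flag(~np.isfinite(df["beta"]), "non-finite beta")
    flag(
        ~np.isfinite(df["pvalue"]) | (df["pvalue"] <= 0) | (df["pvalue"] > 1),
        "p-value outside (0,1]",
    )
    flag(df["effect_allele"] == df["other_allele"], "identical alleles")
    if "eaf" in df.columns:
        bad_eaf = df["eaf"].notna() & ((df["eaf"] <= 0) | (df["eaf"] >= 1))
        flag(bad_eaf, "allele frequency outside (0,1)")

    dup = df.sort_values("pvalue", kind="stable").duplicated(
        subset=["rsid", "effect_allele", "other_allele"], keep="first"
    )
    flag(dup.reindex(df.index), "duplicate record")

    excluded = df[reasons.notna()].assign(reason=reasons[reasons.notna()])
    clean = df[reasons.isna()]
    if len(excluded):
        counts = excluded["reason"].value_counts().to_dict()
        logger.info("excluded %d invalid rows: %s", len(excluded), counts)
    return clean.reset_index(drop=True), excluded.reset_index(drop=True)


def read_sumstats(
    path,
    dialect: Mapping[str, str],
    trait_name: str = "trait",
    trait_type: str = "quantitative",
    sep: Optional[str] = None,
    n_total: Optional[int] = None,
    n_case: Optional[int] = None,
    n_control: Optional[int] = None,
) -> SummaryStats:
    """Read delimited summary statistics using a canonical→file column mapping.

    ``dialect`` maps canonical names (rsid, effect_allele, other_allele, beta,
    se, pvalue, and optionally chrom, pos, eaf, n, gene_id) to header names in
    the file.  Invalid rows are excluded and logged with reasons; row order is
    preserved.  The delimiter is sniffed from the header line when ``sep`` is
    not given.
    """
    required = set(CORE_COLUMNS)
    if not required.issubset(dialect):
        raise SumstatsError(
            f"dialect must map at least {sorted(required)}; "
            f"missing {sorted(required - set(dialect))}"
        )
    if sep is None:
        with open(path) as fh:
            header = fh.readline()
        sep = "\t" if "\t" in header else ","
    raw = pd.read_csv(path, sep=sep)
    absent = [v for v in dialect.values() if v not in raw.columns]
    if absent:
        raise SumstatsError(f"dialect references absent columns: {absent}")
    df = raw[[dialect[k] for k in dialect]].copy()
    df.columns = list(dialect)
    clean, _excluded = validate_records(df)
    if clean.empty:
        raise SumstatsError(f"no valid rows in {path}")
    return SummaryStats(
        df=clean,
        trait_name=trait_name,
        trait_type=trait_type,
        n_total=n_total,
        n_case=n_case,
        n_control=n_control,
    )


# ---------------------------------------------------------------------------
# region exclusion & clumping
# ---------------------------------------------------------------------------

def exclude_region(table: SummaryStats, region: GenomicRegion) -> SummaryStats:
    """Drop all variants inside a genomic region (e.g. the HLA, chr6:25–35 Mb)."""
    if not table.has_positions:
        raise SumstatsError("exclude_region requires chrom/pos columns")
    df = table.df
    inside = (df["chrom"].astype(str) == str(region.chrom)) & df["pos"].between(
        region.start, region.end
    )
    n = int(inside.sum())
    if n:
        logger.info(
            "excluded %d variants in %s:%d-%d", n, region.chrom, region.start, region.end
        )
    return table.with_df(df.loc[~inside])


def clump(
    table: SummaryStats,
    p_threshold: float = GENOME_WIDE_P,
    r2_threshold: float = 0.01,
    ld: Optional[pd.DataFrame] = None,
    window_bp: int = 10_000_000,
) -> SummaryStats:
    """Greedy p-value clumping to approximately independent lead SNPs.

    SNPs are ranked by ascending p-value (ties broken by rsid, so the result
    is invariant to input row order).  A SNP is kept iff p < ``p_threshold``
    and it is independent of every already-kept SNP: squared correlation
    below ``r2_threshold`` when an LD matrix (signed r, rsid-indexed) is
    given, otherwise at least ``window_bp`` away from every kept SNP on the
    same chromosome.
    """
    df = table.df
    sig = df[df["pvalue"] < p_threshold]
    sig = sig.sort_values(["pvalue", "rsid"], kind="stable")
    if ld is None and not table.has_positions:
        raise SumstatsError("distance-mode clumping requires chrom/pos columns")
    if ld is not None:
        missing = set(sig["rsid"]) - set(ld.index)
        if missing:
            raise SumstatsError(f"LD matrix missing rsids: {sorted(missing)[:5]}")

    kept_idx: list[int] = []
    kept_rsid: list[str] = []
    kept_chrom: list[str] = []
    kept_pos: list[int] = []
    for idx, row in sig.iterrows():
        if ld is not None:
            if kept_rsid:
                r = ld.loc[row["rsid"], kept_rsid].to_numpy(dtype=float)
                if np.any(r**2 >= r2_threshold):
                    continue
        else:
            chrom, pos = str(row["chrom"]), int(row["pos"])
            clash = any(
                c == chrom and abs(p - pos) < window_bp
                for c, p in zip(kept_chrom, kept_pos)
            )
            if clash:
                continue
            kept_chrom.append(chrom)
            kept_pos.append(pos)
        kept_idx.append(idx)
        kept_rsid.append(row["rsid"])
    out = df.loc[kept_idx]
    logger.info("clumping kept %d of %d significant SNPs", len(out), len(sig))
    return table.with_df(out)


# ---------------------------------------------------------------------------
# harmonisation
# ---------------------------------------------------------------------------

def is_palindromic(ea: str, oa: str) -> bool:
    """A/T or C/G variants cannot be strand-resolved from alleles alone."""
    return _COMPLEMENT.get(ea) == oa


def _maf(eaf: float) -> float:
    return min(eaf, 1.0 - eaf)


def read_proxy_table(path) -> pd.DataFrame:
    """Read a proxy-lookup TSV: requested_rsid, proxy_rsid, r2,
    proxy_effect_allele, proxy_other_allele.

    ``proxy_effect_allele`` is the proxy's allele correlated with the
    requested SNP's effect allele (the allele map between the two variants).
    """
    df = pd.read_csv(path, sep="\t")
    need = {"requested_rsid", "proxy_rsid", "r2", "proxy_effect_allele", "proxy_other_allele"}
    if not need.issubset(df.columns):
        raise SumstatsError(f"proxy table must carry columns {sorted(need)}")
    return df


def _align_outcome(
    ea: str,
    oa: str,
    out_ea: str,
    out_oa: str,
    beta_out: float,
    eaf_out,
) -> tuple[Optional[str], float, float]:
    """Align one outcome record to the exposure alleles (non-palindromic).

    Returns (action, beta, eaf) with action in {"kept", "flipped", None};
    None means the allele pairs cannot be reconciled.  Strand flips
    (complement alleles) keep the sign; swapped alleles negate the beta.
    """
    comp_ea = _COMPLEMENT.get(out_ea)
    comp_oa = _COMPLEMENT.get(out_oa)
    eaf = eaf_out if eaf_out is not None and np.isfinite(eaf_out) else np.nan
    if (out_ea, out_oa) == (ea, oa):
        return "kept", beta_out, eaf
    if (out_ea, out_oa) == (oa, ea):
        return "flipped", -beta_out, 1.0 - eaf
    if (comp_ea, comp_oa) == (ea, oa):
        return "kept", beta_out, eaf
    if (comp_ea, comp_oa) == (oa, ea):
        return "flipped", -beta_out, 1.0 - eaf
    return None, beta_out, eaf


def harmonise(
    exposure: SummaryStats,
    outcome: SummaryStats,
    palindromic_maf_limit: float = 0.42,
    proxies: Optional[pd.DataFrame] = None,
    proxy_r2_min: float = 0.8,
) -> HarmonisedPairs:
    """Express exposure and outcome estimates on the exposure effect allele.

    Alleles are aligned to the exposure effect allele, flipping the outcome
    beta when the allele pair is swapped (directly or on the opposite
    strand).  Palindromic (A/T, C/G) variants are oriented by allele
    frequency when both minor-allele frequencies fall below
    ``palindromic_maf_limit``, and dropped as ambiguous otherwise.  SNPs
    absent from the outcome are replaced by a proxy (r² ≥ ``proxy_r2_min``)
    when a proxy table is supplied, else dropped.  Every decision is recorded
    in the returned table.
    """
    out_by_rsid = {r.rsid: r for r in outcome.df.itertuples(index=False)}
    proxy_by_rsid: dict[str, tuple] = {}
    if proxies is not None:
        for p in proxies.itertuples(index=False):
            if p.r2 >= proxy_r2_min and (
                p.requested_rsid not in proxy_by_rsid
                or p.r2 > proxy_by_rsid[p.requested_rsid].r2
            ):
                proxy_by_rsid[p.requested_rsid] = p

    rows = []
    for ex in exposure.df.itertuples(index=False):
        ea, oa = ex.effect_allele, ex.other_allele
        eaf_exp = getattr(ex, "eaf", np.nan)
        rec = {
            "rsid": ex.rsid,
            "effect_allele": ea,
            "other_allele": oa,
            "beta_exp": ex.beta,
            "se_exp": ex.se,
            "eaf_exp": eaf_exp,
            "beta_out": np.nan,
            "se_out": np.nan,
            "eaf_out": np.nan,
            "orientation": "dropped",
            "reason": pd.NA,
            "proxy_rsid": pd.NA,
        }

        ou = out_by_rsid.get(ex.rsid)
        out_ea, out_oa = None, None
        if ou is not None:
            out_ea, out_oa = ou.effect_allele, ou.other_allele
        elif ex.rsid in proxy_by_rsid:
            p = proxy_by_rsid[ex.rsid]
            ou = out_by_rsid.get(p.proxy_rsid)
            if ou is not None:
                # express proxy alleles in terms of the requested SNP's alleles
                rec["proxy_rsid"] = p.proxy_rsid
                rec["reason"] = "proxy-substituted"
                sub = {p.proxy_effect_allele: ea, p.proxy_other_allele: oa}
                out_ea = sub.get(ou.effect_allele)
                out_oa = sub.get(ou.other_allele)
                if out_ea is None or out_oa is None:
                    rec["reason"] = "allele-mismatch"
                    rows.append(rec)
                    continue
        if ou is None or out_ea is None:
            rec["reason"] = "missing-in-outcome"
            rows.append(rec)
            continue

        beta_out, se_out = ou.beta, ou.se
        eaf_out = getattr(ou, "eaf", np.nan)

        if is_palindromic(ea, oa):
            if not (out_ea, out_oa) in ((ea, oa), (oa, ea)):
                rec["reason"] = "allele-mismatch"
                rows.append(rec)
                continue
            if (out_ea, out_oa) == (oa, ea):
                # put the outcome record on the exposure's effect allele first
                beta_out = -beta_out
                eaf_out = 1.0 - eaf_out if np.isfinite(eaf_out) else np.nan
            if (
                not np.isfinite(eaf_exp)
                or not np.isfinite(eaf_out)
                or _maf(eaf_exp) >= palindromic_maf_limit
                or _maf(eaf_out) >= palindromic_maf_limit
            ):
                rec["reason"] = "palindromic-ambiguous"
                rows.append(rec)
                continue
            if (eaf_exp < 0.5) == (eaf_out < 0.5):
                rec["orientation"] = "kept"
            else:
                # frequencies disagree: outcome reported on the opposite strand,
                # which for a palindrome is the other allele
                beta_out = -beta_out
                eaf_out = 1.0 - eaf_out
                rec["orientation"] = "flipped"
        else:
            action, beta_out, eaf_out = _align_outcome(
                ea, oa, out_ea, out_oa, beta_out, eaf_out
            )
            if action is None:
                rec["reason"] = "allele-mismatch"
                rows.append(rec)
                continue
            rec["orientation"] = action

        rec["beta_out"] = beta_out
        rec["se_out"] = se_out
        rec["eaf_out"] = eaf_out
        rows.append(rec)

    df = pd.DataFrame(rows)
    n_drop = int((df["orientation"] == "dropped").sum())
    if n_drop:
        logger.info(
            "harmonisation dropped %d/%d SNPs: %s",
            n_drop,
            len(df),
            df.loc[df["orientation"] == "dropped", "reason"].value_counts().to_dict(),
        )
    return HarmonisedPairs(
        df=df, exposure_name=exposure.trait_name, outcome_name=outcome.trait_name
    )


def read_ld_matrix(path) -> pd.DataFrame:
    """Read a square signed-r LD matrix with an rsid header row and column."""
    ld = pd.read_csv(path, sep=None, engine="python", index_col=0)
    if ld.shape[0] != ld.shape[1] or list(ld.index) != list(ld.columns):
        raise SumstatsError("LD matrix must be square with matching rsid labels")
    return ld
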