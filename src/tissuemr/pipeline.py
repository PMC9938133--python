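"""End-to-end workflow orchestration from a single YAML configuration.

Stages: instrument derivation (clump → region exclusion → per-locus
colocalization per tissue → PPA4 threshold selection), univariable MR
(total-effect and per-tissue), tissue-partitioned MVMR with conditional-F
diagnostics.  Every output table carries a provenance header (config hash,
seed, package version) and all randomness flows from the configured seed.
"""

from __future__ import annotations

import hashlib
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import pandas as pd
import yaml

from . import __version__
from .coloc import (
    ColocPriors,
    ColocResult,
    InstrumentSet,
    coloc_abf,
    coloc_results_table,
    select_instruments,
)
from .mr import all_estimators, ivw
from .mvmr import build_weighted_design, mvmr_ivw
from .sumstats import (
    GenomicRegion,
    SummaryStats,
    clump,
    exclude_region,
    harmonise,
    read_ld_matrix,
    read_proxy_table,
    read_sumstats,
)

logger = logging.getLogger("tissuemr")


class PipelineError(RuntimeError):
    pass


@dataclass
class TraitFile:
    file: str
    dialect: dict
    name: str = "trait"
    trait_type: str = "quantitative"
    n_total: Optional[int] = None
    n_case: Optional[int] = None
    n_control: Optional[int] = None
    exposure_file: Optional[str] = None  # sex-stratified exposure override
    exposure_dialect: Optional[dict] = None

    def load(self) -> SummaryStats:
        return read_sumstats(
            self.file,
            self.dialect,
            trait_name=self.name,
            trait_type=self.trait_type,
            n_total=self.n_total,
            n_case=self.n_case,
            n_control=self.n_control,
        )


@dataclass
class EqtlFile:
    tissue: str
    file: str
    dialect: dict
    n_total: Optional[int] = None

    def load(self) -> SummaryStats:
        if "gene_id" not in self.dialect:
            raise PipelineError(f"eQTL dialect for {self.tissue} must map gene_id")
        return read_sumstats(
            self.file, self.dialect, trait_name=f"eqtl_{self.tissue}", n_total=self.n_total
        )


@dataclass
class RunConfig:
    """Validated run configuration (see ``RunConfig.from_yaml``)."""

    exposure: TraitFile
    outcomes: list[TraitFile]
    eqtls: list[EqtlFile]
    p_threshold: float = 5e-8
    r2_threshold: float = 0.01
    ppa4_threshold: float = 0.8
    clump_window_bp: int = 10_000_000
    ld_file: Optional[str] = None
    coloc_window_bp: int = 500_000
    coloc_priors: ColocPriors = field(default_factory=ColocPriors)
    region_exclusions: list[GenomicRegion] = field(default_factory=list)
    palindromic_maf_limit: float = 0.42
    proxy_file: Optional[str] = None
    proxy_r2_min: float = 0.8
    random_effects: bool = True
    n_boot: int = 1000
    min_snps: int = 3
    seed: int = 0
    output_dir: str = "tissuemr_out"
    config_hash: str = ""

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        text = Path(path).read_text()
        raw = yaml.safe_load(text)
        cfg = cls._from_dict(raw)
        cfg.config_hash = hashlib.sha256(text.encode()).hexdigest()[:12]
        cfg.validate()
        return cfg

    @classmethod
    def _from_dict(cls, raw: dict) -> "RunConfig":
        thresholds = raw.get("thresholds", {})
        coloc_cfg = raw.get("coloc", {})
        clump_cfg = raw.get("clump", {})
        harm = raw.get("harmonise", {})
        est = raw.get("estimators", {})
        priors = ColocPriors(
            **{
                k: coloc_cfg[k]
                for k in ("p1", "p2", "p12", "prior_sd_quant", "prior_sd_cc")
                if k in coloc_cfg
            }
        )
        regions = [
            GenomicRegion(str(r["chrom"]), int(r["start"]), int(r["end"]))
            for r in raw.get("region_exclusions", [])
        ]
        return cls(
            exposure=TraitFile(**raw["exposure"]),
            outcomes=[TraitFile(**o) for o in raw.get("outcomes", [])],
            eqtls=[EqtlFile(**e) for e in raw.get("eqtls", [])],
            p_threshold=float(thresholds.get("pvalue", 5e-8)),
            r2_threshold=float(thresholds.get("r2", 0.01)),
            ppa4_threshold=float(thresholds.get("ppa4", 0.8)),
            clump_window_bp=int(clump_cfg.get("window_bp", 10_000_000)),
            ld_file=clump_cfg.get("ld_file"),
            coloc_window_bp=int(coloc_cfg.get("window_bp", 500_000)),
            coloc_priors=priors,
            region_exclusions=regions,
            palindromic_maf_limit=float(harm.get("palindromic_maf_limit", 0.42)),
            proxy_file=harm.get("proxy_file"),
            proxy_r2_min=float(harm.get("proxy_r2_min", 0.8)),
            random_effects=bool(est.get("random_effects", True)),
            n_boot=int(est.get("n_boot", 1000)),
            min_snps=int(est.get("min_snps", 3)),
            seed=int(raw.get("seed", 0)),
            output_dir=str(raw.get("output_dir", "tissuemr_out")),
        )

    def validate(self) -> None:
        if not 0 < self.ppa4_threshold <= 1:
            raise PipelineError(f"ppa4 threshold outside (0,1]: {self.ppa4_threshold}")
        if not 0 < self.p_threshold < 1:
            raise PipelineError(f"p threshold outside (0,1): {self.p_threshold}")
        files = [self.exposure.file] + [o.file for o in self.outcomes] + [e.file for e in self.eqtls]
        files += [o.exposure_file for o in self.outcomes if o.exposure_file]
        if self.ld_file:
            files.append(self.ld_file)
        if self.proxy_file:
            files.append(self.proxy_file)
        for f in files:
            if not Path(f).exists():
                raise PipelineError(f"input file not found: {f}")


def write_tsv(df: pd.DataFrame, path, config: RunConfig) -> None:
    """Write a TSV with a provenance comment header."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        fh.write(
            f"# tissuemr {__version__} | config={config.config_hash} | seed={config.seed}\n"
        )
        df.to_csv(fh, sep="\t", index=False)


# ---------------------------------------------------------------------------
# stage 1: instrument derivation
# ---------------------------------------------------------------------------

def derive_lead_snps(config: RunConfig, exposure: SummaryStats) -> SummaryStats:
    """Clump to independent genome-wide-significant leads, then apply region
    exclusions (e.g. the HLA)."""
    ld = read_ld_matrix(config.ld_file) if config.ld_file else None
    leads = clump(
        exposure,
        p_threshold=config.p_threshold,
        r2_threshold=config.r2_threshold,
        ld=ld,
        window_bp=config.clump_window_bp,
    )
    for region in config.region_exclusions:
        leads = exclude_region(leads, region)
    return leads


def coloc_at_leads(
    config: RunConfig,
    exposure: SummaryStats,
    leads: SummaryStats,
    eqtl: SummaryStats,
) -> list[ColocResult]:
    """Colocalization at every lead-SNP locus against every proximal gene."""
    results: list[ColocResult] = []
    half = config.coloc_window_bp
    for i, lead in enumerate(leads.df.itertuples(index=False)):
        region = GenomicRegion(
            str(lead.chrom), max(1, int(lead.pos) - half), int(lead.pos) + half
        )
        exp_region = exposure.in_region(region)
        eqtl_region = eqtl.in_region(region)
        if not len(eqtl_region.df):
            continue
        for gene, gdf in eqtl_region.df.groupby("gene_id"):
            gene_trait = eqtl.with_df(gdf)
            try:
                results.append(
                    coloc_abf(
                        exp_region,
                        gene_trait,
                        priors=config.coloc_priors,
                        locus_id=lead.rsid,
                        gene_id=str(gene),
                    )
                )
            except Exception as exc:  # no overlap at this gene
                logger.debug("coloc skipped at %s/%s: %s", lead.rsid, gene, exc)
        if (i + 1) % 100 == 0:
            logger.info("coloc progress: %d/%d loci", i + 1, len(leads.df))
    return results


def run_instruments(
    config: RunConfig, write: bool = True
) -> tuple[dict[str, InstrumentSet], SummaryStats, SummaryStats, pd.DataFrame]:
    """Derive per-tissue instrument sets.

    Returns (sets by tissue, full exposure table, lead SNPs, cross-tissue
    PPA4 lookup).  Fails hard with a diagnostic when any tissue yields zero
    instruments (as happens for biologically irrelevant tissue panels, where
    only a handful of variants colocalize).
    """
    exposure = config.exposure.load()
    leads = derive_lead_snps(config, exposure)
    if not len(leads.df):
        raise PipelineError("no genome-wide-significant independent loci in exposure")
    logger.info("%d independent lead SNPs", len(leads.df))

    sets: dict[str, InstrumentSet] = {}
    lookup_rows = []
    outdir = Path(config.output_dir)
    for eq in config.eqtls:
        eqtl = eq.load()
        results = coloc_at_leads(config, exposure, leads, eqtl)
        iset = select_instruments(
            leads, results, ppa4_threshold=config.ppa4_threshold, tissue=eq.tissue
        )
        if len(iset) == 0:
            raise PipelineError(
                f"zero instruments colocalized for tissue {eq.tissue!r} at "
                f"PPA4 >= {config.ppa4_threshold}: the tissue panel may not be "
                f"biologically relevant for this exposure"
            )
        logger.info(
            "tissue %s: %d instruments, mean |beta| = %.4g",
            eq.tissue,
            len(iset),
            iset.mean_abs_beta,
        )
        sets[eq.tissue] = iset
        best = {}
        for r in results:
            if r.locus_id not in best or r.pp_h4 > best[r.locus_id]:
                best[r.locus_id] = r.pp_h4
        lookup_rows.append(
            pd.DataFrame(
                {"rsid": list(best), "tissue": eq.tissue, "ppa4": list(best.values())}
            )
        )
        if write:
            write_tsv(iset.df.assign(tissue=eq.tissue), outdir / f"instruments_{eq.tissue}.tsv", config)
            write_tsv(coloc_results_table(results), outdir / f"coloc_{eq.tissue}.tsv", config)
    lookup = (
        pd.concat(lookup_rows, ignore_index=True)
        if lookup_rows
        else pd.DataFrame(columns=["rsid", "tissue", "ppa4"])
    )
    return sets, exposure, leads, lookup


# ---------------------------------------------------------------------------
# stage 2: MR analyses
# ---------------------------------------------------------------------------

def run_mr(
    config: RunConfig,
    sets: dict[str, InstrumentSet],
    exposure: SummaryStats,
    leads: SummaryStats,
    ppa4_lookup: Optional[pd.DataFrame] = None,
    write: bool = True,
) -> pd.DataFrame:
    """Univariable (total and per-tissue) and tissue-partitioned MVMR per outcome."""
    proxies = read_proxy_table(config.proxy_file) if config.proxy_file else None
    rows = []
    for out_cfg in config.outcomes:
        outcome = out_cfg.load()
        # sex-stratified designs substitute matched exposure estimates
        if out_cfg.exposure_file:
            exp_used = read_sumstats(
                out_cfg.exposure_file,
                out_cfg.exposure_dialect or config.exposure.dialect,
                trait_name=f"{config.exposure.name}_{out_cfg.name}",
            )
        else:
            exp_used = exposure
        leads_used = leads if exp_used is exposure else exp_used.restrict(leads.df["rsid"])

        pairs = harmonise(
            leads_used,
            outcome,
            palindromic_maf_limit=config.palindromic_maf_limit,
            proxies=proxies,
            proxy_r2_min=config.proxy_r2_min,
        )
        if pairs.n_kept < config.min_snps:
            raise PipelineError(
                f"harmonisation left {pairs.n_kept} < {config.min_snps} SNPs "
                f"for outcome {out_cfg.name!r}"
            )
        total = all_estimators(pairs, n_boot=config.n_boot, seed=config.seed)
        for rec in total.to_dict("records"):
            rows.append({"outcome": out_cfg.name, "analysis": "total", "tissue": "all", **rec})

        for tissue, iset in sets.items():
            tpairs = harmonise(
                exp_used.restrict(iset.rsids),
                outcome,
                palindromic_maf_limit=config.palindromic_maf_limit,
                proxies=proxies,
                proxy_r2_min=config.proxy_r2_min,
            )
            res = ivw(tpairs, random_effects=config.random_effects)
            rows.append(
                {
                    "outcome": out_cfg.name,
                    "analysis": "univariable_tissue",
                    "tissue": tissue,
                    **res.as_dict(),
                }
            )

        if len(sets) >= 2:
            inp = build_weighted_design(
                list(sets.values()),
                exp_used,
                outcome,
                ppa4_lookup=ppa4_lookup,
                palindromic_maf_limit=config.palindromic_maf_limit,
                proxies=proxies,
            )
            mv = mvmr_ivw(inp, random_effects=config.random_effects)
            for rec in mv.table.to_dict("records"):
                rows.append(
                    {
                        "outcome": out_cfg.name,
                        "analysis": "mvmr_tissue",
                        "method": "mvmr_ivw",
                        **rec,
                    }
                )
    results = pd.DataFrame(rows)
    if write:
        write_tsv(results, Path(config.output_dir) / "mr_results.tsv", config)
    return results


def run_all(config: RunConfig, write: bool = True) -> pd.DataFrame:
    """Full pipeline: instruments then MR; returns the combined results table."""
    sets, exposure, leads, lookup = run_instruments(config, write=write)
    return run_mr(config, sets, exposure, leads, ppa4_lookup=lookup, write=write)
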