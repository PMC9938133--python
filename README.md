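# tissuemr

Tissue-partitioned two-sample Mendelian randomisation (MR): separate the
contributions of distinct tissue-mediated subcomponents of a heterogeneous
exposure — the motivating example is body mass index (BMI), split into
"adipose-like" and "brain-like" components — to disease outcomes, using
only GWAS and eQTL summary statistics.

The package is aimed at genetic epidemiologists who already run two-sample
MR from summary data and want to ask *which tissue's biology carries the
effect*, plus a simulation engine to decide whether a given design
(instrument count, variance explained, outcome GWAS size) is adequately
powered for that question.

## Method

1. **Instruments.** Clump the exposure GWAS to independent
   genome-wide-significant lead SNPs (P < 5×10⁻⁸, r² < 0.01 or a distance
   window), excluding the HLA region (chr6:25–35 Mb). At each lead locus,
   test colocalization with each proximal gene's eQTLs per tissue using
   Wakefield approximate Bayes factors: with z = β/SE, V = SE²,
   W = prior SD², r = W/(V+W),

       log ABF = ½ log(1−r) + ½ r z²,

   and single-causal-variant enumeration over hypotheses H0–H4. A lead SNP
   joins tissue *t*'s instrument set iff its posterior probability of a
   shared causal variant, PPA4, is ≥ 0.8 for some gene.

2. **Tissue-partitioned MVMR.** Build the weighted design
   B*[i,t] = β̂_exposure,i × PPA4_{i,t} over the union of instrument sets and
   regress harmonised SNP-outcome betas on all tissue columns jointly
   (no intercept, weights 1/SE_out²). Per-tissue coefficients θ̂ₜ are the
   tissue-level "direct" contributions; instrument strength per tissue is
   the conditional F-statistic Fₜ = Σwᵢ residᵢ²/(L−K+1) (exposure-precision
   weights, residuals from projecting tissue t's column on the others),
   with F > 10 the usual adequacy rule.

3. **Supporting analyses.** Univariable IVW / MR-Egger / weighted median /
   penalised weighted median for total effects; PPA4-threshold sensitivity
   of conditional F; a fully seeded power grid over effect size, outcome
   sample size and variance explained.

See `docs/methods.md` for models, defaults and numerical choices.

## Worked example

Simulate a realistic design (915 independent exposure loci from a GWAS of
n = 700,000; 86 adipose-like and 140 brain-like instruments each explaining
1% of exposure variance; outcome GWAS of n = 75,000; true per-tissue
effects 0.1 and 0.125) and recover the tissue effects:

```python
from tissuemr import (SimulationSpec, simulate_exposure_pool, simulate_outcome,
                      build_weighted_design, mvmr_ivw)

spec = SimulationSpec(seed=42)
pool = simulate_exposure_pool(spec, varexp=0.01, seed=42)
outcome = simulate_outcome(pool, theta=(0.1, 0.125), n_outcome=75_000, seed=43)

sets = pool.instrument_sets(threshold=0.8)          # PPA4 >= 0.8 per tissue
design = build_weighted_design(
    sets, pool.to_sumstats(), outcome.to_sumstats(pool.maf),
    ppa4_lookup=pool.ppa4_lookup(),
)
result = mvmr_ivw(design)
print(result.table[["tissue", "estimate", "se", "pvalue", "conditional_f", "n_snp"]]
      .round(4).to_string(index=False))
```

```
 tissue  estimate     se  pvalue  conditional_f  n_snp
adipose    0.1088 0.0446  0.0147        22.8363    226
  brain    0.1092 0.0430  0.0111        24.5556    226
```

Both tissue estimates land within one standard error of their true values
(0.1 and 0.125); conditional F ≈ 23–25 per tissue means neither component
is weakly instrumented (rule of thumb F > 10), so the two "forms" of the
exposure are separable in one joint model. For a binary outcome the
estimates are log odds ratios: `exp(estimate)` is the OR per SD of the
tissue-instrumented exposure.

## Command line

Real data flows through a YAML config (exposure, per-tissue eQTL and
outcome files with column-name dialects, thresholds, seeds):

```sh
tissuemr instruments --config run.yaml   # clump -> coloc -> PPA4 selection
tissuemr mr          --config run.yaml   # univariable + tissue-partitioned MVMR
tissuemr power       --seed 1 --out power_grid.tsv
```

All outputs are TSVs with a provenance header (package version, config
hash, seed); reruns are byte-identical.

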