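# Methods

`tissuemr` implements tissue-partitioned two-sample Mendelian randomisation
(MR): it splits a heterogeneous exposure such as body mass index (BMI) into
tissue-specific components by weighting each genetic instrument's
SNP-exposure effect with its posterior probability of colocalization against
tissue eQTLs, and estimates the separate per-tissue contributions to an
outcome in a multivariable inverse-variance-weighted (IVW) model. This note
records the models, the defaults and why, the numerical choices, and what
the synthetic-data engine does and does not emulate.

## 1. Instrument derivation

**Clumping.** Genome-wide-significant exposure SNPs (P < 5×10⁻⁸) are reduced
to approximately independent leads by greedy p-value ranking: a SNP is kept
iff its squared correlation with every already-kept SNP is below r² = 0.01
(when a signed-r LD matrix is supplied) or it lies at least `window_bp`
away from every kept SNP on the same chromosome (distance mode, default
10 Mb). The 10 Mb default is deliberately conservative: for synthetic
workflows without LD it guarantees independence at least as strict as
r² < 0.01. p-value ties break by rsid lexicographic order, making the
selection invariant to input row order.

**Region exclusion.** The extended MHC/HLA region (chr6:25–35 Mb, 1-based
inclusive) is excluded by default because its long-range LD structure
invalidates the single-causal-variant assumption used downstream.
Coordinates are 1-based inclusive throughout; a single genome build per run
is assumed and never lifted over.

**Colocalization.** At each lead locus (±500 kb by default, configurable)
and for each gene with eQTL records in the window, evidence that the
exposure GWAS and the eQTL share one causal variant is computed with
approximate Bayes factors. Per SNP, with z = β/SE, V = SE², W = prior SD²
and shrinkage r = W/(V+W),

    log ABF = ½·log(1−r) + ½·r·z².

Per-hypothesis evidence (H0 none, H1/H2 one trait only, H3 two distinct
causal SNPs, H4 one shared causal SNP) sums over causal-SNP configurations
in log space via log-sum-exp, so z-scores up to ~100 (routine in
large-biobank GWAS) cause no overflow. Priors default to the published
defaults of the colocalization method: p1 = p2 = 1×10⁻⁴, p12 = 1×10⁻⁵,
effect prior SD 0.15 for quantitative traits and 0.2 on the log odds for
case-control traits. SNPs present in only one trait in a window are ignored
(intersection matching).

**Selection.** A lead SNP enters a tissue's instrument set iff its maximum
posterior probability of the shared-variant hypothesis (PPA4) over tested
genes is ≥ 0.8, the threshold recommended by the method's authors; the
maximum is the only reduction consistent with "evidence of colocalization"
at the variant level, and the attaining gene is recorded. Zero instruments
for a tissue is a hard, diagnostic failure — that is the expected behaviour
when a tissue panel is biologically irrelevant to the exposure.

## 2. Harmonisation

Exposure and outcome estimates are expressed on the exposure effect allele.
Swapped allele pairs (directly or on the opposite strand) flip the outcome
beta; palindromic (A/T, C/G) variants are oriented by allele frequency when
both minor-allele frequencies are below 0.42 (a common MR-harmonisation
convention; effect-allele frequencies on the same side of 0.5 mean the same
orientation) and dropped as ambiguous otherwise, including when a frequency
is missing. SNPs absent from the outcome can be replaced from a
user-supplied proxy table when the proxy r² ≥ 0.8 (the default of the
platform that popularised automatic proxy lookup); building LD references
is out of scope. Every decision (kept / flipped / dropped, with reason) is
recorded in the output.

## 3. Univariable estimators

Four summary-data estimators, matching the conventional two-sample MR
toolkit:

- **IVW**: WLS of outcome on exposure betas through the origin, weights
  1/SE_out². The SE carries a multiplicative random-effects scaling
  max(1, √(Q/(L−1))) by default (fixed-effect via flag); a single SNP
  reduces to the Wald ratio with first-order delta SE.
- **MR-Egger**: the same regression with an intercept after re-orienting
  all exposure betas positive; the intercept is the directional-pleiotropy
  test (df L−2).
- **Weighted median**: per-SNP ratios ordered ascending with normalised
  inverse-variance weights (ratio variance SE_out²/β_exp² by the
  first-order delta method, chosen for oracle reproducibility; a
  second-order option exists), estimate at cumulative weight ½ with the
  midpoint convention and linear interpolation; SE by parametric bootstrap
  (default 1000 replicates, mandatory seed, bit-reproducible).
- **Penalised weighted median**: each SNP's heterogeneity contribution
  Qᵢ = wᵢ(ratioᵢ−est)² is converted to a χ²₁ upper-tail probability qᵢ and
  weights become wᵢ·min(1, 20·qᵢ) (penalty 20, the published convention)
  before recomputing the median.

Binary outcomes are on the log-odds scale; odds ratios are exp(estimate)
with CI exp(estimate ± 1.96·SE) and normal-approximation p-values.

## 4. Tissue-partitioned MVMR

The weighted design has one column per tissue, B*[i,t] = β_exposure,i ×
PPA4_{i,t}, over the deduplicated union of the tissue instrument sets; a
SNP with no colocalization result for a tissue carries 0, and sub-threshold
cross-tissue PPA4 values can be filled from the full colocalization output.
Per-tissue direct effects come from joint no-intercept WLS of harmonised
outcome betas on all columns, weights 1/SE_out², with the same
random-effects SE floor. Designs with condition number above 1×10⁸ abort
with an explicit collinearity error rather than returning silent output.

**Exposure SEs are not rescaled by PPA4.** The weight shrinks the point
estimate only, so a down-weighted SNP contributes less signal but keeps its
full sampling uncertainty in the strength diagnostics — the conservative
reading; `rescale_se=True` gives the alternative.

**Conditional F.** For tissue t, its weighted column is regressed on all
other columns by WLS with exposure-precision weights 1/SE_exp² (pairwise
exposure covariances taken as zero, the behaviour of the standard
conditional-F implementation when no phenotypic covariance is supplied);
with L SNPs and K exposures, F_t = Σᵢ wᵢ·residᵢ² / (L−K+1). F > 10 is the
conventional weak-instrument rule. When the other columns are zero this
reduces exactly to Σw·B*²/(L−1). A threshold-sensitivity routine re-derives
the instrument sets over a grid of PPA4 cut-offs and reports the F pair per
threshold: lower thresholds admit weaker instruments, which is why the 0.8
default is advocated.

Note that with two identical-count tissues of homogeneous strength,
F ≈ c·(A+B)/(2c−1) for c instruments per tissue — approximately the mean
per-instrument conditional strength, essentially flat (mildly decreasing)
in c. What grows with instrument count is the total conditional signal
Q = F·(L−K+1); both are reported in the strength-curve output's terms.

## 5. Simulation engine

Summary statistics are generated directly at the summary level — no
individual-level genotypes — matching two-sample MR practice and keeping
the full grid at desk scale.

Per SNP of a pool of 915 independent loci (the reference count for adult
BMI): MAF ~ U(0.05, 0.5); true effects for the 86 "adipose-like" and 140
"brain-like" subsets are drawn zero-mean normal and rescaled exactly so
each subset's additive variance Σ2p(1−p)β² equals the target variance
explained (grid 0.5%–3%); the unlabelled remainder carries a background 4%
(a modest figure for the residual polygenic signal of genome-wide
significant loci outside the tissue subsets). Estimated betas add noise
with SE = 1/√(2p(1−p)·n), n = 700,000 for the exposure. Own-tissue PPA4 is
drawn from Beta(8,2) truncated to ≥ 0.8 (threshold-passing by
construction), cross-tissue and unlabelled PPA4 from Beta(1,9). These
distribution families are this package's declared defaults — the reference
study names only the grid and pool size — and all are overridable in
`SimulationSpec`.

**Outcome models.** The default, "mediated", takes PPA4 as the fraction of
a SNP's exposure effect acting through the tissue: γᵢ = Σₜ θₜ·βᵢ·PPA4ᵢₜ.
This is the identifying assumption under which PPA4-weighted MVMR is
consistent, and it is what makes the parameter-recovery and coverage
checks meaningful tests of the estimator's sampling behaviour rather than
of model misspecification. The alternative "labelled" model
(γᵢ = θ_tissue(i)·βᵢ for labelled SNPs, else 0) treats PPA4 as pure noise
around a hard tissue assignment; under it the weighted estimator is
inflated by roughly E[p]/E[p²] of the own-tissue PPA4 distribution (~13%
at the defaults) — the same scale non-invariance the design's own
1/c-scaling property implies. Both are exposed; interpret "mediated"
results as estimator calibration and "labelled" results as sensitivity to
PPA4 misinterpretation.

**Determinism.** Every cell/replicate seeds a fresh generator by the
documented rule `default_rng((master_seed, *cell_indices, rep))`, so grids
are reproducible cell-by-cell and extensible without perturbing other
cells.

**What the generator does not emulate:** LD between loci, population
stratification, sample overlap between exposure and outcome GWAS,
winner's-curse selection of instruments, or errors in the colocalization
posteriors themselves. Passing tests therefore demonstrate the estimator's
behaviour under clean two-sample assumptions with known mediation
structure, not robustness to those real-data complications.

**Problem sizes.** The power grid runs 3 effects × 5 outcome sizes × 6
variance-explained levels at 200 replicates per cell by default (~40 s);
calibration checks use 1000 replicates at the reference cell (variance
explained 1%, outcome n = 75,000), chosen to make the Monte-Carlo error on
coverage about 0.7 percentage points. The acceptance script uses 500
replicates per quantity for the same reason at half the cost.

**Synthetic instrument tables.** `synthetic_instrument_tables` is a
clearly-labelled synthetic stand-in for published tissue-partitioned
instrument tables: per-tissue counts (86/140 adult, 56/53 childhood),
half-normal absolute effects rescaled exactly to the published mean |β|
(0.0148/0.0149 SD per allele adult, 0.013 childhood), SEs implied by MAF
and the exposure GWAS size (n = 681,275), and the PPA4 distributions
above. Only the mean effect is pinned; the distribution family is a
modelling choice, so quantities computed from these tables (e.g. mean
conditional F at 30 sampled instruments per tissue, ≈ 34 at the defaults)
carry generator-level spread of roughly ±15% across table draws.

## 6. Known limitations

- Single-causal-variant colocalization only; loci with allelic
  heterogeneity will under-call sharing.
- Conditional F uses the covariance-zero weighting; with correlated
  exposure measurement errors it is only an approximation.
- The pipeline assumes one genome build and rsid-keyed matching; no
  liftover, no GWAS-VCF ingestion, no LD-panel construction.
- Tissue-partitioned estimates are not ordinary causal effects of the
  exposure; they quantify the contribution of instrument subsets defined
  by tissue colocalization and should be interpreted accordingly.
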