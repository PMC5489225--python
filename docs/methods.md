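# Methods

This note documents the models, conventions and design choices behind
`vqscreen`, in the spirit of a statistical-software methods appendix. It
states no empirical claim that the test suite or `scripts/acceptance.py`
does not itself compute.

## Trait preparation

Raw traits are assumed positive (BMI-like). Preparation is strictly
ordered: log10, then z-score with the *sample* SD (n−1 denominator), then
winsorization (clamping) at ±4 SD. The mean/SD used, the winsor limit and
the number of clamped values are recorded in a transform log so any
downstream consumer can reproduce the mapping. Two deliberate choices:

- **No re-standardization after clamping.** Clamping slightly shrinks the
  SD below 1; we leave it. Levene's statistic is scale-invariant, so this
  affects nothing downstream, and re-standardizing would obscure the
  recorded transform.
- **Per-cohort preparation.** Each cohort log-transforms and z-scores its
  own trait before computing summaries, consistent with a design in which
  cohorts submit summary statistics centrally and never pool raw data.
  Per-SNP sample sizes may differ (listwise exclusion per SNP), so N is
  carried per SNP.

## The deviation score and the meta-analysis Levene test

For each SNP, genotype classes are the rounded dosages (an optional
hard-call threshold sets dosages far from any integer to missing; the
default accepts all, since the generator produces hard calls). The
deviation score is Z = |Y − Ȳ_g| with Ȳ_g the mean of the individual's own
genotype group, computed within cohort. Cohort *s* contributes, per SNP:
counts n_is, means Z̄_is, and sample variances σ²_Zis (n−1 denominator;
undefined and transmitted as missing when n_is < 2).

The combined statistic uses the natural weights ω_is = n_is/n_i,
γ_i = n_i/N. Pooled group means Z̄_i = Σ_s ω_is Z̄_is and the grand mean
Z̄ = Σ_i γ_i Z̄_i are exact, so the between-group term
Σ_i γ_i Z̄_i² − Z̄² equals SSB/N of the one-way ANOVA on Z. The within-group
term is reconstructed from the transmitted moments as

    SSW/N = Σ_is [ (n_is − 1) σ²_Zis + n_is Z̄_is² ] / N − Σ_i γ_i Z̄_i² .

The variance correction enters as (n_is − 1)σ²_Zis/N — equivalently
ω_is σ²_Zis γ_i minus σ²_Zis/N per study-group. This is the one algebraic
reading under which a single cohort reproduces the classical mean-centred
Levene statistic *exactly*; that equivalence is enforced by a
1,000-dataset oracle test at 1e-8 relative tolerance and is the contract
that pins down the formula. L = (N−3)/2 · (SSB/N)/(SSW/N) is compared to
F(2, N−3). Groups with n_is = 1 contribute their mean but zero within-group
variance, which is exact.

Skip rules: a SNP needs all three genotype groups after pooling
(`NO_3_GROUPS` otherwise) and df2 = N−3 ≥ 1. A zero denominator with a
positive numerator (deviations constant within every group) yields an
infinite statistic and the floored P-value. P-values are floored at 1e-300
rather than underflowing to 0.

The individual-level route (`levene_direct`) delegates to scipy's
mean-centred Levene implementation and exists as the independent oracle and
for users holding raw data; the summary-statistic path never calls it.

## Quality control

Defaults: imputation info ≥ 0.3, HWE P ≥ 1e-6 (1-df goodness-of-fit
against expectations from the observed allele frequency; monomorphic SNPs
pass by convention), genotype call rate ≥ 0.95, MAF ≥ 1%, and ≥ 30
observations in *every* genotype group per cohort (strict mode; a
permissive mode tolerates an absent rare-homozygote group for users who
want those cohorts to contribute partial information). A SNP×cohort pair
must pass all filters; every exclusion is logged with the first failing
filter as its reason code. Allele harmonization across cohorts flips
swapped orientations (reversing the group order and frequency), resolves
strand-ambiguous A/T and C/G SNPs by allele frequency only when both
frequencies are at least 0.15 from 0.5, and drops them otherwise.

## Scans and the interaction test

The marginal scan is additive OLS of the prepared trait on dosage, two-sided
P from t with n−2 df, per-SNP complete cases, no covariates (a deliberate
simplification: the screen's external marginal statistics come from
consortium meta-analyses in practice; the internal scan exists so the
simulation pipeline is self-contained). The stratified scan runs the same
OLS within exposed and unexposed strata and compares slopes with
z = (β₁−β₀)/√(se₁²+se₀²), two-sided normal P — identical to a 1-df
Cochran's Q. With an all-zero exposure the exposed stratum is flagged and
the unexposed results equal the marginal scan exactly (tested).

## LD pruning

Greedy windowed pruning: within each placement of a `window`-SNP window
(advanced by `step`), any retained pair with squared Pearson correlation
above `r2_max` loses one member. The removal rule — drop the SNP with the
lower sample MAF, ties drop the later-positioned SNP — makes the procedure
fully deterministic. Defaults 50/5/0.1 with 0.8 as the alternate threshold
for odds-ratio analyses on a denser set. A post-condition audit re-scans
every window of the kept set; the acceptance suite runs it at both
thresholds. r² is pairwise-complete over missing dosages; zero-variance
columns contribute r² = 0 rather than an error.

## Rank and enrichment machinery

- **Percentile ranks**: ascending average ranks r of the P-values mapped to
  100·(m−r+1)/m, so the smallest P is the 100th percentile and ties share a
  value. Average ranks are used everywhere (Spearman, Mann-Whitney tie
  correction) — the convention the field's standard tools default to.
- **Centile bands**: "100th centile" means percentile > 99; "99th centile"
  means (98, 99]; half-open on the left.
- **Rank-shift tests**: Mann-Whitney on the tested P-type's percentiles
  between a band of the splitting P-type and the rest, two-sided; exact
  null distribution on small tie-free samples, normal approximation with
  tie correction otherwise (scipy's policy, which the exhaustive-enumeration
  oracle in the tests pins down for n₁+n₂ ≤ 10). When known loci (or SNPs
  within ±500 kb of one, boundary inclusive) are excluded, percentiles are
  recomputed on the surviving set before splitting, so band boundaries
  refer to the post-exclusion distribution.
- **Enrichment**: one-sided upper-tail exact binomial P(X ≥ k) at null rate
  0.05 by default (a two-sided option exists behind a flag). The
  average-rank variant across two interaction scans uses success = average
  percentile > 95 with null rate 0.05, matching the single-scan nominal
  rate.
- **Odds ratios**: cross-product with Woolf CI; Haldane 0.5 correction on
  any zero cell (flagged); undefined when a diagonal is zero.
- **Equality of correlations**: independent-samples Fisher-z form. The
  subsets compared in practice are nested (e.g. "known loci" inside "all
  pruned SNPs"), which this form ignores; we document rather than silently
  alter it, since the overlap is small in the intended use and the
  dependent-correlations alternative requires the cross-correlation the
  summary data do not carry. Degenerate inputs (|ρ| = 1 or n ≤ 3) flag the
  report instead of erroring the pipeline.
- **No multiplicity correction** anywhere: the screen reports nominal
  P-values, and reports carry the number of tests for the reader.

## Synthetic cohorts

The generator emulates a multi-cohort quantitative-trait study: independent
SNPs in HWE with MAF uniform on (0.01, 0.5]; a sparse effect architecture
(default 5% of SNPs with β ~ N(0, 0.02²) z-units per allele, GWAS-like); a
binary exposure with 30% prevalence; and a latent trait

    U = Gβ + a·E + (Gδ)·E + ε ,     raw trait = 10^U ,

so that preparation (log10 → z) recovers a standardized U exactly. The
default has no interaction effects and no exposure main effect: interaction
and enrichment statistics then operate under their null, which is what the
calibration study requires. Scenario code turns effects on explicitly.

**Error model.** ε is a shifted log-normal scaled to SD 1 (mean-zero), with
log-scale shape σ_log = 0.11, giving transformed-trait skewness ≈ 0.3 —
the mild right skew typical of a log-transformed anthropometric trait. The
shape matters: the mean-centred Levene test's type-I rate grows with
skewness (measured in this package's own calibration machinery: ≈ 0.054 at
skewness 0.30, ≈ 0.060 at 0.50, ≈ 0.072 at 0.77 under the default study
conditions), so the default sits where the test's nominal 5% level is
actually held. A normal error family is available and is used where a
calibrated-by-construction reference is wanted.

**Multiple exposures.** The phenotype model accepts an (n, q) exposure
matrix with a per-SNP map of which exposure its δ engages; the exposure
main effect and the stratified scan always use exposure 0. This expresses
the screen's core premise — variance heterogeneity aggregates interactions
across exposures the interaction test never sees — and is what the
recovery scenario below uses.

**What the generator does not model**: LD (SNPs are independent by default,
matching a pruned marker set; an autoregressive block-LD generator exists
solely to exercise the pruner), population structure, relatedness, and
imputation uncertainty (genotypes are hard calls; a dosage-noise option
exercises the hard-calling path). Passing tests therefore demonstrate the
statistical machinery's correctness and calibration under the stated
generating model, not robustness to confounding or structure in real
cohorts.

**Determinism.** A fixed spec and seed give byte-identical data and
byte-identical pipeline output (fixed 10-significant-digit text formats,
'.' for missing). Replicate r of a study seeded s draws from
`default_rng([s, r])`, so replicates are independent and reproducible in
any order.

## Study harnesses and the problem sizes used

`run_pipeline` chains simulate → prepare → summarize → QC → meta-Levene →
marginal/stratified scans → prune → rank table → reports, logging row
counts at every stage (SNPs in = SNPs out + logged exclusions).

`run_null_calibration` repeats the three comparison analyses (pairwise
Spearman correlation P among P_m/P_v/P_int; binomial enrichment of
P_v < 0.05 among P_m < 0.05 and among P_int < 0.05; Mann-Whitney
top-centile shifts in both directions) on freshly simulated replicates and
summarizes each P-value collection with Kolmogorov-Smirnov statistics, both
two-sided and one-sided. The one-sided variant (empirical CDF above
uniform = excess of small P-values) is the calibrated check for the
enrichment tests: their P-values are discrete at desk scale (eligible sets
of ~100 SNPs give probability atoms up to ~0.18), discreteness pushes the
CDF *below* uniform, and a two-sided test would flag that granularity as
miscalibration. Full-scale runs of the original design used thousands of
replicates at 44,000 × 50,335; the test suite runs 200 replicates of
2,000 × 2,000 (under the marginal-only, normal-error architecture for the
uniformity checks, and the all-null skewed-error architecture for the
rejection-rate check, pooled across replicates so the binomial standard
error is small relative to the [0.04, 0.06] band), the package's chosen
desk scale.

`run_power_study` sweeps an interaction-effect grid, pinning designated
SNPs' δ at exactly the grid value, and reports detection rates of P_v and
P_int plus the OR of P_int < 0.05 given P_v < 0.05 — the quantity that says
variance-prioritization enriches for detectable interactions.

**The recovery scenario** (used by the acceptance suite) plants 40 common
"known" loci (MAF 0.3–0.5, β = 0.15) among 160 null SNPs at n = 5,000; ten
known loci carry δ = 1.5 with a *private* Bernoulli(0.3) exposure each.
Private exposures are the scientifically meaningful design: a shared
exposure with many strong same-signed interactions makes the trait an
asymmetric bimodal mixture, and the mean-centred Levene test is genuinely
miscalibrated there (the |Y − Ȳ_g| folding point falls in a density gap, so
group-mean jitter inflates between-group Z dispersion — a known limitation,
see below); with effects spread over independent exposures the trait stays
near-normal, null SNPs hold the 5% rate, and the variance screen finds the
interaction loci no stratified scan could (their exposures are unmeasured).

## Known limitations

- The mean-centred Levene test is anti-conservative for strongly skewed or
  asymmetrically bimodal traits (measurements above). Preparation
  (log-transform, winsorization) is part of the method for exactly this
  reason; a median-centred (Brown-Forsythe) variant is deliberately out of
  scope.
- The equality-of-correlations test ignores subset nesting (documented
  above).
- Enrichment P-values are conservative for small eligible sets
  (discreteness of the exact binomial).
- The marginal scan fits no covariates; external summary statistics are the
  intended source of marginal P-values for real analyses (a covariate hook
  exists but is unused by default).
- Strand-ambiguous SNPs with frequencies near 0.5 cannot be harmonized from
  summary data and are dropped.
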