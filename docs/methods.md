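# Methods

`mrcovadj` studies a specific threat to two-sample Mendelian randomization
(MR): GWAS consortia often release summary associations that were adjusted
for a heritable covariable (waist circumference adjusted for BMI, lung
function for height, and so on). If the covariable is a collider — or
acquires collider status through an unmeasured confounder — conditioning on
it distorts the per-variant associations, and any MR analysis built on them
inherits the distortion. The package contains (1) a structural-equation
Monte-Carlo framework that quantifies this bias across a grid of causal
structures, and (2) the two-sample IVW estimation pipeline itself, usable on
real summary files.

## Data-generating model

Measured variables: independent biallelic variants Z (default 40), exposure
X, covariable W, outcome Y, and in two structures an intermediate R. Six
causal layouts are crossed with five confounding settings:

| structure | genetic architecture (homogeneous mode) | extra edges |
|---|---|---|
| A | all variants → W | W → X (full mediation) |
| B | all variants → X and W | — |
| C | all variants → X | X → W (full mediation) |
| D | all variants → R | R → X, R → W |
| E | as B | W → Y (pleiotropy, InSIDE holds) |
| F | as D | W → Y (pleiotropy, InSIDE violated) |

Confounding settings add standard-normal unmeasured variables: none (1),
U_XW (2), U_WY (3), U_XY (4), or all three (5), each entering both of its
children. In heterogeneous mode the variants are instead split into equal
subgroups with direct effects on X only, W only, both X and W, and — in
structures D and F — on R only; structures without R keep the fourth
subgroup as null variants so every cell has the same number of candidate
instruments. Subgroup sizes are an explicit choice of this package (equal
split), since only the existence of the four subgroups is prescribed.

**Effect-size parameterization.** Genotypes are Hardy–Weinberg draws with
per-variant effect-allele frequencies Uniform(0.1, 0.9) (the common-variant
GWAS regime; configurable). All variants affecting a phenotype are combined
into an unweighted additive allele score, standardized, and given a
coefficient such that the score accounts for 10% of the phenotype's
variance; every phenotypic or unmeasured direct cause accounts for 20%. All
direct effects are positive. Concretely, each cause enters its child with
coefficient `sqrt(v)/sd(cause)` (v = 0.10 or 0.20) and residual Gaussian
noise tops the child up to unit variance: residual variance = 1 − empirical
variance of the systematic part, floored at 0.01. The floor matters only
where positively correlated causes overshoot the nominal budget — in
practice the outcome in cells E5/F5, whose total variance then lands near
1.3 rather than 1. We keep the stated per-cause fractions rather than
rescaling them, so "20% of variance" remains true marginally for each cause.
The non-null causal effect of X on Y falls under the same 20% rule, giving
β ≈ √0.20 ≈ 0.447 on the standardized scale; the generating coefficient is
stored with each cohort and is the estimand used for bias and coverage.

Phenotypes are built in topological order of each cell's DAG (R first where
present; W before X under structure A; X before W under structure C; Y
last), so no variable is read before it is generated — enumerable over all
120 configuration cells.

## GWAS and instrument selection

Each replicate cohort (default 100 000 individuals; the shipped
reduced-scale profile uses 20 000) is split into random halves: the first
estimates variant–exposure associations, the second variant–outcome
associations, reproducing the two-sample design with no sample overlap.
Associations are per-variant OLS of the trait on allele count, with or
without W in the model, computed by Frisch–Waugh–Lovell residualization
(vectorized across variants; exactly equal to per-variant multiple OLS, and
tested against `statsmodels`). Instrument strength is the squared Wald t of
the genotype coefficient — in adjusted models the partial F for the
genotype term, which is the conventional per-variant F in MR practice.
Selection keeps variants with F ≥ 10 (boundary inclusive), applied to
whichever exposure GWAS an analysis combination actually uses: adjusted
analyses select on adjusted F, unadjusted on unadjusted F. For file-based
inputs, genome-wide-significance selection (p < 5 × 10⁻⁸, strict) is the
default instead; LD independence of the input variants is the caller's
responsibility. A further optional filter removes instruments associated
with the covariable at p < 0.05 (retention is p ≥ 0.05).

## Estimation

The causal effect is estimated by inverse-variance weighting with
multiplicative random effects: the point estimate is the zero-intercept
weighted least-squares slope of outcome betas on exposure betas with
weights 1/se_out², identical to the fixed-effect IVW estimate; the standard
error is the fixed-effect one multiplied by the square root of the weighted
residual mean square, floored at 1 so underdispersion never tightens the
interval. Confidence intervals use the normal quantile 1.96 (the
summary-data MR convention; k is typically 30–60 so the t correction is
small). A single surviving instrument degrades to the Wald ratio with its
first-order standard error; zero instruments yield an explicit
non-estimable marker rather than an error, so the other combinations of the
same run still report.

Harmonization of independently sourced exposure/outcome files follows the
usual allele-alignment rules: inner join on variant id; sign-flip of the
outcome beta when effect/other alleles are swapped; strand flips resolved
by complementing; palindromic (A/T, C/G) variants aligned by which side of
0.5 the two effect-allele frequencies fall on, and dropped when either
frequency is missing or inside the ambiguity zone [0.42, 0.58]. These
thresholds are declared package choices, configurable at the module level.

## Monte-Carlo aggregation

Per scenario cell and adjustment combination we report mean bias
(mean estimate − true effect), empirical coverage of the nominal 95%
interval, mean selected-instrument count (over all replicates), mean F of
selected instruments, and the fraction of non-estimable replicates. Bias
and coverage are averaged over estimable replicates only; cells that are
non-estimable in most replicates (e.g. structure A homogeneous with
W-adjusted exposure associations, where adjustment closes every variant–
exposure path) are flagged `excluded` in the bias table. Each replicate's
random stream is derived from (scenario seed, replicate index) via NumPy's
`SeedSequence`, which makes grid output invariant to the number of joblib
workers and lets any single replicate be reproduced in isolation.

## Problem sizes and what the checks show

The shipped acceptance checks use 500 replicates per cell: the
directional-bias grid at 20 000 individuals per cohort, and the coverage
checks at the full 100 000. The reduced cohort keeps per-variant F around
28, which is enough for stable selection and sign-correct bias surfaces but
leaves visible weak-instrument attenuation (≈ −β/F); at 100 000 the mean F
is ≈ 126 and coverage of the valid-instrument cell is near-nominal
(~95.6% under the null, ~93% under the non-null effect — slightly below
nominal is expected for first-order IVW, whose weights ignore exposure-side sampling
error, and coverage is known to dip when the true effect is non-zero).

The generator emulates the study conditions it is designed for —
independent common variants, additive genetics, Gaussian phenotypes,
homoscedastic noise, equal-sized GWAS halves from one population. It does
not emulate linkage disequilibrium, binary traits, dosage uncertainty,
population stratification, or sample overlap, so passing tests say nothing
about those complications; the qualitative bias directions, which rest only
on the causal structure, are the findings expected to transfer.

## Known limitations

* Variance fractions are exact only when a phenotype's causes are mutually
  uncorrelated; correlated-cause cells overshoot (floored residual), which
  slightly rescales biases expressed per SD of Y in E5/F5.
* The heterogeneous-mode equal subgroup split is one of many defensible
  choices; subgroup sizes are configurable through the group-assignment
  layer rather than the public config.
* The Wald-ratio standard error is first-order (outcome side only), the
  standard summary-data approximation; no weak-instrument correction is
  applied.
* Real-data workflows assume pre-clumped (LD-independent) variants and do
  not look up proxies for variants missing on one side.
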