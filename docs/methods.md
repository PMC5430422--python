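# Methods

## The analysis

`gripmr` implements two-sample Mendelian randomization (MR) from GWAS
summary statistics, specialized to the question of whether handgrip
strength causally affects coronary artery disease (CAD), myocardial
infarction (MI) and a panel of cardiometabolic risk factors. Two variants —
rs3121278 (*BMS1L*) and rs752045 (*CSMD1*) — serve as instruments: they are
associated with grip strength at genome-wide significance in the CHARGE
consortium (n = 34,910), are not in linkage disequilibrium, and have no
reported associations with other phenotypes.

For instrument *k*, let E_k be the per-allele effect on grip strength (kg),
D_k the per-allele effect on the outcome (log-odds for binary outcomes, SD
units or mmol/l for continuous ones) and σ_Dk its standard error. The
per-SNP causal estimate is the Wald ratio D_k / E_k, and the K ratios are
pooled with the fixed-effect inverse-variance-weighted (IVW) estimator

    β̂_IVW = Σ_k E_k D_k σ_Dk⁻²  /  Σ_k E_k² σ_Dk⁻²
    SE(β̂_IVW) = ( Σ_k E_k² σ_Dk⁻² )^(-1/2)

which is the slope of a weighted least-squares regression of D on E through
the origin with weights σ_Dk⁻². Confidence intervals and two-sided p-values
use the standard normal (the convention for summary-data MR, where the
per-study degrees of freedom are effectively infinite). Only the
fixed-effect estimator is provided: with K = 2 instruments there is no
information to estimate between-SNP heterogeneity, and sensitivity
estimators such as MR-Egger or the weighted median require more variants
than are available here.

The per-SNP Wald standard error is reported as the first-order delta
approximation σ_Dk / |E_k|. It ignores sampling error in E_k; the pooled
IVW standard error does not use it and depends only on the outcome-side
variances, which is the standard (and slightly anti-conservative)
two-sample convention.

## Input handling

Outcome associations published as odds ratios with a level-γ confidence
interval (L, U) are converted to the log scale: D = ln OR and
σ_D = (ln U − ln L) / (2 z_γ), with z_γ computed from the normal
distribution (1.959964 at 95%) rather than hard-coded as 1.96, so that
arbitrary levels are handled consistently. The difference is far below the
rounding of any published table.

Harmonization orients every outcome record to the exposure record's effect
allele: identical orientation copies through, swapped alleles negate the
outcome effect, and strand complementation is attempted only after direct
and swapped matching both fail, which minimizes silent strand flips.
Palindromic variants (A/T, C/G) cannot be resolved from allele labels and
are either rejected or dropped according to an explicit policy; no
frequency-based disambiguation is attempted (neither packaged instrument is
palindromic). Sample sizes printed with thousands separators ("34,910")
are accepted.

## The packaged fixtures and what "reproduction" means

The per-SNP tables are shipped exactly as published, at two-decimal
precision, including the asymmetric CAD bound 0.9995 for rs752045. The
original analysis consumed full-precision consortium statistics, so pooled
estimates recomputed from the printed cells cannot match the published
values exactly. From the printed inputs the pipeline obtains a pooled CAD
OR of 0.929 (published 0.94), MI 0.915 (published 0.93) and T2D 1.014
(published 0.99) — all within one to three units in the second decimal,
which is the agreement the rounded inputs can support. The comparison table
that `reproduce_headline` emits prints absolute differences but never fails
the run on them; tolerances belong to the test suite.

Two caveats are documented rather than patched:

- **Continuous outcomes.** The published per-SNP table prints the
  continuous traits (BMI, lipids, glucose) in OR-like form around 1
  ("mean difference (SD)" shown as e.g. 0.99 (0.96, 1.02)), without stating
  whether the displayed values are exponentiated betas. The package ingests
  them through the same log-transform path and labels the scale SD-units or
  mmol/l. Under this reading the pooled continuous estimates do *not*
  reproduce the published betas (e.g. LDL +0.007 recomputed vs −0.005
  published); the ambiguity is preserved in the fixtures and surfaced in
  the comparison table, not silently reinterpreted.
- **Interval asymmetry.** Several printed intervals are not symmetric
  around the point estimate on the log scale, so rebuilding an interval
  from (ln OR, CI-derived SE) recovers the printed bounds only to within
  one unit of the table's two-decimal precision (worst case 0.0054). The
  round-trip test asserts recovery at that rounding-limited tolerance.

## Instrument strength

The variance in the exposure explained by one variant is computed literally
as R²_k = β_k² · 2 f_k (1 − f_k), and the joint first-stage F as
F = (R²/K) / ((1 − R²)/(n − K − 1)). The literal formula treats the
phenotype as having unit variance: applied to the published per-allele
effects it gives R² = 0.0852 and F ≈ 1625 at n = 34,910, whereas the
published joint F is 128. Back-solving, F = 128 corresponds to a total
R² ≈ 0.0073 — i.e. an unstated standardization by a residual phenotype SD
of ≈ 3.4 kg (plausible for a covariate-adjusted GWAS residual; the raw
population SD of grip strength is around 10 kg). The package computes the
literal value always, and the rescaled R² and F whenever a phenotype SD is
supplied; it does not pick a winner between 1625 and 128.

## The simulator

The generator instantiates the structural model MR assumes. Genotypes are
drawn in Hardy–Weinberg proportions and linkage equilibrium,
g ~ Binomial(2, f). The exposure is X = Σ γ_k g_k + ε with Gaussian noise;
the outcome is either continuous, Y = baseline + θX + Σ δ_k g_k + η, or
binary with logit P(Y=1) = baseline + θX + Σ δ_k g_k, where θ is the true
causal effect and δ are direct (pleiotropic) genotype effects, zero by
default. Exposure and outcome cohorts are always drawn independently — the
true two-sample regime — with an optional overlap fraction defaulting to 0
(the exposure consortium contributed under 5% of the outcome consortium's
sample, so zero overlap is the realistic default). Each cohort is reduced
to per-SNP summaries the way consortia produce them: simple linear
regression of the exposure (or continuous outcome) on allele count, or
logistic regression for binary outcomes, fitted by IRLS on
genotype-aggregated counts with tolerance 1e-8 and at most 50 iterations;
non-converged or monomorphic fits drop the affected SNP or replicate with a
logged count. All randomness flows through one explicitly threaded seeded
generator; identical configurations produce bit-identical reports.

Default parameters mirror the handgrip instruments: k = 2, f = (0.18,
0.18), γ = (−0.26, +0.47) kg, n = 34,910 per arm. The exposure noise SD
defaults to 3.4 kg, chosen so that the simulated first-stage F-statistic at
the source sample size is ≈ 128, matching the instrument strength the
source cohort reports (see the standardization discussion above). This is
a calibration choice, not a published value: it emulates the
covariate-adjusted residual the GWAS analyzed, not the ~10 kg raw
population SD of grip strength.

What the simulator does *not* emulate: linkage disequilibrium between
instruments, population stratification, winner's-curse selection of
instruments, covariate adjustment, or case-control ascertainment. Passing
recovery tests therefore demonstrates correctness of the estimator and
pipeline under the model's own assumptions, not robustness to their
violation in real data.

## Monte-Carlo calibration and its expected behaviour

The calibration study in the acceptance suite runs the continuous-outcome
architecture at n = 20,000 per arm with 500 replicates (sizes chosen to
make the study a few seconds of compute while leaving Monte-Carlo error
well below the tolerances): at θ = 0.1 the bias must be under 2 Monte-Carlo
SEs and 95% CI coverage within [0.93, 0.97]; at θ = 0 the 5%-level
rejection rate must lie in [0.03, 0.07]. A small finite-sample attenuation
toward the null (of order σ_E²/E² per SNP, here under 2%) is expected
because the IVW weights ignore first-stage sampling error; at the study's
instrument strength it stays within the stated bands.

Binary-outcome recovery is documented as approximate: the marginal odds
ratio a per-SNP logistic regression estimates is attenuated relative to the
conditional θ (non-collapsibility), so the corresponding test allows 15%
relative error at small θ and low prevalence rather than asserting exact
recovery.

## Numerical choices and degenerate inputs

- Zero-width confidence intervals yield SE = 0 with a warning; records with
  non-positive SE are rejected at construction, so degenerate inputs fail
  loudly before pooling.
- A zero exposure effect makes the Wald ratio undefined and raises, rather
  than returning an infinity.
- Noiseless simulated cohorts produce zero residual variance; regression
  SEs are floored at 1e-12 so the summary records remain valid and the
  noiseless limit (Wald ratio = θ exactly) is exercisable.
- Ties in harmonization are impossible by construction: direct and swapped
  matches are mutually exclusive for valid biallelic records, and
  complementation is only consulted when both fail.
- No multiple-testing adjustment is applied across the eight outcomes,
  matching the per-outcome presentation of the source analysis.
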