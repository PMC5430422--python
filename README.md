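# gripmr

Two-sample Mendelian randomization (MR) of handgrip strength on coronary
artery disease, myocardial infarction and cardiometabolic risk factors,
from GWAS summary statistics.

Observational studies link weak grip strength to cardiovascular disease,
but such associations are vulnerable to confounding (body size, frailty,
underlying illness) and reverse causation. MR sidesteps both by using
genetic variants as instruments: alleles are randomized at conception, so
an allele that raises grip strength by a known amount provides a natural
experiment for the downstream effect of grip strength itself. `gripmr`
implements the summary-statistics version of this design for analysts who
have per-SNP association tables from two non-overlapping samples — here,
two grip-strength variants (rs3121278, rs752045) from the CHARGE consortium
(n = 34,910) paired with outcome associations from the CARDIoGRAMplusC4D,
DIAGRAM, GIANT, GLGC and MAGIC consortia, shipped as fixtures exactly as
published.

## The estimator

For instrument *k* with per-allele exposure effect E_k (kg), outcome effect
D_k and outcome standard error σ_Dk, the per-SNP causal estimate is the
Wald ratio D_k / E_k, and K ratios are pooled by fixed-effect
inverse-variance weighting:

    β̂_IVW = Σ E_k D_k σ_Dk⁻² / Σ E_k² σ_Dk⁻²,   SE = (Σ E_k² σ_Dk⁻²)^(-½)

equivalently, the slope of a weighted least-squares regression of D on E
through the origin. Outcome effects published as an odds ratio with 95% CI
(L, U) are converted via D = ln OR, σ_D = (ln U − ln L)/(2·1.959964).
Instrument strength is reported as R²_k = β_k²·2f_k(1−f_k) and
F = (R²/K)/((1−R²)/(n−K−1)). The package also contains a two-cohort
simulator that generates genotypes in Hardy–Weinberg proportions, builds
exposure and (binary or continuous) outcome from a known causal effect θ,
reduces each cohort to per-SNP regression summaries and pushes them through
the identical pipeline — used to verify bias, CI coverage and type-I error
of the estimator. See `docs/methods.md` for assumptions, calibration
choices and known limitations.

## Worked example

```
$ python examples/reproduce_headline.py      # or: gripmr reproduce
```

prints, for the three binary outcomes (abridged):

```
                outcome presentation  published  recomputed  abs_diff
coronary_artery_disease           or     0.9400      0.9292    0.0108
  myocardial_infarction           or     0.9300      0.9148    0.0152
        type_2_diabetes           or     0.9900      1.0137    0.0237
```

Read: per 1-kg genetically determined increase in handgrip strength, the
recomputed pooled odds ratio of coronary artery disease is 0.929 — about a
7% reduction in odds — against 0.94 as published; myocardial infarction
0.915 vs 0.93; type 2 diabetes is null. The differences of one to two units
in the second decimal are expected: the packaged inputs are the printed
two-decimal tables, while the original analysis consumed full-precision
consortium statistics. The instrument block prints both the literal
first-stage F (≈1625, from the unit-variance R² formula) and the rescaled
F (≈130 with a 3.4 kg phenotype SD; the published joint F is 128) — see
`docs/methods.md` for why the two disagree.

Other entry points: `gripmr mr --exposure FILE --outcome FILE` runs the same
pipeline on your own delimited summary files (configurable column names,
either beta/SE or OR/CI effect columns, palindromic-SNP policy), and
`gripmr simulate --config examples/sim_config.yaml` runs a Monte-Carlo
calibration study (`examples/simulation_study.py` shows the library form:
at θ=0.1, n=20,000 per arm, bias +0.002, coverage 0.935, null rejection
0.055).

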