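# Methods

## Model

Whole-blood DNA is a mixture of leukocyte subtypes, and the beta value
(methylated fraction, in [0, 1]) at a CpG is, to first order, the
mixture-weighted average of the per-cell-type betas:

    y_p = Σ_c w_c · R_{p,c} + ε_p,     w on the simplex.

Two consequences drive everything in this package. First, at a CpG that is
unmethylated in exactly one subtype and methylated in the rest (an ISUS),
`1 − y_p` rises linearly with that subtype's proportion, so a single beta is
a cell-ratio proxy. Second, the full proportion vector is recoverable by
constrained projection of `y` onto a signature matrix of reference profiles.
The methylation-derived neutrophil-to-lymphocyte ratio is formed either
directly from marker betas (`mdNLR = β_neu-CpG / β_panlym-CpG`) or from the
deconvolved proportions (`mdNLR_ref = w_Neu / Σ lymphoid w`).

## Marker selection

A probe is an ISUS candidate for subtype *t* when `β_t ≤ low_thr` and every
other subtype has `β ≥ high_thr`. The ranking statistic is the *specificity
margin*, the gap between the most extreme beta on the wrong side and on the
target side (`min(non-target) − max(target)` for target-unmethylated
probes); it is order-free, lies in [−1, 1], and equals ~0.9 for an ideal
binary profile. Defaults `low_thr = 0.3`, `high_thr = 0.7`, `k = 3` per
subtype reproduce the published panel structure (21 ISUS; 3 neutrophil + 3
pan-lymphocyte mdNLR sites). The exact thresholds behind the published panel
are not public, so these are explicit, documented stand-ins; probes eligible
for several subtypes are assigned to the subtype with the larger margin,
ties broken by probe id so that selection is deterministic. Treg is treated
as a distinct reference column with no hierarchy over CD4+ T cells. Probes
with any missing reference beta are excluded before selection.

## Deconvolution

`estimate_proportions` solves `min ‖y − Xw‖²` subject to `w ≥ 0, Σw = 1` as
fully-constrained least squares: active-set nonnegative least squares on the
system augmented with a sum-to-one row weighted 1e4, followed by exact
renormalisation onto the simplex. On every tested instance this matches an
exhaustive simplex grid search (step 1e-3) to within 2e-3 per coordinate.
The signature defaults to the union of panel markers for the six mixed cell
types, capped at the 50 largest margins. Rank deficiency is detected
numerically and reported with the collinear columns named; probes with
missing betas are dropped per sample, and at least as many usable probes as
cell types are required.

## Matched inference

With 1:1 matching, conditioning each case–control pair on containing exactly
one case reduces the conditional likelihood to logistic regression without
intercept on within-pair differences `d_i = x_case − x_control`:
`ℓ(β) = Σ log σ(d_iᵀβ)`. It is maximised by damped Newton iteration
(convergence when the sd-scaled step falls below 1e-8, cap 100 iterations).
Monotone likelihoods (separation) are flagged — fitted linear predictors all
one-signed and a coefficient above 15 per unit-sd covariate — and no OR is
reported for such fits. Odds ratios are reported per 0.1 exposure increment
(a 10 percentage-point methylation increase on the beta scale); Wald CIs and
p-values come from the observed information. Exposures may alternatively be
logit-transformed (`ln(b/(1−b))`, clipped at `eps = 1e-6`), the scale used
for the prospective ddPCR readouts.

AUC is the Mann–Whitney statistic (ties count one half) with a DeLong
placement-variance confidence interval. Holm's step-down adjustment is
applied per analysis block (e.g. the nine mdNLRs form one family). Backward
selection refits the multivariable conditional model and repeatedly drops
the largest Wald p exceeding 0.20 (ties: larger p, then name; empty model
allowed). Internal validation uses Harrell's optimism bootstrap with the
matched pair as resampling unit: the full selection-plus-fit procedure is
repeated on each of B = 200 replicates, optimism is the mean gap between a
replicate model's AUC on its own sample and on the original data, and the
adjusted AUC subtracts that optimism from the apparent AUC. Replicates whose
fit fails are skipped and counted; more than 20% failures aborts.

Wilcoxon signed-rank (zeros dropped; exact null for n ≤ 25 without ties,
else tie-corrected normal approximation with continuity correction),
Mann–Whitney and Spearman delegate to scipy behind the module surface; the
Jonckheere–Terpstra trend statistic (`Σ_{g<h}` pairwise exceedances, ties
half) is computed here, with an exact permutation null for total n ≤ 10,
10⁴ seeded label permutations by default otherwise, and an optional normal
approximation; the choice is returned with the result.

## Synthetic study conditions

The generator emulates the study design the inference machinery is built
for. Reference: planted ISUS (target beta ~ U(0.02, 0.1), others
U(0.85, 0.98)), opposing neutrophil/pan-lymphocyte sets with the same
ranges, and background probes U(0.2, 0.8) shared across cell types. Cohort:
per pair, a control age ~ N(55, 8) truncated to [30, 80] with the case age
within the matching tolerance (±1 year retrospective, ±5 prospective);
latent six-type proportions ~ Dirichlet(mass × group means) with defaults

| group    | Neu  | NK    | TCD4  | TCD8  | B     | Mono  |
|----------|------|-------|-------|-------|-------|-------|
| controls | .45  | .063  | .17   | .10   | .07   | .147  |
| cases    | .49  | .043  | .155  | .095  | .067  | .15   |

anchored to the published totals (neutrophils 49% vs 45%, pan-lymphocyte sum
36% vs 40.3%) with the NK cells carrying the largest relative drop; the
subtype-level split of the lymphocyte total is not published and is a
declared calibration choice. The Dirichlet total mass (60) sets
between-subject spread and is likewise a free knob — no within-group
variances are published. Observed betas are the mixture plus Gaussian noise
(sd 0.02) clipped to [0, 1]; Treg enters the observed betas as a fixed 0.1
fraction of the CD4+ T weight. Epidemiologic covariates (BMI, menopause,
parity, smoking) are drawn independently of case status. The prospective arm
reads the latent NK proportion through a multiplicative assay efficiency
~ N(1, 0.05).

The generator reproduces compositional dilution, matched sampling and
measurement noise; it does not model array artefacts (probe-type bias,
batch), covariate-linked composition (e.g. the published smoking and age
correlations), or beta-distributed error. Passing tests therefore
demonstrate correctness of the estimators under the compositional model, not
robustness to those real-data features.

## Numerical choices

`eps = 1e-6` guards logit clipping and all ratio denominators. The NNLS
sum-to-one weight (1e4) keeps the pre-normalisation sum within ~1e-9 of one;
renormalisation makes it exact. The NK-to-neutrophil ratio uses
unmethylation values in both numerator and denominator so that the score is
increasing in the NK ratio. Missing betas propagate as missing scores;
complete-pair deletion happens only when forming within-pair differences.
All stochastic procedures take explicit seeds.

## Problem sizes

The test suite and acceptance script run the full design at 231 pairs (the
retrospective sample size) and 146 pairs (prospective); calibration checks
use 500 simulations of 100 pairs for type-I error and CI coverage, 100 seeds
of 231-pair cohorts for the direction-level reproduction of the group
shifts, and 10 independent 50-pair null cohorts (B = 200 each) for the
optimism-bootstrap calibration, whose single-run spread at that sample size
motivates averaging over cohorts.

## Known limitations

- Proxy and deconvolution accuracy inherit the quality of the reference
  profiles; real sorted-cell references carry donor and platform variation
  the simulation does not.
- The conditional-likelihood machinery covers 1:1 matching only; m:n strata
  would need the general conditional likelihood.
- N1/N2 neutrophil states, NKT cells and reference-free deconvolution are
  out of scope, as are survival analyses.
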