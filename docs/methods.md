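# Methods

This note documents the statistical procedures `tedscore` implements, the
modelling choices made where the published analysis left the design open, the
synthetic-data generators and what they do and do not emulate, and the
package's numerical conventions and known limitations.

## Orientation and scoring conventions

Throughout the package the positive class is **non-response** to intravenous
glucocorticoids (steroid resistance) and a higher score means more resistant;
classification at a cutoff c uses the discrete rule "positive when
score ≥ c" on the observed score grid. This orientation reproduces every
published sensitivity/specificity pair. The composite score awards one point
per satisfied rule — FGL2 **strictly** greater than 39.5 ng/mL, TSAb quartile
equal to 4 (titer > 2597 %), current smoking — so boundary values
(FGL2 = 39.5 exactly) score zero. The TSAb component is evaluated on the
quartile rather than the raw titer: only the quartile enters the model, and
the fixed boundaries (≤ 489 / 490–984 / 985–2597 / > 2597 %) are treated as
constants of the analysis.

## ROC analysis

The AUC is the pairwise-concordance (Mann–Whitney) form,
`(#{pos > neg} + ½·#{pos = neg}) / (n_pos · n_neg)`, computed via mid-ranks.
For the step curves produced by discrete scores this equals the trapezoidal
area exactly, and it is invariant under strictly increasing transforms and
satisfies `AUC(s) + AUC(−s) = 1` — both asserted as property tests against a
brute-force pair-enumeration oracle. The Youden-optimal cutoff maximizes
J = sensitivity + specificity − 1 over the observed grid; ties are broken
toward higher sensitivity, then toward the lower cutoff (the published
cutoff has sensitivity 1.0, and the tie-break makes the choice
deterministic). A DeLong asymptotic interval is available for comparison,
but the interval the pipeline reports is the percentile bootstrap, below.

## Percentile bootstrap

The AUC interval resamples **patients** with replacement B times (default
1,000), computes the AUC per resample, and takes the empirical (α/2,
1 − α/2) quantiles with linear ("type 7") interpolation. Resamples that lose
an outcome class are redrawn and counted, so exactly B AUC values enter the
quantiles. On the reconstructed 31-patient cohort the interval stabilizes by
B = 10⁴ to within 0.01 per bound across seeds; at B = 1,000 the bounds land
within ±0.01–0.02 of (0.74, 0.96) depending on the seed.

## Generic tests

All procedures use mid-rank tie handling and are implemented from first
principles over `scipy.special` distribution functions:

* **Mann–Whitney U** counts non-responder-over-responder wins with ties as ½.
  The two-sided exact p (used when n_x·n_y ≤ 400 with no ties) comes from
  the standard count recurrence for the exact null distribution of U,
  equivalent to enumerating every group assignment; otherwise a normal
  approximation with tie-corrected variance is used, **without** continuity
  correction so that the two-group Kruskal–Wallis identity H = z² holds
  exactly (a property test).
* **Kruskal–Wallis** uses the tie-corrected H with a χ²(k−1) p-value;
  **Dunn** contrasts use pooled-rank mean differences with the tie-corrected
  variance, BH-adjusted by default.
* **One-way ANOVA / Tukey–Kramer** for ELISA concentration comparisons; the
  studentized-range CDF is evaluated by direct double numerical integration
  (outer over the scale χ/√ν, inner over the normal location), matching
  `scipy.stats.studentized_range` to ~1e-8.
* **2×2 categorical tests** default to Pearson χ² **without** Yates
  correction: on the published smoking-by-outcome table [[3,18],[5,5]] the
  uncorrected test gives p = 0.0337 — matching the printed 0.034 — whereas
  Fisher's exact gives 0.074, so the printed value pins down the convention.
  Yates correction and Fisher's exact are provided as options.
* **Benjamini–Hochberg** q-values use the standard step-up construction;
  q ≥ p, q ≤ 1 and permutation equivariance are property-tested.
* **Spearman** correlates mid-ranks with a t-approximation p on n−2 df.

## Discovery-phase screen

Differential abundance between the TED arms is tested per protein on log2
intensities with a Welch t-test by default (Mann–Whitney optional). The
published analysis ran MSstats on the vendor's DIA output; raw spectra are
out of scope here, and the per-protein test is an approximation whose
adequacy is assessed by synthetic recovery, not by reproducing the published
121/142 counts. The fold-change rule is interpreted on the linear scale
(fold change > 2 ⇔ |log2FC| > 1) with strict inequalities. Proteins with
fewer than two observed values in either arm are reported untested — no
imputation. Candidate (stage-1) status requires DAP classification on
**nominal** p-values (after FDR correction nothing survives at this arm
size, so the screen is hypothesis-generating by design; q-values are
reported but not used as a filter), non-Ig annotation, and detection in
≥ 9 of 10 TED samples.

The four-group specificity filter runs Kruskal–Wallis across non-responders,
responders, Graves' disease and healthy controls, then Dunn contrasts. A
candidate passes when the omnibus p < 0.05 and the non-responder arm is
significantly **higher** than each of the other three groups. Because the
hypothesis is directional, the contrasts are one-sided, BH-adjusted over the
three non-responder-versus-other comparisons — the family the decision rule
consults. This choice is forced by arithmetic, not preference: against a
control arm of 3 samples the Dunn z cannot exceed ≈ 2.2 (two-sided
p ≈ 0.028) even under complete separation, so a two-sided adjustment over
all six pairs leaves the adjusted p above 0.05 for every possible dataset
and would make the filter unsatisfiable. Even the directional version has a
hard power ceiling: planted non-responder-only effects of 2 log2 units pass
in roughly two-thirds of simulated datasets, which is a property of a
4-vs-3 rank comparison, not of the implementation.

## Penalized logistic selection

The LASSO logistic model minimizes `(1/n)·log-loss + λ‖β‖₁` with an
unpenalized intercept (the glmnet penalty convention, so
`λ_max = max_j |x_jᵀ(y − ȳ)|/n` on standardized columns zeroes every
coefficient). Fitting alternates an outer iteratively-reweighted quadratic
approximation (weights floored at 1e-5) with inner cyclic coordinate descent
using soft-thresholding; convergence is a max-coefficient-change below 1e-8.
The fit matches R glmnet to ~5e-7 at matched settings and the statsmodels
IRLS solution to better than 1e-6 at λ = 0 (both are test oracles). A
soft-threshold snap of 1e-15 keeps coefficients exactly zero at the λ_max
boundary. Quasi-separation is flagged either when a standardized coefficient
exceeds 50 or when, at λ = 0, every fitted probability saturates
(max|y − p| < 1e-8) — the signature of a likelihood with no interior
optimum; once saturated the coefficients grow only logarithmically in
iteration count, so the saturation check is the trigger that fires in
practice.

Predictors are standardized to population sd 1 before penalization and the
coefficients are back-transformed to per-original-unit scale for reporting.
The λ grid is log-spaced over 100 points from λ_max down to 10⁻³·λ_max with
warm starts. λ_min is chosen by 5-fold **stratified** cross-validation on
mean out-of-fold binomial deviance (out-of-fold AUC optional), with ties
going to the sparser penalty; fold count, CV loss and standardization were
not stated in the original analysis and are declared defaults here. λ_min is
known to overselect mildly under the null — in pure-noise simulations the
refit model is empty in only a third to a half of seeds — which is why the
pipeline also reports per-predictor bootstrap selection frequencies (B row
resamples refit at fixed λ_min, class-degenerate resamples redrawn). The six
predictors enter as: FGL2 per ng/mL, TSAb quartile as an ordinal 1–4,
smoking / female / thyroid dysfunction as 0/1, age per year. The published
per-predictor coefficients cannot be reproduced without the patient-level
data; on synthetic cohorts of 500 the three score components are recovered
as positive λ_min coefficients in ≥ 90% of seeds.

## Synthetic-data generators

Both generators are seeded (`numpy.random.default_rng`) and bit-reproducible
for identical (design, seed).

**Discovery matrix.** Per-protein baseline ~ N(20, 2) log2 units; per-entry
value = baseline + group effect + N(0, 0.5). Defaults emulate the study's
6 responder / 4 non-responder / 3 Graves / 3 healthy design at a
2,000-protein desk scale (the study quantified 7,499; the scale is
configurable upward and no result here depends on it). Fifty planted DAPs
are shifted by ±2 log2 units in non-responders (alternating sign), and 3
planted biomarkers are shifted +2 in non-responders only, making them
elevated against all three other groups. Missingness follows a decreasing
logistic in the true intensity (midpoint 15, steepness 1, ~0.7% dropout at
the baseline mean, rising steeply below it); the original study reports no
missingness mechanism, so this is a plausible intensity-dependent model, not
an estimate. 10% of proteins are flagged as immunoglobulin fragments, drawn
from the non-biomarker proteins — flagging a planted biomarker would make
the recovery experiment unanswerable by construction. Setting
`dropout_midpoint=None` disables dropout.

**Validation cohort.** 21 responders and 10 non-responders by default. FGL2
is drawn from a moment-matched lognormal (μ = ln(m²/√(m²+s²)),
σ² = ln(1+s²/m²)) at the published group moments — responders 27.8 ± 17.8,
non-responders 44.8 ± 18.0 ng/mL — chosen because concentrations are
positive and right-skewed and the lognormal matches both moments exactly; a
truncated normal (rejection resampling, which avoids a point mass at zero
but biases the mean upward) is provided for sensitivity checks. TSAb is
generated category-first from the published per-outcome quartile counts
(responders 7/5/6/3, non-responders 1/2/2/5), with a continuous titer drawn
uniformly within the drawn quartile's boundaries (capped at 10,000 %) for
completeness. Smoking (3/21 vs 5/10), thyroid dysfunction (3/21 vs 5/10)
and sex (12/21 vs 5/10 female) are Bernoulli; age is normal at 54 ± 14 vs
47 ± 13 years. FGL2 is drawn independently of TSAb within outcome groups,
mirroring the reported absence of correlation between the two markers.

**What the generators do not emulate** — and hence what passing tests do not
show about real data: peptide/spectrum-level structure and protein
inference, between-protein correlation (each protein is independent),
batch/run effects, the joint distribution of the clinical predictors within
an outcome arm (components are conditionally independent given outcome, so
synthetic composite-score AUCs run higher than the published 0.86), and the
treatment-response definition itself (the outcome is a supplied binary
label).

## Published fixtures

The fixture bundle embeds, verbatim: the per-score outcome table (11/0, 9/5,
1/3, 0/2 responders/non-responders at scores 0–3), the TSAb
quartile-by-outcome table, the 2×2 smoking table, and the FGL2 group moments
for all four ELISA groups. Expanding the score table to 31 patient records
and evaluating the score reproduces AUC = 181/210 ≈ 0.862, cutoff ≥ 1,
sensitivity 10/10 and specificity 11/21 exactly, and the 1,000-resample
percentile bootstrap reproduces the published (0.74, 0.96) interval to
within the resampling noise. The published interval 0.72–0.95 attached to
the ROC figure was computed by an unstated method and is not reproduced.

## Numerical and degenerate-input conventions

Zero-variance inputs: a rank test on fully tied data returns p = 1; ANOVA
with zero between- and within-group variance returns F = 0, p = 1; Spearman
on a constant vector raises. The exact Mann–Whitney mode refuses tied data.
Constant design columns raise in `standardize` (named in the error). Scores
and probabilities are clipped only where logarithms require it (deviance,
at 1e-12). Quadrature tolerance for the studentized-range CDF is 1e-8.

## Problem sizes used in the test suite

Monte-Carlo properties run at the defaults above: 10–20 generator seeds for
discovery-screen recovery (2,000 proteins each), 20 seeds for λ_min
component recovery on cohorts of 500, B = 200–10,000 for bootstrap checks.
The acceptance script uses 100,000 draws per arm for the Gaussian FGL2
simulation and B = 1,000 for the bootstrap interval, matching the published
analysis.

## Known limitations

* The per-protein Welch/Mann–Whitney test is a stand-in for a feature-level
  DIA model; equivalence is not claimed.
* The four-group filter's power ceiling (above) means the candidate funnel
  on synthetic data recovers planted biomarkers in a majority — not all —
  of runs.
* No elastic-net mixing, grouped penalties, or post-selection inference on
  penalized coefficients; no partial AUC or smoothed ROC curves; no
  calibration or decision-curve analysis.
* The composite score's published ablation AUC (0.78 without FGL2) depends
  on the unpublished joint distribution of the components and is checked
  only directionally (removing FGL2 lowers mean AUC on synthetic cohorts).
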