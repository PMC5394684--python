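# Methods

This note documents the models implemented in `adsubtype`, their
assumptions, the tunable parameters, what the synthetic generator does and
does not emulate, and the numerical choices made where the design was open.

## Subtype decision rule

Each subject carries four ordinal ratings: MTA left/right (0–4), PA (0–3),
GCA-F (0–3); zero denotes no atrophy. The two MTA sides are combined by
arithmetic mean (`composite_mta`, rule `"mean"`), producing the half-point
grid {0, 0.5, …, 4} that the half-integer cutoffs presuppose; a `"max"`
(worse-side) rule is available for sensitivity analyses. Abnormality is
inclusive (score ≥ threshold) everywhere. MTA thresholds are age-banded —
1.5, 1.5, 2, 2.5 for bands 45–64, 65–74, 75–84, 85–94 years — because
medial temporal atrophy accumulates in normal ageing; PA and GCA-F use a
single threshold of 1. Band membership is half-open on the right against
the next band's lower edge (age 64.5 → younger band) and the last band is
closed at 94. Ages outside 45–94 raise by default; `clamp=True` clamps to
the nearest band (the literature gives no rule, so silence is the safe
default). Per-side ratings must be integers; only the bilateral composite
may be half-integer.

The four labels are the 2×2 of "MTA abnormal" × "cortex (PA and/or GCA-F)
abnormal"; the predicates are mutually exclusive and jointly exhaustive by
construction, verified exhaustively over all 576 composite × PA × GCA-F ×
band combinations in the test suite. Only subjects flagged as AD are
labelled; controls pass through unlabelled, mirroring clinical use.

## Synthetic cohort generator

The generator defines the study conditions for every downstream test. Key
design choice: the subtype label is sampled *first* and ratings are drawn
uniformly from the label's admissible region given the subject's age band
(abnormal-MTA labels draw the composite from the grid at/above the band
threshold; cortex-abnormal labels draw (PA, GCA-F) uniformly from the 15
cells with at least one scale ≥ 1). This inverts the analysis direction and
guarantees the classifier recovers generating labels with zero error —
which is precisely what makes the classifier testable. Controls receive
ratings from the all-normal region.

Default group sizes are 230 controls and 100/33/35/30 AD subjects; default
demographics (age, education, % female, baseline MMSE/CDR means and SDs)
follow the motivating cohort's descriptive table.

Cognitive scores are generated on a standardized latent scale: predictors
(TMT-B, digit symbol, BNT, semantic fluency, learning) are drawn from a
zero-mean unit-variance joint with configurable correlation (identity, i.e.
orthogonal, by default), and each memory outcome is Σ βⱼxⱼ + ε with residual
variance 1 − βᵀΣβ, so target standardized coefficients are exact in
expectation. Per-group default β's are the published delayed-recall models
(e.g. healthy controls: learning 0.744; no-atrophy: learning 0.725, digit
symbol −0.336). The latents are then affinely mapped to test-score units and
truncated to valid ranges last, with truncation flagged per subject —
rescaling after generation preserves the correlation structure, truncation
slightly attenuates it (flagged so analysts can exclude). The raw-unit
means/SDs per group (e.g. HC learning 45 ± 9 of 75 words, AD delayed recall
1.5–2.5 ± 2 of 15) are free calibration constants chosen for plausible
control–patient separation; they are not published quantities.

Longitudinal CDR and MMSE follow y_ij = α_g + b_i + β_g·t + γ_g·t² + ε_ij
with b_i ~ N(0, σ_b²), ε ~ N(0, σ²), visits at 0/1/2 years. Default slopes
are the published fixed-effect estimates: CDR 0.03 (HC), 0.29, 0.28, 0.16,
0.14; MMSE −0.01 (HC), −2.69, −3.08, −1.48 — the no-atrophy MMSE slope is
not printed anywhere, so the default −1.60 is a calibration constant chosen
at the mild end of the published AD range. Variance components are likewise
unpublished; defaults σ_b = 0.2, σ = 0.15 (CDR) and σ_b = 1.5, σ = 1.0
(MMSE) are free constants documented here. γ_g defaults to 0 (published
progression is linear). CDR is simulated continuously (the model scale);
optional rounding to half points exists but is off by default. Longitudinal
ratings follow a monotone step process: each scale independently increments
one grade per follow-up visit with configurable probability, capped at the
scale maximum.

All randomness flows from one seed through named, deterministically spawned
substreams; identical spec + seed gives byte-identical CSV output.

**What the generator does not emulate:** informative dropout, practice
effects, floor/ceiling-induced skew beyond simple truncation, rater
disagreement in the generated ratings, correlations between demographics and
cognition, and ordinal CDR measurement. Passing recovery tests therefore
demonstrates estimator correctness under the stated generating model, not
robustness to these real-data features.

## Memory profiling

AVLT components: learning = Σ trials 1–5 (0–75); interference = list-B
recall; immediate and delayed free recall and recognition (each 0–15);
delayed% and recognition% relative to the 15-word list; gain =
recognition% − delayed% in percentage points. Positive gain means the
subject recognizes more than they freely retrieve — benefit from cues, i.e.
a retrieval rather than a storage problem. (The source literature states
the subtraction in both directions in different places; this orientation is
the one consistent with "higher gain = more retrieval problems".)

Impairment is flagged against reference-group norms (mean/SD, ddof = 1) at
1.5 SD: performance components at z ≤ −1.5 (boundary inclusive), gain at
z ≥ +1.5. The split-plot ANOVA (between = subtype, within = component) runs
on z-standardized components so the within-factor levels share a scale —
this also makes the interaction F invariant to affine rescaling of any
single component. Covariates are handled by residualizing each standardized
component on centered covariates before the ANOVA. Sphericity is not
corrected by default; Greenhouse–Geisser is available via `correction=True`.
Complete cases across components are required per subject (the split-plot
design needs every within level).

## Backward regression and dominance analysis

Backward elimination drops the predictor with the largest p-value while that
p ≥ 0.10 (the classic convention; configurable) and reports standardized β
of the final model (outcome and retained predictors z-scored before the
final fit). Complete-case analysis per model; rank deficiency is detected up
front and reported with the offending columns.

General dominance weights are computed by exhaustive enumeration of all 2^p
subset OLS fits: the weight of predictor j is the mean over subset sizes of
the mean incremental R² from adding j to each subset excluding j. This
equals j's Shapley value over predictor orderings — verified against an
independent p!-ordering brute-force oracle to 1e−10 in the tests — and the
weights sum to the full-model R² to machine precision. p is capped at 20.

Bootstrap stability resamples rows (cases, not residuals — the procedure is
non-parametric) B = 1000 times, recomputes the weights, and calls a
predictor *stable* when the lower bound of its 95% percentile interval
exceeds a floor of 0.01 (1% of outcome variance). The published stability
criterion is verbal only; floor and interval are explicit, configurable
stand-ins and are logged with every result. `reconcile` reports only
predictors that are both backward-retained and bootstrap-stable, listing
retained-but-unstable predictors as rejected.

## Longitudinal mixed models

Fixed effects: group, time, group×time (optionally time², group×time²,
centered covariates); random effect: per-subject intercept (a random slope
is available behind a flag but off by default, matching the
intercept-only design). Estimation is REML; the linear-vs-quadratic
comparison refits both models by ML and uses a likelihood-ratio χ² with df
equal to the number of quadratic terms, since REML likelihoods are not
comparable across fixed-effect structures. Absolute per-group slopes are
reference slope + interaction offset, with standard errors from the
fixed-effect covariance.

Slope contrasts are Wald t tests with a residual-df convention
(df = n_obs − n_fixed-effects). A Satterthwaite approximation was
considered and not implemented: the underlying REML machinery does not
expose the pieces needed, the published df convention for these contrasts
is unstated, and at the cohort sizes involved (hundreds of subjects) the
t is indistinguishable from z. Contrast families are BH-adjusted.

Degenerate noise-free data (exact linear interpolation) leaves the variance
components unidentifiable; in that case the fitted fixed effects are the
exact OLS solution (to which GLS reduces for any variance value), returned
with zero standard errors and flagged internally. This preserves exact
recovery in the zero-noise limit (tested to 1e−8).

## Characterization utilities

Random forest: 500 trees by default (the only specified hyperparameter);
everything else follows library defaults (√p features per split, unlimited
depth), recorded in the result object. Per-group error uses out-of-bag
votes; a stratified k-fold alternative exists behind `method="kfold"`.
Chance error for G equally weighted groups is 100·(1 − 1/G)% — 80% for the
five study groups.

Weighted κ = 1 − (Σ wᵢⱼOᵢⱼ)/(Σ wᵢⱼEᵢⱼ) with disagreement weights |i−j|
(linear, the default — common for Scheltens-family scales) or (i−j)²
(quadratic); E is the outer product of the marginals. Verified against an
independent implementation in the tests. κ on an empty or mismatched pair
raises; a degenerate table with zero expected disagreement returns κ = 1.

Benjamini–Hochberg adjustment is the standard step-up: sort, multiply by
m/rank, enforce monotonicity from the largest p downwards, cap at 1.

## Problem sizes

The recovery experiments run at 500 subjects per group (3 visits) for the
mixed models and n = 2000 for the regressions — sizes at which the
estimator standard errors are several times smaller than the reporting
tolerances, so recovery is informative rather than lucky. Simulation-based
calibration tests (type-I rates, FDR control) use a few hundred to a few
thousand replicates, enough for ~3-σ binomial bounds around the nominal
rates.

## Known limitations

* The classifier is a faithful implementation of one published cutoff
  scheme; alternative cutoff tables must be supplied explicitly.
* Dominance analysis reports general dominance weights only (what the
  motivating analysis tabulates), not conditional/complete dominance ranks.
* The ANOVA's published degrees of freedom could not be reconciled with a
  5-within × 4-between split-plot design, so reproducing that specific F
  statistic is out of scope; the implementation reports the standard
  split-plot decomposition.
* No modelling of dropout or missing-not-at-random follow-up; thinning in
  the generator is missing-completely-at-random.
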