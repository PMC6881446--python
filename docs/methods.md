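# Methods

## The prediction problem

The target is all-cause death within 30 days of hospital admission for adult
(≥ 16 y) TBI patients undergoing ICP monitoring in the ICU. Predictions are
issued on a fixed schedule — first at 24 h after admission, then every 8 h up
to 120 h (13 timepoints) — using only data observed up to each prediction
time. Two model variants exist: ICP-MAP-CPP (monitor data only, fully
automatic) and ICP-MAP-CPP-GCS (adds the motor and eye GCS components, which
require bedside assessment).

## Preprocessing

Raw monitor samples arrive at 1–5 minute spacing. Each sample's timestamp is
rounded to the nearest 5-minute grid point (round-half-up at the 2.5-min
boundary; the convention at ties is a design choice) and all samples landing
on the same grid point are reduced to their median. Values strictly outside
ICP ∈ [0, 100] mmHg or MAP ∈ [20, 150] mmHg are artifacts; boundary values are
kept because the exclusion is written as a strict inequality. The filter runs
on the raw samples *before* the median (so artifacts cannot bias the
aggregate) and again on the grid as a no-op safety net; both passes use the
same bounds. CPP is derived as MAP − ICP only at grid points where both
channels have a value; absence propagates.

Cohort rules: the ICP monitoring span (last grid time − first grid time,
ignoring interior gaps — "span" is not defined elsewhere, so we chose the
extent) must exceed 24 h; deaths at or before 36 h are excluded; for deaths
within 120 h everything after (death − 12 h) is discarded to keep
treatment-withdrawal physiology out of the training data. The 30-day clock
starts at admission, which the baseline table must carry. Nothing is ever
imputed: a missing window yields a missing feature, and a patient missing a
required feature at a timepoint is simply not scored at that timepoint.

## Derived series and features

Every feature is an (signal, statistic, aspect) triple.

**Rolling windows.** A derived series reduces one channel with one statistic
over half-open windows (end − L, end], anchored at the patient's monitoring
start. For the continuous channels L = step = 4 h. For the GCS components the
window is L = 24 h **stepping by 8 h**: GCS is observed only at ~12-hourly
wake-up tests, so a 4-h window would usually be empty, while a 24-h step would
leave the trailing-8-h aspects undefined at 8 of the 13 prediction times and
the slope aspect undefined at 24 h — incompatible with a day-1 prediction
from GCS features. Overlapping 24-h windows at the 8-h prediction cadence are
the only reading under which every documented GCS feature ("mean eye response
in the last 8 h", a GCS slope at day 1) is computable; this is the one place
we deviated from a literal equal-step reading.

**Statistics.** mean; diff = mean of consecutive *signed* differences (≥ 2
values, else missing); population variance; q90/q10 with linear interpolation
between order statistics (no convention is documented; this is numpy's
default); min; max; ht20/lt10/ht120 = fraction of values strictly
above/below the threshold. Empty windows produce gaps, never zeros.

**Aspects.** `begin` = mean (or extreme, for min/max statistics) of derived
points in the first 24 h of monitoring; `end` = mean/extreme over the trailing
8 h (t − 8 h, t]; `coef` = OLS slope (units/hour) of the derived series from
monitoring start up to t, missing with fewer than two points; `last` = the
most recent derived point in the trailing 8 h (used by the last-window min/max
and threshold-fraction features). The "begin" anchor is each patient's
monitoring start, not admission.

**Candidate sets.** Continuous signals contribute
{mean, diff, var, q90, q10} × {begin, end, coef} + last-window min/max
(17 each), plus icp_ht20, icp_lt10, map_ht120 → 54. The GCS variant adds
{mean, var} × {begin, end, coef} + min/max × {begin, end} per component → 74.
The published full enumeration is not available; this scheme is the canonical
reconstruction consistent with the documented counts and every documented
feature name. The ordinal age category ([16,30) → 0, … , 75+ → 1; 15-year
bands, since no banding is documented) is appended to both sets.

Feature values are min-max normalized to [0, 1] with bounds learned on
training rows only; application-time values are clipped; a degenerate feature
(max = min in training) maps to 0.5.

## Model and selection

Training rows are pooled (patient, prediction-time) instances over the whole
five-day schedule. The learner is L2-regularized logistic regression with a
deliberately weak penalty (C = 100, recorded in the model artifact; no
regularization is documented, so we chose near-MLE behavior with a numeric
safety net). Coefficients are constant across prediction times.

Recursive feature elimination drops the smallest-|coefficient| feature
repeatedly (exact ties broken lexicographically) and scores every subset size
on the elimination path by patient-grouped, outcome-stratified 3-fold CV AUC
on out-of-fold predictions. Among sizes within 0.005 AUC of the best, the
smallest wins. This parsimony margin is what removes perfectly collinear
duplicates — under L2 a duplicated pair is never *exactly* tied with its
singleton — and it biases selection toward compact models; on synthetic
cohorts, where the mortality signal is concentrated in a few planted effects,
it selects far fewer features than a heterogeneous real cohort would support.

All cross-validation splits group by patient: rows of one patient never appear
on both sides of a split, and normalization bounds and feature selection are
refit inside every training fold (verified by poisoning held-out rows and
checking the trained artifact is unchanged).

## Evaluation

Discrimination is the rank-based (Mann-Whitney) AUC, ties counted 0.5,
computed per prediction time on held-out risks. The curve comes from repeated
stratified 5-fold patient-level CV (20 repetitions by default; repetition
seeds are master seed + repetition index): held-out risks are pooled within a
repetition, an AUC per timepoint per repetition is computed, the point
estimate is the mean over repetitions and the 95% CI the 2.5/97.5 percentiles
of the repetition distribution (the CI construction is undocumented; a
percentile interval over repetitions is the natural choice for a
repetition-level summary). Patients without a usable feature row at t drop out
of that timepoint only.

The misclassification audit uses the *last* prediction per patient at a 50%
threshold, strict: risk > 0.5 in a survivor is a false positive, risk ≤ 0.5 in
a non-survivor a false negative. False positives are broken down by
monitoring duration and last-risk band (borderline 50–57% vs higher).

The static baseline refits logistic regression on the IMPACT admission
covariates (motor ordinal; pupils and Marshall class as indicators with
"both react" / DI I reference levels — the original coding is undocumented);
records missing glucose or hemoglobin are served by a core model without the
labs instead of imputing. Calibration is a 10-bin equal-frequency
observed-vs-predicted curve (a calibration-belt method is out of scope).

## Synthetic cohort generator

The generator emulates the statistical structure the method depends on, not
ICU physiology:

- **Baselines** from marginals typical of an ICP-monitored TBI cohort (age
  lognormal, median 48; 69% admission GCS 3–8; 79% bilaterally reactive
  pupils; 49% mass lesions; ~1% missing labs). Death is drawn from a logistic
  latent risk over age, motor score, pupils, CT class and labs, with the
  intercept calibrated by bisection to the configured mortality (raw default
  0.21, so that the *included* cohort lands near 19% after the 36-h exclusion
  removes part of the early deaths).
- **Vitals** are AR(1)-perturbed (φ = 0.9) piecewise-linear mean trajectories
  sampled every 2 min. Survivors: ICP ~ N(12, 5.5²) mmHg with mild random
  drift; non-survivors: ICP ~ N(15, 5.5²) rising by N(3, 2²) mmHg/day (scaled
  by `effect_ramp`) plus a 10 mmHg terminal ramp over the last 24 h before an
  in-monitoring death. MAP ~ N(85, 9²) identically in both groups, so the CPP
  contrast is ICP-mediated. The natural signal is clipped to the validity
  bounds; artifacts (rate 0.005/sample) are injected strictly outside them and
  tracked in a side file, so the artifact filter must remove exactly the
  injected set. Samples drop out at 0.03/sample.
- **GCS** observed only at 12-hourly wake-up tests; latent motor/eye levels
  (lower and declining for non-survivors, with a pre-death drop) are rounded
  and clipped to the ordinal ranges.
- **Monitoring** lasts N(96, 30²) h clipped to [12, 150] (short stays exercise
  the exclusion rule); non-survivors dying earlier stop at death. Death times
  are uniform on (36, 720] h with a configurable 8% point mass in
  [12, 36) h to exercise the early-death exclusion.

The between-patient spreads were chosen so the groups overlap substantially
rather than separating perfectly. The synthetic cohort still discriminates
more cleanly than a real one (day-1 cross-validated AUC ≈ 0.8 versus reported
levels near 0.67): real mortality has causes the monitored channels never see.
Consequently, passing tests demonstrate that the pipeline recovers planted
time-ramped effects, respects causality and censoring, and reproduces the
qualitative rise of discrimination with monitoring time — not that the
published performance numbers transfer.

## Problem sizes and numerical choices

The acceptance script and the heavier tests run a 300-patient cohort with
5-fold × 5-repetition CV and elimination refit per fold — enough repetitions
for stable means while keeping a full run in minutes; the library default
remains 20 repetitions. The permutation-null check averages pooled
out-of-fold AUC over 20 label shufflings with a fixed feature list. Logistic
fits use lbfgs with max_iter = 5000 and raise with iteration diagnostics on
non-convergence. Grid times are exact integers (minutes); CSV readers parse
floats in round-trip mode so write → read → write is byte-identical; the
single master seed fans out deterministically (simulation per-patient streams
via spawned seed sequences; repetition seeds by offset), making manifests and
outputs bit-reproducible.

## Known limitations

- Single-population generator: no center strata, no treatment-effect
  confounding (ICP-lowering interventions mask risk in real data), no
  decompressive-craniectomy patients — the documented source of real
  false positives.
- The canonical 54/74 feature scheme is a reconstruction; if the original
  algorithms enumerated their candidates differently, the published-model
  feature lists remain valid but candidate membership could differ at the
  margin.
- No per-prediction uncertainty; risks are point estimates.
- The parsimony margin in feature elimination trades a little held-out AUC for
  stability; set `parsimony_tol=0` to recover pure best-subset behavior.
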