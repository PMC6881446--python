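# tbidyn — dynamic 30-day mortality prediction for ICU-treated TBI

Patients with moderate-to-severe traumatic brain injury (TBI) are monitored in
the ICU for intracranial pressure (ICP), mean arterial pressure (MAP) and the
derived cerebral perfusion pressure (CPP = MAP − ICP), alongside intermittent
Glasgow Coma Scale (GCS) assessments. Classical prognostic models (IMPACT-TBI,
CRASH) are *static*: they score the patient once, at admission, and cannot
react to the evolving monitor data. `tbidyn` implements a *dynamic*
alternative: a logistic risk model over rolling-window summary features of the
monitored signals that re-estimates the probability of 30-day death every 8
hours, from 24 h up to 120 h after admission.

Because individual neuromonitoring data cannot be shared, the package includes
a first-class synthetic cohort generator that reproduces the statistical
structure such a cohort exhibits — ~19% 30-day mortality, higher and rising
ICP (hence lower CPP) but similar MAP in non-survivors, declining motor
scores before death, sparse wake-up-test GCS observations, monitoring gaps and
out-of-range artifacts — so the entire pipeline is testable end to end.

## Method

1. **Preprocessing.** Raw samples are median-aggregated to a 5-minute grid
   (nearest grid point, ties round up). Values outside physiologic bounds
   (ICP ∉ [0, 100] mmHg, MAP ∉ [20, 150] mmHg, strict) are removed as
   artifacts. CPP(t) = MAP(t) − ICP(t) where both exist. Patients with ≤ 24 h
   of ICP monitoring or death ≤ 36 h are excluded; for deaths within 120 h the
   last 12 h before death are censored (treatment-withdrawal bias). Gaps are
   never imputed.
2. **Feature engineering.** Each channel is reduced over rolling windows (4 h
   for ICP/MAP/CPP; 24 h windows stepping by 8 h for the GCS motor/eye
   components) with statistics mean, diff (mean of consecutive differences),
   var, q90, q10, min, max and the threshold fractions ht20/lt10 (ICP) and
   ht120 (MAP). At each prediction time t the derived series are reduced by
   aspect: `begin` (first 24 h of monitoring), `end` (trailing 8 h before t)
   and `coef` (OLS slope up to t), giving 54 candidate features for the
   ICP-MAP-CPP variant and 74 for ICP-MAP-CPP-GCS, plus an ordinal age
   category. All features are min-max normalized to [0, 1] on training data.
3. **Model.** One L2-regularized logistic regression on pooled
   (patient × prediction-time) rows, with recursive feature elimination scored
   by patient-grouped stratified CV AUC. Coefficients are constant over time;
   only the feature values roll forward. Per-feature contributions
   (coefficient × normalized value) accompany every prediction.
4. **Evaluation.** Repeated stratified 5-fold cross-validation (folds split by
   patient, 20 repetitions by default) with the whole pipeline refit inside
   each training fold; discrimination is reported as a time-dependent AUC
   curve with percentile 95% CIs, risk distributions by outcome for violin
   plots, and a false-positive/negative audit of the *last* prediction at the
   50% threshold. A static logistic refit on the IMPACT admission covariates
   (age, motor score, pupils, hypoxia, hypotension, Marshall CT class, tSAH,
   epidural mass, glucose, hemoglobin) serves as the comparison baseline, with
   a binned calibration curve.

## Worked example

```python
from tbidyn import SimConfig, simulate_cohort, preprocess, build_feature_matrix
from tbidyn.synthetic import cohort_frames
from tbidyn.evaluation import cross_validated_auc_curve

patients = simulate_cohort(SimConfig(n_patients=200, seed=42))
vitals, baselines, _ = cohort_frames(patients)
cohort, report = preprocess(vitals, baselines)
feat = build_feature_matrix(cohort, "ICP-MAP-CPP")
for e in cross_validated_auc_curve(feat, "ICP-MAP-CPP", n_folds=5, n_repeats=5, seed=42):
    print(f"t={e.t_h:5.0f} h  AUC={e.auc:.2f}  (95% CI {e.ci_low:.2f}-{e.ci_high:.2f}, n={e.n_patients})")
```

prints (every fourth timepoint shown):

```
t=   24 h  AUC=0.85  (95% CI 0.83-0.86, n=197)
t=   48 h  AUC=0.92  (95% CI 0.91-0.93, n=188)
t=   72 h  AUC=0.95  (95% CI 0.94-0.95, n=163)
t=   96 h  AUC=0.95  (95% CI 0.94-0.97, n=98)
t=  120 h  AUC=0.98  (95% CI 0.95-1.00, n=29)
```

Discrimination rises with monitoring time because the simulated
survivor/non-survivor divergence ramps over days — the qualitative signature
of dynamic prognostication (the synthetic cohort separates more cleanly than a
real one would; see `docs/methods.md`). `n` is the number of patients still
contributing a usable feature row at each time: it shrinks as monitoring ends
and as deaths are censored.

The same run from the shell:

```sh
tbidyn run-all --simulate-n 200 --seed 42 --folds 5 --repeats 5 --output-dir run
```

writes `auc_curve.json`, `model.json`, `predictions.csv` (risks plus
per-feature contributions), `risk_distributions.csv`,
`impact_calibration.csv` and a provenance `manifest.json` — identical seeds
give bit-identical outputs.

## Layout

- `src/tbidyn/synthetic.py` — cohort generator (`SimConfig`, `simulate_cohort`, `write_cohort`)
- `src/tbidyn/preprocessing.py` — 5-min grids, artifact filter, CPP, inclusion/censoring
- `src/tbidyn/features.py` — rolling-window derived series, feature scheme, normalization
- `src/tbidyn/model.py` — RFE, pooled logistic fit, rolling prediction, threshold classification
- `src/tbidyn/evaluation.py` — rank AUC, repeated-CV AUC curve, misclassification audit
- `src/tbidyn/impact.py` — static IMPACT-covariate baseline and calibration curve
- `src/tbidyn/published.py` — feature lists of the published algorithms
- `src/tbidyn/pipeline.py`, `src/tbidyn/cli.py` — orchestration, validation, CLI
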