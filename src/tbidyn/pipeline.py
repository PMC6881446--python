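"""End-to-end orchestration: simulate -> preprocess -> featurize -> train ->
predict -> evaluate, with input validation and a reproducibility manifest.

A single master seed fans out deterministically to simulation, fold assignment
and CV repetitions; running the same config twice yields byte-identical
manifests and outputs.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from . import evaluation as ev
from . import features as fe
from . import impact as im
from . import model as md
from . import preprocessing as pp
from .synthetic import SimConfig, simulate_cohort, write_cohort


@dataclass
class RunConfig:
    vitals_path: str | None = None
    baseline_path: str | None = None
    output_dir: str = "tbidyn_run"
    variant: str = "ICP-MAP-CPP"
    seed: int = 0
    first_t_h: int = 24
    step_t_h: int = 8
    last_t_h: int = 120
    decision_threshold: float = 0.5
    cv_folds: int = 5
    cv_repeats: int = 20
    rfe: bool = True
    rfe_folds: int = 3
    C: float = md.DEFAULT_C
    simulate_n: int | None = None  # when set, generate the cohort first
    sim: dict = field(default_factory=dict)  # extra SimConfig overrides

    def __post_init__(self) -> None:
        if self.first_t_h < 24 or self.step_t_h <= 0 or self.last_t_h < self.first_t_h:
            raise ValueError("prediction schedule must satisfy first_t >= 24 h, step > 0")

    @property
    def times_h(self) -> tuple[int, ...]:
        return tuple(range(self.first_t_h, self.last_t_h + 1, self.step_t_h))

    def to_dict(self) -> dict:
        return asdict(self)


class StageError(RuntimeError):
    def __init__(self, stage: str, exc: BaseException):
        super().__init__(f"[{stage}] {exc}")
        self.stage = stage


def validate_inputs(vitals_path, baseline_path) -> dict:
    """Schema, dtype, range and referential checks; report-only, data untouched."""
    violations: list[str] = []
    vitals = pp.load_vitals_csv(vitals_path)
    base = pp.load_baseline_csv(baseline_path)

    for col in ("patient_id", "t_min", "channel", "value"):
        if col not in vitals.columns:
            violations.append(f"vitals: missing column {col!r}")
    missing_base = [c for c in im.BASELINE_COLUMNS if c not in base.columns]
    for col in missing_base:
        violations.append(f"baseline: missing column {col!r}")
    if violations:
        return {"violations": violations, "n_vitals_rows": len(vitals), "n_baseline_rows": len(base)}

    bad_channel = ~vitals["channel"].isin(pp.CSV_CHANNELS)
    if bad_channel.any():
        violations.append(f"vitals: {int(bad_channel.sum())} rows with unknown channel")
    t = pd.to_numeric(vitals["t_min"], errors="coerce")
    if t.isna().any():
        violations.append(f"vitals: {int(t.isna().sum())} non-numeric t_min values")
    elif (t < 0).any():
        violations.append(f"vitals: {int((t < 0).sum())} negative t_min values")
    v = pd.to_numeric(vitals["value"], errors="coerce")
    if v.isna().any():
        violations.append(f"vitals: {int(v.isna().sum())} non-numeric values")

    no_base = ~vitals["patient_id"].astype(str).isin(base["patient_id"].astype(str))
    if no_base.any():
        n = vitals.loc[no_base, "patient_id"].nunique()
        violations.append(f"referential: {n} vitals patients without a baseline row")
    bad_motor = ~base["motor"].isin(range(1, 7))
    if bad_motor.any():
        violations.append(f"baseline: {int(bad_motor.sum())} motor scores outside 1-6")
    bad_pupils = ~base["pupils"].isin(im.PUPIL_LEVELS)
    if bad_pupils.any():
        violations.append(f"baseline: {int(bad_pupils.sum())} invalid pupil levels")
    bad_marshall = ~base["marshall"].isin(im.MARSHALL_LEVELS)
    if bad_marshall.any():
        violations.append(f"baseline: {int(bad_marshall.sum())} invalid Marshall classes")
    death = pd.to_numeric(base["death_time_h"], errors="coerce")
    adm = pd.to_numeric(base["admission_time_h"], errors="coerce").fillna(0.0)
    before = death.notna() & (death < adm)
    if before.any():
        violations.append(f"integrity: {int(before.sum())} deaths before admission")
    return {"violations": violations, "n_vitals_rows": len(vitals), "n_baseline_rows": len(base)}


def _config_hash(config: RunConfig) -> str:
    blob = json.dumps(config.to_dict(), sort_keys=True).encode()
    return hashlib.sha256(blob).hexdigest()


def run_pipeline(config: RunConfig) -> dict:
    """Execute every stage and write artifacts + manifest to the output dir."""
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "config": config.to_dict(),
        "config_sha256": _config_hash(config),
        "seed": config.seed,
        "version": __version__,
        "stages": {},
    }

    # ---- simulate (optional)
    vitals_path, baseline_path = config.vitals_path, config.baseline_path
    if config.simulate_n is not None:
        try:
            sim_cfg = SimConfig(n_patients=config.simulate_n, seed=config.seed, **config.sim)
            patients = simulate_cohort(sim_cfg)
            vitals_path = str(out / "vitals.csv")
            baseline_path = str(out / "baseline.csv")
            write_cohort(patients, vitals_path, baseline_path, str(out / "artifact_flags.csv"))
            manifest["stages"]["simulate"] = {"n_patients": len(patients)}
        except Exception as exc:
            raise StageError("simulate", exc) from exc
    if vitals_path is None or baseline_path is None:
        raise StageError("input", ValueError("vitals_path and baseline_path required"))

    # ---- load + preprocess
    try:
        vitals = pp.load_vitals_csv(vitals_path)
        baselines = pp.load_baseline_csv(baseline_path)
        cohort, report = pp.preprocess(vitals, baselines)
        manifest["stages"]["preprocess"] = {
            "rows_in": report.rows_in,
            "rows_kept": report.rows_kept,
            "rows_rejected": report.rows_rejected,
            "rows_filtered": report.rows_filtered,
            "n_included": len(cohort.patients),
            "n_excluded": report.n_excluded,
        }
        if not cohort.patients:
            raise ValueError("no patients pass inclusion rules")
    except StageError:
        raise
    except Exception as exc:
        raise StageError("preprocess", exc) from exc

    # ---- featurize
    try:
        feat = fe.build_feature_matrix(cohort, config.variant, config.times_h)
        feat.reset_index().to_csv(out / "features.csv", index=False)
        manifest["stages"]["featurize"] = {
            "n_rows": len(feat),
            "n_features": len(fe.feature_columns(feat)),
            "missing_cells": int(feat[fe.feature_columns(feat)].isna().sum().sum()),
        }
    except Exception as exc:
        raise StageError("featurize", exc) from exc

    # ---- evaluate (repeated stratified CV)
    try:
        evals = ev.cross_validated_auc_curve(
            feat, config.variant, n_folds=config.cv_folds, n_repeats=config.cv_repeats,
            seed=config.seed, select_features=config.rfe, C=config.C,
            rfe_folds=config.rfe_folds)
        curve = [e.to_dict() for e in evals]
        with open(out / "auc_curve.json", "w") as fh:
            json.dump(curve, fh, indent=1, sort_keys=True)
        manifest["stages"]["evaluate"] = {"auc_curve": curve}
    except Exception as exc:
        raise StageError("evaluate", exc) from exc

    # ---- train final model + rolling predictions
    try:
        final = md.fit_dynamic_model(feat, config.variant, seed=config.seed,
                                     select=config.rfe, C=config.C,
                                     rfe_folds=config.rfe_folds)
        final.save(out / "model.json")
        tracks = [md.predict_rolling(final, p, config.times_h) for p in cohort.patients]
        labels = cohort.labels()
        rows = []
        for tr in tracks:
            for t, r, contrib in zip(tr.t_h, tr.risk, tr.contributions):
                rows.append({"patient_id": tr.patient_id, "t_h": t, "risk": r,
                             **{f"contrib_{k}": v for k, v in contrib.items()}})
        pd.DataFrame(rows).to_csv(out / "predictions.csv", index=False)
        monitoring_h = {p.patient_id: (p.usable_end - p.monitoring_start) / 60.0
                        for p in cohort.patients}
        misclass = ev.misclassification_report(tracks, labels, monitoring_h,
                                               config.decision_threshold)
        violin = ev.risk_distribution_over_time(tracks, labels)
        violin.to_csv(out / "risk_distributions.csv", index=False)
        manifest["stages"]["predict"] = {
            "n_tracks": len(tracks),
            "selected_features": final.feature_names,
            "confusion": misclass["counts"],
            "fp_by_band": misclass["fp_by_band"],
        }
    except Exception as exc:
        raise StageError("predict", exc) from exc

    # ---- static IMPACT baseline
    try:
        base_idx = pd.Index([p.patient_id for p in cohort.patients])
        base_df = pd.DataFrame([p.baseline for p in cohort.patients], index=base_idx)
        impact_model = im.fit_impact_model(base_df, labels)
        static_risks = impact_model.predict(base_df)
        cal = im.calibration_curve(static_risks, labels)
        cal.to_csv(out / "impact_calibration.csv", index=False)
        comparison = im.compare_static_vs_dynamic(static_risks, tracks, labels,
                                                  config.decision_threshold)
        manifest["stages"]["impact_baseline"] = {
            "auc": ev.auc(static_risks.to_numpy(), labels.to_numpy()),
            "comparison": comparison,
        }
    except Exception as exc:
        raise StageError("impact_baseline", exc) from exc

    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True, default=_json_default)
    return manifest


def _json_default(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    raise TypeError(f"not JSON serializable: {type(obj)}")
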