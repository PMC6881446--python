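"""Static admission-covariate baseline: refit logistic model on IMPACT covariates.

The IMPACT covariate set describes the patient at admission: age, admission
GCS motor score, pupillary light reactivity, pre-hospital hypoxia (SpO2 < 90%)
and hypotension (SBP < 90 mmHg), Marshall CT class, traumatic subarachnoid
hemorrhage, epidural mass, and the laboratory pair glucose / hemoglobin. The
coefficients are refit on the cohort at hand (not the published scores); the
lab model is used wherever glucose and hemoglobin are available, and records
missing either fall back to a core model without the labs rather than being
imputed. Calibration is summarized as a binned observed-vs-predicted curve
over equal-frequency risk bins.
"""

from __future__ import annotations

from dataclasses import dataclass
import warnings

import numpy as np
import pandas as pd
from sklearn.linear_model import LogisticRegression

from .evaluation import auc
from .model import RiskTrack, classify_at_threshold

PUPIL_LEVELS = ("both", "one", "none")
MARSHALL_LEVELS = ("DI_I", "DI_II", "DI_III", "DI_IV", "EML_NEML")

BASELINE_COLUMNS = [
    "patient_id", "age", "motor", "pupils", "hypoxia", "hypotension",
    "marshall", "tsah", "epidural_mass", "glucose", "hb",
    "admission_time_h", "death_time_h",
]

#: admission covariates; motor kept ordinal, categorical fields as indicator levels
CORE_TERMS = ["age", "motor", "pupils_one", "pupils_none", "hypoxia", "hypotension",
              "marshall_DI_II", "marshall_DI_III", "marshall_DI_IV", "marshall_EML_NEML",
              "tsah", "epidural_mass"]
LAB_TERMS = CORE_TERMS + ["glucose", "hb"]


def encode_impact(baselines: pd.DataFrame, include_labs: bool) -> pd.DataFrame:
    """Design matrix for the IMPACT refit (reference levels: both pupils, DI I)."""
    d = pd.DataFrame(index=baselines.index)
    d["age"] = baselines["age"].astype(float)
    d["motor"] = baselines["motor"].astype(float)
    for lev in PUPIL_LEVELS[1:]:
        d[f"pupils_{lev}"] = (baselines["pupils"] == lev).astype(float)
    d["hypoxia"] = baselines["hypoxia"].astype(float)
    d["hypotension"] = baselines["hypotension"].astype(float)
    for lev in MARSHALL_LEVELS[1:]:
        d[f"marshall_{lev}"] = (baselines["marshall"] == lev).astype(float)
    d["tsah"] = baselines["tsah"].astype(float)
    d["epidural_mass"] = baselines["epidural_mass"].astype(float)
    if include_labs:
        d["glucose"] = baselines["glucose"].astype(float)
        d["hb"] = baselines["hb"].astype(float)
    return d[LAB_TERMS if include_labs else CORE_TERMS]


@dataclass
class ImpactModel:
    """Lab-variant logistic refit with a core-covariate fallback for missing labs."""

    lab: LogisticRegression
    core: LogisticRegression
    lab_terms: list[str]
    core_terms: list[str]

    def predict(self, baselines: pd.DataFrame) -> pd.Series:
        idx = baselines.index
        risks = pd.Series(np.nan, index=idx, name="impact_risk")
        has_labs = baselines["glucose"].notna() & baselines["hb"].notna()
        if has_labs.any():
            X = encode_impact(baselines[has_labs], include_labs=True)
            risks[has_labs] = self.lab.predict_proba(X.to_numpy())[:, 1]
        if (~has_labs).any():
            X = encode_impact(baselines[~has_labs], include_labs=False)
            risks[~has_labs] = self.core.predict_proba(X.to_numpy())[:, 1]
        return risks


def fit_impact_model(baselines: pd.DataFrame, labels: pd.Series, C: float = 100.0) -> ImpactModel:
    """Refit logistic models on IMPACT admission covariates (one row per patient).

    The lab model is fit on complete-case rows; the core model (no glucose/Hb)
    on all rows, serving records with missing labs.
    """
    y = labels.reindex(baselines.index).astype(int)
    if y.nunique() < 2:
        raise ValueError("IMPACT refit requires both outcome classes")
    complete = baselines["glucose"].notna() & baselines["hb"].notna()
    Xlab = encode_impact(baselines[complete], include_labs=True)
    Xcore = encode_impact(baselines, include_labs=False)
    lab = LogisticRegression(C=C, solver="lbfgs", max_iter=5000)
    lab.fit(Xlab.to_numpy(), y[complete].to_numpy())
    core = LogisticRegression(C=C, solver="lbfgs", max_iter=5000)
    core.fit(Xcore.to_numpy(), y.to_numpy())
    return ImpactModel(lab=lab, core=core, lab_terms=LAB_TERMS, core_terms=CORE_TERMS)


def impact_auc(model: ImpactModel, baselines: pd.DataFrame, labels: pd.Series) -> float:
    risks = model.predict(baselines)
    return auc(risks.to_numpy(), labels.reindex(baselines.index).to_numpy())


def calibration_curve(predicted: pd.Series, labels: pd.Series, n_bins: int = 10) -> pd.DataFrame:
    """Observed mortality vs mean predicted risk over equal-frequency bins."""
    p = pd.Series(predicted).astype(float)
    y = pd.Series(labels).reindex(p.index).astype(int)
    if len(p) < n_bins:
        warnings.warn(f"only {len(p)} predictions; reducing bins from {n_bins}")
        n_bins = max(1, len(p))
    bins = pd.qcut(p.rank(method="first"), q=n_bins, labels=False)
    rows = []
    for b in range(n_bins):
        m = bins == b
        if not m.any():
            continue
        rows.append({"bin": b, "n": int(m.sum()),
                     "mean_predicted": float(p[m].mean()),
                     "observed_rate": float(y[m].mean())})
    return pd.DataFrame(rows)


def compare_static_vs_dynamic(
    static_risks: pd.Series,
    tracks: list[RiskTrack],
    labels: pd.Series,
    threshold: float = 0.5,
) -> dict:
    """Among patients the static model calls fatal, how does the dynamic model do?

    Mirrors the audit of static false positives: of the patients with static
    risk above the threshold, count deaths, static FPs, and the dynamic
    model's last-prediction classification on the same patients.
    """
    labels = pd.Series(labels)
    if set(static_risks.index) != set(labels.index):
        raise ValueError("static risks and labels cover different patient sets")
    by_pid = {t.patient_id: t for t in tracks}
    if not set(by_pid).issubset(set(labels.index)):
        raise ValueError("dynamic tracks include patients outside the labeled cohort")
    high = static_risks[static_risks > threshold]
    dyn_counts = {"TP": 0, "FP": 0, "TN": 0, "FN": 0, "unclassified": 0}
    for pid in high.index:
        tr = by_pid.get(pid)
        cls = classify_at_threshold(tr, bool(labels[pid]), threshold) if tr else None
        dyn_counts[cls if cls else "unclassified"] += 1
    n_died = int(labels[high.index].sum())
    return {
        "threshold": threshold,
        "n_static_predicted_death": int(len(high)),
        "n_of_those_died": n_died,
        "static_false_positives": int(len(high) - n_died),
        "dynamic_on_same_patients": dyn_counts,
        "dynamic_false_positives": dyn_counts["FP"],
        "dynamic_misclassified": dyn_counts["FP"] + dyn_counts["FN"],
    }
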