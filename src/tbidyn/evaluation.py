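"""Time-dependent cross-validated discrimination and misclassification accounting.

Discrimination is summarized as an AUC curve over the prediction schedule:
within each repetition of a patient-level stratified K-fold split, the entire
training pipeline (normalization bounds, feature elimination, logistic fit) is
re-run inside the training fold and the held-out patients are scored; the
held-out risks of one repetition are pooled and an AUC is computed per
prediction time. The point estimate at each time is the mean over repetitions
and the 95% CI the 2.5/97.5 percentiles of the repetition distribution.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import rankdata
from sklearn.model_selection import StratifiedKFold

from . import features as fe
from .model import DEFAULT_C, RiskTrack, TrainedDynamicModel, classify_at_threshold, fit_dynamic_model

#: last-risk bands used in the false-positive breakdown
FP_RISK_BANDS = ((0.5, 0.57, "50-57%"), (0.57, 0.62, "57-62%"),
                 (0.62, 0.74, "62-74%"), (0.74, 1.0, ">74%"))


def auc(scores, labels) -> float:
    """Rank-based (Mann-Whitney) AUC; ties count 0.5; NaN if one class only."""
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels, dtype=int)
    ok = ~np.isnan(s)
    s, y = s[ok], y[ok]
    n1 = int(y.sum())
    n0 = int(y.size - n1)
    if n1 == 0 or n0 == 0:
        return math.nan
    r = rankdata(s)
    u = r[y == 1].sum() - n1 * (n1 + 1) / 2.0
    return float(u / (n1 * n0))


@dataclass
class TimepointEvaluation:
    t_h: float
    auc: float
    ci_low: float
    ci_high: float
    n_patients: int
    #: pooled held-out risks for violin rendering, by outcome group
    risks_by_group: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {"t_h": self.t_h, "auc": self.auc, "ci_low": self.ci_low,
                "ci_high": self.ci_high, "n_patients": self.n_patients}


def _patient_table(feature_df: pd.DataFrame) -> tuple[np.ndarray, np.ndarray]:
    lab = feature_df.groupby(level="patient_id", sort=True)["label"].first()
    return lab.index.to_numpy(), lab.to_numpy(dtype=int)


def fit_fold(
    feature_df: pd.DataFrame,
    train_pids,
    variant: str,
    seed: int,
    select_features: bool = True,
    feature_subset: list[str] | None = None,
    C: float = DEFAULT_C,
    rfe_folds: int = 3,
) -> TrainedDynamicModel:
    """Train the full pipeline on the rows of the given patients only.

    Splitting by patient id (never by row) is the leakage guard: nothing from
    held-out patients can reach the normalization bounds or the selection.
    """
    train_df = feature_df.loc[feature_df.index.get_level_values("patient_id").isin(set(train_pids))]
    return fit_dynamic_model(train_df, variant, seed=seed, select=select_features,
                             feature_subset=feature_subset, C=C, rfe_folds=rfe_folds)


def cross_validated_auc_curve(
    feature_df: pd.DataFrame,
    variant: str,
    n_folds: int = 5,
    n_repeats: int = 20,
    seed: int = 0,
    select_features: bool = True,
    feature_subset: list[str] | None = None,
    C: float = DEFAULT_C,
    rfe_folds: int = 3,
    return_risks: bool = False,
):
    """Repeated stratified patient-level K-fold AUC as a function of time.

    Returns a list of TimepointEvaluation (one per scheduled time present in
    the matrix); with ``return_risks`` also the long table of held-out risks
    (repetition, patient_id, t_h, risk, label).
    """
    pids, pid_labels = _patient_table(feature_df)
    if len(np.unique(pid_labels)) < 2:
        raise ValueError("cohort contains a single outcome class")
    times = sorted(feature_df.index.get_level_values("t_h").unique())
    held_out = []
    per_rep_auc: dict[float, list[float]] = {t: [] for t in times}

    for rep in range(n_repeats):
        rep_seed, tries = seed + rep, 0
        while True:
            skf = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=rep_seed)
            folds = list(skf.split(pids.reshape(-1, 1), pid_labels))
            if all(len(np.unique(pid_labels[tr])) == 2 for tr, _ in folds):
                break
            tries += 1
            rep_seed = seed + n_repeats + 9973 * tries + rep  # re-draw, deterministic
            warnings.warn(f"repetition {rep}: fold lacked both classes, re-drawing")
            if tries > 50:
                raise ValueError("cannot build stratified folds with both classes")
        rep_rows = []
        for tr, te in folds:
            model = fit_fold(feature_df, pids[tr], variant, seed=rep_seed,
                             select_features=select_features,
                             feature_subset=feature_subset, C=C, rfe_folds=rfe_folds)
            test_mask = feature_df.index.get_level_values("patient_id").isin(set(pids[te]))
            test_df = feature_df.loc[test_mask]
            risks = model.predict_frame(test_df)
            out = test_df.loc[risks.index, ["label"]].copy()
            out["risk"] = risks
            rep_rows.append(out)
        rep_df = pd.concat(rep_rows)
        rep_df["repetition"] = rep
        held_out.append(rep_df)
        for t in times:
            sub = rep_df.xs(t, level="t_h")
            per_rep_auc[t].append(auc(sub["risk"].to_numpy(), sub["label"].to_numpy()))

    all_df = pd.concat(held_out).reset_index()
    evals = []
    for t in times:
        vals = np.asarray(per_rep_auc[t], dtype=float)
        vals = vals[~np.isnan(vals)]
        sub = all_df[all_df["t_h"] == t]
        groups = {
            "survivor": sub.loc[sub["label"] == 0, "risk"].to_numpy(),
            "nonsurvivor": sub.loc[sub["label"] == 1, "risk"].to_numpy(),
        }
        if vals.size == 0:
            evals.append(TimepointEvaluation(float(t), math.nan, math.nan, math.nan,
                                             sub["patient_id"].nunique(), groups))
            continue
        evals.append(TimepointEvaluation(
            t_h=float(t),
            auc=float(vals.mean()),
            ci_low=float(np.percentile(vals, 2.5)),
            ci_high=float(np.percentile(vals, 97.5)),
            n_patients=int(sub["patient_id"].nunique()),
            risks_by_group=groups,
        ))
    if return_risks:
        return evals, all_df
    return evals


def misclassification_report(
    tracks: list[RiskTrack],
    labels: dict[str, int] | pd.Series,
    monitoring_hours: dict[str, float] | None = None,
    threshold: float = 0.5,
) -> dict:
    """Confusion totals from last predictions, with a false-positive breakdown.

    The FP stratum detail mirrors a clinical audit: how long each FP was
    monitored and in which band its last risk fell (borderline 50-57% calls
    versus confident ones).
    """
    labels = pd.Series(labels)
    counts = {"TP": 0, "FP": 0, "TN": 0, "FN": 0}
    unclassifiable, fp_detail = [], []
    for tr in tracks:
        cls = classify_at_threshold(tr, bool(labels[tr.patient_id]), threshold)
        if cls is None:
            unclassifiable.append(tr.patient_id)
            continue
        counts[cls] += 1
        if cls == "FP":
            band = next((name for lo, hi, name in FP_RISK_BANDS
                         if lo < tr.last_risk <= hi), ">74%")
            detail = {"patient_id": tr.patient_id, "last_risk": tr.last_risk,
                      "last_t_h": tr.last_t, "band": band}
            if monitoring_hours is not None:
                detail["monitoring_h"] = monitoring_hours.get(tr.patient_id)
            fp_detail.append(detail)
    fp_short = sum(1 for d in fp_detail
                   if d.get("monitoring_h") is not None and d["monitoring_h"] <= 48.0)
    return {
        "counts": counts,
        "n_classified": int(sum(counts.values())),
        "unclassifiable": unclassifiable,
        "fp_detail": fp_detail,
        "fp_by_band": {name: sum(1 for d in fp_detail if d["band"] == name)
                       for _, _, name in FP_RISK_BANDS},
        "fp_monitored_24_48h": fp_short,
    }


def risk_distribution_over_time(
    tracks: list[RiskTrack], labels: dict[str, int] | pd.Series
) -> pd.DataFrame:
    """Violin-ready per-time, per-outcome summaries (n, mean, deciles)."""
    labels = pd.Series(labels)
    rows = []
    for tr in tracks:
        group = "nonsurvivor" if labels[tr.patient_id] else "survivor"
        for t, r in zip(tr.t_h, tr.risk):
            rows.append((t, group, r))
    long = pd.DataFrame(rows, columns=["t_h", "group", "risk"])
    out = []
    for (t, g), sub in long.groupby(["t_h", "group"], sort=True):
        r = sub["risk"].to_numpy()
        rec = {"t_h": t, "group": g, "n": r.size, "mean": float(r.mean())}
        for q in range(10, 100, 10):
            rec[f"q{q}"] = float(np.percentile(r, q))
        out.append(rec)
    return pd.DataFrame(out)
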