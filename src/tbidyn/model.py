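"""Pooled logistic risk model with recursive feature elimination and rolling scoring.

Training rows are pooled (patient, prediction-time) instances across the whole
five-day schedule; cross-validation folds are always split by patient so that
no patient contributes rows to both sides of a split. The fitted coefficients
are constant over time — the same artifact scores every prediction time; only
the feature values roll forward with the monitoring data.

Feature selection is recursive elimination: starting from all candidates, the
feature with the smallest absolute coefficient is dropped repeatedly (exact
ties broken by lexicographic name order), and every candidate subset size on
the elimination path is scored by patient-grouped stratified CV AUC; the
best-scoring size wins, with exact score ties resolved toward the smaller set.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import StratifiedGroupKFold

from . import features as fe
from .preprocessing import CensoredPatient

#: weak L2 default; recorded in the model artifact
DEFAULT_C = 100.0


def _sigmoid(z):
    return 1.0 / (1.0 + np.exp(-z))


def _rank_auc(scores: np.ndarray, labels: np.ndarray) -> float:
    from .evaluation import auc  # local import to avoid a cycle

    return auc(scores, labels)


def _fit_logistic(X: np.ndarray, y: np.ndarray, C: float) -> LogisticRegression:
    clf = LogisticRegression(C=C, solver="lbfgs", max_iter=5000)
    clf.fit(X, y)
    return clf


@dataclass
class TrainedDynamicModel:
    """Serializable logistic risk model artifact.

    Coefficients are in log-odds units per unit of normalized feature value and
    are applied unchanged at every prediction time.
    """

    variant: str
    feature_names: list[str]
    coef: list[float]
    intercept: float
    normalizer: fe.MinMaxNormalizer
    seed: int
    meta: dict = field(default_factory=dict)

    def predict_frame(self, df: pd.DataFrame) -> pd.Series:
        """Risk for every row of a raw (unnormalized) feature frame.

        Rows missing any selected feature are dropped (no imputation).
        """
        X = self.normalizer.transform(df[self.feature_names])
        X = X.dropna()
        z = self.intercept + X.to_numpy() @ np.asarray(self.coef)
        return pd.Series(_sigmoid(z), index=X.index, name="risk")

    def contributions(self, row: pd.Series) -> dict[str, float]:
        """Signed per-feature contribution (coefficient x normalized value)."""
        X = self.normalizer.transform(row[self.feature_names].to_frame().T)
        vals = X.iloc[0]
        return {n: float(c * vals[n]) for n, c in zip(self.feature_names, self.coef)}

    def to_dict(self) -> dict:
        return {
            "variant": self.variant,
            "feature_names": list(self.feature_names),
            "coef": [float(c) for c in self.coef],
            "intercept": float(self.intercept),
            "normalizer_bounds": self.normalizer.to_dict(),
            "seed": int(self.seed),
            "meta": self.meta,
        }

    def save(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=1, sort_keys=True)

    @classmethod
    def from_dict(cls, d: dict) -> "TrainedDynamicModel":
        return cls(
            variant=d["variant"],
            feature_names=list(d["feature_names"]),
            coef=[float(c) for c in d["coef"]],
            intercept=float(d["intercept"]),
            normalizer=fe.MinMaxNormalizer.from_dict(d["normalizer_bounds"]),
            seed=int(d["seed"]),
            meta=dict(d.get("meta", {})),
        )

    @classmethod
    def load(cls, path) -> "TrainedDynamicModel":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))


def _grouped_splits(y: np.ndarray, groups: np.ndarray, n_folds: int, seed: int):
    """Patient-grouped, outcome-stratified row splits, precomputed for reuse."""
    cv = StratifiedGroupKFold(n_splits=n_folds, shuffle=True, random_state=seed)
    return list(cv.split(np.zeros_like(y), y, groups))


def select_features_rfe(
    X: pd.DataFrame,
    y: pd.Series,
    groups: pd.Series | np.ndarray,
    seed: int = 0,
    n_folds: int = 3,
    C: float = DEFAULT_C,
    min_features: int = 1,
    parsimony_tol: float = 0.005,
) -> list[str]:
    """Recursive feature elimination scored by patient-grouped CV AUC.

    Returns the best-scoring feature subset along the elimination path,
    preserving the input column order; among subset sizes whose CV AUC is
    within ``parsimony_tol`` of the best, the smallest wins, so redundant
    (e.g. perfectly collinear) features are not retained for a negligible
    score difference. Deterministic given the seed.
    """
    names = list(X.columns)
    if len(names) == 0:
        raise ValueError("no candidate features")
    if len(names) == 1:
        return names
    yv = np.asarray(y, dtype=int)
    if len(np.unique(yv)) < 2:
        raise ValueError("feature selection requires both outcome classes")
    gv = np.asarray(groups)
    Xv = X.to_numpy(dtype=float)
    if np.isnan(Xv).any():
        raise ValueError("candidate matrix must be complete-case (drop NaN rows first)")

    # elimination path on the full training data
    path: list[list[str]] = []
    current = list(names)
    while True:
        path.append(list(current))
        if len(current) <= min_features:
            break
        idx = [names.index(n) for n in current]
        clf = _fit_logistic(Xv[:, idx], yv, C)
        absc = np.abs(clf.coef_[0])
        weakest = min((a, n) for a, n in zip(absc, current))[1]
        current.remove(weakest)

    # score every subset size with the same grouped, stratified splits
    splits = _grouped_splits(yv, gv, n_folds, seed)
    scored = []
    for subset in reversed(path):  # ascending size
        idx = [names.index(n) for n in subset]
        oof = np.full(len(yv), np.nan)
        for tr, te in splits:
            clf = _fit_logistic(Xv[np.ix_(tr, idx)], yv[tr], C)
            oof[te] = clf.predict_proba(Xv[np.ix_(te, idx)])[:, 1]
        scored.append((subset, _rank_auc(oof, yv)))
    best_score = max(s for _, s in scored)
    for subset, score in scored:  # smallest acceptable subset
        if score >= best_score - parsimony_tol:
            return subset
    raise AssertionError("unreachable")


def fit_dynamic_model(
    feature_df: pd.DataFrame,
    variant: str,
    seed: int = 0,
    select: bool = True,
    feature_subset: list[str] | None = None,
    C: float = DEFAULT_C,
    rfe_folds: int = 3,
) -> TrainedDynamicModel:
    """Fit the full training pipeline on pooled rows: normalize, select, fit.

    ``feature_df`` is a raw feature matrix (``build_feature_matrix`` output,
    training rows only) with a ``label`` column. Rows with any missing
    candidate value are dropped (no imputation). The normalizer bounds, the
    selected features and the logistic fit all derive from these rows alone.
    """
    cols = feature_subset if feature_subset is not None else fe.feature_columns(feature_df)
    df = feature_df[cols + ["label"]].dropna()
    y = df["label"].astype(int)
    if y.nunique() < 2:
        raise ValueError("training rows contain a single outcome class")
    norm = fe.MinMaxNormalizer().fit(df[cols])
    Xn = norm.transform(df[cols])
    groups = df.index.get_level_values("patient_id")

    if select and feature_subset is None:
        selected = select_features_rfe(Xn, y, groups, seed=seed, n_folds=rfe_folds, C=C)
    else:
        selected = cols
    clf = _fit_logistic(Xn[selected].to_numpy(), y.to_numpy(), C)
    if clf.n_iter_[0] >= clf.max_iter:
        raise RuntimeError(
            f"logistic fit did not converge within {clf.max_iter} iterations"
        )
    return TrainedDynamicModel(
        variant=variant,
        feature_names=list(selected),
        coef=[float(c) for c in clf.coef_[0]],
        intercept=float(clf.intercept_[0]),
        normalizer=norm,
        seed=seed,
        meta={"C": C, "rfe": bool(select and feature_subset is None),
              "rfe_folds": rfe_folds, "n_rows": int(len(df)),
              "n_iter": int(clf.n_iter_[0])},
    )


@dataclass
class RiskTrack:
    """Rolling risk predictions for one patient (at most 13 scheduled points)."""

    patient_id: str
    t_h: list[float]
    risk: list[float]
    contributions: list[dict[str, float]]

    @property
    def last_risk(self) -> float | None:
        return self.risk[-1] if self.risk else None

    @property
    def last_t(self) -> float | None:
        return self.t_h[-1] if self.t_h else None


def predict_rolling(
    model: TrainedDynamicModel,
    patient: CensoredPatient,
    times_h: tuple[int, ...] = fe.PREDICTION_TIMES_H,
) -> RiskTrack:
    """Score one patient at every scheduled prediction time with usable data.

    Timepoints where any selected feature is missing (empty required window)
    are skipped for that patient.
    """
    known = {e.name for e in fe.enumerate_features(model.variant)} | {"agecat"}
    unknown = set(model.feature_names) - known
    if unknown:
        raise ValueError(
            f"model/variant mismatch: features {sorted(unknown)} are not part of "
            f"the {model.variant} candidate scheme")
    entries = [e for e in fe.enumerate_features(model.variant) if e.name in model.feature_names]
    series = fe.derived_series_for(patient, entries)
    coef = np.asarray(model.coef)
    track = RiskTrack(patient.patient_id, [], [], [])
    for t_h in times_h:
        row = fe.build_feature_vector(patient, t_h, entries, series)
        if row is None:
            continue
        raw = pd.DataFrame([{n: row[n] for n in model.feature_names}])
        x = model.normalizer.transform(raw).iloc[0].to_numpy()
        if np.isnan(x).any():
            continue
        track.t_h.append(float(t_h))
        track.risk.append(float(_sigmoid(model.intercept + coef @ x)))
        track.contributions.append(
            {n: float(c * v) for n, c, v in zip(model.feature_names, coef, x)}
        )
    return track


def classify_at_threshold(track: RiskTrack, died: bool, threshold: float = 0.5) -> str | None:
    """Confusion class from the LAST prediction; strict ">" calls death.

    Returns None for an empty track (patient unclassifiable).
    """
    if not track.risk:
        return None
    predicted_death = track.last_risk > threshold
    if predicted_death:
        return "TP" if died else "FP"
    return "FN" if died else "TN"
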