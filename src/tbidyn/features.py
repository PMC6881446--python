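"""Dynamic feature scheme over rolling-window derived series.

Every feature is built in two steps. First, a *derived series* reduces one
gridded channel with one summary statistic over rolling windows: 4-hour windows
stepping by 4 h for the continuous channels (icp, map, cpp) and 24-hour windows
stepping by 8 h for the GCS components (mr, er), whose sparse wake-up-test
observations need the longer window. A window with no grid points contributes
no derived point — gaps propagate, nothing is imputed. Second, an *aspect*
reduces the derived series relative to a prediction time t:

- ``begin``  mean (or extreme, for min/max statistics) of derived points in the
  first 24 h of monitoring;
- ``end``    mean/extreme of derived points in the trailing 8 h window (t-8h, t];
- ``coef``   OLS slope (per hour) of the derived series from monitoring start
  up to t;
- ``last``   the value of the most recent derived point inside (t-8h, t]
  (used for the last-window min/max and the ht/lt threshold fractions).

Names follow the field convention ``signal_statistic_aspect`` with the mean
statistic elided (``icp_end``, ``map_coef``, ``cpp_q10_end``, ``er_min_end``).
The candidate sets contain 54 dynamic features for the ICP-MAP-CPP variant and
74 for the ICP-MAP-CPP-GCS variant; the ordinal age category is appended
separately. All feature values are min-max normalized to [0, 1] with bounds
learned on training data only.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .preprocessing import CensoredCohort, CensoredPatient, VitalsGrid

VARIANTS = ("ICP-MAP-CPP", "ICP-MAP-CPP-GCS")
CONTINUOUS_SIGNALS = ("icp", "map", "cpp")
GCS_SIGNALS = ("mr", "er")

#: rolling window length / step per signal, minutes
WINDOW_MIN = {"icp": 240, "map": 240, "cpp": 240, "mr": 1440, "er": 1440}
STEP_MIN = {"icp": 240, "map": 240, "cpp": 240, "mr": 480, "er": 480}

BEGIN_SPAN_MIN = 1440   # "begin" aspect: first 24 h of monitoring
END_SPAN_MIN = 480      # "end" aspect: trailing 8 h before the prediction

#: prediction schedule: first at 24 h, then every 8 h up to 120 h
PREDICTION_TIMES_H = tuple(range(24, 121, 8))

AGE_BANDS = (30.0, 45.0, 60.0, 75.0)
MIN_AGE = 16.0


@dataclass(frozen=True)
class FeatureSpecEntry:
    name: str
    signal: str
    statistic: str
    aspect: str


@dataclass
class DerivedSeries:
    """One statistic of one channel over rolling windows (gaps omitted)."""

    signal: str
    statistic: str
    end_t: np.ndarray   # window end times, minutes
    values: np.ndarray
    window_min: int
    step_min: int


def window_stat(values, statistic: str) -> float:
    """Summary statistic of the values inside one rolling window.

    ``diff`` is the mean of consecutive signed differences and needs at least
    two values; ``var`` is the population variance; ``q90``/``q10`` use linear
    interpolation between order statistics; ``htX``/``ltX`` are the fractions
    of values strictly above/below the threshold X. Empty input -> NaN (gap).
    """
    v = np.asarray(values, dtype=np.float64)
    if v.size == 0:
        return math.nan
    if statistic == "mean":
        return float(v.mean())
    if statistic == "diff":
        return float(np.diff(v).mean()) if v.size >= 2 else math.nan
    if statistic == "var":
        return float(v.var())
    if statistic == "q90":
        return float(np.percentile(v, 90))
    if statistic == "q10":
        return float(np.percentile(v, 10))
    if statistic == "min":
        return float(v.min())
    if statistic == "max":
        return float(v.max())
    if statistic.startswith(("ht", "lt")):
        thr = float(statistic[2:])
        return float((v > thr).mean() if statistic[0] == "h" else (v < thr).mean())
    raise ValueError(f"unknown statistic {statistic!r}")


def build_derived_series(grid: VitalsGrid, statistic: str, anchor_min: float) -> DerivedSeries:
    """Reduce a grid to rolling-window statistic points anchored at monitoring start.

    Window k covers the half-open interval (end_k - L, end_k] with
    end_k = anchor + k*step; windows run from the anchor to the last grid time.
    Windows whose statistic is undefined (no points; single point for ``diff``)
    yield no derived point.
    """
    L, step = WINDOW_MIN[grid.channel], STEP_MIN[grid.channel]
    ends, vals = [], []
    if len(grid):
        n_windows = int(math.ceil((float(grid.t[-1]) - anchor_min) / step))
        for k in range(1, n_windows + 1):
            end = anchor_min + k * step
            lo = np.searchsorted(grid.t, end - L, side="right")
            hi = np.searchsorted(grid.t, end, side="right")
            s = window_stat(grid.v[lo:hi], statistic)
            if not math.isnan(s):
                ends.append(end)
                vals.append(s)
    return DerivedSeries(grid.channel, statistic, np.asarray(ends, float), np.asarray(vals, float), L, step)


def trend_coef(series: DerivedSeries, up_to_min: float) -> float:
    """OLS slope (units per hour) of derived values against window end time.

    Fit over all derived points at or before ``up_to_min``; NaN with fewer than
    two points.
    """
    m = series.end_t <= up_to_min
    if m.sum() < 2:
        return math.nan
    x = series.end_t[m] / 60.0
    y = series.values[m]
    xc = x - x.mean()
    return float((xc @ (y - y.mean())) / (xc @ xc))


def _name(signal: str, statistic: str, aspect: str) -> str:
    if statistic == "mean":
        return f"{signal}_{aspect}"
    return f"{signal}_{statistic}_{aspect}"


def enumerate_features(variant: str) -> list[FeatureSpecEntry]:
    """The canonical candidate feature scheme (54 or 74 dynamic entries).

    Continuous signals: {mean, diff, var, q90, q10} x {begin, end, coef} plus
    last-window min and max; additionally icp_ht20, icp_lt10 and map_ht120
    threshold fractions. GCS components add {mean, var} x {begin, end, coef}
    plus min/max over the begin and end spans.
    """
    if variant not in VARIANTS:
        raise ValueError(f"unknown variant {variant!r}; expected one of {VARIANTS}")
    entries: list[FeatureSpecEntry] = []
    for sig in CONTINUOUS_SIGNALS:
        for stat in ("mean", "diff", "var", "q90", "q10"):
            for aspect in ("begin", "end", "coef"):
                entries.append(FeatureSpecEntry(_name(sig, stat, aspect), sig, stat, aspect))
        entries.append(FeatureSpecEntry(f"{sig}_min", sig, "min", "last"))
        entries.append(FeatureSpecEntry(f"{sig}_max", sig, "max", "last"))
    entries.append(FeatureSpecEntry("icp_ht20", "icp", "ht20", "last"))
    entries.append(FeatureSpecEntry("icp_lt10", "icp", "lt10", "last"))
    entries.append(FeatureSpecEntry("map_ht120", "map", "ht120", "last"))
    if variant == "ICP-MAP-CPP-GCS":
        for sig in GCS_SIGNALS:
            for stat in ("mean", "var"):
                for aspect in ("begin", "end", "coef"):
                    entries.append(FeatureSpecEntry(_name(sig, stat, aspect), sig, stat, aspect))
            for stat in ("min", "max"):
                for aspect in ("begin", "end"):
                    entries.append(FeatureSpecEntry(f"{sig}_{stat}_{aspect}", sig, stat, aspect))
    names = [e.name for e in entries]
    assert len(names) == len(set(names))
    return entries


def encode_agecat(age: float) -> float:
    """Ordinal age category on [0, 1]: 15-year bands from 16 up, top band 75+."""
    if age < MIN_AGE:
        raise ValueError(f"age {age} below cohort minimum of {MIN_AGE}")
    band = sum(age >= b for b in AGE_BANDS)
    return band / len(AGE_BANDS)


def _aspect_value(series: DerivedSeries, entry: FeatureSpecEntry, t_min: float, anchor_min: float) -> float:
    if entry.aspect == "coef":
        return trend_coef(series, t_min)
    if entry.aspect == "begin":
        m = series.end_t <= anchor_min + BEGIN_SPAN_MIN
    else:  # "end" and "last": trailing 8 h window
        m = (series.end_t > t_min - END_SPAN_MIN) & (series.end_t <= t_min)
    sel = series.values[m]
    if sel.size == 0:
        return math.nan
    if entry.aspect == "last":
        return float(sel[-1])
    if entry.statistic == "min":
        return float(sel.min())
    if entry.statistic == "max":
        return float(sel.max())
    return float(sel.mean())


def derived_series_for(
    patient: CensoredPatient, entries: list[FeatureSpecEntry]
) -> dict[tuple[str, str], DerivedSeries]:
    """All (signal, statistic) derived series a feature list needs for one patient."""
    needed = sorted({(e.signal, e.statistic) for e in entries})
    out = {}
    for sig, stat in needed:
        grid = patient.grids.get(sig)
        if grid is None:
            grid = VitalsGrid(patient.patient_id, sig, np.empty(0, np.int64), np.empty(0))
        out[(sig, stat)] = build_derived_series(grid, stat, patient.monitoring_start)
    return out


def build_feature_vector(
    patient: CensoredPatient,
    t_h: float,
    entries: list[FeatureSpecEntry],
    series: dict[tuple[str, str], DerivedSeries] | None = None,
) -> dict[str, float] | None:
    """One feature row at prediction time ``t_h`` (hours); None if no usable data.

    Aspects computed from windows after t are impossible by construction
    (every derived point used ends at or before t), so rows are causal.
    Missing aspects stay NaN.
    """
    t_min = t_h * 60.0
    if t_min > patient.usable_end or t_min - patient.monitoring_start < BEGIN_SPAN_MIN:
        return None
    if series is None:
        series = derived_series_for(patient, entries)
    row = {
        e.name: _aspect_value(series[(e.signal, e.statistic)], e, t_min, patient.monitoring_start)
        for e in entries
    }
    row["agecat"] = encode_agecat(float(patient.baseline["age"]))
    return row


def build_feature_matrix(
    cohort: CensoredCohort,
    variant: str,
    times_h: tuple[int, ...] = PREDICTION_TIMES_H,
) -> pd.DataFrame:
    """Design matrix over (patient, prediction time) rows, with a ``label`` column.

    A row exists only where the patient's usable data covers at least 24 h
    before t and does not end before t. Missing feature cells are NaN.
    """
    entries = enumerate_features(variant)
    index, rows = [], []
    for p in cohort.patients:
        series = derived_series_for(p, entries)
        for t_h in times_h:
            row = build_feature_vector(p, t_h, entries, series)
            if row is None:
                continue
            row["label"] = int(p.label)
            index.append((p.patient_id, t_h))
            rows.append(row)
    cols = [e.name for e in entries] + ["agecat", "label"]
    df = pd.DataFrame(rows, index=pd.MultiIndex.from_tuples(index, names=["patient_id", "t_h"]))
    return df.reindex(columns=cols)


def feature_columns(df: pd.DataFrame) -> list[str]:
    return [c for c in df.columns if c != "label"]


class MinMaxNormalizer:
    """Per-feature min-max scaling to [0, 1], fitted on training rows only.

    Application-time values are clipped to [0, 1]; degenerate features
    (max == min on the training data) map to 0.5. NaN passes through.
    """

    def __init__(self) -> None:
        self.bounds: dict[str, tuple[float, float]] | None = None

    def fit(self, df: pd.DataFrame) -> "MinMaxNormalizer":
        self.bounds = {
            c: (float(np.nanmin(df[c])) if df[c].notna().any() else 0.0,
                float(np.nanmax(df[c])) if df[c].notna().any() else 0.0)
            for c in df.columns
        }
        return self

    def transform(self, df: pd.DataFrame) -> pd.DataFrame:
        if self.bounds is None:
            raise RuntimeError("normalizer has not been fitted")
        out = {}
        for c in df.columns:
            lo, hi = self.bounds[c]
            x = df[c].astype(float)
            if hi == lo:
                out[c] = x.where(x.isna(), 0.5)
            else:
                out[c] = ((x - lo) / (hi - lo)).clip(0.0, 1.0)
        return pd.DataFrame(out, index=df.index)

    def inverse_transform(self, df: pd.DataFrame) -> pd.DataFrame:
        if self.bounds is None:
            raise RuntimeError("normalizer has not been fitted")
        out = {}
        for c in df.columns:
            lo, hi = self.bounds[c]
            out[c] = df[c].astype(float) * (hi - lo) + lo
        return pd.DataFrame(out, index=df.index)

    def to_dict(self) -> dict:
        if self.bounds is None:
            raise RuntimeError("normalizer has not been fitted")
        return {k: [v[0], v[1]] for k, v in self.bounds.items()}

    @classmethod
    def from_dict(cls, d: dict) -> "MinMaxNormalizer":
        norm = cls()
        norm.bounds = {k: (float(v[0]), float(v[1])) for k, v in d.items()}
        return norm
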