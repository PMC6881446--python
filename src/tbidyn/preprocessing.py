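"""Raw vitals -> clean 5-minute grids, CPP derivation, inclusion and death censoring.

Monitor channels (ICP, MAP) arrive as irregular samples at roughly 1-5 minute
spacing; they are reduced to a 5-minute grid by taking the median of all samples
whose timestamp rounds to the same grid point. Grid points with no contributing
sample stay absent — downstream code treats absence as a gap, never as zero, and
nothing is imputed. Extreme values outside the physiologic plausibility bounds
(ICP outside [0, 100] mmHg, MAP outside [20, 150] mmHg, strict inequalities) are
treated as measurement artifacts and dropped; GCS component channels pass
through the artifact filter untouched.

Cohort rules: a patient is included only when the ICP monitoring span exceeds
24 h and death (if any) occurred later than 36 h after admission. For deaths
within the first 120 h the final 12 h of data before death are discarded to
avoid treatment-withdrawal bias. The outcome label is all-cause death within
30 days of admission.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

GRID_STEP_MIN = 5
#: hours of monitoring represented by one 5-minute median value
GRID_HOURS_PER_VALUE = GRID_STEP_MIN / 60.0

#: channels as stored in the long-format vitals CSV -> internal signal names
CSV_CHANNELS = {"ICP": "icp", "MAP": "map", "GCS_M": "mr", "GCS_E": "er"}
SIGNAL_TO_CSV = {v: k for k, v in CSV_CHANNELS.items()}

#: inclusive validity bounds; values strictly outside are artifacts
ARTIFACT_BOUNDS = {"icp": (0.0, 100.0), "map": (20.0, 150.0)}

MIN_MONITORING_MIN = 24 * 60        # strict: span must exceed this
EARLY_DEATH_LIMIT_H = 36.0          # deaths at or before this are excluded
CENSOR_BEFORE_DEATH_H = 12.0        # discarded window before death
CENSOR_DEATH_LIMIT_H = 120.0        # censoring applies to deaths within 5 days
LABEL_HORIZON_H = 30 * 24.0         # 30-day mortality


class DataIntegrityError(ValueError):
    """Raised when input data violates a hard consistency requirement."""


@dataclass
class VitalsGrid:
    """One channel of one patient on the 5-minute grid.

    ``t`` holds grid times in minutes from admission (strictly increasing,
    multiples of 5); ``v`` the values (mmHg for icp/map/cpp, ordinal scores
    for mr/er).
    """

    patient_id: str
    channel: str
    t: np.ndarray
    v: np.ndarray

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=np.int64)
        self.v = np.asarray(self.v, dtype=np.float64)
        if self.t.size != self.v.size:
            raise DataIntegrityError("t and v must have equal length")
        if self.t.size and (np.any(np.diff(self.t) <= 0) or np.any(self.t % GRID_STEP_MIN)):
            raise DataIntegrityError("grid times must be strictly increasing multiples of 5")

    def __len__(self) -> int:
        return int(self.t.size)

    @property
    def span_min(self) -> int:
        return int(self.t[-1] - self.t[0]) if len(self) else 0

    def truncate(self, end_min: float) -> "VitalsGrid":
        keep = self.t <= end_min
        return VitalsGrid(self.patient_id, self.channel, self.t[keep], self.v[keep])


def round_to_grid(t_min: np.ndarray) -> np.ndarray:
    """Round timestamps to the nearest 5-minute grid point, half-up at ties."""
    t = np.asarray(t_min, dtype=np.float64)
    return (np.floor(t / GRID_STEP_MIN + 0.5) * GRID_STEP_MIN).astype(np.int64)


def resample_to_grid(t_min, values, patient_id: str, channel: str) -> VitalsGrid:
    """Median-aggregate raw samples onto the 5-minute grid.

    Each grid point carries the median of the raw values whose timestamps round
    to it; grid points without contributors are simply absent.
    """
    t = np.asarray(t_min, dtype=np.float64)
    v = np.asarray(values, dtype=np.float64)
    ok = np.isfinite(t) & np.isfinite(v)
    t, v = t[ok], v[ok]
    if t.size == 0:
        return VitalsGrid(patient_id, channel, np.empty(0, np.int64), np.empty(0))
    g = round_to_grid(t)
    order = np.argsort(g, kind="stable")
    g, v = g[order], v[order]
    bounds = np.flatnonzero(np.r_[True, np.diff(g) != 0])
    t_grid = g[bounds]
    med = np.array([np.median(v[lo:hi]) for lo, hi in zip(bounds, np.r_[bounds[1:], g.size])])
    return VitalsGrid(patient_id, channel, t_grid, med)


def filter_artifacts(grid: VitalsGrid) -> tuple[VitalsGrid, int]:
    """Drop values strictly outside the channel's validity bounds.

    Returns the filtered grid and the number of removed points. Channels
    without bounds (GCS components, CPP) pass through unchanged. Idempotent.
    """
    bounds = ARTIFACT_BOUNDS.get(grid.channel)
    if bounds is None or len(grid) == 0:
        return grid, 0
    lo, hi = bounds
    keep = (grid.v >= lo) & (grid.v <= hi)
    removed = int((~keep).sum())
    if removed == 0:
        return grid, 0
    return VitalsGrid(grid.patient_id, grid.channel, grid.t[keep], grid.v[keep]), removed


def filter_raw_samples(values: np.ndarray, channel: str) -> np.ndarray:
    """Boolean keep-mask applying the artifact bounds to raw (pre-grid) samples."""
    v = np.asarray(values, dtype=np.float64)
    bounds = ARTIFACT_BOUNDS.get(channel)
    if bounds is None:
        return np.ones(v.size, dtype=bool)
    return (v >= bounds[0]) & (v <= bounds[1])


def derive_cpp(icp: VitalsGrid, map_grid: VitalsGrid) -> VitalsGrid:
    """CPP(t) = MAP(t) - ICP(t), defined only where both channels have a value."""
    if icp.patient_id != map_grid.patient_id:
        raise DataIntegrityError(
            f"patient mismatch: {icp.patient_id!r} vs {map_grid.patient_id!r}"
        )
    common, i_icp, i_map = np.intersect1d(icp.t, map_grid.t, return_indices=True)
    return VitalsGrid(icp.patient_id, "cpp", common, map_grid.v[i_map] - icp.v[i_icp])


@dataclass
class CensoredPatient:
    patient_id: str
    grids: dict  # signal name -> VitalsGrid (icp, map, cpp, optionally mr/er)
    label: bool  # died within 30 days of admission
    usable_end: float  # minutes; no grid point exceeds it
    monitoring_start: float  # minutes; first ICP grid time
    death_hour: float | None
    baseline: dict


@dataclass
class CensoredCohort:
    patients: list[CensoredPatient]
    exclusions: list[tuple[str, str]] = field(default_factory=list)

    def labels(self) -> pd.Series:
        return pd.Series(
            {p.patient_id: int(p.label) for p in self.patients}, name="label", dtype=int
        )


@dataclass
class PreprocessReport:
    """Row bookkeeping: rows_in = rows_kept + rows_rejected + rows_filtered."""

    rows_in: int = 0
    rows_rejected: int = 0       # non-numeric / unparseable
    rows_filtered: int = 0       # artifact bounds (raw pass)
    grid_points_filtered: int = 0  # artifact bounds (post-grid pass)
    n_excluded: dict = field(default_factory=dict)

    @property
    def rows_kept(self) -> int:
        return self.rows_in - self.rows_rejected - self.rows_filtered


def grids_from_vitals(
    vitals: pd.DataFrame, report: PreprocessReport | None = None
) -> dict[str, dict[str, VitalsGrid]]:
    """Build per-patient, per-channel grids from a long-format vitals table.

    Artifact bounds are applied to the raw samples before the median (so
    artifacts cannot bias the aggregate) and again on the grid; both passes use
    the same bounds, making the second a no-op safety net.
    """
    report = report if report is not None else PreprocessReport()
    df = vitals.copy()
    report.rows_in += len(df)
    df["value"] = pd.to_numeric(df["value"], errors="coerce")
    df["t_min"] = pd.to_numeric(df["t_min"], errors="coerce")
    bad = df["value"].isna() | df["t_min"].isna() | ~df["channel"].isin(CSV_CHANNELS)
    report.rows_rejected += int(bad.sum())
    df = df[~bad]

    out: dict[str, dict[str, VitalsGrid]] = {}
    for (pid, csv_ch), sub in df.groupby(["patient_id", "channel"], sort=True):
        signal = CSV_CHANNELS[csv_ch]
        keep = filter_raw_samples(sub["value"].to_numpy(), signal)
        report.rows_filtered += int((~keep).sum())
        sub = sub[keep].sort_values("t_min", kind="stable")
        grid = resample_to_grid(sub["t_min"].to_numpy(), sub["value"].to_numpy(), str(pid), signal)
        grid, n_removed = filter_artifacts(grid)
        report.grid_points_filtered += n_removed
        out.setdefault(str(pid), {})[signal] = grid
    return out


def apply_inclusion_and_censoring(
    grids_by_patient: dict[str, dict[str, VitalsGrid]],
    baselines: pd.DataFrame,
    report: PreprocessReport | None = None,
) -> CensoredCohort:
    """Apply the cohort inclusion rules and the pre-death censoring window.

    Exclusions: ICP monitoring span <= 24 h; death <= 36 h after admission.
    For deaths within 120 h all data after (death - 12 h) is discarded. The
    label is death within 30 days of first hospital admission.
    """
    report = report if report is not None else PreprocessReport()
    base = baselines.set_index(baselines["patient_id"].astype(str))
    patients: list[CensoredPatient] = []
    exclusions: list[tuple[str, str]] = []

    for pid in sorted(grids_by_patient):
        grids = dict(grids_by_patient[pid])
        if pid not in base.index:
            exclusions.append((pid, "no-baseline-record"))
            continue
        row = base.loc[pid].to_dict()
        adm = float(row.get("admission_time_h", 0.0) or 0.0)
        death_raw = row.get("death_time_h")
        death_hour: float | None = None
        if death_raw is not None and not pd.isna(death_raw):
            if float(death_raw) < adm:
                raise DataIntegrityError(f"patient {pid}: death precedes admission")
            death_hour = float(death_raw) - adm

        icp = grids.get("icp")
        if icp is None or len(icp) == 0:
            exclusions.append((pid, "no-icp-data"))
            continue
        if death_hour is not None and death_hour <= EARLY_DEATH_LIMIT_H:
            exclusions.append((pid, "death-within-36h"))
            continue

        usable_end = float(icp.t[-1])
        if death_hour is not None and death_hour <= CENSOR_DEATH_LIMIT_H:
            usable_end = min(usable_end, (death_hour - CENSOR_BEFORE_DEATH_H) * 60.0)
            grids = {ch: g.truncate(usable_end) for ch, g in grids.items()}
            icp = grids["icp"]
        if len(icp) == 0 or icp.span_min <= MIN_MONITORING_MIN:
            exclusions.append((pid, "monitoring-span-le-24h"))
            continue

        if "map" in grids:
            grids["cpp"] = derive_cpp(grids["icp"], grids["map"])
        patients.append(
            CensoredPatient(
                patient_id=pid,
                grids=grids,
                label=death_hour is not None and death_hour <= LABEL_HORIZON_H,
                usable_end=usable_end,
                monitoring_start=float(icp.t[0]),
                death_hour=death_hour,
                baseline=row,
            )
        )

    for _, reason in exclusions:
        report.n_excluded[reason] = report.n_excluded.get(reason, 0) + 1
    return CensoredCohort(patients=patients, exclusions=exclusions)


def load_vitals_csv(path) -> pd.DataFrame:
    try:
        # exact float parsing so write -> read -> write is byte-stable
        return pd.read_csv(path, float_precision="round_trip")
    except OSError as exc:  # surface path context
        raise OSError(f"cannot read vitals file {path}: {exc}") from exc


def load_baseline_csv(path) -> pd.DataFrame:
    try:
        return pd.read_csv(path, float_precision="round_trip")
    except OSError as exc:
        raise OSError(f"cannot read baseline file {path}: {exc}") from exc


def preprocess(
    vitals: pd.DataFrame, baselines: pd.DataFrame
) -> tuple[CensoredCohort, PreprocessReport]:
    """Full preprocessing stage: grid, filter, derive CPP, include/censor."""
    report = PreprocessReport()
    grids = grids_from_vitals(vitals, report)
    cohort = apply_inclusion_and_censoring(grids, baselines, report)
    return cohort, report
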