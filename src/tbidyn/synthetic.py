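"""Synthetic ICU cohort generator for TBI vital-sign time series.

Real neuromonitoring data cannot be shared, so every downstream stage is
exercised on a simulated cohort that reproduces the statistical structure the
method depends on: roughly one patient in five dies within 30 days;
non-survivors run a higher and rising mean ICP (hence a lower CPP) and a lower,
declining motor score, while MAP is distributed alike in both groups; GCS
components are observed only at sedation-pause wake-up tests every ~12 h;
monitoring lasts about 3-5 days and is peppered with short dropouts and
occasional out-of-range artifact readings.

Vitals are AR(1)-perturbed piecewise-linear mean trajectories sampled every
couple of minutes — deliberately non-mechanistic, but sufficient to create the
group contrasts above. Baseline covariates are drawn from marginals anchored
to a typical ICP-monitored TBI cohort (median age ~48, ~69% admission GCS 3-8,
~79% bilaterally reactive pupils, ~49% mass lesions), and the death indicator
is drawn from a logistic latent risk over those covariates so the static
admission model has signal to find. Identical config + seed gives bit-identical
output.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from scipy.signal import lfilter

from .preprocessing import ARTIFACT_BOUNDS, SIGNAL_TO_CSV

EARLY_DEATH_CUTOFF_H = 36.0


class InvalidConfigError(ValueError):
    pass


@dataclass
class SimConfig:
    """Cohort-level simulation parameters; defaults are the study conditions."""

    n_patients: int
    #: raw 30-day mortality; set above the ~19% cohort figure because the
    #: inclusion rules later remove deaths occurring within 36 h
    mortality_rate: float = 0.21
    seed: int = 0
    monitoring_hours_mean: float = 96.0
    monitoring_hours_sd: float = 30.0
    icp_survivor_mean: float = 12.0
    icp_nonsurvivor_mean_start: float = 15.0
    icp_nonsurvivor_drift_per_day: float = 3.0
    icp_between_patient_sd: float = 5.5
    icp_drift_sd: float = 2.0            # between-patient spread of the fatal drift
    survivor_icp_drift_sd: float = 0.8   # survivors drift mildly around zero
    gcs_between_patient_sd: float = 1.0
    map_mean: float = 85.0
    map_sd: float = 9.0
    gcs_obs_interval_hours: float = 12.0
    artifact_rate: float = 0.005
    gap_rate: float = 0.03
    min_death_hour: float = 12.0
    max_death_hour: float = 720.0
    early_death_frac: float = 0.08  # point mass of deaths below 36 h
    effect_ramp: float = 1.0  # scales the survivor/non-survivor divergence over time
    sample_interval_min: int = 2
    ar_phi: float = 0.9
    icp_noise_sd: float = 1.5
    map_noise_sd: float = 2.0
    terminal_icp_rise: float = 10.0  # extra mmHg ramped over the last 24 h before death

    def __post_init__(self) -> None:
        if self.n_patients <= 0:
            raise InvalidConfigError("n_patients must be positive")
        for name in ("mortality_rate", "artifact_rate", "gap_rate", "early_death_frac"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise InvalidConfigError(f"{name} must be in [0, 1], got {v}")
        if self.monitoring_hours_mean <= 24:
            raise InvalidConfigError("monitoring_hours_mean must exceed 24 h")
        if not 0 < self.min_death_hour <= self.max_death_hour:
            raise InvalidConfigError("death-hour bounds must satisfy 0 < min <= max")
        if self.sample_interval_min < 1:
            raise InvalidConfigError("sample_interval_min must be >= 1 minute")

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class SyntheticPatient:
    patient_id: str
    baseline: dict
    #: raw samples: DataFrame(t_min, channel, value, is_artifact)
    vitals: pd.DataFrame
    death_hour: float | None = None


# ---------------------------------------------------------------- baselines

_MOTOR_P = (0.16, 0.15, 0.06, 0.18, 0.30, 0.15)          # scores 1..6
_PUPILS_P = {"both": 0.79, "one": 0.16, "none": 0.05}
_MARSHALL_P = {"DI_I": 0.02, "DI_II": 0.27, "DI_III": 0.18, "DI_IV": 0.04, "EML_NEML": 0.49}

#: latent log-odds of death per covariate (intercept calibrated to mortality_rate)
_BETA = {"age_per_year": 0.045, "motor_per_point": -0.28, "pupil_per_nonreactive": 0.55,
         "eml": 0.45, "di_high": 0.25, "glucose": 0.06, "hb": -0.012}


def _draw_baseline(rng: np.random.Generator) -> dict:
    age = float(np.clip(np.exp(rng.normal(np.log(48.0), 0.35)), 16.0, 95.0))
    motor = int(rng.choice(np.arange(1, 7), p=_MOTOR_P))
    pupils = str(rng.choice(list(_PUPILS_P), p=list(_PUPILS_P.values())))
    marshall = str(rng.choice(list(_MARSHALL_P), p=list(_MARSHALL_P.values())))
    glucose = float(np.exp(rng.normal(np.log(7.6), 0.25)))
    hb = float(rng.normal(130.0, 18.0))
    rec = {
        "age": age,
        "motor": motor,
        "pupils": pupils,
        "hypoxia": int(rng.random() < 0.17),
        "hypotension": int(rng.random() < 0.11),
        "marshall": marshall,
        "tsah": int(rng.random() < 0.72),
        "epidural_mass": int(rng.random() < 0.10),
        "glucose": np.nan if rng.random() < 0.01 else glucose,
        "hb": np.nan if rng.random() < 0.005 else hb,
        "admission_time_h": 0.0,
    }
    return rec


def _latent_risk(rec: dict) -> float:
    nonreactive = {"both": 0, "one": 1, "none": 2}[rec["pupils"]]
    lin = (_BETA["age_per_year"] * (rec["age"] - 48.0)
           + _BETA["motor_per_point"] * (rec["motor"] - 4)
           + _BETA["pupil_per_nonreactive"] * nonreactive
           + _BETA["eml"] * (rec["marshall"] == "EML_NEML")
           + _BETA["di_high"] * (rec["marshall"] in ("DI_III", "DI_IV")))
    if not np.isnan(rec["glucose"]):
        lin += _BETA["glucose"] * (rec["glucose"] - 7.6)
    if not np.isnan(rec["hb"]):
        lin += _BETA["hb"] * (rec["hb"] - 130.0)
    return lin


def _calibrate_intercept(lin: np.ndarray, target: float) -> float:
    lo, hi = -20.0, 20.0
    for _ in range(80):
        mid = 0.5 * (lo + hi)
        if (1.0 / (1.0 + np.exp(-(mid + lin)))).mean() < target:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


# ------------------------------------------------------------------ vitals

def _ar1(rng: np.random.Generator, n: int, phi: float, sd: float) -> np.ndarray:
    innov = rng.normal(0.0, sd, size=n)
    innov[0] = 0.0
    return lfilter([1.0], [1.0, -phi], innov)


def _continuous_channel(rng, t_min, mean_traj, cfg: SimConfig, noise_sd, channel):
    lo, hi = ARTIFACT_BOUNDS[channel]
    # natural signal stays within physiologic bounds; only injected artifacts exceed them
    v = np.clip(mean_traj + _ar1(rng, t_min.size, cfg.ar_phi, noise_sd), lo, hi)
    keep = rng.random(t_min.size) >= cfg.gap_rate
    t, v = t_min[keep], v[keep]
    art = rng.random(t.size) < cfg.artifact_rate
    out_low = lo - 5.0 - 10.0 * rng.random(t.size)
    out_high = hi + 10.0 + 40.0 * rng.random(t.size)
    v = np.where(art, np.where(rng.random(t.size) < 0.5, out_low, out_high), v)
    return pd.DataFrame({"t_min": t, "channel": SIGNAL_TO_CSV[channel],
                         "value": v, "is_artifact": art})


def _simulate_patient(rng: np.random.Generator, pid: str, rec: dict, died: bool,
                      death_hour: float | None, cfg: SimConfig) -> SyntheticPatient:
    dur_h = float(np.clip(rng.normal(cfg.monitoring_hours_mean, cfg.monitoring_hours_sd),
                          12.0, 150.0))
    if died and death_hour is not None and death_hour < dur_h:
        dur_h = death_hour
    t_min = np.arange(0, int(dur_h * 60) + 1, cfg.sample_interval_min, dtype=np.int64)
    t_h = t_min / 60.0

    if died:
        icp_base = rng.normal(cfg.icp_nonsurvivor_mean_start, cfg.icp_between_patient_sd)
        drift = rng.normal(cfg.effect_ramp * cfg.icp_nonsurvivor_drift_per_day, cfg.icp_drift_sd)
        icp_mean = icp_base + drift * t_h / 24.0
        if death_hour is not None and death_hour <= 150.0:
            ramp = np.clip((t_h - (death_hour - 24.0)) / 24.0, 0.0, 1.0)
            icp_mean = icp_mean + cfg.terminal_icp_rise * ramp
    else:
        icp_base = rng.normal(cfg.icp_survivor_mean, cfg.icp_between_patient_sd)
        drift = rng.normal(0.0, cfg.survivor_icp_drift_sd)
        icp_mean = icp_base + drift * t_h / 24.0
    map_base = rng.normal(cfg.map_mean, cfg.map_sd)

    frames = [
        _continuous_channel(rng, t_min, icp_mean, cfg, cfg.icp_noise_sd, "icp"),
        _continuous_channel(rng, t_min, np.full(t_h.size, map_base), cfg, cfg.map_noise_sd, "map"),
    ]

    # GCS at wake-up tests; ordinal, declining for non-survivors
    obs_t = np.arange(0.0, dur_h + 1e-9, cfg.gcs_obs_interval_hours)
    gcs_shift = rng.normal(0.0, cfg.gcs_between_patient_sd)
    if died:
        mr_lat = 3.2 + gcs_shift - cfg.effect_ramp * 0.5 * obs_t / 24.0
        er_lat = 2.0 + 0.7 * gcs_shift - cfg.effect_ramp * 0.3 * obs_t / 24.0
        if death_hour is not None and death_hour <= 150.0:
            drop = np.clip((obs_t - (death_hour - 24.0)) / 24.0, 0.0, 1.0)
            mr_lat = mr_lat - 1.5 * drop
            er_lat = er_lat - 1.0 * drop
    else:
        mr_lat = 4.2 + gcs_shift + 0.15 * obs_t / 24.0
        er_lat = 2.6 + 0.7 * gcs_shift + 0.10 * obs_t / 24.0
    mr = np.clip(np.rint(mr_lat + rng.normal(0, 0.8, obs_t.size)), 1, 6)
    er = np.clip(np.rint(er_lat + rng.normal(0, 0.7, obs_t.size)), 1, 4)
    for ch, vals in (("GCS_M", mr), ("GCS_E", er)):
        frames.append(pd.DataFrame({"t_min": (obs_t * 60).astype(np.int64),
                                    "channel": ch, "value": vals.astype(float),
                                    "is_artifact": False}))

    vitals = pd.concat(frames, ignore_index=True)
    vitals = vitals.sort_values(["channel", "t_min"], kind="stable").reset_index(drop=True)
    rec = dict(rec)
    rec["death_time_h"] = death_hour if died else np.nan
    return SyntheticPatient(pid, rec, vitals, death_hour if died else None)


def simulate_cohort(config: SimConfig) -> list[SyntheticPatient]:
    """Draw a full cohort: baselines, outcomes, death times, vitals streams."""
    ss = np.random.SeedSequence(config.seed)
    master = np.random.default_rng(ss)
    records = [_draw_baseline(master) for _ in range(config.n_patients)]
    lin = np.array([_latent_risk(r) for r in records])
    if config.mortality_rate <= 0.0:
        died = np.zeros(config.n_patients, dtype=bool)
    elif config.mortality_rate >= 1.0:
        died = np.ones(config.n_patients, dtype=bool)
    else:
        alpha = _calibrate_intercept(lin, config.mortality_rate)
        died = master.random(config.n_patients) < 1.0 / (1.0 + np.exp(-(alpha + lin)))

    death_hours = np.full(config.n_patients, np.nan)
    for i in np.flatnonzero(died):
        if master.random() < config.early_death_frac and config.min_death_hour < EARLY_DEATH_CUTOFF_H:
            death_hours[i] = master.uniform(config.min_death_hour,
                                            min(EARLY_DEATH_CUTOFF_H, config.max_death_hour))
        else:
            death_hours[i] = master.uniform(max(config.min_death_hour, EARLY_DEATH_CUTOFF_H),
                                            config.max_death_hour)

    patients = []
    for i, child in enumerate(ss.spawn(config.n_patients)):
        rng = np.random.default_rng(child)
        patients.append(_simulate_patient(
            rng, f"P{i:04d}", records[i], bool(died[i]),
            float(death_hours[i]) if died[i] else None, config))
    return patients


# --------------------------------------------------------------------- I/O

def cohort_frames(patients: list[SyntheticPatient]) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Long vitals table, baseline table, and the artifact debug side table."""
    vit_parts, base_rows, art_parts = [], [], []
    for p in patients:
        v = p.vitals
        vit_parts.append(v.assign(patient_id=p.patient_id)[["patient_id", "t_min", "channel", "value"]])
        art = v[v["is_artifact"]]
        if len(art):
            art_parts.append(art.assign(patient_id=p.patient_id)[["patient_id", "t_min", "channel", "value"]])
        base_rows.append({"patient_id": p.patient_id, **p.baseline})
    empty_v = pd.DataFrame(columns=["patient_id", "t_min", "channel", "value"])
    vitals = pd.concat(vit_parts, ignore_index=True) if vit_parts else empty_v
    artifacts = pd.concat(art_parts, ignore_index=True) if art_parts else empty_v.copy()
    from .impact import BASELINE_COLUMNS

    baselines = pd.DataFrame(base_rows, columns=BASELINE_COLUMNS)
    return vitals, baselines, artifacts


def write_cohort(patients: list[SyntheticPatient], vitals_path, baseline_path,
                 artifacts_path=None) -> None:
    """Write the vitals/baseline CSV dialects (artifact flags go to a side file).

    The main vitals CSV never carries the debug flag; the side file lists the
    injected artifact rows so tests can verify the filter removes exactly them.
    """
    vitals, baselines, artifacts = cohort_frames(patients)
    try:
        vitals.to_csv(vitals_path, index=False)
        baselines.to_csv(baseline_path, index=False)
        if artifacts_path is not None:
            artifacts.to_csv(artifacts_path, index=False)
    except OSError as exc:
        raise OSError(f"failed writing cohort files ({vitals_path}, {baseline_path}): {exc}") from exc
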