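import numpy as np
import pandas as pd
import pytest
from scipy import stats

from tbidyn.preprocessing import ARTIFACT_BOUNDS, CSV_CHANNELS, preprocess
from tbidyn.synthetic import (
    EARLY_DEATH_CUTOFF_H,
    InvalidConfigError,
    SimConfig,
    cohort_frames,
    simulate_cohort,
    write_cohort,
)


class TestConfig:
    def test_nonpositive_n_rejected(self):
        with pytest.raises(InvalidConfigError):
            SimConfig(n_patients=0)

    @pytest.mark.parametrize("kwargs", [
        {"mortality_rate": 1.2}, {"gap_rate": -0.1},
        {"monitoring_hours_mean": 20.0}, {"min_death_hour": 0.0},
    ])
    def test_invalid_rates_rejected(self, kwargs):
        with pytest.raises(InvalidConfigError):
            SimConfig(n_patients=10, **kwargs)


class TestSimulation:
    def test_zero_mortality_no_deaths(self):
        patients = simulate_cohort(SimConfig(n_patients=25, mortality_rate=0.0, seed=1))
        assert all(p.death_hour is None for p in patients)

    def test_determinism_bit_identical(self):
        cfg = dict(n_patients=15, seed=123)
        a = simulate_cohort(SimConfig(**cfg))
        b = simulate_cohort(SimConfig(**cfg))
        for pa, pb in zip(a, b):
            assert pa.baseline == pb.baseline or (
                pa.baseline.keys() == pb.baseline.keys()
                and all(v == pb.baseline[k] or (pd.isna(v) and pd.isna(pb.baseline[k]))
                        for k, v in pa.baseline.items()))
            pd.testing.assert_frame_equal(pa.vitals, pb.vitals)

    def test_death_fraction_within_binomial_99ci(self):
        rate, n = 0.19, 500
        patients = simulate_cohort(SimConfig(n_patients=n, mortality_rate=rate, seed=2024))
        observed = sum(p.death_hour is not None for p in patients)
        lo, hi = stats.binom.ppf([0.005, 0.995], n, rate)
        assert lo <= observed <= hi

    def test_death_hours_within_configured_bounds(self, small_patients):
        cfg = SimConfig(n_patients=1)  # defaults
        for p in small_patients:
            if p.death_hour is not None:
                assert cfg.min_death_hour <= p.death_hour <= cfg.max_death_hour

    def test_some_early_deaths_exercise_exclusion(self):
        patients = simulate_cohort(SimConfig(n_patients=400, seed=5, early_death_frac=0.3))
        early = [p for p in patients if p.death_hour is not None
                 and p.death_hour < EARLY_DEATH_CUTOFF_H]
        assert early, "expected a point mass of deaths below 36 h"

    def test_gcs_values_in_ordinal_ranges(self, small_patients):
        for p in small_patients:
            mr = p.vitals.loc[p.vitals["channel"] == "GCS_M", "value"]
            er = p.vitals.loc[p.vitals["channel"] == "GCS_E", "value"]
            assert mr.isin(range(1, 7)).all()
            assert er.isin(range(1, 5)).all()

    def test_artifacts_all_outside_validity_bounds(self, small_patients):
        for p in small_patients:
            art = p.vitals[p.vitals["is_artifact"]]
            for csv_ch, sig in CSV_CHANNELS.items():
                if sig not in ARTIFACT_BOUNDS:
                    continue
                lo, hi = ARTIFACT_BOUNDS[sig]
                vals = art.loc[art["channel"] == csv_ch, "value"]
                assert ((vals < lo) | (vals > hi)).all()


@pytest.fixture(scope="module")
def big():
    return simulate_cohort(SimConfig(n_patients=400, seed=31))


class TestGroupContrast:
    def _mean_icp(self, patients, died, lo_h, hi_h):
        means = []
        for p in patients:
            if (p.death_hour is not None) != died:
                continue
            v = p.vitals
            m = (v["channel"] == "ICP") & ~v["is_artifact"] \
                & (v["t_min"] >= lo_h * 60) & (v["t_min"] < hi_h * 60)
            if m.any():
                means.append(v.loc[m, "value"].mean())
        return np.array(means)

    def test_day1_contrast_matches_configuration_within_3se(self, big):
        cfg = SimConfig(n_patients=400, seed=31)
        patients = big
        ns = self._mean_icp(patients, True, 0, 24)
        sv = self._mean_icp(patients, False, 0, 24)
        diff = ns.mean() - sv.mean()
        se = np.sqrt(ns.var(ddof=1) / ns.size + sv.var(ddof=1) / sv.size)
        expected = (cfg.icp_nonsurvivor_mean_start
                    + cfg.effect_ramp * cfg.icp_nonsurvivor_drift_per_day * 0.5
                    - cfg.icp_survivor_mean)
        assert abs(diff - expected) <= 3 * se

    def test_divergence_grows_with_time(self, big):
        d1 = self._mean_icp(big, True, 0, 24).mean() - self._mean_icp(big, False, 0, 24).mean()
        d5 = self._mean_icp(big, True, 96, 120).mean() - self._mean_icp(big, False, 96, 120).mean()
        assert d5 >= d1

    def test_map_similar_between_groups(self, big):
        ns, sv = [], []
        for p in big:
            m = (p.vitals["channel"] == "MAP") & ~p.vitals["is_artifact"]
            (ns if p.death_hour is not None else sv).append(p.vitals.loc[m, "value"].mean())
        diff = abs(np.mean(ns) - np.mean(sv))
        se = np.sqrt(np.var(ns, ddof=1) / len(ns) + np.var(sv, ddof=1) / len(sv))
        assert diff <= 4 * se  # no systematic MAP contrast


class TestWriteCohort:
    def test_empty_cohort_header_only(self, tmp_path):
        write_cohort([], tmp_path / "v.csv", tmp_path / "b.csv")
        v = pd.read_csv(tmp_path / "v.csv")
        b = pd.read_csv(tmp_path / "b.csv")
        assert len(v) == 0 and list(v.columns) == ["patient_id", "t_min", "channel", "value"]
        assert len(b) == 0 and "glucose" in b.columns

    def test_count_conservation(self, tmp_path, small_patients):
        p = small_patients[0]
        write_cohort([p], tmp_path / "v.csv", tmp_path / "b.csv")
        v = pd.read_csv(tmp_path / "v.csv")
        b = pd.read_csv(tmp_path / "b.csv")
        assert len(v) == len(p.vitals)
        assert len(b) == 1

    def test_round_trip_byte_identical(self, tmp_path, small_patients):
        from tbidyn.preprocessing import load_baseline_csv, load_vitals_csv

        write_cohort(small_patients[:5], tmp_path / "v1.csv", tmp_path / "b1.csv")
        v = load_vitals_csv(tmp_path / "v1.csv")
        b = load_baseline_csv(tmp_path / "b1.csv")
        v.to_csv(tmp_path / "v2.csv", index=False)
        b.to_csv(tmp_path / "b2.csv", index=False)
        assert (tmp_path / "v1.csv").read_bytes() == (tmp_path / "v2.csv").read_bytes()
        assert (tmp_path / "b1.csv").read_bytes() == (tmp_path / "b2.csv").read_bytes()

    def test_round_trips_through_preprocessing(self, tmp_path, small_patients):
        subset = small_patients[:8]
        write_cohort(subset, tmp_path / "v.csv", tmp_path / "b.csv")
        cohort, _ = preprocess(pd.read_csv(tmp_path / "v.csv"), pd.read_csv(tmp_path / "b.csv"))
        assert 0 < len(cohort.patients) <= len(subset)
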