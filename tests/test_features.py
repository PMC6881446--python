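import math

import numpy as np
import pandas as pd
import pytest

from tbidyn.features import (
    BEGIN_SPAN_MIN,
    END_SPAN_MIN,
    PREDICTION_TIMES_H,
    STEP_MIN,
    WINDOW_MIN,
    MinMaxNormalizer,
    build_derived_series,
    build_feature_matrix,
    build_feature_vector,
    derived_series_for,
    encode_agecat,
    enumerate_features,
    trend_coef,
    window_stat,
)
from tbidyn.published import published_feature_list
from helpers import constant_patient, grid, make_patient


class TestWindowStat:
    @pytest.mark.parametrize("values,stat,expected", [
        ([2, 4, 6], "diff", 2.0),
        ([7, 7, 7], "var", 0.0),
        ([7, 7, 7], "diff", 0.0),
        ([15, 25, 25, 15], "ht20", 0.5),
        ([5, 15, 25], "lt10", 1 / 3),
        ([100, 125], "ht120", 0.5),
        ([3, 1, 2], "min", 1.0),
        ([3, 1, 2], "max", 3.0),
        ([1, 2, 3, 4], "mean", 2.5),
    ])
    def test_known_values(self, values, stat, expected):
        assert window_stat(values, stat) == pytest.approx(expected)

    def test_percentile_matches_sorted_interpolation_oracle(self):
        # brute-force linear-interpolation percentile on the order statistics
        rng = np.random.default_rng(42)
        for _ in range(20):
            v = rng.normal(size=rng.integers(1, 30))
            s = np.sort(v)
            for q, stat in ((90, "q90"), (10, "q10")):
                pos = q / 100 * (len(s) - 1)
                lo = int(math.floor(pos))
                frac = pos - lo
                oracle = s[lo] if lo + 1 >= len(s) else s[lo] * (1 - frac) + s[lo + 1] * frac
                assert window_stat(v, stat) == pytest.approx(oracle)

    def test_empty_is_gap_not_zero(self):
        assert math.isnan(window_stat([], "mean"))
        assert math.isnan(window_stat([5.0], "diff"))

    def test_variance_is_population(self):
        assert window_stat([1, 3], "var") == pytest.approx(1.0)  # not 2.0


class TestDerivedSeries:
    def test_constant_icp_over_24h_gives_six_points(self):
        t = np.arange(5, 24 * 60 + 1, 5)
        s = build_derived_series(grid("icp", t, np.full(t.size, 12.0)), "mean", anchor_min=0)
        assert list(s.end_t) == [240, 480, 720, 960, 1200, 1440]
        np.testing.assert_allclose(s.values, 12.0)

    def test_empty_window_yields_gap(self):
        # data in the first and third 4-h windows only
        t = np.r_[np.arange(5, 241, 5), np.arange(485, 721, 5)]
        s = build_derived_series(grid("icp", t, np.full(t.size, 9.0)), "mean", anchor_min=0)
        assert 480 not in s.end_t
        assert {240, 720}.issubset(set(s.end_t))

    def test_linear_ramp_means_follow_sample_midpoints(self):
        t = np.arange(5, 48 * 60 + 1, 5)
        a, b = 10.0, 0.01
        s = build_derived_series(grid("icp", t, a + b * t), "mean", anchor_min=0)
        for end, val in zip(s.end_t, s.values):
            in_win = t[(t > end - 240) & (t <= end)]
            assert val == pytest.approx(a + b * in_win.mean())

    def test_gcs_windows_are_24h_long_8h_step(self):
        assert WINDOW_MIN["mr"] == 1440 and STEP_MIN["mr"] == 480
        t = np.arange(0, 72 * 60 + 1, 720)  # 12-hourly wake-up tests
        s = build_derived_series(grid("mr", t, np.linspace(6, 1, t.size)), "mean", anchor_min=0)
        assert list(s.end_t) == list(range(480, 72 * 60 + 1, 480))


class TestTrendCoef:
    def test_exact_line(self):
        from tbidyn.features import DerivedSeries

        s = DerivedSeries("icp", "mean", np.array([0.0, 240.0, 480.0]),
                          np.array([1.0, 3.0, 5.0]), 240, 240)
        assert trend_coef(s, 480) == pytest.approx(0.5)

    def test_constant_series_zero(self):
        t = np.arange(5, 1441, 5)
        s = build_derived_series(grid("icp", t, np.full(t.size, 7.0)), "mean", anchor_min=0)
        assert trend_coef(s, 1440) == pytest.approx(0.0)

    def test_matches_closed_form_ols(self):
        rng = np.random.default_rng(3)
        t = np.arange(5, 2881, 5)
        v = 10 + rng.normal(size=t.size)
        s = build_derived_series(grid("icp", t, v), "mean", anchor_min=0)
        x, y = s.end_t / 60.0, s.values
        oracle = ((x - x.mean()) @ (y - y.mean())) / ((x - x.mean()) @ (x - x.mean()))
        assert trend_coef(s, 2880) == pytest.approx(oracle)

    def test_fewer_than_two_points_missing(self):
        s = build_derived_series(grid("icp", [5], [9.0]), "mean", anchor_min=0)
        assert math.isnan(trend_coef(s, 240))


class TestEnumeration:
    def test_candidate_counts(self):
        assert len(enumerate_features("ICP-MAP-CPP")) == 54
        assert len(enumerate_features("ICP-MAP-CPP-GCS")) == 74

    def test_unknown_variant(self):
        with pytest.raises(ValueError):
            enumerate_features("ICP-ONLY")

    @pytest.mark.parametrize("variant", ["ICP-MAP-CPP", "ICP-MAP-CPP-GCS"])
    def test_published_features_are_candidates(self, variant):
        names = {e.name for e in enumerate_features(variant)}
        for f in published_feature_list(variant, with_age=False):
            assert f in names

    def test_threshold_features_present(self):
        names = {e.name for e in enumerate_features("ICP-MAP-CPP")}
        assert {"icp_ht20", "icp_lt10", "map_ht120"}.issubset(names)


class TestAgecat:
    @pytest.mark.parametrize("age,expected", [
        (16, 0.0), (29.9, 0.0), (30, 0.25), (48, 0.5), (60, 0.75), (74.9, 0.75),
        (75, 1.0), (90, 1.0),
    ])
    def test_bands(self, age, expected):
        assert encode_agecat(age) == expected

    def test_below_cohort_minimum(self):
        with pytest.raises(ValueError):
            encode_agecat(15)


class TestFeatureVector:
    def test_constant_signal(self):
        p = constant_patient(value=12.0, hours=48)
        entries = enumerate_features("ICP-MAP-CPP")
        row = build_feature_vector(p, 48, entries)
        assert row["icp_begin"] == pytest.approx(12.0)
        assert row["icp_end"] == pytest.approx(12.0)
        assert row["icp_coef"] == pytest.approx(0.0)
        assert row["cpp_begin"] == pytest.approx(73.0)
        assert row["icp_ht20"] == 0.0
        assert row["agecat"] == 0.5

    def test_rising_icp_signs(self):
        t = np.arange(0, 48 * 60 + 1, 5)
        v = 10 + 20 * t / t[-1]
        g = {"icp": grid("icp", t, v)}
        p = make_patient(g)
        entries = [e for e in enumerate_features("ICP-MAP-CPP") if e.signal == "icp"]
        row = build_feature_vector(p, 48, entries)
        assert row["icp_coef"] > 0
        assert row["icp_end"] > row["icp_begin"]

    def test_causality_future_poisoning(self):
        rng = np.random.default_rng(5)
        t = np.arange(0, 96 * 60 + 1, 5)
        v = 15 + rng.normal(0, 3, t.size)
        p = make_patient({"icp": grid("icp", t, v.copy())})
        entries = [e for e in enumerate_features("ICP-MAP-CPP") if e.signal == "icp"]
        t_pred = 48
        row = build_feature_vector(p, t_pred, entries)
        v_poison = v.copy()
        v_poison[t > t_pred * 60] = 1e9
        p2 = make_patient({"icp": grid("icp", t, v_poison)})
        row2 = build_feature_vector(p2, t_pred, entries)
        assert row == row2

    def test_row_not_emitted_without_24h_coverage(self):
        p = constant_patient(hours=30)
        entries = enumerate_features("ICP-MAP-CPP")
        assert build_feature_vector(p, 20, entries) is None  # schedule floor
        p.usable_end = 20 * 60
        assert build_feature_vector(p, 24, entries) is None


def brute_force_row(p, t_h, entries):
    """Naive recomputation materializing every rolling window explicitly."""
    out = {}
    t_min = t_h * 60.0
    for e in entries:
        g = p.grids[e.signal]
        L, step = WINDOW_MIN[e.signal], STEP_MIN[e.signal]
        windows = []
        end = p.monitoring_start + step
        while end <= g.t[-1] + step - 1e-9:
            vals = [v for tt, v in zip(g.t, g.v) if end - L < tt <= end]
            s = window_stat(vals, e.statistic)
            if not math.isnan(s):
                windows.append((end, s))
            end += step
        if e.aspect == "begin":
            pts = [s for w, s in windows if w <= p.monitoring_start + BEGIN_SPAN_MIN]
        elif e.aspect in ("end", "last"):
            pts = [s for w, s in windows if t_min - END_SPAN_MIN < w <= t_min]
        else:  # coef: OLS over all windows up to t
            pts = [(w, s) for w, s in windows if w <= t_min]
            if len(pts) < 2:
                out[e.name] = math.nan
                continue
            x = np.array([w for w, _ in pts]) / 60.0
            y = np.array([s for _, s in pts])
            out[e.name] = float(np.polyfit(x, y, 1)[0])
            continue
        if not pts:
            out[e.name] = math.nan
        elif e.aspect == "last":
            out[e.name] = pts[-1]
        elif e.statistic == "min":
            out[e.name] = min(pts)
        elif e.statistic == "max":
            out[e.name] = max(pts)
        else:
            out[e.name] = float(np.mean(pts))
    return out


class TestBruteForceEquivalence:
    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_random_grid_matches_naive_windowing(self, seed):
        rng = np.random.default_rng(seed)
        t_icp = np.sort(rng.choice(np.arange(0, 60 * 60, 5), size=300, replace=False))
        t_map = np.sort(rng.choice(np.arange(0, 60 * 60, 5), size=280, replace=False))
        g = {
            "icp": grid("icp", t_icp, rng.uniform(5, 35, t_icp.size)),
            "map": grid("map", t_map, rng.uniform(60, 130, t_map.size)),
            "mr": grid("mr", np.arange(0, 60 * 60, 720), rng.integers(1, 7, 5).astype(float)),
            "er": grid("er", np.arange(0, 60 * 60, 720), rng.integers(1, 5, 5).astype(float)),
        }
        from tbidyn.preprocessing import derive_cpp

        g["cpp"] = derive_cpp(g["icp"], g["map"])
        p = make_patient(g, start=0.0)
        entries = enumerate_features("ICP-MAP-CPP-GCS")
        for t_h in (24, 40, 56):
            got = build_feature_vector(p, t_h, entries)
            expected = brute_force_row(p, t_h, entries)
            for name, exp in expected.items():
                if math.isnan(exp):
                    assert math.isnan(got[name]), name
                else:
                    assert got[name] == pytest.approx(exp), name


class TestNormalizer:
    def test_midpoint_and_clip(self):
        norm = MinMaxNormalizer().fit(pd.DataFrame({"a": [0.0, 10.0]}))
        out = norm.transform(pd.DataFrame({"a": [5.0, 12.0, -1.0]}))
        assert list(out["a"]) == [0.5, 1.0, 0.0]

    def test_round_trip_identity_in_range(self):
        rng = np.random.default_rng(0)
        df = pd.DataFrame({"a": rng.uniform(2, 9, 50), "b": rng.normal(size=50)})
        norm = MinMaxNormalizer().fit(df)
        back = norm.inverse_transform(norm.transform(df))
        pd.testing.assert_frame_equal(back, df, check_exact=False)

    def test_degenerate_feature_maps_to_half(self):
        norm = MinMaxNormalizer().fit(pd.DataFrame({"a": [3.0, 3.0]}))
        assert list(norm.transform(pd.DataFrame({"a": [3.0, 99.0]}))["a"]) == [0.5, 0.5]

    def test_unfitted_raises(self):
        with pytest.raises(RuntimeError):
            MinMaxNormalizer().transform(pd.DataFrame({"a": [1.0]}))


class TestFeatureMatrix:
    def test_schedule_and_shape(self, small_features):
        t_vals = small_features.index.get_level_values("t_h").unique()
        assert set(t_vals).issubset(set(PREDICTION_TIMES_H))
        assert len(small_features.columns) == 54 + 2  # + agecat + label

    def test_values_normalizable(self, small_features):
        cols = [c for c in small_features.columns if c != "label"]
        norm = MinMaxNormalizer().fit(small_features[cols])
        out = norm.transform(small_features[cols])
        arr = out.to_numpy()
        assert np.nanmin(arr) >= 0.0 and np.nanmax(arr) <= 1.0
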