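"""Track reading, step geometry, cleaning rules and summaries."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

import dispersr as d

from conftest import make_track

CFG = d.FilterConfig()


class TestReadGpsCsv:
    CSV = ("individual-local-identifier,timestamp,x,y\n"
           "a,2023-01-01 00:00:00,0,0\n"
           "a,2023-01-01 03:00:00,100,0\n"
           "a,2023-01-01 06:00:00,200,0\n")

    def test_row_count_preserved(self, tmp_path):
        p = tmp_path / "t.csv"
        p.write_text(self.CSV)
        tracks = d.read_gps_csv(p)
        assert len(tracks) == 1 and tracks[0].n_fixes == 3

    def test_rows_sorted_and_individuals_split(self, tmp_path):
        rows = ["individual-local-identifier,timestamp,x,y",
                "b,2023-01-01 06:00:00,5,0",
                "a,2023-01-01 03:00:00,1,0",
                "b,2023-01-01 03:00:00,4,0",
                "a,2023-01-01 00:00:00,0,0"]
        p = tmp_path / "t.csv"
        p.write_text("\n".join(rows))
        tracks = {t.individual_id: t for t in d.read_gps_csv(p)}
        assert set(tracks) == {"a", "b"}
        for t in tracks.values():
            assert t.fixes["t"].is_monotonic_increasing
        assert tracks["a"].fixes["x"].tolist() == [0.0, 1.0]

    def test_duplicate_timestamps_keep_first(self, tmp_path):
        p = tmp_path / "t.csv"
        p.write_text(self.CSV + "a,2023-01-01 06:00:00,999,0\n")
        (tr,) = d.read_gps_csv(p)
        assert tr.n_fixes == 3 and tr.fixes["x"].iloc[-1] == 200

    def test_missing_column_is_config_error(self, tmp_path):
        p = tmp_path / "t.csv"
        p.write_text("id,timestamp,x,y\na,2023-01-01,0,0\n")
        with pytest.raises(ValueError, match="individual-local-identifier"):
            d.read_gps_csv(p)

    def test_bad_timestamp_names_row(self, tmp_path):
        p = tmp_path / "t.csv"
        p.write_text(self.CSV + "a,not-a-time,1,1\n")
        with pytest.raises(ValueError, match="rows: 5"):
            d.read_gps_csv(p)

    def test_lonlat_projected_to_meters(self, tmp_path):
        p = tmp_path / "t.csv"
        p.write_text("individual-local-identifier,timestamp,"
                     "location-long,location-lat\n"
                     "a,2023-01-01 00:00:00,25.0,65.0\n"
                     "a,2023-01-01 03:00:00,25.0,65.009\n")
        (tr,) = d.read_gps_csv(p)
        # ~0.009 deg latitude ~ 1000 m
        dy = tr.fixes["y"].iloc[1] - tr.fixes["y"].iloc[0]
        assert dy == pytest.approx(1000.0, rel=0.01)


class TestBuildSteps:
    def test_three_four_five_triangle(self):
        tr = make_track([(0, 0), (3000, 4000)])
        s = tr.steps.iloc[0]
        assert s["length_m"] == pytest.approx(5000.0)
        assert s["speed_kmph"] == pytest.approx(5.0 / 3.0)

    @pytest.mark.parametrize("end,heading", [
        ((0, 1000), 0.0), ((1000, 0), 90.0), ((0, -1000), 180.0),
        ((-1000, 0), 270.0)])
    def test_heading_axis_convention(self, end, heading):
        tr = make_track([(0, 0), end])
        assert tr.steps["heading_deg"].iloc[0] == pytest.approx(heading)

    def test_turn_angle_wrap(self):
        # headings 90 then 180 -> turn +90; 350 then 10 -> +20
        tr = make_track([(0, 0), (1000, 0), (1000, -1000)])
        assert tr.steps["turn_angle_deg"].iloc[1] == pytest.approx(90.0)
        tr2 = make_track([(0, 0),
                          (-1000 * np.sin(np.radians(10)), 1000 * np.cos(np.radians(10))),
                          (-1000 * np.sin(np.radians(10)) + 1000 * np.sin(np.radians(10)),
                           1000 * np.cos(np.radians(10)) + 1000 * np.cos(np.radians(10)))])
        assert tr2.steps["turn_angle_deg"].iloc[1] == pytest.approx(20.0)

    def test_first_step_turn_undefined(self):
        tr = make_track([(0, 0), (0, 1000), (0, 2000)])
        assert np.isnan(tr.steps["turn_angle_deg"].iloc[0])
        assert tr.steps["turn_angle_deg"].iloc[1] == pytest.approx(0.0)


class TestTrim:
    @pytest.mark.parametrize("n,remain", [(10, 4), (8, 2)])
    def test_trim_counts(self, n, remain):
        tr = make_track([(i * 100.0, 0) for i in range(n)])
        assert d.trim_track(tr, CFG).n_fixes == remain

    def test_too_short_errors(self):
        tr = make_track([(i * 100.0, 0) for i in range(7)])
        with pytest.raises(ValueError, match="too short"):
            d.trim_track(tr, CFG)

    def test_first_day_extends_front_cut(self):
        # 3-h fixes: first 24 h covers 9 fixes > trim_steps
        tr = make_track([(i * 100.0, 0) for i in range(20)])
        out = d.trim_track(tr, CFG, first_day=True)
        assert out.n_fixes == 20 - 9 - 3
        assert out.fixes["x"].iloc[0] == 900.0


class TestSpeedFilter:
    def test_outlier_end_fix_removed(self):
        # one 130 km / 3 h jump (43.3 kmph)
        tr = make_track([(0, 0), (500, 0), (130_500, 0), (131_000, 0),
                         (131_500, 0)])
        out, log = d.filter_speed_outliers(tr, CFG)
        assert out.n_fixes == 4 and len(log) == 1
        assert log[0]["x"] == 130_500

    def test_exactly_40_kmph_retained(self):
        tr = make_track([(0, 0), (120_000, 0), (120_500, 0)])
        out, log = d.filter_speed_outliers(tr, CFG)
        assert out.n_fixes == 3 and not log

    def test_clean_track_unchanged(self):
        tr = make_track([(i * 500.0, 0) for i in range(6)])
        out, log = d.filter_speed_outliers(tr, CFG)
        pd.testing.assert_frame_equal(out.fixes, tr.fixes)
        assert not log


class TestGapSplit:
    def _track_with_gap(self, gap_days):
        t = pd.Timestamp("2023-01-01", tz="UTC")
        times = [t, t + pd.Timedelta(hours=3), t + pd.Timedelta(hours=6),
                 t + pd.Timedelta(hours=6) + pd.Timedelta(days=gap_days),
                 t + pd.Timedelta(hours=9) + pd.Timedelta(days=gap_days)]
        fixes = pd.DataFrame({"t": times, "x": np.arange(5) * 100.0,
                              "y": 0.0, "imputed": False, "segment": 0})
        return d.Track("a", fixes)

    def test_eight_day_gap_splits(self):
        out = d.split_on_gaps(self._track_with_gap(8), CFG)
        assert out.n_segments == 2
        assert len(out.steps) == out.n_fixes - out.n_segments

    def test_exactly_seven_days_kept(self):
        out = d.split_on_gaps(self._track_with_gap(7), CFG)
        assert out.n_segments == 1

    def test_no_gap_single_segment(self):
        out = d.split_on_gaps(make_track([(i * 100.0, 0) for i in range(5)]), CFG)
        assert out.n_segments == 1


class TestRegularize:
    def test_linear_midpoint_imputed(self):
        tr = make_track([(0, 0), (600, 0)], interval_h=6.0)
        out = d.regularize(tr, CFG)
        assert out.n_fixes == 3
        mid = out.fixes.iloc[1]
        assert mid["x"] == pytest.approx(300.0) and bool(mid["imputed"])
        assert not out.fixes["imputed"].iloc[0]

    def test_already_regular_identity(self):
        tr = make_track([(i * 100.0, 0) for i in range(5)])
        out = d.regularize(tr, CFG)
        assert out.n_fixes == 5 and not out.fixes["imputed"].any()
        np.testing.assert_allclose(out.fixes["x"], tr.fixes["x"])

    def test_irregular_day_gives_nine_grid_fixes(self):
        rng = np.random.default_rng(0)
        dts = rng.uniform(2, 4, size=12)
        sec = np.r_[0, np.cumsum(dts)] * 3600
        sec = sec * (24 * 3600 / sec[-1])          # span exactly 24 h
        t = pd.Timestamp("2023-01-01", tz="UTC") + pd.to_timedelta(sec, unit="s")
        fixes = pd.DataFrame({"t": t, "x": np.arange(13) * 50.0, "y": 0.0,
                              "imputed": False, "segment": 0})
        out = d.regularize(d.Track("a", fixes), CFG)
        assert out.n_fixes == 9
        dt = out.steps["dt_s"].to_numpy()
        np.testing.assert_allclose(dt, 10800.0)


class TestSummaries:
    def test_displacement_examples(self):
        assert d.displacement(make_track([(0, 0), (1, 1), (3000, 4000)])) \
            == pytest.approx(5000.0)
        assert d.displacement(make_track([(0, 0), (500, 0), (0, 0)])) == 0.0

    def test_total_distance_out_and_back(self):
        tr = make_track([(0, 0), (5000, 0), (0, 0)])
        assert d.total_distance(tr) == pytest.approx(10_000.0)
        assert d.displacement(tr) == 0.0

    @settings(derandomize=True, max_examples=30, deadline=None)
    @given(st.lists(st.tuples(st.floats(-1e5, 1e5), st.floats(-1e5, 1e5)),
                    min_size=2, max_size=30))
    def test_against_brute_force_and_triangle_inequality(self, coords):
        tr = make_track(coords)
        xy = np.asarray(coords, dtype=float)
        brute_total = sum(np.hypot(*(xy[i + 1] - xy[i]))
                          for i in range(len(xy) - 1))
        brute_disp = float(np.hypot(*(xy[-1] - xy[0])))
        assert d.total_distance(tr) == pytest.approx(brute_total, abs=1e-6)
        assert d.displacement(tr) == pytest.approx(brute_disp, abs=1e-6)
        assert d.total_distance(tr) >= d.displacement(tr) - 1e-9

    def test_monthly_distance_start_fix_convention(self):
        t0 = "2023-03-31T23:00:00Z"
        tr = make_track([(0, 0), (1000, 0), (2000, 0)], t0=t0)
        m = d.monthly_distance(tr)
        assert m[pd.Period("2023-03")] == pytest.approx(1000.0)
        assert m[pd.Period("2023-04")] == pytest.approx(1000.0)
        assert m.sum() == pytest.approx(d.total_distance(tr))


class TestWelch:
    def test_identical_samples(self):
        r = d.welch_t([1, 2, 3], [1, 2, 3])
        assert r["t"] == 0.0 and r["p"] == pytest.approx(1.0)

    def test_closed_form_small_sample(self):
        # equal variances 1, n=3 each: t = -3/sqrt(2/3), df = 4
        r = d.welch_t([1, 2, 3], [4, 5, 6])
        assert r["t"] == pytest.approx(-3 / np.sqrt(2 / 3), abs=1e-9)
        assert r["df"] == pytest.approx(4.0, abs=1e-9)

    def test_matches_hand_formula_on_random_pairs(self):
        rng = np.random.default_rng(1)
        for _ in range(100):
            a = rng.normal(0, 1, rng.integers(3, 20))
            b = rng.normal(0.5, 2, rng.integers(3, 20))
            r = d.welch_t(a, b)
            va, vb = a.var(ddof=1) / len(a), b.var(ddof=1) / len(b)
            t = (a.mean() - b.mean()) / np.sqrt(va + vb)
            df = (va + vb) ** 2 / (va ** 2 / (len(a) - 1) + vb ** 2 / (len(b) - 1))
            assert r["t"] == pytest.approx(t, abs=1e-10)
            assert r["df"] == pytest.approx(df, abs=1e-10)

    def test_degenerate_errors(self):
        with pytest.raises(ValueError):
            d.welch_t([1.0], [1, 2])
        with pytest.raises(ValueError):
            d.welch_t([2.0, 2.0], [3.0, 3.0])


class TestFilterChainProperties:
    def _noisy_track(self, seed):
        rng = np.random.default_rng(seed)
        n = 60
        xy = np.cumsum(rng.normal(0, 300, size=(n, 2)), axis=0)
        xy[25] += 140_000                        # speed outlier
        t = pd.Timestamp("2023-01-01", tz="UTC") \
            + pd.to_timedelta(np.arange(n) * 3.0, unit="h")
        t = t.where(np.arange(n) < 40, t + pd.Timedelta(days=9))  # 9-day gap
        fixes = pd.DataFrame({"t": t, "x": xy[:, 0], "y": xy[:, 1],
                              "imputed": False, "segment": 0})
        return d.Track("a", fixes)

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_processed_track_invariants(self, seed):
        tr, report = d.process_track(self._noisy_track(seed), CFG)
        assert len(tr.steps) == tr.n_fixes - tr.n_segments
        assert (tr.steps["speed_kmph"] <= CFG.max_speed_kmph).all()
        assert (tr.steps["dt_s"] == 10800.0).all()
        assert report["n_speed_outliers"] >= 1

    def test_filter_chain_idempotent(self):
        def chain(tr):
            tr, _ = d.filter_speed_outliers(tr, CFG)
            return d.regularize(d.split_on_gaps(tr, CFG), CFG)

        trimmed = d.trim_track(self._noisy_track(3), CFG)
        once = chain(trimmed)
        twice = chain(once)
        pd.testing.assert_frame_equal(
            once.fixes.drop(columns="imputed"),
            twice.fixes.drop(columns="imputed"))

    def test_regularization_preserves_segment_start(self):
        tr = self._noisy_track(4)
        proc, _ = d.process_track(tr, CFG)
        for _, seg in proc.fixes.groupby("segment"):
            assert not seg["imputed"].iloc[0]
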