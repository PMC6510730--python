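import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from phenocart import growth, simulate as sim
from phenocart.growth import (
    ExtractionConfig,
    GrowthCurve,
    exponential_window,
    extract_parameters,
    filter_outlier_slopes,
    log_slopes,
    rate_from_slopes,
    saturated_density,
    subtract_background,
)
from .conftest import logistic_curve


class TestBackgroundSubtraction:
    def test_mean_of_background_wells_subtracted(self, toy_run, toy_layout):
        curves = subtract_background(toy_run, toy_layout)
        by_well = {c.well_id: c for c in curves}
        # background wells average to [0.075, 0.085, 0.075, 0.085, 0.08]
        np.testing.assert_allclose(
            by_well["B1"].od, [0.105, 0.195, 0.405, 0.595, 0.62]
        )

    def test_sample_equal_to_background_gives_zero_growth(self, toy_run, toy_layout):
        curves = subtract_background(toy_run, toy_layout)
        flat = next(c for c in curves if c.well_id == "B2")
        p = extract_parameters(flat)
        assert p.r == 0.0
        assert "zero_growth" in p.qc_flags

    def test_constant_offset_cancels(self, toy_run, toy_layout):
        import phenocart.plate_io as pio
        shifted = pio.PlateRun(
            run_id="s", times=toy_run.times,
            wells={w: od + 0.05 for w, od in toy_run.wells.items()},
        )
        a = subtract_background(toy_run, toy_layout)
        b = subtract_background(shifted, toy_layout)
        for ca, cb in zip(a, b):
            np.testing.assert_allclose(ca.od, cb.od, atol=1e-12)


class TestSaturatedDensity:
    def test_mean_of_three_reads_around_maximum(self):
        c = GrowthCurve("x", np.arange(6) * 0.5, [0.05, 0.1, 0.4, 0.9, 0.85, 0.86])
        K, edge = saturated_density(c)
        assert K == pytest.approx((0.4 + 0.9 + 0.85) / 3)
        assert not edge

    def test_constant_series_flags_edge(self):
        c = GrowthCurve("x", np.arange(5) * 0.5, np.full(5, 0.5))
        K, edge = saturated_density(c)
        assert K == pytest.approx(0.5)
        assert edge

    def test_rising_to_last_read_uses_final_three(self):
        od = np.linspace(0.1, 1.0, 10)
        c = GrowthCurve("x", np.arange(10) * 0.5, od)
        K, edge = saturated_density(c)
        assert K == pytest.approx(od[-3:].mean())
        assert edge

    def test_too_short_curve_rejected(self):
        with pytest.raises(Exception):
            saturated_density(GrowthCurve("x", [0.0, 1.0], [0.1, 0.2]))


class TestExponentialWindow:
    def test_logistic_window_spans_floor_to_sat_fraction(self):
        c = logistic_curve(r=0.8, K=1.0, od0=0.02, lag=0.0, duration=24)
        cfg = ExtractionConfig()
        start, end, flags = exponential_window(c, cfg, K=1.0)
        assert c.od[start] >= cfg.noise_floor
        assert np.all(c.od[start:end] < cfg.sat_fraction * 1.0)
        assert c.od[end] >= cfg.sat_fraction * 1.0

    def test_flat_curve_gives_empty_window_and_flag(self):
        c = GrowthCurve("x", np.arange(10) * 0.5, np.zeros(10))
        start, end, flags = exponential_window(c)
        assert (start, end) == (0, 0)
        assert "zero_growth" in flags

    def test_lag_spike_excluded_from_window(self):
        t = np.arange(49) * 0.5
        od = sim.logistic_od(t, 0.6, 0.8, 1e-3, lag=6.0)
        od[2] = 0.15  # isolated spike at t = 1 h, long before growth
        c = GrowthCurve("x", t, od)
        start, end, _ = exponential_window(c, K=0.8)
        assert start > 2  # window starts after the spike's dip below the floor


class TestLogSlopes:
    def test_exact_doubling_per_hour(self):
        c = GrowthCurve("x", [0.0, 1.0, 2.0], [0.1, 0.2, 0.4])
        slopes, pos = log_slopes(c, (0, 3), method="pairwise")
        np.testing.assert_allclose(slopes, [np.log(2), np.log(2)])
        assert list(pos) == [0, 1]

    @pytest.mark.parametrize("method", ["pairwise", "gradient", "regression"])
    def test_exact_exponential_all_methods_agree(self, method):
        t = np.arange(10) * 0.5
        c = GrowthCurve("x", t, 0.01 * np.exp(0.5 * t))
        slopes, _ = log_slopes(c, (0, 10), method=method)
        np.testing.assert_allclose(slopes, 0.5, rtol=1e-12)

    def test_half_hour_spacing(self):
        c = GrowthCurve("x", [0.0, 0.5], [0.1, 0.2])
        slopes, _ = log_slopes(c, (0, 2), method="pairwise")
        assert slopes[0] == pytest.approx(1.386294, abs=1e-6)

    def test_nonpositive_reads_dropped_with_warning(self):
        c = GrowthCurve("x", [0.0, 0.5, 1.0, 1.5], [0.1, -0.01, 0.2, 0.4])
        with pytest.warns(UserWarning, match="non-positive"):
            slopes, pos = log_slopes(c, (0, 4), method="pairwise")
        assert len(slopes) == 2  # pairs among the three positive reads


class TestOutlierFilter:
    def test_tukey_fences_remove_spike_slope(self):
        slopes = np.array([0.3, 0.4, 0.45, 0.5, 2.5])
        keep = filter_outlier_slopes(slopes, ExtractionConfig(tukey_k=1.5))
        # Q1 = 0.4, Q3 = 0.5 (linear interpolation), fences [0.25, 0.65]
        assert list(keep) == [True, True, True, True, False]

    def test_degenerate_iqr_retains_equal_slopes(self):
        keep = filter_outlier_slopes(np.full(5, 0.5))
        assert keep.all()

    def test_negative_outlier_removed(self):
        keep = filter_outlier_slopes(np.array([0.5, 0.5, 0.5, -3.0]))
        assert list(keep) == [True, True, True, False]

    def test_below_q1_mode_drops_lower_tail_only(self):
        slopes = np.array([0.1, 0.4, 0.5, 0.6, 5.0])
        keep = filter_outlier_slopes(slopes, ExtractionConfig(outlier_rule="below_q1"))
        assert not keep[0] and keep[4]

    def test_none_mode_keeps_everything(self):
        keep = filter_outlier_slopes(np.array([1.0, -99.0, 99.0]),
                                     ExtractionConfig(outlier_rule="none"))
        assert keep.all()


class TestGrowthRateStep4:
    def test_max_slope_averaged_with_neighbours(self):
        r, n = rate_from_slopes(np.array([0.4, 0.6, 0.55, 0.5]))
        assert r == pytest.approx((0.4 + 0.6 + 0.55) / 3)
        assert n == 3

    def test_neighbours_skip_filtered_slopes(self):
        slopes = np.array([0.4, 9.0, 0.6, 0.55])
        keep = np.array([True, False, True, True])
        r, n = rate_from_slopes(slopes, keep)
        assert r == pytest.approx((0.4 + 0.6 + 0.55) / 3)

    def test_single_surviving_slope(self):
        r, n = rate_from_slopes(np.array([0.7]))
        assert (r, n) == (0.7, 1)

    def test_boundary_maximum_uses_one_neighbour(self):
        r, n = rate_from_slopes(np.array([0.8, 0.6, 0.2]))
        assert r == pytest.approx(0.7)
        assert n == 2

    def test_negative_mean_floored_at_zero(self):
        r, _ = rate_from_slopes(np.array([-0.5, -0.4, -0.6]))
        assert r == 0.0


class TestExtractParameters:
    def test_noise_free_logistic_recovery(self):
        p = extract_parameters(logistic_curve(r=0.8, K=1.0, od0=0.005))
        assert abs(p.r - 0.8) / 0.8 < 0.10
        assert abs(p.K - 1.0) < 0.02

    def test_exact_exponential_rate_recovered_to_1e9(self):
        t = np.arange(30) * 0.5
        c = GrowthCurve("x", t, 0.001 * np.exp(0.4 * t))
        cfg = ExtractionConfig(sat_fraction=0.9)
        start, end, _ = exponential_window(c, cfg)
        slopes, _ = log_slopes(c, (start, end), method=cfg.slope_method,
                               slope_window=cfg.slope_window)
        keep = filter_outlier_slopes(slopes, cfg)
        r, _ = rate_from_slopes(slopes, keep)
        assert abs(r - 0.4) / 0.4 < 1e-9

    def test_flat_curve_zero_growth(self):
        c = GrowthCurve("x", np.arange(10) * 0.5, np.zeros(10))
        p = extract_parameters(c)
        assert p.r == 0.0 and "zero_growth" in p.qc_flags

    def test_exponential_phase_spike_tolerated_with_filter(self):
        # With spike-sensitive point slopes, the box-plot filter is what
        # keeps a single corrupted read from inflating the rate.
        cfg_full = ExtractionConfig(slope_method="gradient")
        cfg_none = ExtractionConfig(slope_method="gradient", outlier_rule="none")
        errs_filtered, errs_naive = [], []
        for i in range(50):
            c = logistic_curve(r=0.6, K=0.8, noise=0.005, seed=i)
            mid = np.searchsorted(c.od, 0.3)
            c.od[mid] += 0.3
            pf = extract_parameters(c, cfg_full)
            pn = extract_parameters(c, cfg_none)
            errs_filtered.append(abs(pf.r - 0.6) / 0.6)
            errs_naive.append(abs(pn.r - 0.6) / 0.6)
        assert np.median(errs_filtered) < 0.15
        assert np.median(errs_filtered) < np.median(errs_naive)

    def test_still_rising_curve_flagged_incomplete(self):
        # growth begins so late that the run ends mid-exponential
        c = logistic_curve(r=0.25, K=1.0, od0=1e-3, lag=8.0, duration=24)
        p = extract_parameters(c)
        assert "incomplete" in p.qc_flags


class TestScalingInvariances:
    @settings(max_examples=20, deadline=None)
    @given(lam=st.floats(min_value=0.2, max_value=5.0),
           r=st.floats(min_value=0.3, max_value=0.9))
    def test_od_scaling_preserves_rate_and_scales_density(self, lam, r):
        c = logistic_curve(r=r, K=1.0, od0=0.005)
        scaled = GrowthCurve("s", c.times, c.od * lam)
        cfg = ExtractionConfig(noise_floor=0.01 * lam)
        p1 = extract_parameters(c, ExtractionConfig())
        p2 = extract_parameters(scaled, cfg)
        assert p2.r == pytest.approx(p1.r, rel=1e-6)
        assert p2.K == pytest.approx(lam * p1.K, rel=1e-9)


class TestRefineAndAggregate:
    def test_planted_truncations_removed(self):
        curves = [logistic_curve(r=0.5, K=0.8, noise=0.003, seed=i) for i in range(20)]
        for i in range(3):  # make three curves still-rising at the end
            curves[i] = logistic_curve(r=0.3, K=1.0, lag=30.0,
                                       noise=0.003, seed=100 + i)
        rows = []
        for i, c in enumerate(curves):
            c.curve_id = f"c{i}"
            c.combination_id = f"combo{i % 5}"
            p = extract_parameters(c)
            rows.append({"curve_id": c.curve_id, "combination_id": c.combination_id,
                         "replicate_index": i // 5, "r": p.r, "K": p.K,
                         "qc_flags": p.flags_str})
        import phenocart.plate_io as pio
        records = pio.make_growth_table(rows)
        refined, log = growth.refine_dataset(records)
        assert len(log) == 3
        assert len(refined) == 17
        assert set(log["curve_id"]) == {"c0", "c1", "c2"}

    def test_all_complete_set_identity(self):
        import phenocart.plate_io as pio
        records = pio.make_growth_table([
            {"curve_id": "a", "combination_id": "c", "replicate_index": 0,
             "r": 0.5, "K": 0.9, "qc_flags": ""}])
        refined, log = growth.refine_dataset(records)
        assert len(refined) == 1 and len(log) == 0

    def test_flat_curves_retained_with_zero_rate(self):
        import phenocart.plate_io as pio
        records = pio.make_growth_table([
            {"curve_id": "a", "combination_id": "c", "replicate_index": 0,
             "r": 0.0, "K": 0.004, "qc_flags": "zero_growth"}])
        refined, _ = growth.refine_dataset(records)
        assert len(refined) == 1 and refined["r"].iloc[0] == 0.0

    def test_aggregation_mean_and_se(self):
        import phenocart.plate_io as pio
        records = pio.make_growth_table([
            {"curve_id": "a", "combination_id": "c1", "replicate_index": 0,
             "r": 0.5, "K": 0.8, "qc_flags": ""},
            {"curve_id": "b", "combination_id": "c1", "replicate_index": 1,
             "r": 0.7, "K": 0.8, "qc_flags": ""},
            {"curve_id": "c", "combination_id": "c2", "replicate_index": 0,
             "r": 0.4, "K": 0.6, "qc_flags": ""},
        ])
        agg = growth.aggregate_combinations(records, n_min=3)
        assert agg.loc["c1", "mean_r"] == pytest.approx(0.6)
        assert agg.loc["c1", "se_r"] == pytest.approx(0.1)
        assert agg.loc["c1", "se_K"] == pytest.approx(0.0)
        assert np.isnan(agg.loc["c2", "se_r"])
        assert agg["low_n"].all()
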