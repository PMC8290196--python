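"""Trait arithmetic, hulls, crossing statistics, spectra."""

from types import SimpleNamespace

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from shapely.geometry import MultiPoint

from chronorsa.phenotype import (aligned_difference_curve, convex_hull_area,
                                 derivative_at_crossing, growth_speed,
                                 intersection_time, lr_density_over_hull,
                                 measure_frame, measure_sequence, slope_fit,
                                 spectral_energy, windowed_energy_series)
from chronorsa.rsa_graph import (graph_from_skeleton, label_roots,
                                 skeletonize_mask)
from chronorsa.synthetic import (RootSystemSpec, render_mask,
                                 simulate_growth_signal,
                                 simulate_root_system)


def _fake_graph(mr, lrs, t=1.0):
    return SimpleNamespace(labelled=True, timestamp_h=t, mr_length_mm=mr,
                           lr_lengths_mm=dict(enumerate(lrs, 1)),
                           tracking_failure=False)


class TestMeasureFrame:
    def test_arithmetic(self):
        row = measure_frame(_fake_graph(10.0, [2.0, 3.0]))
        assert row["tr_length_mm"] == 15.0
        assert row["lr_count"] == 2
        assert row["lr_density_per_mm"] == pytest.approx(0.2)
        assert row["mr_fraction"] == pytest.approx(2 / 3)

    def test_no_laterals(self):
        row = measure_frame(_fake_graph(5.0, []))
        assert row["lr_total_length_mm"] == 0.0
        assert row["mr_fraction"] == 1.0

    def test_zero_mr_gives_missing_density(self):
        row = measure_frame(_fake_graph(0.0, []))
        assert np.isnan(row["lr_density_per_mm"])

    def test_unlabelled_rejected(self):
        g = _fake_graph(1.0, [])
        g.labelled = False
        with pytest.raises(ValueError):
            measure_frame(g)

    def test_series_identity_on_synthetic_sequence(self, two_lr_spec):
        gt = simulate_root_system(two_lr_spec)
        prev, graphs = None, []
        for frame in gt.frames[::8]:
            mask = render_mask(frame, two_lr_spec)
            if not mask.any():
                continue
            g = label_roots(graph_from_skeleton(
                skeletonize_mask(mask), mm_per_px=two_lr_spec.mm_per_px,
                timestamp_h=frame.time_h), prev)
            prev = g
            graphs.append(g)
        df = measure_sequence(graphs)
        assert np.allclose(df["tr_length_mm"],
                           df["mr_length_mm"] + df["lr_total_length_mm"])
        assert ((df["mr_fraction"] >= 0) & (df["mr_fraction"] <= 1)).all()


class TestConvexHull:
    def test_square_of_pixel_centers(self):
        pts = np.array([[0, 0], [0, 9], [9, 0], [9, 9]])
        assert convex_hull_area(pts, 0.1) == pytest.approx(0.81)

    def test_collinear_and_tiny_inputs(self):
        assert convex_hull_area(np.array([[0, 0], [5, 5], [9, 9]])) == 0.0
        assert convex_hull_area(np.array([[0, 0], [1, 1]])) == 0.0

    def test_matches_independent_hull_oracle(self):
        rng = np.random.default_rng(0)
        for _ in range(5):
            pts = rng.integers(0, 100, size=(200, 2))
            mine = convex_hull_area(pts, 1.0)
            oracle = MultiPoint([tuple(p) for p in pts]).convex_hull.area
            assert mine == pytest.approx(oracle, abs=1e-9)

    def test_mask_input(self):
        mask = np.zeros((20, 20), bool)
        mask[5:15, 5:15] = True
        assert convex_hull_area(mask, 1.0) == pytest.approx(81.0)

    def test_density_over_hull(self):
        assert lr_density_over_hull(30.0, 15.0) == pytest.approx(2.0)
        assert lr_density_over_hull(0.0, 15.0) == 0.0
        assert np.isnan(lr_density_over_hull(1.0, 0.0))

    def test_density_scaling_homogeneity(self):
        # lengths x2, area x4 => ratio x1/2
        assert (lr_density_over_hull(2 * 30.0, 4 * 15.0)
                == pytest.approx(0.5 * lr_density_over_hull(30.0, 15.0)))


class TestIntersection:
    def test_closed_form_crossing(self):
        t = np.arange(0, 48.25, 0.25)
        assert intersection_time(np.full_like(t, 10.0), t.astype(float),
                                 t) == pytest.approx(10.0)

    def test_no_crossing_signal(self):
        t = np.arange(0, 10, 0.25)
        assert intersection_time(np.full_like(t, 10.0), 0.1 * t, t) is None

    def test_piecewise_linear_analytic_crossing(self):
        t = np.arange(0, 60.25, 0.25)
        mr = 0.3 * t + 2.0
        lr = np.where(t > 20, 0.8 * (t - 20), 0.0)
        # analytic: 0.8 (t-20) = 0.3 t + 2 -> t = 18/0.5 + ... solve
        t_true = (0.8 * 20 + 2.0) / (0.8 - 0.3)
        got = intersection_time(mr, lr, t)
        assert got == pytest.approx(t_true, abs=0.25)

    def test_pandas_series_input(self):
        t = np.arange(0, 48.25, 0.25)
        mr = pd.Series(np.full_like(t, 5.0), index=t)
        lr = pd.Series(0.5 * t, index=t)
        assert intersection_time(mr, lr) == pytest.approx(10.0)


class TestAlignedCurve:
    def test_full_window_has_193_samples_and_zero_at_origin(self):
        t = np.arange(0, 96.25, 0.25)
        mr = np.full_like(t, 20.0)
        lr = 0.5 * t
        ts = intersection_time(mr, lr, t)
        tau, d, truncated = aligned_difference_curve(mr, lr, ts, t)
        assert len(tau) == 193
        assert not truncated
        assert d[np.argmin(np.abs(tau))] == pytest.approx(0.0, abs=1e-9)

    def test_linear_inputs_give_linear_curve(self):
        t = np.arange(0, 96.25, 0.25)
        mr = 0.2 * t + 5
        lr = 0.5 * t
        ts = intersection_time(mr, lr, t)
        tau, d, _ = aligned_difference_curve(mr, lr, ts, t)
        assert np.allclose(d, -0.3 * tau, atol=1e-9)

    def test_truncated_window_is_flagged(self):
        t = np.arange(0, 30.25, 0.25)
        mr = np.full_like(t, 5.0)
        lr = 0.5 * t
        tau, d, truncated = aligned_difference_curve(mr, lr, 10.0, t)
        assert truncated
        assert len(tau) < 193


class TestDerivativeAndSlope:
    def test_exact_on_linear(self):
        tau = np.arange(-24, 24.25, 0.25)
        v, one_sided = derivative_at_crossing(tau, -0.7 * tau)
        assert v == pytest.approx(-0.7, abs=1e-12)
        assert not one_sided

    def test_zero_on_even_function(self):
        tau = np.arange(-24, 24.25, 0.25)
        v, _ = derivative_at_crossing(tau, tau ** 2)
        assert v == pytest.approx(0.0, abs=1e-12)

    def test_sine_difference_quotient(self):
        tau = np.arange(-24, 24.25, 0.25)
        v, _ = derivative_at_crossing(tau, np.sin(tau))
        assert v == pytest.approx(np.sin(0.25) / 0.25, abs=1e-12)

    def test_one_sided_fallback_flagged(self):
        tau = np.array([0.0, 0.25, 0.5])
        v, one_sided = derivative_at_crossing(tau, 2.0 * tau)
        assert one_sided and v == pytest.approx(2.0)

    def test_slope_fit_exact_line_and_quadratic(self):
        tau = np.arange(-24, 24.25, 0.25)
        assert slope_fit(tau, -0.3 * tau + 1) == pytest.approx(-0.3)
        assert slope_fit(tau, tau ** 2) == pytest.approx(0.0, abs=1e-9)
        assert np.isnan(slope_fit(np.zeros(3), np.ones(3)))

    def test_slope_recovery_under_noise(self):
        tau = np.arange(-24, 24.25, 0.25)
        rng = np.random.default_rng(0)
        d = 0.45 * tau + rng.normal(0, 0.1, tau.shape)
        slope = slope_fit(tau, d)
        se = 0.1 / np.sqrt(np.sum((tau - tau.mean()) ** 2))
        assert abs(slope - 0.45) < 3 * se


class TestGrowthSpeed:
    def test_linear_length(self):
        t = np.arange(0, 24.25, 0.25)
        _, v = growth_speed(2 * t, t, smooth_window_h=0)
        assert np.allclose(v, 2.0)
        _, v = growth_speed(2 * t, t)          # smoothing preserves a constant
        assert np.allclose(v, 2.0)

    def test_constant_length(self):
        t = np.arange(0, 24.25, 0.25)
        _, v = growth_speed(np.full_like(t, 7.0), t)
        assert np.allclose(v, 0.0)

    def test_short_series_empty(self):
        t, v = growth_speed(np.array([1.0]))
        assert len(v) == 0

    def test_sinusoidal_speed_recovered(self):
        t = np.arange(0, 24 * 7 + 0.25, 0.25)
        length = t + (24 / (2 * np.pi)) * (1 - np.cos(2 * np.pi * t / 24))
        mid, v = growth_speed(length, t, smooth_window_h=0)
        expected = 1 + np.sin(2 * np.pi * mid / 24)
        amp_err = (np.abs(v - expected)).max()
        assert amp_err < 0.01 * 1.0            # < 1% of the amplitude


class TestSpectral:
    @pytest.fixture()
    def sin24(self):
        _, s = simulate_growth_signal(1.0, 0.0, 0.2, 0.0, 24 * 14, 0.25, 0)
        return s[:-1]                          # exactly 14 * 96 samples

    def test_pure_circadian_peak_and_leakage(self, sin24):
        f = spectral_energy(sin24)
        k24 = np.argmin(np.abs(f.frequencies_per_h - 1 / 24))
        assert np.argmax(f.energy) == k24
        assert f.energy_12 <= 1e-10 * f.energy_24

    def test_constant_signal_no_energy_after_highpass(self):
        f = spectral_energy(np.full(96 * 14, 3.0))
        assert np.all(f.energy[1:] < 1e-20)

    def test_two_sine_energy_ratio(self):
        _, s = simulate_growth_signal(0.8, 0.4, 0.2, 0.0, 24 * 14, 0.25, 0)
        f = spectral_energy(s[:-1])
        assert f.energy_24 / f.energy_12 == pytest.approx(4.0, rel=1e-6)

    def test_parseval(self, sin24):
        f = spectral_energy(sin24, preprocess=False)
        assert f.energy.sum() == pytest.approx((sin24 ** 2).sum(), rel=1e-6)

    def test_gaps_abort(self):
        x = np.ones(100)
        x[3] = np.nan
        with pytest.raises(ValueError, match="gaps"):
            spectral_energy(x)

    def test_amplitude_recovery_with_noise(self):
        _, s = simulate_growth_signal(1.0, 0.5, 0.2, 0.1, 24 * 14, 0.25, 7)
        f = spectral_energy(s[:-1])
        assert f.amplitude(f.energy_24) == pytest.approx(1.0, rel=0.1)
        assert f.amplitude(f.energy_12) == pytest.approx(0.5, rel=0.1)


class TestWindowedEnergy:
    def test_stationary_signal_constant_energy(self):
        _, s = simulate_growth_signal(1.0, 0.0, 0.2, 0.0, 24 * 14, 0.25, 0)
        c, e = windowed_energy_series(s[:-1], 1 / 24)
        assert e.std() / e.mean() < 0.01
        assert len(c) == len(s[:-1]) - 672 + 1

    def test_ramping_amplitude_monotone(self):
        t = np.arange(0, 24 * 14, 0.25)
        ramp = (t / t[-1]) * np.sin(2 * np.pi * t / 24)
        _, e = windowed_energy_series(ramp, 1 / 24, preprocess=False)
        assert np.all(np.diff(e) >= -1e-9)

    def test_cross_target_orthogonality(self):
        _, s = simulate_growth_signal(0.0, 1.0, 0.2, 0.0, 24 * 14, 0.25, 0)
        _, e24 = windowed_energy_series(s[:-1], 1 / 24)
        _, e12 = windowed_energy_series(s[:-1], 1 / 12)
        assert np.max(e24) <= 1e-10 * np.max(e12)

    def test_short_record_aborts(self):
        with pytest.raises(ValueError, match="window"):
            windowed_energy_series(np.ones(100), 1 / 24)

    def test_windowed_amplitude_ratio_recovery(self):
        _, s = simulate_growth_signal(1.0, 0.5, 0.2, 0.1, 24 * 16, 0.25, 3)
        c, e24 = windowed_energy_series(s[:-1], 1 / 24)
        _, e12 = windowed_energy_series(s[:-1], 1 / 12)
        ratio = np.sqrt(np.median(e24) / np.median(e12))
        assert ratio == pytest.approx(2.0, rel=0.1)


def test_two_condition_cohort_separates_in_generator_direction():
    """Faster growth + denser laterals must separate every classic trait
    curve in the direction implied by the generator parameters."""
    def cohort(speed, emergences, seed):
        spec = RootSystemSpec(
            seed_position=(10, 150), mr_speed=speed,
            lr_emergence_times=tuple(emergences),
            lr_angles=tuple(50.0 * (-1) ** i for i in range(len(emergences))),
            lr_speeds=(0.12,) * len(emergences),
            duration_h=50, image_size=(300, 300), mm_per_px=0.1,
            rng_seed=seed)
        gt = simulate_root_system(spec)
        prev, graphs, masks = None, [], []
        for frame in gt.frames[::4]:
            mask = render_mask(frame, spec)
            if not mask.any():
                continue
            g = label_roots(graph_from_skeleton(
                skeletonize_mask(mask), mm_per_px=0.1,
                timestamp_h=frame.time_h), prev)
            prev = g
            graphs.append(g)
            masks.append(mask)
        return measure_sequence(graphs, masks, 0.1)

    fast = cohort(0.35, [8.0, 16.0, 24.0, 32.0], 1)
    slow = cohort(0.25, [14.0, 30.0], 2)
    a, b = fast.iloc[-1], slow.iloc[-1]
    assert a["mr_length_mm"] > b["mr_length_mm"]
    assert a["lr_total_length_mm"] > b["lr_total_length_mm"]
    assert a["tr_length_mm"] > b["tr_length_mm"]
    assert a["lr_count"] > b["lr_count"]
    assert a["lr_density_per_mm"] > b["lr_density_per_mm"]
    assert a["mr_fraction"] < b["mr_fraction"]
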