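"""Approach-curve physics, synthetic surfaces and the hopping-scan model."""

import numpy as np
import pytest

from sicmtools import (
    ApproachCurveParams,
    ConfigurationError,
    ScanConfig,
    SurfaceSpec,
    approach_current,
    count_noise_points,
    current_change_rate,
    make_surface,
    simulate_hop_scan,
    trigger_distance,
)
from sicmtools.topo import HeightMap


class TestApproachCurve:
    def test_hand_value_correction_factor_one(self):
        # ln(r_o/r) = 1.5, tan(theta) = 1, d = r  ->  I = I_ref / 2
        p = ApproachCurveParams(I_ref=1.0, r=30.0, r_o=30.0 * np.exp(1.5), tan_theta=1.0)
        assert approach_current(30.0, p) == pytest.approx(0.5, abs=1e-12)

    def test_far_field_limit(self, curve_params):
        d = 1e9 * curve_params.r
        assert approach_current(d, curve_params) == pytest.approx(
            curve_params.I_ref, abs=1e-6
        )

    def test_monotone_increasing(self, curve_params, rng):
        d = np.sort(rng.uniform(1.0, 1e4, 500))
        i = approach_current(d, curve_params)
        assert (np.diff(i) > 0).all()
        assert (i > 0).all() and (i < curve_params.I_ref).all()

    def test_rejects_nonpositive_distance(self, curve_params):
        with pytest.raises(ValueError):
            approach_current(0.0, curve_params)

    def test_trigger_distance_solves_threshold(self, curve_params):
        d = trigger_distance(curve_params, 0.99)
        assert approach_current(d, curve_params) == pytest.approx(
            0.99 * curve_params.I_ref, abs=1e-12
        )


class TestChangeRate:
    def test_matches_direct_formula(self, curve_params, rng):
        for _ in range(100):
            d0, d1 = rng.uniform(10, 5000, 2)
            if d0 == d1:
                continue
            expected = (
                approach_current(d0, curve_params) - approach_current(d1, curve_params)
            ) / (d0 - d1)
            assert current_change_rate(d0, d1, curve_params) == pytest.approx(
                expected, abs=1e-12
            )

    def test_rate_magnitude_grows_toward_sample(self, curve_params):
        # covering more distance per period ends closer to the surface where
        # the curve is steeper, so the sampled change rate is larger
        d0 = 2000.0
        slow = current_change_rate(d0, d0 - 300.0, curve_params)
        fast = current_change_rate(d0, d0 - 1200.0, curve_params)
        assert abs(fast) > abs(slow)

    def test_far_field_plateau(self, curve_params):
        rate = current_change_rate(1e8, 2e8, curve_params)
        assert abs(rate) < 1e-12

    def test_degenerate_interval_rejected(self, curve_params):
        with pytest.raises(ValueError):
            current_change_rate(100.0, 100.0, curve_params)


class TestMakeSurface:
    def test_deterministic_given_seed(self):
        spec = SurfaceSpec(seed=3)
        a, b = make_surface(spec), make_surface(spec)
        np.testing.assert_array_equal(a.heights, b.heights)

    def test_no_features_flat_at_min(self):
        m = make_surface(SurfaceSpec(n_features=0, height_range=(2.0, 30.0)))
        np.testing.assert_allclose(m.heights, 2.0)

    def test_realized_span(self):
        m = make_surface(SurfaceSpec(shape=(48, 48), height_range=(0.0, 30.0),
                                     n_features=5, seed=7))
        assert 28.5 <= m.h_max - m.h_min <= 31.5

    def test_smooth_no_isolated_spikes(self):
        m = make_surface(SurfaceSpec(shape=(48, 48), height_range=(0.0, 30.0),
                                     n_features=5, seed=7))

        def max_lap(h):
            return np.abs(h[1:-1, 1:-1] * 4 - h[:-2, 1:-1] - h[2:, 1:-1]
                          - h[1:-1, :-2] - h[1:-1, 2:]).max()

        spiked = m.heights.copy()
        spiked[20, 20] += 3.0  # a typical false-trigger spike
        # the clean surface's discrete Laplacian is bounded well below what
        # any isolated spike would produce
        assert max_lap(m.heights) * 2 < max_lap(spiked)

    def test_oversample_keeps_base_lattice(self):
        spec = SurfaceSpec(shape=(24, 24), n_features=4, seed=5)
        base = make_surface(spec)
        fine = make_surface(spec, oversample=2)
        assert fine.shape == (48, 48)
        assert fine.pixel_pitch == pytest.approx(base.pixel_pitch / 2)
        np.testing.assert_allclose(fine.heights[::2, ::2], base.heights, atol=1e-12)

    def test_zero_area_rejected(self):
        with pytest.raises(ValueError):
            SurfaceSpec(shape=(0, 5))


class TestHopScan:
    def test_noiseless_error_within_step(self, surface48, curve_params):
        cfg = ScanConfig(current_noise_sd=0.0, speed_v=60.0)
        noisy, mask = simulate_hop_scan(surface48, cfg, curve_params)
        D_um = cfg.step_D / 1000.0
        assert np.abs(noisy.heights - surface48.heights).max() <= D_um * (1 + 1e-9)
        assert mask.count == 0

    def test_deterministic_given_seed(self, surface48, curve_params, scan_cfg):
        a, am = simulate_hop_scan(surface48, scan_cfg, curve_params, seed=5)
        b, bm = simulate_hop_scan(surface48, scan_cfg, curve_params, seed=5)
        np.testing.assert_array_equal(a.heights, b.heights)
        np.testing.assert_array_equal(am.mask, bm.mask)

    def test_spikes_positive_and_isolated(self, surface48, curve_params, scan_cfg):
        # false triggers happen early in the descent, above the surface
        errs = []
        for s in range(20):
            noisy, mask = simulate_hop_scan(surface48, scan_cfg, curve_params, seed=s)
            errs.extend((noisy.heights - surface48.heights)[mask.mask])
        assert errs, "expected some noise points across 20 scans"
        assert (np.asarray(errs) > 0).all()

    def test_noise_count_grows_with_speed(self, surface48, curve_params):
        means = []
        for v in (240.0, 960.0):
            counts = [
                simulate_hop_scan(surface48, ScanConfig(speed_v=v), curve_params,
                                  seed=s)[1].count
                for s in range(50)
            ]
            means.append(np.mean(counts))
        assert means[1] >= means[0]

    def test_hop_height_must_clear_relief(self, curve_params):
        steep = HeightMap(np.array([[0.0, 20.0], [0.0, 20.0]]))
        with pytest.raises(ConfigurationError):
            simulate_hop_scan(steep, ScanConfig(hop_height=5.0), curve_params)


class TestCountNoisePoints:
    def test_identical_maps(self, surface48):
        assert count_noise_points(surface48, surface48, 0.1) == 0

    def test_injected_spikes(self, surface48):
        bumped = surface48.heights.copy()
        for r, c in ((3, 4), (10, 20), (40, 7)):
            bumped[r, c] += 1.0
        assert count_noise_points(HeightMap(bumped), surface48, 0.1) == 3

    def test_matches_loop_oracle(self, surface48, curve_params, scan_cfg):
        noisy, _ = simulate_hop_scan(surface48, scan_cfg, curve_params, seed=2)
        tol = 0.5
        expected = sum(
            1
            for i in range(48)
            for j in range(48)
            if abs(noisy.heights[i, j] - surface48.heights[i, j]) > tol
        )
        assert count_noise_points(noisy, surface48, tol) == expected

    def test_shape_mismatch_rejected(self, surface48):
        small = HeightMap(np.zeros((4, 4)) + 1.0)
        with pytest.raises(ValueError):
            count_noise_points(small, surface48, 0.1)
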