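"""Analytic source-model tests: fields, peak laws, boundaries, patterns."""

import numpy as np
import pytest
from scipy.optimize import brentq

from wlpkit.model import (
    FieldGrid,
    SourcePair,
    SpatioTemporalSource,
    classify_midpoint_concavity,
    count_temporal_peaks,
    default_grid,
    evaluate_potential,
    first_max_latency_map,
    gaussian_pair,
    make_pattern,
    pattern_latency_map,
    peak_velocity_gaussian,
    peak_velocity_periodic,
    periodic_pair,
    pldc_scan,
    track_peak,
)


class TestEvaluatePotential:
    def test_symmetric_pair_value_at_origin(self):
        pair = gaussian_pair(dx=1.0, sigma_x=1.0, dt=2.0, sigma_t=1.0)
        g = evaluate_potential(pair, FieldGrid(x=np.array([0.0]), t=np.array([0.0])))
        assert g.potential[0, 0] == pytest.approx(2 * np.exp(-0.625), rel=1e-12)

    def test_gaussian_tails_vanish(self):
        pair = gaussian_pair(1.0)
        g = evaluate_potential(pair, FieldGrid(x=np.array([50.0]), t=np.array([0.0])))
        assert g.potential[0, 0] < 1e-10

    def test_spacetime_mirror_symmetry(self):
        pair = gaussian_pair(dx=1.2, sigma_x=0.8, dt=1.5, sigma_t=0.7)
        x = np.linspace(-3, 3, 41)
        t = np.linspace(-3, 3, 41)
        V = evaluate_potential(pair, FieldGrid(x=x, t=t)).potential
        # V(x, t) = V(-x, 2*tbar - t) with tbar = 0
        assert np.allclose(V, V[::-1, ::-1], atol=1e-12)

    def test_linear_in_amplitude_and_additive(self):
        s1 = SpatioTemporalSource(center_x=-0.5, spatial_scale=1.0, center_t=-1.0)
        s2 = SpatioTemporalSource(center_x=0.5, spatial_scale=1.0, center_t=1.0)
        s1_scaled = SpatioTemporalSource(
            center_x=-0.5, spatial_scale=1.0, center_t=-1.0, amplitude=3.0
        )
        grid = FieldGrid(x=np.linspace(-2, 2, 11), t=np.linspace(-2, 2, 11))
        v_pair = evaluate_potential(SourcePair(s1, s2), grid).potential
        v1 = evaluate_potential(SourcePair(s1, s1_scaled), grid).potential
        v1_only = np.outer(s1.spatial_profile(grid.x), s1.temporal_profile(grid.t))
        assert np.allclose(v_pair, v1_only + np.outer(s2.spatial_profile(grid.x), s2.temporal_profile(grid.t)))
        assert np.allclose(v1, 4 * v1_only)

    def test_mismatched_temporal_modes_rejected(self):
        g = SpatioTemporalSource(center_x=0.0, spatial_scale=1.0)
        p = SpatioTemporalSource(center_x=1.0, spatial_scale=1.0, temporal_mode="periodic")
        with pytest.raises(ValueError):
            SourcePair(g, p)


class TestTrackPeak:
    def test_symmetric_pair_midtime_peak_at_origin(self):
        pair = gaussian_pair(1.0, 1.0, 2.0, 1.0)
        traj = track_peak(pair, [0.0])
        assert traj.positions[0] == pytest.approx(0.0, abs=1e-9)

    def test_early_times_peak_at_first_source(self):
        pair = gaussian_pair(1.0, 1.0, 2.0, 1.0)
        traj = track_peak(pair, [-6.0])
        assert traj.positions[0] == pytest.approx(-0.5, abs=0.02)

    def test_matches_dense_grid_argmax(self):
        pair = gaussian_pair(dx=1.0, sigma_x=1.0, dt=2.0, sigma_t=1.0)
        xs = np.linspace(-4, 4, 10_000)
        for t in (-0.6, 0.0, 0.4):
            V = np.zeros_like(xs)
            for s in pair.sources:
                V += s.spatial_profile(xs) * float(s.temporal_profile(np.array([t]))[0])
            argmax = xs[np.argmax(V)]
            traj = track_peak(pair, [t])
            assert abs(traj.positions[0] - argmax) < (xs[1] - xs[0])

    def test_separated_sources_flagged_degenerate(self):
        pair = gaussian_pair(dx=8.0, sigma_x=1.0, dt=0.0, sigma_t=1.0)
        traj = track_peak(pair, [0.0])
        assert traj.degenerate[0]


def _numeric_velocity_gaussian(dx, sx, dt, st, h=1e-5):
    pair = gaussian_pair(dx, sx, dt, st)
    traj = track_peak(pair, [-h, h])
    return (traj.positions[1] - traj.positions[0]) / (2 * h)


def _numeric_velocity_periodic(x0, dx, sx, f, dphi):
    """Finite-difference velocity of the tracked periodic peak as it passes x0."""
    w = 2 * np.pi * f
    x1, x2 = -dx / 2, dx / 2
    p1, p2 = -dphi / 2, dphi / 2

    def Vx(x, t):
        g1 = np.exp(-((x - x1) ** 2) / (2 * sx**2))
        g2 = np.exp(-((x - x2) ** 2) / (2 * sx**2))
        return np.cos(w * t + p1) * (-(x - x1) / sx**2) * g1 + np.cos(w * t + p2) * (
            -(x - x2) / sx**2
        ) * g2

    tt = np.linspace(-0.5 / f, 0.5 / f, 2001)
    vals = Vx(x0, tt)
    for i in np.flatnonzero(np.sign(vals[:-1]) != np.sign(vals[1:])):
        t0 = brentq(lambda t: Vx(x0, t), tt[i], tt[i + 1], xtol=1e-14)
        h = 1e-5
        if (Vx(x0 + h, t0) - Vx(x0 - h, t0)) / (2 * h) < 0:  # a maximum
            h = 1e-6
            xp = lambda t: brentq(lambda x: Vx(x, t), x0 - 0.4 * sx, x0 + 0.4 * sx, xtol=1e-14)
            return (xp(t0 + h) - xp(t0 - h)) / (2 * h)
    raise AssertionError("no tracked maximum passes x0")


class TestPeakVelocities:
    def test_gaussian_example_two_thirds(self):
        assert peak_velocity_gaussian(1.0, 1.0, 2.0, 1.0) == pytest.approx(2 / 3, rel=1e-12)

    def test_simultaneous_activation_is_static(self):
        assert peak_velocity_gaussian(1.0, 1.0, 0.0, 1.0) == 0.0

    def test_velocity_increases_toward_concavity_boundary(self):
        vs = [peak_velocity_gaussian(dx, 1.0, 2.0, 1.0) for dx in np.linspace(0.2, 1.95, 20)]
        assert np.all(np.diff(vs) > 0)

    def test_domain_error_beyond_boundary(self):
        with pytest.raises(ValueError):
            peak_velocity_gaussian(2.5, 1.0, 2.0, 1.0)

    def test_zero_phase_difference_is_static(self):
        assert peak_velocity_periodic(0.0, 1.0, 1.0, 1.0, 0.0) == 0.0

    def test_phase_flip_reverses_direction(self):
        v_fwd = peak_velocity_periodic(0.1, 1.0, 1.0, 1.0, np.pi / 3)
        v_bwd = peak_velocity_periodic(0.1, 1.0, 1.0, 1.0, -np.pi / 3)
        assert v_fwd == pytest.approx(-v_bwd, rel=1e-9)

    def test_magnitude_proportional_to_frequency(self):
        v1 = peak_velocity_periodic(0.0, 1.0, 1.0, 1.0, np.pi / 2)
        v3 = peak_velocity_periodic(0.0, 1.0, 1.0, 3.0, np.pi / 2)
        assert v3 == pytest.approx(3 * v1, rel=1e-12)

    def test_domain_error_in_separated_regime(self):
        with pytest.raises(ValueError):
            peak_velocity_periodic(0.0, 3.0, 1.0, 1.0, np.pi / 2)

    def test_gaussian_closed_form_matches_tracked_peak(self):
        rng = np.random.default_rng(12345)
        for _ in range(25):
            sx = rng.uniform(0.5, 2.0)
            dx = rng.uniform(0.2, 1.8) * sx
            st = rng.uniform(0.5, 2.0)
            dt = rng.uniform(0.2, 3.0) * st
            v_cf = peak_velocity_gaussian(dx, sx, dt, st)
            v_num = _numeric_velocity_gaussian(dx, sx, dt, st)
            assert v_cf == pytest.approx(v_num, rel=1e-3)

    def test_periodic_closed_form_matches_tracked_peak(self):
        rng = np.random.default_rng(54321)
        checked = 0
        while checked < 15:
            sx = rng.uniform(0.5, 2.0)
            dx = rng.uniform(0.3, 1.7) * sx
            f = rng.uniform(0.5, 3.0)
            dphi = rng.uniform(0.2, 2.9) * (1 if rng.random() < 0.5 else -1)
            x0 = rng.uniform(-0.3, 0.3) * dx
            v_cf = peak_velocity_periodic(x0, dx, sx, f, dphi)
            try:
                v_num = _numeric_velocity_periodic(x0, dx, sx, f, dphi)
            except (AssertionError, ValueError):
                continue
            assert v_cf == pytest.approx(v_num, rel=1e-3)
            checked += 1

    def test_reversed_activation_order_negates_velocity(self):
        # swapping the activation times (dt -> -dt) with positions fixed
        # reverses the propagation direction
        h = 1e-5
        v = np.diff(track_peak(gaussian_pair(1.0, 1.0, 2.0, 1.0), [-h, h]).positions)[0] / (2 * h)
        v_rev = np.diff(track_peak(gaussian_pair(1.0, 1.0, -2.0, 1.0), [-h, h]).positions)[0] / (2 * h)
        assert v == pytest.approx(-v_rev, rel=1e-6)
        assert peak_velocity_gaussian(1.0, 1.0, -2.0, 1.0) == pytest.approx(-2 / 3, rel=1e-12)


class TestBoundaries:
    @pytest.mark.parametrize(
        "dx, sigma, expected",
        [(1.0, 1.0, "concave"), (3.0, 1.0, "convex"), (0.0, 2.0, "concave"), (2.0, 1.0, "concave")],
    )
    def test_concavity_classification(self, dx, sigma, expected):
        assert classify_midpoint_concavity(dx, sigma) == expected

    @pytest.mark.parametrize("ratio, n", [(1.0, 1), (3.0, 2), (2.0, 1), (0.4, 1)])
    def test_temporal_peak_count(self, ratio, n):
        assert count_temporal_peaks(gaussian_pair(1.0, 1.0, ratio, 1.0)) == n

    def test_concavity_transitions_once_near_two(self):
        ratios = np.arange(1.9, 2.1, 1e-3)
        labels = [classify_midpoint_concavity(r, 1.0) == "concave" for r in ratios]
        flips = np.flatnonzero(np.diff(np.asarray(labels, dtype=int)))
        assert flips.size == 1
        assert abs(ratios[flips[0]] - 2.0) <= 1e-3

    def test_unimodality_transitions_once_near_two(self):
        ratios = np.arange(1.99, 2.01, 1e-3)
        counts = [count_temporal_peaks(gaussian_pair(1.0, 1.0, r, 1.0)) for r in ratios]
        jumps = np.flatnonzero(np.diff(counts))
        assert jumps.size == 1
        assert abs(ratios[jumps[0]] - 2.0) <= 1e-3


class TestPatterns:
    def test_plane_centers_two_sigma_apart(self):
        pair = make_pattern("plane")
        gap = np.linalg.norm(np.subtract(pair.second.center_x, pair.first.center_x))
        sx = np.sqrt(np.asarray(pair.first.spatial_scale)[0, 0])
        assert gap == pytest.approx(2 * sx)
        assert np.allclose(pair.first.spatial_scale, pair.second.spatial_scale)

    def test_radial_cocentric_with_tighter_first(self):
        pair = make_pattern("radial")
        assert np.allclose(pair.first.center_x, pair.second.center_x)
        assert np.trace(np.asarray(pair.first.spatial_scale)) < np.trace(
            np.asarray(pair.second.spatial_scale)
        )

    def test_spiral_major_axes_orthogonal(self):
        pair = make_pattern("spiral_like")
        v1 = np.linalg.eigh(np.asarray(pair.first.spatial_scale))[1][:, -1]
        v2 = np.linalg.eigh(np.asarray(pair.second.spatial_scale))[1][:, -1]
        assert abs(v1 @ v2) < 1e-9

    def test_unknown_pattern_rejected(self):
        with pytest.raises(ValueError):
            make_pattern("vortex")

    def test_plane_and_radial_latency_maps_look_like_waves(self):
        for kind in ("plane", "radial"):
            _, _, pldc = pattern_latency_map(kind)
            assert pldc > 0.9


class TestPldcScan:
    def test_overlapping_sources_high_pldc(self):
        grid = pldc_scan([0.5], [1.0])
        assert grid[0, 0] > 0.9

    def test_simultaneous_activation_undefined(self):
        # dt = 0: every position peaks at t = tbar, zero latency variance
        grid = pldc_scan([0.5], [0.0])
        assert np.isnan(grid[0, 0])

    def test_high_in_wlp_regime(self):
        grid = pldc_scan([0.5, 1.0, 1.5], [1.0])
        assert np.all(grid > 0.9)


class TestValidation:
    def test_source_invariants(self):
        with pytest.raises(ValueError):
            SpatioTemporalSource(center_x=0.0, spatial_scale=-1.0)
        with pytest.raises(ValueError):
            SpatioTemporalSource(center_x=0.0, spatial_scale=1.0, temporal_scale=0.0)
        with pytest.raises(ValueError):
            SpatioTemporalSource(
                center_x=np.zeros(2), spatial_scale=np.array([[1.0, 2.0], [2.0, 1.0]])
            )

    def test_grid_requires_increasing_coordinates(self):
        with pytest.raises(ValueError):
            FieldGrid(x=np.array([0.0, 0.0, 1.0]), t=np.array([0.0, 1.0]))

    def test_default_grid_spans_sources(self):
        pair = gaussian_pair(1.0)
        g = default_grid(pair)
        assert g.x[0] <= -4.0 and g.x[-1] >= 4.0
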