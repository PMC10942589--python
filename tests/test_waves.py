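"""Wave clustering, latency maps, PLDC, center paths and speed tests."""

import numpy as np
import pytest

from wlpkit.layout import ElectrodeLayout
from wlpkit.lfp import PhaseCrossing
from wlpkit.waves import (
    LatencyMap,
    Wave,
    cluster_crossings,
    compute_plm,
    compute_pldc,
    compute_wcp,
    estimate_speed,
    select_waves,
    shuffled_pldc,
)


def xing(ch, t, amp=1.0):
    return PhaseCrossing(channel=ch, time=t, amplitude=amp)


class TestClusterCrossings:
    def test_chained_crossings_form_one_wave(self, grid_3x1):
        crossings = [xing(0, 0.0), xing(1, 0.090), xing(2, 0.180)]
        waves = cluster_crossings(crossings, grid_3x1, window=0.100)
        assert len(waves) == 1
        assert waves[0].n_channels == 3

    def test_sparse_crossings_stay_singletons(self, grid_3x1):
        crossings = [xing(0, 0.0), xing(1, 0.150), xing(2, 0.300)]
        waves = cluster_crossings(crossings, grid_3x1, window=0.100)
        assert [w.n_channels for w in waves] == [1, 1, 1]

    def test_fully_connected_2x2(self, grid_2x2):
        crossings = [xing(ch, 0.01 * ch) for ch in range(4)]
        waves = cluster_crossings(crossings, grid_2x2, window=0.050)
        assert len(waves) == 1 and waves[0].n_channels == 4

    def test_partition_independent_of_input_order(self, grid_3x1):
        rng = np.random.default_rng(0)
        crossings = [xing(0, 0.0), xing(1, 0.09), xing(2, 0.18), xing(0, 0.5), xing(1, 0.56)]
        ref = cluster_crossings(crossings, grid_3x1, window=0.100)
        ref_sets = [frozenset((c.channel, c.time) for c in w.crossings) for w in ref]
        for _ in range(5):
            perm = [crossings[i] for i in rng.permutation(len(crossings))]
            got = cluster_crossings(perm, grid_3x1, window=0.100)
            got_sets = [frozenset((c.channel, c.time) for c in w.crossings) for w in got]
            assert sorted(ref_sets, key=sorted) == sorted(got_sets, key=sorted)

    def test_waves_sorted_by_start_time(self, grid_3x1):
        crossings = [xing(2, 1.0), xing(0, 0.0)]
        waves = cluster_crossings(crossings, grid_3x1, window=0.100)
        assert waves[0].start_time == 0.0

    def test_wave_summary_fields(self):
        w = Wave(crossings=[xing(0, 1.0), xing(1, 2.0)], window=0.1)
        assert w.middle_time == 1.5 and w.width == 1.0
        assert w.spike_window() == (0.5, 2.5)
        assert w.start_channel == 0


class TestSelectWaves:
    def test_fraction_rule(self):
        lay = ElectrodeLayout(12, 10)
        big = Wave(crossings=[xing(ch, 0.001 * ch) for ch in range(80)], window=0.1)
        assert select_waves([big], lay, "fraction", 2 / 3) == [big]
        small = Wave(crossings=[xing(ch, 0.001 * ch) for ch in range(79)], window=0.1)
        assert select_waves([small], lay, "fraction", 2 / 3) == []

    def test_count_rule_strictly_greater(self):
        lay = ElectrodeLayout(12, 10)
        w31 = Wave(crossings=[xing(ch, 0.0) for ch in range(31)], window=0.1)
        w30 = Wave(crossings=[xing(ch, 0.0) for ch in range(30)], window=0.1)
        kept = select_waves([w31, w30], lay, "count", 30)
        assert kept == [w31]
        assert w31.criterion == "count:30"

    def test_empty_input(self):
        assert select_waves([], ElectrodeLayout(2, 2), "fraction", 2 / 3) == []


class TestLatencyMap:
    def test_first_crossing_per_channel_used(self, grid_3x1):
        w = Wave(crossings=[xing(0, 0.0), xing(1, 0.05), xing(1, 0.09)], window=0.1)
        plm = compute_plm(w, grid_3x1)
        assert plm.latencies[1] == 0.05

    def test_singleton_wave(self, grid_3x1):
        w = Wave(crossings=[xing(2, 0.3)], window=0.1)
        plm = compute_plm(w, grid_3x1)
        assert plm.latencies == {2: 0.3}
        assert np.allclose(plm.start_position, grid_3x1.positions[2])

    def test_start_tie_broken_by_lowest_channel(self, grid_3x1):
        w = Wave(crossings=[xing(2, 0.0), xing(1, 0.0)], window=0.1)
        assert compute_plm(w, grid_3x1).start_channel == 1


class TestPldc:
    def _linear_map(self, lay, slope):
        lat = {ch: 0.1 + slope * lay.positions[ch, 0] for ch in range(lay.n_channels)}
        return LatencyMap(latencies=lat, start_channel=0, start_position=lay.positions[0])

    def test_perfect_gradient_gives_unity(self):
        lay = ElectrodeLayout(1, 10)
        pldc, reason = compute_pldc(self._linear_map(lay, 2.0), lay)
        assert pldc == pytest.approx(1.0) and reason is None

    def test_latency_decreasing_with_distance_gives_minus_one(self):
        lay = ElectrodeLayout(1, 10)
        lat = {ch: 1.0 - 0.05 * ch for ch in range(10)}
        plm = LatencyMap(latencies=lat, start_channel=0, start_position=lay.positions[0])
        pldc, _ = compute_pldc(plm, lay)
        assert pldc == pytest.approx(-1.0)

    def test_affine_invariance(self):
        lay = ElectrodeLayout(1, 12)
        base = self._linear_map(lay, 2.0)
        jitter = np.random.default_rng(3).normal(0, 0.1, 12)
        lat = {ch: base.latencies[ch] + jitter[ch] for ch in range(12)}
        p1, _ = compute_pldc(LatencyMap(lat, 0, lay.positions[0]), lay)
        lat2 = {ch: 5.0 + 3.0 * v for ch, v in lat.items()}
        p2, _ = compute_pldc(LatencyMap(lat2, 0, lay.positions[0]), lay)
        assert p1 == pytest.approx(p2, rel=1e-12)

    def test_shuffled_latencies_center_on_zero(self):
        lay = ElectrodeLayout(10, 12)
        plm = self._linear_map(lay, 2.0)
        null = shuffled_pldc(plm, lay, n_permutations=1000, seed=0)
        assert abs(np.nanmean(null)) < 0.05

    def test_degenerate_inputs_reported_missing(self):
        lay = ElectrodeLayout(1, 5)
        flat = LatencyMap({ch: 1.0 for ch in range(5)}, 0, lay.positions[0])
        pldc, reason = compute_pldc(flat, lay)
        assert np.isnan(pldc) and "latency" in reason
        tiny = LatencyMap({0: 0.0, 1: 0.1}, 0, lay.positions[0])
        pldc, reason = compute_pldc(tiny, lay)
        assert np.isnan(pldc) and "3 channels" in reason


class TestWaveCenterPath:
    def test_single_channel_path_constant(self, grid_3x1):
        w = Wave(crossings=[xing(1, 0.0), xing(1, 0.2)], window=0.3)
        wcp = compute_wcp(w, grid_3x1, n_samples=11)
        assert np.allclose(wcp.positions, grid_3x1.positions[1])

    def test_symmetric_crossings_midpoint_halfway(self, grid_3x1):
        w = Wave(crossings=[xing(0, 0.0), xing(2, 0.2)], window=0.3)
        wcp = compute_wcp(w, grid_3x1, n_samples=21)
        mid = wcp.positions[10]
        assert np.allclose(mid, grid_3x1.positions[1], atol=1e-9)

    def test_matches_direct_formula_on_five_crossing_toy(self):
        lay = ElectrodeLayout(1, 5)
        crossings = [
            xing(0, 0.00, 1.0),
            xing(1, 0.05, 2.0),
            xing(2, 0.12, 1.5),
            xing(3, 0.21, 0.7),
            xing(4, 0.30, 1.2),
        ]
        w = Wave(crossings=crossings, window=0.1)
        n = 61
        wcp = compute_wcp(w, lay, n_samples=n)
        times = np.array([c.time for c in crossings])
        amps = np.array([c.amplitude for c in crossings])
        pos = lay.positions[[c.channel for c in crossings]]
        dt_bar = np.diff(np.sort(times)).mean()
        t_samples = np.linspace(0.0, 0.30, n)
        half = n / 2.0
        for i, t in enumerate(t_samples):
            sigma = (
                2 * dt_bar + (8 * dt_bar / half) * i
                if i < half
                else 10 * dt_bar - (8 * dt_bar / half) * (i - half)
            )
            wgt = amps * np.exp(-((t - times) ** 2) / (2 * sigma**2))
            expected = (pos * wgt[:, None]).sum(axis=0) / wgt.sum()
            assert np.allclose(wcp.positions[i], expected, atol=1e-12)

    def test_endpoints_anchor_to_first_and_last_crossing(self):
        lay = ElectrodeLayout(1, 5)
        w = Wave(
            crossings=[xing(ch, 0.1 * ch) for ch in range(5)], window=0.15
        )
        wcp = compute_wcp(w, lay, n_samples=101)
        # the narrow sigma at the ends keeps the endpoints less biased toward
        # the wave center than the heavily smoothed midpoint
        start_x, end_x, centroid_x = lay.positions[0, 0], lay.positions[4, 0], lay.positions[2, 0]
        mid = wcp.positions[50, 0]
        assert abs(wcp.positions[0, 0] - start_x) < abs(mid - start_x)
        assert abs(wcp.positions[-1, 0] - end_x) < abs(mid - end_x)
        assert abs(mid - centroid_x) < 0.5 * lay.pitch


class TestSpeed:
    def test_uniform_motion_recovered(self):
        wcp_times = np.linspace(0.0, 0.25, 26)
        pos = np.column_stack([np.linspace(0, 0.5, 26), np.zeros(26)])
        from wlpkit.waves import WaveCenterPath

        wcp = WaveCenterPath(times=wcp_times, positions=pos, sigma=np.ones(26))
        assert estimate_speed(wcp) == pytest.approx(2.0, rel=1e-9)

    def test_constant_path_zero_speed(self):
        from wlpkit.waves import WaveCenterPath

        wcp = WaveCenterPath(
            times=np.linspace(0, 1, 10), positions=np.tile([0.3, 0.3], (10, 1)), sigma=np.ones(10)
        )
        assert estimate_speed(wcp) == pytest.approx(0.0, abs=1e-12)

    def test_two_module_recording_speed_near_gap_over_delay(self):
        """With mild conduction smearing the apparent speed approaches
        (module gap)/(activation delay)."""
        from wlpkit.lfp import FilterSpec, detect_recording_crossings, estimate_noise_threshold
        from wlpkit.simulate import generate_trials, two_module_config
        from wlpkit.waves import cluster_crossings, select_waves

        cfg = two_module_config(conduction_sigma=0.15, onset_jitter_sd=0.01)
        trials = generate_trials(cfg, 4, seed=4)
        thr = estimate_noise_threshold(trials, FilterSpec(), seed=0)
        speeds = []
        for rec in trials:
            crossings = detect_recording_crossings(rec, FilterSpec(), threshold=thr)
            sel = select_waves(
                cluster_crossings(crossings, rec.layout, 0.100), rec.layout, "fraction", 2 / 3
            )
            for w in sel[:1]:
                speeds.append(estimate_speed(compute_wcp(w, rec.layout, sample_rate=rec.sample_rate)))
        expected = 0.5 / 0.28
        assert speeds, "no large wave detected"
        assert np.median(speeds) == pytest.approx(expected, rel=0.25)
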