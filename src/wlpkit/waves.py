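"""Grouping phase crossings into waves; latency maps, PLDC, center paths, speed.

A "wave" is a spatiotemporally connected set of phase crossings: crossings
on the same or rook-adjacent channels whose times differ by at most a
band-specific window (100 ms for the 0-2 Hz band, 2 ms for 12-35 Hz) are
linked, and waves are the connected components of that graph, seeded in
time order.  Components are canonical, so the partition is independent of
visit order.

From a wave we derive the phase latency map (first crossing per channel),
the phase-latency/distance correlation (PLDC, the conventional
traveling-wave statistic), the amplitude-weighted wave center path (WCP)
with its widening-then-narrowing temporal kernel, and a speed estimate
from the center path.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.stats import pearsonr

from .layout import ElectrodeLayout
from .lfp import PhaseCrossing

__all__ = [
    "Wave",
    "LatencyMap",
    "WaveCenterPath",
    "BAND_WINDOWS",
    "cluster_crossings",
    "select_waves",
    "compute_plm",
    "compute_pldc",
    "shuffled_pldc",
    "compute_wcp",
    "estimate_speed",
]

# clustering window (s) by analysis band (Hz)
BAND_WINDOWS = {(0.0, 2.0): 0.100, (12.0, 35.0): 0.002}


@dataclass
class Wave:
    """A connected cluster of phase crossings."""

    crossings: list[PhaseCrossing]
    window: float
    criterion: str | None = None  # set by select_waves

    def __post_init__(self) -> None:
        if not self.crossings:
            raise ValueError("a wave needs at least one crossing")
        self.crossings = sorted(self.crossings, key=lambda c: (c.time, c.channel))

    @property
    def times(self) -> np.ndarray:
        return np.array([c.time for c in self.crossings])

    @property
    def channels(self) -> np.ndarray:
        return np.array([c.channel for c in self.crossings])

    @property
    def start_time(self) -> float:
        return self.crossings[0].time

    @property
    def end_time(self) -> float:
        return self.crossings[-1].time

    @property
    def start_channel(self) -> int:
        first = self.start_time
        cands = [c.channel for c in self.crossings if c.time == first]
        return min(cands)

    @property
    def middle_time(self) -> float:
        """T = midpoint between first and last crossing."""
        return 0.5 * (self.start_time + self.end_time)

    @property
    def width(self) -> float:
        """W = last - first crossing time."""
        return self.end_time - self.start_time

    @property
    def n_channels(self) -> int:
        return len(set(c.channel for c in self.crossings))

    def recruitment_fraction(self, layout: ElectrodeLayout) -> float:
        return self.n_channels / layout.n_channels

    def first_crossings(self) -> dict[int, PhaseCrossing]:
        """Earliest crossing per recruited channel."""
        out: dict[int, PhaseCrossing] = {}
        for c in self.crossings:  # already time-sorted
            out.setdefault(c.channel, c)
        return out

    def spike_window(self) -> tuple[float, float]:
        """[T - W, T + W]: the interval used for first-spike extraction."""
        return self.middle_time - self.width, self.middle_time + self.width


@dataclass
class LatencyMap:
    """Per-channel phase latency with the wave's start point."""

    latencies: dict[int, float]
    start_channel: int
    start_position: np.ndarray


@dataclass
class WaveCenterPath:
    """Amplitude/time-weighted center-of-mass trajectory of a wave."""

    times: np.ndarray
    positions: np.ndarray  # (n, 2), mm
    sigma: np.ndarray  # the sigma(t) schedule used, s


def cluster_crossings(
    crossings: Sequence[PhaseCrossing],
    layout: ElectrodeLayout,
    window: float = 0.100,
) -> list[Wave]:
    """Partition crossings into waves by spatiotemporal flood fill.

    Two crossings are linked when their channels are identical or rook
    neighbors and their times differ by at most ``window``.  Waves are the
    connected components, returned in start-time order.
    """
    if window <= 0:
        raise ValueError("window must be positive")
    n = len(crossings)
    if n == 0:
        return []
    order = sorted(range(n), key=lambda i: (crossings[i].time, crossings[i].channel))
    parent = list(range(n))

    def find(i: int) -> int:
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    def union(i: int, j: int) -> None:
        ri, rj = find(i), find(j)
        if ri != rj:
            parent[rj] = ri

    # per-channel time-sorted index lists for neighbor lookups
    by_channel: dict[int, list[int]] = {}
    for i in order:
        by_channel.setdefault(crossings[i].channel, []).append(i)

    for i in order:
        ci = crossings[i]
        for ch in [ci.channel, *layout.neighbors(ci.channel)]:
            for j in by_channel.get(ch, ()):
                if j != i and abs(crossings[j].time - ci.time) <= window:
                    union(i, j)

    groups: dict[int, list[PhaseCrossing]] = {}
    for i in range(n):
        groups.setdefault(find(i), []).append(crossings[i])
    waves = [Wave(crossings=g, window=window) for g in groups.values()]
    return sorted(waves, key=lambda w: (w.start_time, w.start_channel))


def select_waves(
    waves: Sequence[Wave],
    layout: ElectrodeLayout,
    criterion: str = "fraction",
    value: float = 2.0 / 3.0,
) -> list[Wave]:
    """Keep waves meeting a recruitment criterion.

    ``criterion="fraction"`` keeps waves recruiting at least ``value`` of
    the array's channels (2/3 for the 0-2 Hz band, 5/6 for 12-35 Hz);
    ``criterion="count"`` keeps waves recruiting strictly more than
    ``value`` channels (the first-spike analysis uses > 30).
    """
    if criterion not in ("fraction", "count"):
        raise ValueError(f"unknown criterion {criterion!r}")
    out = []
    for w in waves:
        if criterion == "fraction":
            keep = w.recruitment_fraction(layout) >= value
        else:
            keep = w.n_channels > value
        if keep:
            w.criterion = f"{criterion}:{value:g}"
            out.append(w)
    return out


def compute_plm(wave: Wave, layout: ElectrodeLayout) -> LatencyMap:
    """Phase latency map: first crossing per channel; start = earliest crossing."""
    firsts = wave.first_crossings()
    lat = {ch: c.time for ch, c in firsts.items()}
    start = wave.start_channel
    return LatencyMap(
        latencies=lat, start_channel=start, start_position=layout.positions[start]
    )


def compute_pldc(
    plm: LatencyMap, layout: ElectrodeLayout
) -> tuple[float, str | None]:
    """Pearson correlation of latency with distance from the wave start point.

    Returns (pldc, reason): pldc is NaN with an explanatory reason when the
    correlation is undefined (fewer than 3 channels, or zero variance in
    either vector); reason is None for a valid value.
    """
    chans = sorted(plm.latencies)
    if len(chans) < 3:
        return float("nan"), "fewer than 3 channels"
    lat = np.array([plm.latencies[c] for c in chans])
    dist = layout.distances_from(plm.start_position)[chans]
    if np.ptp(lat) == 0:
        return float("nan"), "zero latency variance"
    if np.ptp(dist) == 0:
        return float("nan"), "zero distance variance"
    return float(pearsonr(dist, lat)[0]), None


def shuffled_pldc(
    plm: LatencyMap,
    layout: ElectrodeLayout,
    n_permutations: int = 1000,
    seed: int = 0,
) -> np.ndarray:
    """Null PLDC distribution from channel-permuted latencies."""
    chans = sorted(plm.latencies)
    lat = np.array([plm.latencies[c] for c in chans])
    dist = layout.distances_from(plm.start_position)[chans]
    rng = np.random.default_rng(seed)
    out = np.empty(n_permutations)
    for k in range(n_permutations):
        perm = rng.permutation(lat)
        out[k] = pearsonr(dist, perm)[0] if np.ptp(perm) > 0 else np.nan
    return out


def _sigma_schedule(n_samples: int, mean_dt: float) -> np.ndarray:
    """sigma(t) ramp: 2 dTbar at the ends, 10 dTbar at the wave midpoint."""
    i = np.arange(n_samples, dtype=float)
    half = n_samples / 2.0
    sig = np.where(
        i < half,
        2.0 * mean_dt + (8.0 * mean_dt / half) * i,
        10.0 * mean_dt - (8.0 * mean_dt / half) * (i - half),
    )
    return sig


def compute_wcp(
    wave: Wave,
    layout: ElectrodeLayout,
    sample_rate: float | None = None,
    n_samples: int | None = None,
) -> WaveCenterPath:
    """Amplitude- and time-weighted center-of-mass trajectory.

    At each time sample t between the first and last crossing,

        X_cm(t) = sum_i X_i A_i exp(-(t - t_i)^2 / 2 sigma(t)^2)
                  / sum_i A_i exp(-(t - t_i)^2 / 2 sigma(t)^2)

    over all wave crossings (X_i electrode position, A_i envelope
    amplitude, t_i crossing time).  sigma(t) ramps linearly from 2 dTbar at
    the first sample to 10 dTbar at the midpoint and back, where dTbar is
    the mean difference between consecutive sorted crossing times; the
    narrow ends keep the path anchored to the earliest/latest crossings.
    """
    times = wave.times
    chans = wave.channels
    amps = np.array([c.amplitude for c in wave.crossings])
    pos = layout.positions[chans]

    if n_samples is None:
        if sample_rate is not None and wave.width > 0:
            n_samples = max(int(round(wave.width * sample_rate)) + 1, 2)
        else:
            n_samples = 100 if wave.width > 0 else 1
    t_samples = (
        np.linspace(wave.start_time, wave.end_time, n_samples)
        if n_samples > 1
        else np.array([wave.start_time])
    )

    diffs = np.diff(np.sort(times))
    mean_dt = float(diffs.mean()) if diffs.size else 0.0
    if mean_dt <= 0:
        # all crossings simultaneous (or a single crossing): uniform weights
        sig = np.full(len(t_samples), np.inf)
    else:
        sig = _sigma_schedule(len(t_samples), mean_dt)

    out = np.empty((len(t_samples), 2))
    for k, t in enumerate(t_samples):
        if np.isinf(sig[k]):
            w = amps.copy()
        else:
            w = amps * np.exp(-0.5 * ((t - times) / sig[k]) ** 2)
        total = w.sum()
        if total == 0:
            w = amps
            total = w.sum()
        out[k] = (pos * w[:, None]).sum(axis=0) / total
    return WaveCenterPath(times=t_samples, positions=out, sigma=sig)


def estimate_speed(wcp: WaveCenterPath) -> float:
    """Speed (mm/s): least-squares slope of the path along its principal axis.

    The path positions are projected onto the principal displacement axis
    (first PCA component) and regressed against time; the speed is the
    absolute slope.  A path that never moves has speed 0.
    """
    if len(wcp.times) < 2:
        return 0.0
    pos = wcp.positions - wcp.positions.mean(axis=0)
    if not np.any(pos):
        return 0.0
    _, _, vt = np.linalg.svd(pos, full_matrices=False)
    proj = pos @ vt[0]
    t = wcp.times - wcp.times.mean()
    denom = float(t @ t)
    if denom == 0:
        return 0.0
    return float(abs(proj @ t) / denom)
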