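"""Channel-level spiking excitability: first spikes, ALSA, and phase locking.

ALSA (average local spiking activity) is a robust local excitability
estimate: each channel's spike train is rate-smoothed (100 ms boxcar, then
a 100 ms-sigma Gaussian) and averaged with its rook neighbors at half
weight,

    ALSA_i = (S_i + sum_{j in nn(i)} S_j / 2) / (1 + sum_{j in nn(i)} 1/2).

Onsets are either first spikes inside a wave's [T - W, T + W] interval or
the first local maximum of a channel's ALSA around the wave.  Spike trains
arrive already assigned to channels; for real data the upstream contract
is assignment to the channel of maximal average spike amplitude.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.ndimage import gaussian_filter1d, uniform_filter1d

from .layout import ElectrodeLayout
from .lfp import AnalyticTrace
from .waves import Wave

__all__ = [
    "SpikeTrainSet",
    "AlsaMatrix",
    "OnsetSet",
    "PhaseLocking",
    "first_spikes_in_wave",
    "compute_alsa",
    "alsa_onsets",
    "phase_locking",
]


@dataclass
class SpikeTrainSet:
    """Per-channel sorted spike times (s)."""

    trains: list[np.ndarray]
    provenance: str = "synthetic ground truth"

    def __post_init__(self) -> None:
        self.trains = [np.sort(np.asarray(tr, dtype=float)) for tr in self.trains]

    @property
    def n_channels(self) -> int:
        return len(self.trains)


@dataclass
class AlsaMatrix:
    """Smoothed neighbor-weighted local spiking activity (spikes/s)."""

    rates: np.ndarray  # (n_channels, n_samples)
    sample_rate: float
    boxcar_s: float
    gaussian_sigma_s: float

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.rates.shape[1]) / self.sample_rate


@dataclass
class OnsetSet:
    """Per-channel onset times inside a stated window."""

    onsets: dict[int, float]
    window: tuple[float, float]
    kind: str  # "first_spike" or "alsa"

    @property
    def channels(self) -> list[int]:
        return sorted(self.onsets)

    @property
    def times(self) -> np.ndarray:
        return np.array([self.onsets[c] for c in self.channels])


@dataclass
class PhaseLocking:
    """Circular histogram of spike phases with summary statistics."""

    phases: np.ndarray
    bin_edges: np.ndarray
    counts: np.ndarray
    modal_phase: float
    circular_mean: float
    resultant_length: float


def first_spikes_in_wave(spikes: SpikeTrainSet, wave: Wave) -> OnsetSet:
    """Earliest spike per channel inside the wave's [T - W, T + W] interval.

    Channels without a spike in the interval are excluded; downstream
    paired comparisons restrict the LFP sample to the same channels.
    """
    lo, hi = wave.spike_window()
    onsets: dict[int, float] = {}
    for ch, train in enumerate(spikes.trains):
        inside = train[(train >= lo) & (train <= hi)]
        if inside.size:
            onsets[ch] = float(inside[0])
    return OnsetSet(onsets=onsets, window=(lo, hi), kind="first_spike")


def compute_alsa(
    spikes: SpikeTrainSet,
    layout: ElectrodeLayout,
    duration: float,
    sample_rate: float = 1000.0,
    boxcar_s: float = 0.100,
    gaussian_sigma_s: float = 0.100,
) -> AlsaMatrix:
    """Boxcar + Gaussian smoothed rates, neighbor-averaged at half weight."""
    n = int(round(duration * sample_rate))
    smoothed = np.zeros((layout.n_channels, n))
    box_len = max(int(round(boxcar_s * sample_rate)), 1)
    for ch, train in enumerate(spikes.trains):
        if train.size == 0:
            continue
        idx = np.clip((train * sample_rate).astype(int), 0, n - 1)
        counts = np.bincount(idx, minlength=n).astype(float)
        # boxcar mean count per sample x sample_rate -> rate in spikes/s
        rate = uniform_filter1d(counts, box_len) * sample_rate
        smoothed[ch] = gaussian_filter1d(rate, gaussian_sigma_s * sample_rate)

    alsa = np.empty_like(smoothed)
    for ch in range(layout.n_channels):
        nn = layout.neighbors(ch)
        acc = smoothed[ch] + 0.5 * smoothed[nn].sum(axis=0)
        alsa[ch] = acc / (1.0 + 0.5 * len(nn))
    return AlsaMatrix(
        rates=alsa,
        sample_rate=sample_rate,
        boxcar_s=boxcar_s,
        gaussian_sigma_s=gaussian_sigma_s,
    )


def _first_local_max(trace: np.ndarray) -> int | None:
    """Index of the first strict local maximum (plateaus: first plateau sample)."""
    n = trace.size
    i = 1
    while i < n - 1:
        if trace[i] > trace[i - 1]:
            j = i
            while j + 1 < n and trace[j + 1] == trace[j]:
                j += 1
            if j + 1 < n and trace[j + 1] < trace[j]:
                return i
            i = j + 1
        else:
            i += 1
    return None


def alsa_onsets(alsa: AlsaMatrix, wave: Wave) -> OnsetSet:
    """First ALSA local maximum per channel within [start - W/2, end + W/2].

    Channels whose ALSA is identically zero in the window, or whose first
    maximum falls outside it, are excluded.
    """
    half = wave.width / 2.0
    lo = wave.start_time - half
    hi = wave.end_time + half
    i0 = max(int(np.floor(lo * alsa.sample_rate)), 0)
    i1 = min(int(np.ceil(hi * alsa.sample_rate)) + 1, alsa.rates.shape[1])
    onsets: dict[int, float] = {}
    for ch in range(alsa.rates.shape[0]):
        seg = alsa.rates[ch, i0:i1]
        if seg.size < 3 or not np.any(seg > 0):
            continue
        idx = _first_local_max(seg)
        if idx is not None and seg[idx] > 0:
            onsets[ch] = (i0 + idx) / alsa.sample_rate
    return OnsetSet(onsets=onsets, window=(lo, hi), kind="alsa")


def phase_locking(
    spikes: SpikeTrainSet,
    traces: Sequence[AnalyticTrace],
    n_bins: int = 36,
) -> PhaseLocking:
    """Pool LFP phases at spike times; report histogram, mode, circular mean."""
    phases = []
    for ch, train in enumerate(spikes.trains):
        if train.size == 0 or ch >= len(traces) or traces[ch].undefined:
            continue
        tr = traces[ch]
        t_axis = np.arange(len(tr.phase)) / tr.sample_rate
        unwrapped = np.unwrap(tr.phase)
        ph = np.interp(train, t_axis, unwrapped)
        phases.append(np.angle(np.exp(1j * ph)))
    pooled = np.concatenate(phases) if phases else np.empty(0)
    edges = np.linspace(-np.pi, np.pi, n_bins + 1)
    counts, _ = np.histogram(pooled, bins=edges)
    if pooled.size:
        centers = 0.5 * (edges[:-1] + edges[1:])
        modal = float(centers[int(np.argmax(counts))])
        z = np.mean(np.exp(1j * pooled))
        cmean, rlen = float(np.angle(z)), float(np.abs(z))
    else:
        modal = cmean = rlen = float("nan")
    return PhaseLocking(
        phases=pooled,
        bin_edges=edges,
        counts=counts,
        modal_phase=modal,
        circular_mean=cmean,
        resultant_length=rlen,
    )
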