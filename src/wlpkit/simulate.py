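"""Ground-truthed synthetic MEA recordings: modular excitability, smeared LFP.

The generator emulates visually evoked ex vivo cortical recordings on a
100 um-pitch electrode grid.  Its microscale model follows the modular-
activation premise directly:

* every electrode site hosts a local current source — a Hann-windowed
  ~1 Hz sine burst (1.5 cycles, so the trace starts and ends at zero);
* sources are grouped into spatially contiguous *modules* that activate
  sequentially: all sources of a module start at stimulus + response
  latency + module delay, plus a small per-channel onset jitter
  (biological onset variability, 20 ms by default);
* the measured LFP at a channel is the volume-conducted mixture of all
  sources — a spatial Gaussian kernel of scale ``conduction_sigma``
  (0.4 mm by default, the few-hundred-micrometer decay of extracellular
  potentials) — plus pink (1/f) noise, whose power sits in the slow band
  like real LFP baseline fluctuations;
* spikes are an inhomogeneous Poisson process driven by the channel's OWN
  source phase through a von Mises tuning curve (preferred phase 0.53 pi),
  gated to the source's active window.

The result reproduces the phenomenon this package analyses: LFP phase
latencies grade smoothly across the array (wave-like), while spiking
stays segregated into sequentially activated modules.  Everything is
bit-reproducible from one master seed via fixed-key per-trial/per-channel
substreams.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
from scipy.signal import hilbert

from .layout import ElectrodeLayout

__all__ = [
    "ModuleSpec",
    "SpikeModel",
    "RecordingConfig",
    "Recording",
    "generate_recording",
    "generate_trials",
    "noiseless_lfp",
    "two_module_config",
    "single_module_config",
]

PREFERRED_PHASE = 0.53 * np.pi  # peak spiking phase of the evoked LFP cycle


@dataclass(frozen=True)
class ModuleSpec:
    """One sequentially activated module of local sources.

    Parameters
    ----------
    channels:
        Spatially contiguous member channel indices (each hosts a source).
    delay:
        Activation delay (s) relative to stimulus + response latency.
    frequency:
        Oscillation frequency of the evoked burst, Hz.
    amplitude:
        Peak source amplitude, uV.
    n_cycles:
        Burst length in cycles (Hann-windowed; 1.5 keeps both ends at zero).
    """

    channels: tuple[int, ...]
    delay: float = 0.0
    frequency: float = 1.0
    amplitude: float = 100.0
    n_cycles: float = 1.5

    def __post_init__(self) -> None:
        if len(self.channels) == 0:
            raise ValueError("ModuleSpec.channels must be non-empty")
        if self.delay < 0:
            raise ValueError("ModuleSpec.delay must be >= 0")
        if self.frequency <= 0:
            raise ValueError("ModuleSpec.frequency must be positive")
        if self.n_cycles <= 0:
            raise ValueError("ModuleSpec.n_cycles must be positive")

    @property
    def burst_length(self) -> float:
        return self.n_cycles / self.frequency

    def centroid(self, layout: ElectrodeLayout) -> np.ndarray:
        return layout.positions[list(self.channels)].mean(axis=0)


@dataclass(frozen=True)
class SpikeModel:
    """Phase-locked inhomogeneous-Poisson spiking parameters."""

    baseline_rate: float = 0.2  # Hz inside the active window (sparse spontaneous)
    peak_rate: float = 20.0  # Hz at the preferred phase
    preferred_phase: float = PREFERRED_PHASE  # radians
    kappa: float = 4.0  # von Mises concentration

    def __post_init__(self) -> None:
        if self.baseline_rate < 0:
            raise ValueError("SpikeModel.baseline_rate must be >= 0")
        if self.peak_rate < self.baseline_rate:
            raise ValueError("SpikeModel.peak_rate must be >= baseline_rate")
        if self.kappa < 0:
            raise ValueError("SpikeModel.kappa must be >= 0")

    def rate(self, phase: np.ndarray) -> np.ndarray:
        """Instantaneous rate (Hz) as a function of source phase (radians)."""
        vm = np.exp(self.kappa * (np.cos(phase - self.preferred_phase) - 1.0))
        return self.baseline_rate + (self.peak_rate - self.baseline_rate) * vm


@dataclass(frozen=True)
class RecordingConfig:
    """Full study configuration for one synthetic trial family."""

    layout: ElectrodeLayout
    modules: tuple[ModuleSpec, ...]
    sample_rate: float = 1000.0  # Hz
    duration: float = 5.0  # s
    stim_time: float = 1.0  # s
    response_latency: float = 0.2  # s post-stimulus
    conduction_sigma: float = 0.4  # mm, volume-conduction kernel scale
    onset_jitter_sd: float = 0.02  # s, per-channel source onset variability
    noise_sd: float = 10.0  # uV
    noise_kind: str = "pink"  # "pink" (1/f) or "white"
    spike_model: SpikeModel = field(default_factory=SpikeModel)

    def __post_init__(self) -> None:
        if self.sample_rate <= 0:
            raise ValueError("RecordingConfig.sample_rate must be positive")
        fmax = max(m.frequency for m in self.modules) if self.modules else 0.0
        if self.modules and self.sample_rate < 4 * fmax:
            raise ValueError("RecordingConfig.sample_rate must be >= 4x module frequency")
        if self.duration <= 0:
            raise ValueError("RecordingConfig.duration must be positive")
        if not 0 <= self.stim_time < self.duration:
            raise ValueError("RecordingConfig.stim_time must lie within the trial")
        if self.response_latency < 0:
            raise ValueError("RecordingConfig.response_latency must be >= 0")
        if self.conduction_sigma <= 0:
            raise ValueError("RecordingConfig.conduction_sigma must be positive")
        if self.onset_jitter_sd < 0:
            raise ValueError("RecordingConfig.onset_jitter_sd must be >= 0")
        if self.noise_sd < 0:
            raise ValueError("RecordingConfig.noise_sd must be >= 0")
        if self.noise_kind not in ("pink", "white"):
            raise ValueError("RecordingConfig.noise_kind must be 'pink' or 'white'")
        n = self.layout.n_channels
        for k, m in enumerate(self.modules):
            if min(m.channels) < 0 or max(m.channels) >= n:
                raise ValueError(f"RecordingConfig.modules[{k}].channels out of range")
        end = self.stim_time + self.response_latency + max(
            (m.delay + m.burst_length for m in self.modules), default=0.0
        )
        if end > self.duration:
            raise ValueError("RecordingConfig.duration does not cover the response")

    @property
    def n_samples(self) -> int:
        return int(round(self.duration * self.sample_rate))

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.n_samples) / self.sample_rate

    def module_onset(self, k: int) -> float:
        return self.stim_time + self.response_latency + self.modules[k].delay

    def module_labels(self) -> np.ndarray:
        """Per-channel module index; -1 for channels in no module."""
        labels = np.full(self.layout.n_channels, -1, dtype=int)
        for k, m in enumerate(self.modules):
            labels[list(m.channels)] = k
        return labels

    def conduction_kernel(self) -> np.ndarray:
        """Row-normalised channel x source volume-conduction mixing matrix."""
        pos = self.layout.positions
        d2 = ((pos[:, None, :] - pos[None, :, :]) ** 2).sum(-1)
        K = np.exp(-0.5 * d2 / self.conduction_sigma**2)
        return K / K.sum(axis=1, keepdims=True)


@dataclass
class Recording:
    """One synthetic trial: LFP, spikes, stimulus times and ground truth."""

    layout: ElectrodeLayout
    sample_rate: float
    lfp: np.ndarray  # (n_channels, n_samples), uV
    spikes: list[np.ndarray]  # per-channel sorted spike times, s
    stim_times: np.ndarray
    ground_truth: dict | None = None
    seed: int | None = None

    @property
    def duration(self) -> float:
        return self.lfp.shape[1] / self.sample_rate

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.lfp.shape[1]) / self.sample_rate


# ---------------------------------------------------------------------------
# generation
# ---------------------------------------------------------------------------

def _module_waveform(m: ModuleSpec, t: np.ndarray, onset: float) -> np.ndarray:
    """Hann-windowed sine burst starting at ``onset`` (zero elsewhere).

    The sine carrier starts at phase -pi/2 (trough-to-peak rise), so the
    analytic phase sweeps upward through +pi/2 half a cycle after onset.
    """
    tau = t - onset
    length = m.burst_length
    active = (tau >= 0) & (tau <= length)
    out = np.zeros_like(t)
    taua = tau[active]
    window = 0.5 * (1.0 - np.cos(2.0 * np.pi * taua / length))
    out[active] = m.amplitude * window * np.sin(2.0 * np.pi * m.frequency * taua)
    return out


def _channel_rng(master_seed: int, trial: int, stream: int, channel: int) -> np.random.Generator:
    # fixed-key substreams: adding channels or trials never perturbs others
    return np.random.default_rng(
        np.random.SeedSequence([int(master_seed), int(trial), int(stream), int(channel)])
    )


def _noise_trace(
    rng: np.random.Generator, n: int, sample_rate: float, sd: float, kind: str
) -> np.ndarray:
    if sd == 0:
        return np.zeros(n)
    w = rng.standard_normal(n)
    if kind == "white":
        return sd * w
    # pink: shape the spectrum by 1/sqrt(f) with a 0.1 Hz flattening floor
    spec = np.fft.rfft(w)
    f = np.fft.rfftfreq(n, 1.0 / sample_rate)
    shape = 1.0 / np.sqrt(np.maximum(f, 0.1))
    shape[0] = 0.0
    p = np.fft.irfft(spec * shape, n)
    return p * (sd / p.std())


def _source_onsets(config: RecordingConfig, seed: int, trial: int) -> np.ndarray:
    """Per-channel source onset (NaN for channels outside every module)."""
    onsets = np.full(config.layout.n_channels, np.nan)
    for k, m in enumerate(config.modules):
        base = config.module_onset(k)
        for ch in m.channels:
            rng = _channel_rng(seed, trial, 2, ch)
            onsets[ch] = base + rng.normal(0.0, config.onset_jitter_sd)
    return onsets


def _source_matrix(config: RecordingConfig, onsets: np.ndarray) -> np.ndarray:
    t = config.times
    labels = config.module_labels()
    src = np.zeros((config.layout.n_channels, t.size))
    for ch in range(config.layout.n_channels):
        k = labels[ch]
        if k >= 0:
            src[ch] = _module_waveform(config.modules[k], t, onsets[ch])
    return src


def noiseless_lfp(config: RecordingConfig) -> np.ndarray:
    """(n_channels, n_samples) noise- and jitter-free LFP template."""
    cfg = replace(config, onset_jitter_sd=0.0)
    onsets = _source_onsets(cfg, seed=0, trial=0)
    return cfg.conduction_kernel() @ _source_matrix(cfg, onsets)


def generate_recording(config: RecordingConfig, seed: int = 0, _trial: int = 0) -> Recording:
    """Draw one trial.  Identical (config, seed) pairs are bit-identical."""
    t = config.times
    onsets = _source_onsets(config, seed, _trial)
    src = _source_matrix(config, onsets)
    lfp = config.conduction_kernel() @ src

    labels = config.module_labels()
    sm = config.spike_model
    spikes: list[np.ndarray] = []
    for ch in range(config.layout.n_channels):
        k = labels[ch]
        if k < 0:
            spikes.append(np.empty(0))
            continue
        phase = np.angle(hilbert(src[ch]))
        rate = sm.rate(phase)
        w0, w1 = onsets[ch], onsets[ch] + config.modules[k].burst_length
        rate[(t < w0) | (t > w1)] = 0.0
        rng = _channel_rng(seed, _trial, 1, ch)
        spikes.append(_draw_inhomogeneous_poisson(rate, t, rng))

    for ch in range(config.layout.n_channels):
        rng = _channel_rng(seed, _trial, 0, ch)
        lfp[ch] += _noise_trace(rng, t.size, config.sample_rate, config.noise_sd, config.noise_kind)

    gt = {
        "module_labels": labels,
        "module_onsets": np.array([config.module_onset(k) for k in range(len(config.modules))]),
        "source_onsets": onsets,
        "inter_module_delays": np.array([m.delay for m in config.modules]),
        "preferred_phase": sm.preferred_phase,
        "kappa": sm.kappa,
        "peak_rate": sm.peak_rate,
        "baseline_rate": sm.baseline_rate,
        "noise_sd": config.noise_sd,
        "conduction_sigma": config.conduction_sigma,
    }
    return Recording(
        layout=config.layout,
        sample_rate=config.sample_rate,
        lfp=lfp,
        spikes=spikes,
        stim_times=np.array([config.stim_time]),
        ground_truth=gt,
        seed=seed,
    )


def _draw_inhomogeneous_poisson(
    rate: np.ndarray, t: np.ndarray, rng: np.random.Generator
) -> np.ndarray:
    """Thinning: homogeneous candidates at the max rate, accepted by rate ratio."""
    rmax = float(rate.max())
    if rmax <= 0:
        return np.empty(0)
    duration = t[-1] - t[0]
    n_cand = rng.poisson(rmax * duration)
    cand = np.sort(rng.uniform(t[0], t[-1], n_cand))
    local = np.interp(cand, t, rate)
    keep = rng.uniform(0.0, rmax, n_cand) < local
    return cand[keep]


def generate_trials(config: RecordingConfig, n_trials: int, seed: int = 0) -> list[Recording]:
    """Independent trials; trial k uses substream (seed, k) of the master seed."""
    if n_trials < 1:
        raise ValueError("n_trials must be >= 1")
    return [generate_recording(config, seed=seed, _trial=k) for k in range(n_trials)]


# ---------------------------------------------------------------------------
# canonical study configurations
# ---------------------------------------------------------------------------

def two_module_config(
    n_rows: int = 12,
    n_cols: int = 10,
    dT: float = 0.28,
    *,
    noise_sd: float = 10.0,
    amplitude: float = 100.0,
    frequency: float = 1.0,
    conduction_sigma: float = 0.4,
    onset_jitter_sd: float = 0.02,
    spike_model: SpikeModel | None = None,
) -> RecordingConfig:
    """The default two-module study: grid split into left/right halves.

    With the default 12 x 10 grid at 0.1 mm pitch the module centroids sit
    0.5 mm apart and the second module activates dT = 0.28 s after the
    first.
    """
    layout = ElectrodeLayout(n_rows, n_cols)
    half = n_cols // 2
    left = tuple(r * n_cols + c for r in range(n_rows) for c in range(half))
    right = tuple(r * n_cols + c for r in range(n_rows) for c in range(half, n_cols))
    mk = lambda chans, delay: ModuleSpec(
        channels=chans, delay=delay, frequency=frequency, amplitude=amplitude
    )
    return RecordingConfig(
        layout=layout,
        modules=(mk(left, 0.0), mk(right, dT)),
        conduction_sigma=conduction_sigma,
        onset_jitter_sd=onset_jitter_sd,
        noise_sd=noise_sd,
        spike_model=spike_model or SpikeModel(),
    )


def single_module_config(n_rows: int = 12, n_cols: int = 10, **kwargs) -> RecordingConfig:
    """Negative control: one module covering the whole grid (no modularity)."""
    cfg = two_module_config(n_rows, n_cols, dT=0.0, **kwargs)
    merged = ModuleSpec(
        channels=tuple(range(cfg.layout.n_channels)),
        delay=0.0,
        frequency=cfg.modules[0].frequency,
        amplitude=cfg.modules[0].amplitude,
    )
    return replace(cfg, modules=(merged,))
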