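"""LFP filtering, analytic signal, thresholded phase crossings, and spectra.

The chain is: zero-phase Butterworth band selection -> Hilbert analytic
signal (envelope + instantaneous phase) -> upward crossings of a target
phase (pi/2 by default), kept only when the envelope exceeds a noise
threshold calibrated on pre-stimulus epochs (mean + 4 sd of pre-stimulus
crossing amplitudes).

Filtering is forward-backward (filtfilt) after symmetric zero padding of
one trace length.  Zero phase matters here: a causal filter would add a
frequency-dependent delay and fabricate exactly the latency gradients this
package is built to scrutinise.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.signal import butter, hilbert, sosfilt, sosfiltfilt, welch

from .simulate import Recording

__all__ = [
    "FilterSpec",
    "AnalyticTrace",
    "PhaseCrossing",
    "apply_filter",
    "analytic_signal",
    "estimate_noise_threshold",
    "detect_phase_crossings",
    "detect_recording_crossings",
    "welch_psd",
]


@dataclass(frozen=True)
class FilterSpec:
    """Butterworth filter specification (zero-phase by default).

    ``corners`` is (high,) for lowpass or (low, high) for bandpass, in Hz.
    ``order`` is the design order of one pass; the default 8 with two
    passes gives 16th-order magnitude response.
    """

    kind: str = "lowpass"
    corners: tuple[float, ...] = (2.0,)
    order: int = 8
    zero_phase: bool = True

    def __post_init__(self) -> None:
        if self.kind not in ("lowpass", "bandpass"):
            raise ValueError(f"unknown filter kind {self.kind!r}")
        n = 1 if self.kind == "lowpass" else 2
        if len(self.corners) != n:
            raise ValueError(f"{self.kind} needs {n} corner(s)")
        if any(c <= 0 for c in self.corners):
            raise ValueError("corner frequencies must be positive")
        if self.order <= 0 or self.order % 2:
            raise ValueError("order must be even and positive")

    def validate_rate(self, sample_rate: float) -> None:
        if max(self.corners) >= sample_rate / 2:
            raise ValueError(
                f"corner {max(self.corners)} Hz >= Nyquist ({sample_rate / 2} Hz)"
            )


@dataclass
class AnalyticTrace:
    """Envelope and wrapped instantaneous phase of one band-limited trace.

    Phase convention: for cos(2 pi f t) the phase is 0 at the peak and
    increases through +pi/2 a quarter period later.
    """

    envelope: np.ndarray
    phase: np.ndarray
    sample_rate: float
    band: tuple[float, ...] = (2.0,)
    undefined: bool = False  # all-zero input trace


@dataclass(frozen=True)
class PhaseCrossing:
    """One upward crossing of the target phase on one channel."""

    channel: int
    time: float  # s, sub-sample by linear interpolation
    amplitude: float  # Hilbert envelope at the crossing, uV
    target_phase: float = np.pi / 2


def apply_filter(lfp: np.ndarray, spec: FilterSpec, sample_rate: float) -> np.ndarray:
    """Zero-phase Butterworth with symmetric zero padding of one trace length.

    Accepts (T,) or (C, T) arrays; padding is removed on return.
    """
    spec.validate_rate(sample_rate)
    x = np.atleast_2d(np.asarray(lfp, dtype=float))
    n = x.shape[1]
    if n <= 3 * spec.order:
        raise ValueError("trace too short for the requested filter order")
    wn = [c / (sample_rate / 2) for c in spec.corners]
    # second-order sections: a deep lowpass corner (e.g. 2 Hz at 1 kHz) is
    # numerically unstable in transfer-function form
    sos = butter(
        spec.order, wn if len(wn) > 1 else wn[0], btype=spec.kind.replace("pass", ""),
        output="sos",
    )
    pad = np.zeros((x.shape[0], n))
    padded = np.concatenate([pad, x, pad], axis=1)
    if spec.zero_phase:
        y = sosfiltfilt(sos, padded, axis=1)
    else:
        y = sosfilt(sos, padded, axis=1)
    y = y[:, n : 2 * n]
    return y[0] if np.ndim(lfp) == 1 else y


def analytic_signal(
    trace: np.ndarray, sample_rate: float, band: tuple[float, ...] = (2.0,)
) -> AnalyticTrace:
    """Hilbert analytic signal of an already band-limited trace."""
    trace = np.asarray(trace, dtype=float)
    if not np.any(trace):
        return AnalyticTrace(
            envelope=np.zeros_like(trace),
            phase=np.zeros_like(trace),
            sample_rate=sample_rate,
            band=band,
            undefined=True,
        )
    z = hilbert(trace)
    return AnalyticTrace(
        envelope=np.abs(z), phase=np.angle(z), sample_rate=sample_rate, band=band
    )


def _upward_crossings(phase: np.ndarray, target: float) -> np.ndarray:
    """Fractional sample indices where unwrapped phase crosses target + 2 pi k upward."""
    ph = np.unwrap(phase)
    # shift so crossings of target sit at multiples of 2 pi
    z = ph - target
    k = np.floor(z / (2 * np.pi))
    idx = np.flatnonzero(np.diff(k) > 0)  # upward integer-level crossing
    out = []
    for i in idx:
        level = k[i + 1] * 2 * np.pi
        dz = z[i + 1] - z[i]
        frac = (level - z[i]) / dz if dz != 0 else 0.0
        out.append(i + frac)
    return np.asarray(out)


def detect_phase_crossings(
    traces: Sequence[AnalyticTrace],
    target_phase: float = np.pi / 2,
    threshold: float = 0.0,
) -> list[PhaseCrossing]:
    """Upward crossings of ``target_phase`` per channel, envelope-thresholded.

    Crossing times are sub-sample (linear interpolation of the unwrapped
    phase); crossings whose envelope falls below ``threshold`` are dropped.
    """
    out: list[PhaseCrossing] = []
    for ch, tr in enumerate(traces):
        if tr.undefined:
            continue
        for fidx in _upward_crossings(tr.phase, target_phase):
            i = int(np.floor(fidx))
            frac = fidx - i
            amp = tr.envelope[i] * (1 - frac) + tr.envelope[min(i + 1, len(tr.envelope) - 1)] * frac
            if amp >= threshold:
                out.append(
                    PhaseCrossing(
                        channel=ch,
                        time=fidx / tr.sample_rate,
                        amplitude=float(amp),
                        target_phase=target_phase,
                    )
                )
    return out


def _recording_traces(
    rec: Recording, spec: FilterSpec, channels: Sequence[int] | None = None
) -> list[AnalyticTrace]:
    filt = apply_filter(rec.lfp, spec, rec.sample_rate)
    chans = range(rec.lfp.shape[0]) if channels is None else channels
    return [analytic_signal(filt[ch], rec.sample_rate, spec.corners) for ch in chans]


def estimate_noise_threshold(
    trials: Sequence[Recording],
    spec: FilterSpec | None = None,
    target_phase: float = np.pi / 2,
    pre_stim_window: tuple[float, float] = (0.5, 1.0),
    n_sample_trials: int = 100,
    seed: int = 0,
) -> float:
    """Amplitude threshold = mean + 4 sd of pre-stimulus crossing envelopes.

    Crossing amplitudes are collected in the window ``pre_stim_window``
    *before* the stimulus of up to ``n_sample_trials`` randomly chosen
    trials.
    """
    spec = spec or FilterSpec()
    rng = np.random.default_rng(seed)
    picks = list(range(len(trials)))
    if len(picks) > n_sample_trials:
        picks = sorted(rng.choice(picks, n_sample_trials, replace=False))
    amps: list[float] = []
    for i in picks:
        rec = trials[i]
        stim = float(rec.stim_times[0])
        t0, t1 = stim - pre_stim_window[1], stim - pre_stim_window[0]
        for c in detect_phase_crossings(_recording_traces(rec, spec), target_phase, 0.0):
            if t0 <= c.time <= t1:
                amps.append(c.amplitude)
    if not amps:
        raise ValueError(
            "no pre-stimulus phase crossings found; use a longer baseline epoch"
        )
    a = np.asarray(amps)
    return float(a.mean() + 4.0 * a.std())


def detect_recording_crossings(
    rec: Recording,
    spec: FilterSpec | None = None,
    target_phase: float = np.pi / 2,
    threshold: float = 0.0,
) -> list[PhaseCrossing]:
    """Filter a recording to the band and return thresholded phase crossings."""
    spec = spec or FilterSpec()
    return detect_phase_crossings(_recording_traces(rec, spec), target_phase, threshold)


def welch_psd(
    trials: Sequence[Recording],
    window: tuple[float, float] = (0.25, 2.25),
    channel: int | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Trial-averaged Welch PSD of the post-stimulus response window.

    The 2 s window starting 250 ms post-stimulus is split into three 1 s
    segments with 500 ms overlap; PSDs are averaged over channels (or one
    ``channel``) and trials.  Returns (frequencies, psd).
    """
    psds = []
    freqs = None
    for rec in trials:
        stim = float(rec.stim_times[0])
        i0 = int(round((stim + window[0]) * rec.sample_rate))
        i1 = int(round((stim + window[1]) * rec.sample_rate))
        if i0 < 0 or i1 > rec.lfp.shape[1]:
            raise ValueError("analysis window exceeds the trial duration")
        seg = rec.lfp[:, i0:i1] if channel is None else rec.lfp[channel : channel + 1, i0:i1]
        nper = int(round(1.0 * rec.sample_rate))
        f, p = welch(seg, fs=rec.sample_rate, nperseg=nper, noverlap=nper // 2, axis=1)
        freqs = f
        psds.append(p.mean(axis=0))
    return freqs, np.mean(psds, axis=0)
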