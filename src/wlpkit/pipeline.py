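"""End-to-end experiments: simulate -> filter -> detect -> quantify -> report.

``run_experiment`` executes the full analysis chain on synthetic trials:
band filtering, noise-calibrated phase-crossing detection, flood-fill wave
clustering, recruitment selection, phase-latency maps with PLDC and a
shuffled control, wave-center-path speed estimates, first-spike and ALSA
onsets, and the paired LFP-vs-onset dip comparison.  ``run_model_suite``
executes the analytic-model scans (concavity and unimodality boundaries,
velocity laws, PLDC grids, the 2D pattern zoo).

Both return plain dictionaries that serialise to JSON; every number is
traceable to a trial id and the master seed.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np

from . import model
from .dip import paired_comparison
from .lfp import FilterSpec, detect_recording_crossings, estimate_noise_threshold
from .simulate import (
    Recording,
    RecordingConfig,
    generate_trials,
    single_module_config,
    two_module_config,
)
from .spikes import SpikeTrainSet, alsa_onsets, compute_alsa, first_spikes_in_wave
from .waves import (
    BAND_WINDOWS,
    cluster_crossings,
    compute_plm,
    compute_pldc,
    compute_wcp,
    estimate_speed,
    select_waves,
    shuffled_pldc,
)

__all__ = ["ExperimentConfig", "run_experiment", "run_model_suite", "split_onset_gap"]

log = logging.getLogger("wlpkit")


@dataclass
class ExperimentConfig:
    """Configuration of one synthetic experiment."""

    recording: RecordingConfig = field(default_factory=two_module_config)
    n_trials: int = 100
    seed: int = 0
    band: tuple[float, float] = (0.0, 2.0)
    cluster_window: float | None = None  # s; default looked up from the band
    selection: tuple[str, float] = ("fraction", 2.0 / 3.0)
    n_boot: int = 500
    n_shuffles: int = 200  # latency permutations per wave for the PLDC null
    filter_order: int = 8

    def window(self) -> float:
        if self.cluster_window is not None:
            return self.cluster_window
        return BAND_WINDOWS.get(tuple(self.band), 0.100)

    def filter_spec(self) -> FilterSpec:
        lo, hi = self.band
        if lo <= 0:
            return FilterSpec(kind="lowpass", corners=(hi,), order=self.filter_order)
        return FilterSpec(kind="bandpass", corners=(lo, hi), order=self.filter_order)


def split_onset_gap(times: np.ndarray) -> float:
    """Two-cluster gap of a 1D onset sample (exact 1D 2-means split).

    The split minimising within-cluster variance is found by scanning the
    sorted sample; returns the difference of cluster means.
    """
    t = np.sort(np.asarray(times, dtype=float))
    if t.size < 2:
        return 0.0
    best, gap = np.inf, 0.0
    for k in range(1, t.size):
        g0, g1 = t[:k], t[k:]
        v = ((g0 - g0.mean()) ** 2).sum() + ((g1 - g1.mean()) ** 2).sum()
        if v < best:
            best, gap = v, float(g1.mean() - g0.mean())
    return gap


def _analyse_trial(rec: Recording, cfg: ExperimentConfig, threshold: float, trial: int) -> dict:
    spec = cfg.filter_spec()
    crossings = detect_recording_crossings(rec, spec, threshold=threshold)
    waves = cluster_crossings(crossings, rec.layout, cfg.window())
    crit, val = cfg.selection
    selected = select_waves(waves, rec.layout, crit, val)
    log.info("trial=%d stage=waves n_crossings=%d n_waves=%d n_selected=%d",
             trial, len(crossings), len(waves), len(selected))
    out = {
        "trial": trial,
        "n_crossings": len(crossings),
        "n_waves": len(waves),
        "n_selected": len(selected),
        "waves": [],
    }
    sts = SpikeTrainSet(rec.spikes)
    alsa = compute_alsa(sts, rec.layout, rec.duration, rec.sample_rate)
    for wi, w in enumerate(selected):
        plm = compute_plm(w, rec.layout)
        pldc, reason = compute_pldc(plm, rec.layout)
        shuffled = shuffled_pldc(plm, rec.layout, cfg.n_shuffles, seed=cfg.seed + 7919 * trial + wi)
        speed = estimate_speed(compute_wcp(w, rec.layout, sample_rate=rec.sample_rate))
        fs = first_spikes_in_wave(sts, w)
        ao = alsa_onsets(alsa, w)
        out["waves"].append(
            {
                "wave": wi,
                "n_channels": w.n_channels,
                "start_time": w.start_time,
                "width": w.width,
                "pldc": pldc,
                "pldc_missing_reason": reason,
                "pldc_shuffled_mean": float(np.nanmean(shuffled)),
                "speed_mm_s": speed,
                "_wave_obj": w,
                "_first_spikes": fs,
                "_alsa_onsets": ao,
            }
        )
    return out


def run_experiment(cfg: ExperimentConfig, out_dir: str | None = None) -> dict:
    """Run the full chain; returns (and optionally writes) the report."""
    trials = generate_trials(cfg.recording, cfg.n_trials, seed=cfg.seed)
    spec = cfg.filter_spec()
    threshold = estimate_noise_threshold(trials, spec, seed=cfg.seed)
    log.info("stage=threshold value_uV=%.3f", threshold)

    per_trial = [_analyse_trial(rec, cfg, threshold, k) for k, rec in enumerate(trials)]

    # paired dip comparisons on the first selected wave of each trial
    waves, fs_sets, alsa_sets, ids = [], [], [], []
    for tr in per_trial:
        if tr["waves"]:
            w0 = tr["waves"][0]
            waves.append(w0["_wave_obj"])
            fs_sets.append(w0["_first_spikes"])
            alsa_sets.append(w0["_alsa_onsets"])
            ids.append(tr["trial"])
    layout = cfg.recording.layout
    cmp_fs = paired_comparison(waves, layout, fs_sets, n_boot=cfg.n_boot, seed=cfg.seed + 1)
    cmp_alsa = paired_comparison(waves, layout, alsa_sets, n_boot=cfg.n_boot, seed=cfg.seed + 2)

    alsa_gaps = [split_onset_gap(s.times) for s in alsa_sets if len(s.onsets) >= 4]
    pldcs = np.array([w["pldc"] for tr in per_trial for w in tr["waves"]])
    shuf = np.array([w["pldc_shuffled_mean"] for tr in per_trial for w in tr["waves"]])
    speeds = np.array([w["speed_mm_s"] for tr in per_trial for w in tr["waves"]])

    for tr in per_trial:  # strip non-serialisable working objects
        for w in tr["waves"]:
            w.pop("_wave_obj"), w.pop("_first_spikes"), w.pop("_alsa_onsets")

    report = {
        "seed": cfg.seed,
        "n_trials": cfg.n_trials,
        "band": list(cfg.band),
        "threshold_uV": threshold,
        "trials": per_trial,
        "pldc": {
            "values": pldcs.tolist(),
            "median": float(np.nanmedian(pldcs)) if pldcs.size else None,
            "shuffled_mean": float(np.nanmean(shuf)) if shuf.size else None,
        },
        "speed_mm_s": {
            "values": speeds.tolist(),
            "median": float(np.median(speeds)) if speeds.size else None,
        },
        "alsa_onset_gap_s": {
            "values": alsa_gaps,
            "median": float(np.median(alsa_gaps)) if alsa_gaps else None,
        },
        "dip_first_spikes": _comparison_summary(cmp_fs),
        "dip_alsa": _comparison_summary(cmp_alsa),
    }
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        with open(out / "report.json", "w") as fh:
            json.dump(report, fh, indent=2)
    return report


def _comparison_summary(cmp) -> dict:
    return {
        "records": cmp.records,
        "skipped": cmp.skipped,
        "median_p_lfp": cmp.median_p_lfp,
        "median_p_onset": cmp.median_p_onset,
        "median_p_difference": cmp.median_p_difference,
        "fraction_lfp_greater": cmp.fraction_lfp_greater(),
    }


# ---------------------------------------------------------------------------
# analytic model suite
# ---------------------------------------------------------------------------

def concavity_boundary(step: float = 1e-3, lo: float = 0.1, hi: float = 4.0) -> float:
    """Scan dx/sigma_x and locate the concave->convex sign change.

    Returns the midpoint of the step interval where the second spatial
    derivative at (x=0, t=tbar) changes sign.
    """
    ratios = np.arange(lo, hi + step / 2, step)
    curv = np.array([model.midpoint_curvature(r, 1.0) for r in ratios])
    sign_change = np.flatnonzero((curv[:-1] <= 0) & (curv[1:] > 0))
    if sign_change.size != 1:
        raise RuntimeError(f"expected exactly one sign change, found {sign_change.size}")
    i = sign_change[0]
    # linear interpolation of the curvature zero inside the step interval
    c0, c1 = curv[i], curv[i + 1]
    return float(ratios[i] + step * (0.0 - c0) / (c1 - c0))


def unimodality_boundary(step: float = 1e-3, lo: float = 0.1, hi: float = 4.0) -> float:
    """Scan dt/sigma_t and locate the 1 -> 2 temporal-peak transition."""
    ratios = np.arange(lo, hi + step / 2, step)
    # bisect on the monotone peak count to avoid 4000 dense-grid evaluations
    def n_peaks(r: float) -> int:
        return model.count_temporal_peaks(model.gaussian_pair(1.0, 1.0, r, 1.0))

    lo_i, hi_i = 0, len(ratios) - 1
    if n_peaks(ratios[lo_i]) != 1 or n_peaks(ratios[hi_i]) != 2:
        raise RuntimeError("peak count is not 1 at the low end and 2 at the high end")
    while hi_i - lo_i > 1:
        mid = (lo_i + hi_i) // 2
        if n_peaks(ratios[mid]) == 1:
            lo_i = mid
        else:
            hi_i = mid
    return float(0.5 * (ratios[lo_i] + ratios[hi_i]))


def run_model_suite(out_dir: str | None = None) -> dict:
    """Analytic-model scans: boundaries, velocity laws, PLDC grids, patterns."""
    report: dict = {}
    report["concavity_boundary"] = concavity_boundary()
    report["unimodality_boundary"] = unimodality_boundary()

    dx = np.linspace(0.2, 1.8, 9)
    report["velocity_vs_dx"] = {
        "dx": dx.tolist(),
        "v_mid": [model.peak_velocity_gaussian(d, 1.0, 2.0, 1.0) for d in dx],
    }

    dxs = [0.5, 1.0, 1.5, 2.0]
    dts = [0.5, 1.0, 1.5, 2.0]
    grid = model.pldc_scan(dxs, dts)
    report["pldc_grid"] = {"dx": dxs, "delay": dts, "pldc": grid.tolist()}

    patterns = {}
    for kind in ("plane", "radial", "spiral_like"):
        _, _, pldc = model.pattern_latency_map(kind)
        patterns[kind] = pldc
    report["pattern_pldc"] = patterns

    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        with open(out / "model_report.json", "w") as fh:
            json.dump(report, fh, indent=2)
    return report
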