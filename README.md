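# wlpkit

Tools for deciding whether "traveling waves" seen in field-potential
recordings are really traveling at the level of neuronal excitability — or
whether they are **wave-like patterns (WLPs)**: sequentially activated,
spatially discrete modules whose volume-conducted potentials merely look
like a propagating wavefront.

The package is aimed at electrophysiologists analysing multi-electrode
array (MEA) or EEG-like data, and at methodologists who want a sandbox in
which the ground truth (wave vs. modules) is known exactly.

## What is inside

**Analytic model** (`wlpkit.model`). The potential of two sequentially
activated Gaussian sources,

    V(x, t) = Σᵢ exp(−(x − xᵢ)²/2σₓ²) · Tᵢ(t),

with a Gaussian bump `Tᵢ(t) = exp(−(t − tᵢ)²/2σₜ²)` or a cosine
`Tᵢ(t) = cos(2πft + φᵢ)`. The module provides the moving-peak trajectory
and its closed-form velocity laws, the concavity boundary (a single merged
peak exists iff `Δx ≤ 2σₓ`), the temporal unimodality boundary
(`Δt ≤ 2σₜ`), 2D plane/radial/spiral-like source arrangements, and
phase-latency-distance-correlation (PLDC) scans. Every closed form is
validated against numeric peak tracking.

**Synthetic MEA generator** (`wlpkit.simulate`). A 100 µm-pitch electrode
grid where each site hosts a local source; sources are grouped into two
sequentially activated modules (0.28 s apart by default), the LFP is their
volume-conducted mixture (Gaussian kernel, σ = 0.4 mm) plus pink noise,
and spikes are an inhomogeneous Poisson process phase-locked to the local
source (preferred phase 0.53π). Ground truth (module labels, onsets) rides
along in every `Recording`.

**Analysis chain** (`wlpkit.lfp`, `wlpkit.waves`, `wlpkit.spikes`,
`wlpkit.dip`). Zero-phase Butterworth filtering, Hilbert phase, amplitude-
thresholded π/2 phase crossings (mean + 4 sd of pre-stimulus crossings),
spatiotemporal flood-fill wave clustering, phase latency maps, PLDC with
shuffled controls, amplitude-weighted wave center paths and speeds, first
spikes and ALSA (neighbor-weighted local spiking activity) onsets, and
Hartigan's dip statistic with a uniform-bootstrap p-value — implemented
from the greatest-convex-minorant definition and validated against a
brute-force LP oracle.

**Pipeline and CLI** (`wlpkit.pipeline`, `wlpkit` command). One call runs
simulate → filter → detect → quantify and emits a JSON report.

## Worked example

```python
from wlpkit.pipeline import ExperimentConfig, run_experiment
from wlpkit.simulate import two_module_config

cfg = ExperimentConfig(recording=two_module_config(), n_trials=20, seed=1)
report = run_experiment(cfg)
print("PLDC median:          %.2f" % report["pldc"]["median"])
print("shuffled-control mean: %.3f" % report["pldc"]["shuffled_mean"])
print("median p (LFP):       %.3f" % report["dip_first_spikes"]["median_p_lfp"])
print("median p (spikes):    %.3f" % report["dip_first_spikes"]["median_p_onset"])
print("ALSA onset gap (s):   %.3f" % report["alsa_onset_gap_s"]["median"])
```

prints

```
PLDC median:          0.57
shuffled-control mean: -0.001
median p (LFP):       0.874
median p (spikes):    0.002
ALSA onset gap (s):   0.281
```

Read: the LFP latency map correlates with distance (a "wave", PLDC well
above the shuffled control), and its crossing times test as unimodal
(p ≈ 0.87) — yet the spike onsets on the same channels are flagrantly
bimodal (p at the bootstrap floor), and the ALSA onset clusters recover
the configured 0.28 s inter-module delay. The "wave" is two modules.

The analytic boundaries are available directly:

```python
from wlpkit.pipeline import concavity_boundary, unimodality_boundary
concavity_boundary()    # 2.000  (Δx/σx at which the merged peak splits)
unimodality_boundary()  # 2.0005 (Δt/σt at which V(0,t) becomes bimodal)
```

## CLI

```bash
wlpkit simulate --n-trials 10 --seed 1 --out trials/
wlpkit analyze --n-trials 20 --seed 1 --report report.json
wlpkit model --scan concavity
```
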