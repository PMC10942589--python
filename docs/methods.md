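# Methods

## The problem this package models

A latency gradient across sensors is the conventional signature of a
traveling wave: each channel reaches a reference phase of its oscillation
a little later than its neighbor, and the Pearson correlation between
phase latency and distance from the wave origin (PLDC) is close to 1.
The difficulty is that the same signature arises without any traveling
excitability. If two spatially discrete neuronal modules activate one
after the other, and the measurement mixes their potentials over space
(volume conduction, field spread, filtering), the measured latency map
grades smoothly between the two activation times and is read as a wave —
a *wave-like pattern* (WLP). This package implements both the analytic
theory of that confusion and a full detection/quantification chain that
can discriminate the two cases when spiking (local supra-threshold
excitability) is recorded alongside the field potential.

## Analytic source model

`wlpkit.model` treats the potential of two sources as

    V(x, t) = Σ_{i=1,2} a_i · exp(−(x − x_i)² / 2σ_x²) · T_i(t)

with transient mode `T_i(t) = exp(−(t − t_i)²/2σ_t²)` or periodic mode
`T_i(t) = cos(2πf t + φ_i)`. All quantities are in model units; only
ratios matter for the boundaries.

* **Concavity boundary.** The mid-time profile at `x = 0` has second
  derivative `∝ (Δx²/4 − σ_x²)`; a single concave (merged) peak exists
  iff `Δx ≤ 2σ_x`, with equality the inflection case, classified concave.
* **Temporal unimodality.** `V(0, t)` is an equal mixture of two temporal
  Gaussians; it has one maximum iff `Δt ≤ 2σ_t` (plateau at equality).
* **Moving-peak velocity, transient mode.** Implicit differentiation of
  `∂V/∂x = 0` at the symmetric mid-point gives
  `v_p = Δt σ_x² Δx / (σ_t² (4σ_x² − Δx²))`: linear in `Δx` for small
  separations and diverging at the concavity boundary.
* **Moving-peak velocity, periodic mode.** The same derivation with the
  cosine factors gives, with `u = xΔx/σ_x²` and `E = e^u`,

      v_p = −ω σ_x² e^{−u} · {[Δx(E−1) − 2x(E+1)]² + 4E(Δx² − 4x²)sin²(Δφ/2)}
            / {Δx (4σ_x² + 4x² − Δx²) sin(Δφ)},   ω = 2πf.

  Sign convention: `Δφ = φ₂ − φ₁ > 0` means the second source leads in
  phase (peaks earlier), so the peak travels from source 2 toward source
  1 — negative velocity at the mid-point. Reversing `Δφ` reverses the
  direction; the magnitude is proportional to `f`. Both closed forms are
  validated in the test suite against finite differences of the
  numerically tracked root of `∂V/∂x` (relative error < 10⁻³ over 100
  random parameter draws); the derivation was additionally checked
  symbolically.
* **Peak tracking.** Bisection (`brentq`, xtol 10⁻⁹·σ_x) on the analytic
  spatial derivative bracketed between the source centers; if the
  bracketed critical point is a minimum (separated sources), the global
  dense-grid argmax is returned and flagged degenerate.
* **Latency convention for model fields.** Latency of a sample point is
  the time of the first temporal maximum of `V` at that point. For
  periodic fields the window spans exactly one oscillation period — a
  cosine trace has one maximum per cycle, and longer windows create wrap
  artifacts in the latency map.
* **Pattern zoo.** 2D arrangements whose one-cycle latency maps mimic
  plane, radial and spiral-like waves. All use the periodic mode
  (f = 1, phases ±3π/8, the earlier source leading) with
  density-normalised amplitudes (`1/√det Σ`), so that a tight and a wide
  source carry comparable total activation: plane — identical isotropic
  Gaussians (σ = 1) with centers 2σ apart; radial — co-centered Gaussians
  with σ = 0.75 and 1.5 (the tight one first, so activation appears to
  expand); spiral-like — orthogonal anisotropic Gaussians
  (diag(2², 0.5²) / diag(0.5², 2²)) with centers offset one unit on each
  axis. Latency maps are sampled on a 21×21 grid over ±2 units (≈ ±1.3σ
  of the wide source). With these defaults the radial pattern's PLDC is
  ≈ 0.95 and the plane pattern's ≈ 0.95 — high enough to be read as
  traveling waves, which is the point of the exercise. The covariances
  and phases are package choices; only their qualitative arrangement is
  constrained by the phenomenon being illustrated.

## Synthetic MEA recordings

`wlpkit.simulate` generates ground-truthed trials emulating visually
evoked slow activity on a 100 µm-pitch grid (default 12 × 10 channels,
1 kHz, 5 s, stimulus at 1 s, response latency 0.2 s).

Design rationale: the generator puts one local current source at every
electrode site rather than one template per module. Modules are then
*populations of sources with a common onset*. This matters because the
discriminating statistics operate per channel: per-channel spiking must
reflect the local source, while the per-channel LFP must be a spatial
mixture of many sources. A two-template construction (one waveform per
module, mixed by a footprint) produces LFP latency histograms with two
plateaus — every channel's latency is a deterministic function of a
single mixing ratio — and is flagged bimodal by the dip test no matter
how wide the footprint; the per-source construction with onset
variability produces the smoothly graded latency samples seen in real
slow waves.

* **Source waveform**: Hann-windowed sine burst, 1.5 cycles of 1 Hz,
  100 µV peak. The sine carrier starts at phase −π/2, so the analytic
  phase rises through +π/2 half a cycle after onset; 1.5 cycles keeps the
  trace continuous at both ends.
* **Onsets**: module onset = stimulus + 0.2 s + module delay (second
  module delayed `dT` = 0.28 s by default), plus per-channel Gaussian
  jitter of 20 ms (biological onset variability).
* **LFP**: row-normalised Gaussian volume-conduction kernel of scale
  0.4 mm applied to all sources — the few-hundred-micrometer spatial
  decay of extracellular potentials — plus pink (1/f, floored at 0.1 Hz)
  noise of 10 µV total sd. Pink rather than white: slow-band LFP noise
  dominates at low frequencies, and it is the in-band noise that gives
  phase-crossing latencies their realistic jitter (white noise of the
  same sd carries ~0.6 µV below 2 Hz, i.e. essentially none).
* **Spikes**: inhomogeneous Poisson (thinning), rate = 0.2 Hz baseline
  plus a von Mises bump (κ = 4) of the channel's *own source* phase
  peaking at 20 Hz at phase 0.53π, gated to the source's active window.
  Driving spikes from the local source rather than the mixed LFP is the
  modular-excitability premise itself; the sparse baseline keeps
  first-spike samples from being polluted by pre-burst stragglers.
* **Determinism**: every random draw comes from a fixed-key substream
  `SeedSequence([master, trial, stream, channel])`, so identical seeds
  are bit-identical and adding trials or channels never perturbs others.

What the generator does *not* emulate: spike waveforms and sorting
(spikes are born channel-assigned; for real data the upstream contract is
assignment to the maximal-average-amplitude channel), multi-band activity
beyond the single slow component, electrode artifacts, non-stationary
noise, and trial-to-trial amplitude variability. Passing tests therefore
demonstrate that the chain recovers modular structure under realistic
noise, smearing and sparsity — not that it is robust to every real-data
pathology.

## Analysis chain

* **Filtering** (`wlpkit.lfp`): zero-phase (forward–backward)
  eighth-order Butterworth in second-order-section form, after symmetric
  zero padding of one trace length. Zero phase is essential: a causal
  filter adds a frequency-dependent delay, i.e. fabricates exactly the
  latency structure under scrutiny. SOS form because a 2 Hz corner at
  1 kHz is numerically unstable as a transfer function.
* **Phase crossings**: upward crossings of π/2 on the unwrapped Hilbert
  phase, sub-sample by linear interpolation; crossings with envelope
  below the noise threshold (mean + 4 sd of pre-stimulus crossing
  envelopes of up to 100 random trials; window 0.5–1.0 s before the
  stimulus) are discarded. This also rejects the small filter pre-ring
  of the evoked burst.
* **Wave clustering** (`wlpkit.waves`): crossings on identical or rook-
  adjacent channels within a band-specific window (100 ms for 0–2 Hz,
  2 ms for 12–35 Hz) are linked; waves are connected components — so the
  partition is canonical and independent of visit order. Selection:
  recruitment fraction ≥ 2/3 (0–2 Hz) or 5/6 (12–35 Hz), or > 30
  channels for first-spike analyses.
* **Latency maps and PLDC**: first crossing per channel; start point is
  the earliest crossing's electrode (ties to the lowest channel index);
  PLDC is Pearson r of latency vs. Euclidean distance from the start
  point, with undefined cases returned as missing plus a reason, never a
  silent 0. Shuffled controls permute latencies across channels.
* **Wave center path**: amplitude-weighted center of mass with a
  Gaussian temporal kernel whose width ramps linearly from 2·ΔT̄ at the
  wave edges to 10·ΔT̄ at its middle (ΔT̄ = mean spacing of sorted
  crossing times) — narrow ends keep the endpoints anchored, the wide
  middle suppresses jitter. Speed is the absolute least-squares slope of
  the path projected on its principal displacement axis versus time.
  This estimate is unbiased only when conduction smearing is mild; under
  the default 0.4 mm kernel the latency span is compressed below the
  true inter-module delay and the apparent speed is correspondingly
  inflated (≈ 3.5 mm/s vs. the 0.5 mm/0.28 s ≈ 1.8 mm/s of the
  centroids), which is itself a property of WLPs worth knowing about.
* **ALSA** (`wlpkit.spikes`): per-channel spike counts → 100 ms boxcar →
  Gaussian smoothing with σ = 100 ms → neighbor average with half-weight
  rook neighbors, `ALSA_i = (S_i + Σ S_j/2)/(1 + Σ 1/2)`. The Gaussian's
  "width" is interpreted as its σ and exposed as a parameter. Onsets are
  the first strict local maximum (plateaus: first plateau sample) within
  [wave start − W/2, wave end + W/2].
* **Dip statistic** (`wlpkit.dip`): implemented from the greatest-convex-
  minorant / least-concave-majorant definition with iterative modal-
  interval refinement; exact floor 1/(2n), ceiling 1/4. Validated against
  a brute-force LP minimisation over piecewise-linear unimodal CDFs
  (exact for tie-free samples; agreement to 10⁻⁸). The dip is invariant
  under affine maps and reflection — not under general monotone
  transforms, which change the spacings it measures. p-values: fraction
  of n_boot = 500 uniform(0,1) samples of the same size whose dip meets
  or exceeds the observed one (the worst-case-unimodal null), floored at
  1/(n_boot+1). Within one paired comparison the null sample is cached
  per sample size, so both sides of a pair are ranked against the same
  null.
* **Paired comparison**: per wave, LFP first-crossing times vs. spike (or
  ALSA) onset times restricted to the channels present in both; waves
  with < 4 common channels are skipped with a reason.

## Problem sizes and numerical choices

Default experiment: 100 trials, 12 × 10 channels, 5 s at 1 kHz; the
negative control (one module spanning the grid) runs 50 trials — medians
of dip p-value differences need the larger sample to be stable, while
the two-module contrast is unambiguous already at smaller n. Boundary
scans use step 10⁻³ over ratios [0.1, 4]; temporal peak counting uses a
4001-point grid over ±4σ_t (resolves the shallow double maximum to
within 10⁻³ of the boundary). Root finding uses absolute tolerance
10⁻⁹ of the spatial scale. The velocity-law validation draws parameters
with 0.2 < Δx/σ_x < 1.8 to stay clear of the degenerate boundary.

## Known limitations

* The generator's latency geometry is planar (left/right modules), so
  the data-analog PLDC tops out near the geometric ceiling of a plane
  gradient measured against radial distance (~0.77 noiseless, ~0.6 with
  jitter); radial corner-to-corner waves, where PLDC approaches 1, are
  explored in the analytic model instead.
* The dip's bootstrap null assumes exchangeable, continuous samples;
  heavily tied onset samples (e.g. from very low sample rates) shift it.
* `estimate_speed` reports the apparent WLP speed, not the module
  centroid speed, whenever conduction smearing is substantial (see
  above).
* Single-frequency, single-cycle-family responses only; no multi-band
  interactions.
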