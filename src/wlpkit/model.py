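"""Analytic model of wave-like patterns from sequentially activated Gaussian sources.

Two (or more) spatially fixed Gaussian sources, activated one after the
other, produce a potential whose single moving maximum is easily mistaken
for a traveling wave.  This module provides the closed-form model

    V(x, t) = sum_i  a_i * exp(-(x - x_i)^2 / 2 sigma_x^2) * T_i(t)

with a temporal factor ``T_i`` that is either a Gaussian bump
``exp(-(t - t_i)^2 / 2 sigma_t^2)`` or a cosine ``cos(2 pi f t + phi_i)``,
together with the derived quantities a practitioner needs to map the
wave/module discrimination boundary:

* the trajectory and velocity of the moving peak,
* the mid-point concavity boundary (``dx <= 2 sigma_x`` gives a single
  concave peak; beyond it the mid-point is convex and the two modules are
  visible as separate bumps),
* the temporal unimodality boundary (``dt <= 2 sigma_t`` gives a single
  temporal maximum at the mid-point),
* 2D source arrangements whose latency maps mimic plane, radial and
  spiral-like waves,
* phase-latency/distance correlation (PLDC) scans over model parameters.

Positions and scales are in arbitrary model units; only their ratios
matter for every boundary computed here.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
from scipy.optimize import brentq

__all__ = [
    "SpatioTemporalSource",
    "SourcePair",
    "FieldGrid",
    "PeakTrajectory",
    "gaussian_pair",
    "periodic_pair",
    "default_grid",
    "evaluate_potential",
    "track_peak",
    "peak_velocity_gaussian",
    "peak_velocity_periodic",
    "classify_midpoint_concavity",
    "midpoint_curvature",
    "count_temporal_peaks",
    "make_pattern",
    "pattern_latency_map",
    "first_max_latency_map",
    "pldc_scan",
]


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SpatioTemporalSource:
    """One Gaussian source with Gaussian-bump or periodic temporal activation.

    Parameters
    ----------
    center_x:
        Source center; a scalar (1D) or a length-2 vector (2D), model units.
    spatial_scale:
        Spatial standard deviation ``sigma_x > 0`` (1D) or a 2x2 symmetric
        positive-definite covariance matrix (2D).
    temporal_mode:
        ``"gaussian"`` (transient bump) or ``"periodic"`` (cosine).
    center_t, temporal_scale:
        Bump center ``t_i`` and width ``sigma_t`` (gaussian mode only).
    frequency, phase:
        Oscillation frequency ``f > 0`` (cycles per time unit) and phase
        offset ``phi_i`` in radians (periodic mode only).
    amplitude:
        Dimensionless source strength, default 1.
    """

    center_x: float | np.ndarray
    spatial_scale: float | np.ndarray
    temporal_mode: Literal["gaussian", "periodic"] = "gaussian"
    center_t: float = 0.0
    temporal_scale: float = 1.0
    frequency: float = 1.0
    phase: float = 0.0
    amplitude: float = 1.0

    def __post_init__(self) -> None:
        if self.temporal_mode not in ("gaussian", "periodic"):
            raise ValueError(f"unknown temporal_mode {self.temporal_mode!r}")
        if self.is_2d:
            cov = np.asarray(self.spatial_scale, dtype=float)
            if cov.shape != (2, 2) or not np.allclose(cov, cov.T):
                raise ValueError("2D spatial_scale must be a symmetric 2x2 covariance")
            if np.any(np.linalg.eigvalsh(cov) <= 0):
                raise ValueError("2D covariance must be positive definite")
        elif float(self.spatial_scale) <= 0:
            raise ValueError("spatial_scale must be positive")
        if self.temporal_mode == "gaussian" and self.temporal_scale <= 0:
            raise ValueError("temporal_scale must be positive")
        if self.temporal_mode == "periodic" and self.frequency <= 0:
            raise ValueError("frequency must be positive")

    @property
    def is_2d(self) -> bool:
        return np.ndim(self.center_x) == 1

    # -- factors -----------------------------------------------------------
    def spatial_profile(self, points: np.ndarray) -> np.ndarray:
        """Unnormalised spatial Gaussian evaluated at ``points``.

        ``points`` is (n,) for 1D sources or (n, 2) for 2D sources.
        """
        points = np.asarray(points, dtype=float)
        if self.is_2d:
            d = points - np.asarray(self.center_x, dtype=float)
            prec = np.linalg.inv(np.asarray(self.spatial_scale, dtype=float))
            quad = np.einsum("ni,ij,nj->n", d, prec, d)
            return np.exp(-0.5 * quad)
        z = (points - float(self.center_x)) / float(self.spatial_scale)
        return np.exp(-0.5 * z * z)

    def temporal_profile(self, t: np.ndarray) -> np.ndarray:
        t = np.asarray(t, dtype=float)
        if self.temporal_mode == "gaussian":
            z = (t - self.center_t) / self.temporal_scale
            return np.exp(-0.5 * z * z)
        return np.cos(2.0 * np.pi * self.frequency * t + self.phase)


@dataclass(frozen=True)
class SourcePair:
    """Two sources with matched temporal mode, plus derived separations."""

    first: SpatioTemporalSource
    second: SpatioTemporalSource

    def __post_init__(self) -> None:
        if self.first.temporal_mode != self.second.temporal_mode:
            raise ValueError("sources must share the same temporal_mode")
        if self.first.is_2d != self.second.is_2d:
            raise ValueError("sources must share dimensionality")

    @property
    def sources(self) -> tuple[SpatioTemporalSource, SpatioTemporalSource]:
        return (self.first, self.second)

    @property
    def dx(self) -> float | np.ndarray:
        return np.subtract(self.second.center_x, self.first.center_x)

    @property
    def dt(self) -> float:
        return self.second.center_t - self.first.center_t

    @property
    def dphi(self) -> float:
        return self.second.phase - self.first.phase

    @property
    def tbar(self) -> float:
        return 0.5 * (self.first.center_t + self.second.center_t)

    @property
    def temporal_mode(self) -> str:
        return self.first.temporal_mode

    def reversed(self) -> "SourcePair":
        return SourcePair(self.second, self.first)


def gaussian_pair(
    dx: float,
    sigma_x: float = 1.0,
    dt: float = 2.0,
    sigma_t: float = 1.0,
    *,
    tbar: float = 0.0,
) -> SourcePair:
    """Symmetric pair: centers at ``+-dx/2``, activation times ``tbar -+ dt/2``."""
    mk = lambda s, ti: SpatioTemporalSource(
        center_x=s, spatial_scale=sigma_x, center_t=ti, temporal_scale=sigma_t
    )
    return SourcePair(mk(-dx / 2.0, tbar - dt / 2.0), mk(dx / 2.0, tbar + dt / 2.0))


def periodic_pair(
    dx: float,
    sigma_x: float = 1.0,
    frequency: float = 1.0,
    dphi: float = np.pi / 2,
) -> SourcePair:
    """Symmetric periodic pair with phases ``-+ dphi/2``."""
    mk = lambda s, ph: SpatioTemporalSource(
        center_x=s,
        spatial_scale=sigma_x,
        temporal_mode="periodic",
        frequency=frequency,
        phase=ph,
    )
    return SourcePair(mk(-dx / 2.0, -dphi / 2.0), mk(dx / 2.0, dphi / 2.0))


@dataclass
class FieldGrid:
    """Discretised potential V on a spatial x temporal grid.

    ``x`` is (nx,) for 1D models or (nx, 2) for 2D sampling points;
    ``potential`` has shape (nx, nt).
    """

    x: np.ndarray
    t: np.ndarray
    potential: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.x = np.asarray(self.x, dtype=float)
        self.t = np.asarray(self.t, dtype=float)
        if self.t.ndim != 1 or np.any(np.diff(self.t) <= 0):
            raise ValueError("t must be strictly increasing 1D")
        if self.x.ndim == 1 and np.any(np.diff(self.x) <= 0):
            raise ValueError("x must be strictly increasing")
        if self.potential is not None:
            self.potential = np.asarray(self.potential, dtype=float)
            if self.potential.shape != (self.x.shape[0], self.t.size):
                raise ValueError("potential shape must be (n_x, n_t)")


@dataclass
class PeakTrajectory:
    """Tracked peak positions/velocities; ``degenerate`` flags argmax fallback."""

    times: np.ndarray
    positions: np.ndarray
    velocities: np.ndarray
    degenerate: np.ndarray

    def __post_init__(self) -> None:
        n = len(self.times)
        if not (len(self.positions) == len(self.velocities) == len(self.degenerate) == n):
            raise ValueError("trajectory arrays must share one length")


# ---------------------------------------------------------------------------
# field evaluation and peak tracking
# ---------------------------------------------------------------------------

def default_grid(pair: SourcePair, n_x: int = 2001, n_t: int = 2001) -> FieldGrid:
    """Grid spanning centers +-4 sigma_x and tbar +-4 sigma_t (or two periods)."""
    if pair.first.is_2d:
        raise ValueError("default_grid supports 1D pairs; sample 2D pairs explicitly")
    c1, c2 = float(pair.first.center_x), float(pair.second.center_x)
    sx = max(float(pair.first.spatial_scale), float(pair.second.spatial_scale))
    x = np.linspace(min(c1, c2) - 4 * sx, max(c1, c2) + 4 * sx, n_x)
    if pair.temporal_mode == "gaussian":
        st = max(pair.first.temporal_scale, pair.second.temporal_scale)
        t = np.linspace(pair.tbar - 4 * st, pair.tbar + 4 * st, n_t)
    else:
        period = 1.0 / pair.first.frequency
        t = np.linspace(-period, period, n_t)
    return FieldGrid(x=x, t=t)


def evaluate_potential(pair: SourcePair, grid: FieldGrid) -> FieldGrid:
    """Fill ``grid.potential`` with V(x, t) summed over the pair's sources."""
    V = np.zeros((grid.x.shape[0], grid.t.size))
    for src in pair.sources:
        V += src.amplitude * np.outer(src.spatial_profile(grid.x), src.temporal_profile(grid.t))
    return FieldGrid(x=grid.x, t=grid.t, potential=V)


def _spatial_derivative(pair: SourcePair, x: float, t: float) -> float:
    """Analytic dV/dx for a 1D pair at a single point."""
    total = 0.0
    for src in pair.sources:
        sx = float(src.spatial_scale)
        g = src.amplitude * src.spatial_profile(np.array([x]))[0]
        total += g * float(src.temporal_profile(np.array([t]))[0]) * (
            -(x - float(src.center_x)) / sx**2
        )
    return total


def track_peak(pair: SourcePair, times: Sequence[float]) -> PeakTrajectory:
    """Track the interior maximum of V between the two source centers.

    The peak position is the bracketed root of the analytic spatial
    derivative between the centers; when no interior root exists (well
    separated sources) the global argmax over a dense grid is used and the
    sample is flagged degenerate.  Velocities are central finite
    differences of the positions.
    """
    times = np.asarray(times, dtype=float)
    lo = min(float(pair.first.center_x), float(pair.second.center_x))
    hi = max(float(pair.first.center_x), float(pair.second.center_x))
    sx = max(float(pair.first.spatial_scale), float(pair.second.spatial_scale))
    xs_dense = np.linspace(lo - 4 * sx, hi + 4 * sx, 4001)
    positions = np.empty_like(times)
    degenerate = np.zeros(times.shape, dtype=bool)
    for k, t in enumerate(times):
        dlo = _spatial_derivative(pair, lo, t)
        dhi = _spatial_derivative(pair, hi, t)
        root = None
        if lo < hi and dlo * dhi < 0:
            root = brentq(
                lambda x: _spatial_derivative(pair, x, t), lo, hi, xtol=1e-9 * max(sx, 1.0)
            )
            # the bracketed critical point is a minimum when the sources have
            # separated into two bumps; fall back to the argmax then
            h = 1e-6 * max(sx, 1.0)
            curv = _spatial_derivative(pair, root + h, t) - _spatial_derivative(pair, root - h, t)
            if curv > 0:
                root = None
        if root is not None:
            positions[k] = root
        else:
            V = np.zeros_like(xs_dense)
            for src in pair.sources:
                V += src.amplitude * src.spatial_profile(xs_dense) * float(
                    src.temporal_profile(np.array([t]))[0]
                )
            positions[k] = xs_dense[int(np.argmax(V))]
            degenerate[k] = True
    velocities = np.gradient(positions, times) if times.size > 1 else np.zeros_like(times)
    return PeakTrajectory(times=times, positions=positions, velocities=velocities, degenerate=degenerate)


# ---------------------------------------------------------------------------
# closed-form laws
# ---------------------------------------------------------------------------

def peak_velocity_gaussian(dx: float, sigma_x: float, dt: float, sigma_t: float) -> float:
    """Mid-point peak velocity for the transient (Gaussian-in-time) pair.

    Valid for ``0 <= dx < 2 sigma_x`` (single concave peak); the peak
    crosses x = 0 at t = tbar with velocity

        v_p = dt * sigma_x^2 * dx / (sigma_t^2 * (4 sigma_x^2 - dx^2))

    which diverges at the concavity boundary ``dx -> 2 sigma_x``.
    """
    if sigma_x <= 0 or sigma_t <= 0:
        raise ValueError("scales must be positive")
    if not 0 <= dx < 2 * sigma_x:
        raise ValueError("peak velocity defined only for 0 <= dx < 2*sigma_x")
    return dt * sigma_x**2 * dx / (sigma_t**2 * (4 * sigma_x**2 - dx**2))


def peak_velocity_periodic(
    x: float, dx: float, sigma_x: float, frequency: float, dphi: float
) -> float:
    """Instantaneous velocity of the tracked peak of the periodic pair at position ``x``.

    Derived by implicit differentiation of dV/dx = 0 for the cosine-activated
    pair with phases ``-+ dphi/2`` and centers ``-+ dx/2`` (the tracked peak
    passes position ``x`` at the cycle time where the two cosine factors
    balance).  With ``E = exp(x dx / sigma_x^2)``:

        v_p = -omega sigma_x^2 E^{-1}
              * { [dx (E-1) - 2x (E+1)]^2 + 4 E (dx^2 - 4x^2) sin^2(dphi/2) }
              / { dx (4 sigma_x^2 + 4 x^2 - dx^2) sin(dphi) }

    For ``dphi > 0`` (second source leads in phase, so it activates earlier)
    the peak travels from the second source toward the first: negative
    velocity at the mid-point.  Reversing the sign of ``dphi`` reverses the
    propagation direction; the magnitude scales linearly with ``frequency``.
    """
    if sigma_x <= 0 or frequency <= 0:
        raise ValueError("sigma_x and frequency must be positive")
    if dx <= 0:
        raise ValueError("dx must be positive")
    denom_geom = 4 * sigma_x**2 + 4 * x**2 - dx**2
    if denom_geom <= 0:
        raise ValueError("peak velocity undefined here: x^2 + sigma_x^2 <= (dx/2)^2")
    s = np.sin(dphi)
    if s == 0.0:
        return 0.0
    omega = 2.0 * np.pi * frequency
    u = x * dx / sigma_x**2
    E = np.exp(u)
    num = (dx * (E - 1.0) - 2.0 * x * (E + 1.0)) ** 2 + 4.0 * E * (
        dx**2 - 4.0 * x**2
    ) * np.sin(dphi / 2.0) ** 2
    return float(-omega * sigma_x**2 * np.exp(-u) * num / (dx * denom_geom * s))


def classify_midpoint_concavity(dx: float, sigma_x: float) -> str:
    """Concavity of the mid-time spatial profile at x = 0.

    Evaluates the analytic second spatial derivative of the symmetric pair
    at (x=0, t=tbar); returns ``"concave"`` when it is <= 0 (single merged
    peak, the boundary dx = 2 sigma_x included as the inflection case) and
    ``"convex"`` otherwise (two separable bumps).
    """
    if dx < 0 or sigma_x <= 0:
        raise ValueError("need dx >= 0 and sigma_x > 0")
    return "concave" if midpoint_curvature(dx, sigma_x) <= 0 else "convex"


def midpoint_curvature(dx: float, sigma_x: float) -> float:
    """d2V/dx2 at (x=0, t=tbar) for the symmetric pair (common temporal factor dropped).

    Each source contributes ``((x - x_i)^2/sigma_x^4 - 1/sigma_x^2) G_i`` at
    x = 0; by symmetry both contribute equally.
    """
    h = dx / 2.0
    g = np.exp(-0.5 * (h / sigma_x) ** 2)
    return float(2.0 * g * (h**2 / sigma_x**4 - 1.0 / sigma_x**2))


def count_temporal_peaks(pair: SourcePair, n_t: int = 4001) -> int:
    """Number of strict local temporal maxima of V(0, t) for a symmetric gaussian pair.

    Evaluated on a dense grid over tbar +- 4 sigma_t.  One maximum for
    dt <= 2 sigma_t (plateau boundary included), two beyond.
    """
    if pair.temporal_mode != "gaussian":
        raise ValueError("temporal peak counting applies to gaussian pairs")
    st = max(pair.first.temporal_scale, pair.second.temporal_scale)
    span = abs(pair.dt) / 2.0 + 4 * st
    t = np.linspace(pair.tbar - span, pair.tbar + span, n_t)
    v = np.zeros_like(t)
    for src in pair.sources:
        v += src.amplitude * float(src.spatial_profile(np.array([0.0]))[0]) * src.temporal_profile(t)
    interior = (v[1:-1] > v[:-2]) & (v[1:-1] > v[2:])
    return int(np.count_nonzero(interior))


# ---------------------------------------------------------------------------
# 2D pattern zoo
# ---------------------------------------------------------------------------

_PATTERNS = ("plane", "radial", "spiral_like")


def make_pattern(
    kind: str, *, frequency: float = 1.0, dphi: float = -3 * np.pi / 4
) -> SourcePair:
    """Canonical 2D source arrangements whose latency maps mimic wave types.

    All patterns use the periodic temporal activation; ``dphi < 0`` puts the
    first source ahead in time (it reaches its cosine peak earlier).
    Amplitudes are density-normalised (1/det(cov)^{1/2} in 2D scales as
    1/sigma^2 for isotropic sources) so each module carries comparable total
    activation regardless of its spread.

    plane
        Identical isotropic Gaussians (sigma = 1) abutting at the concavity
        boundary: centers 2 sigma apart along the propagation axis.
    radial
        Co-centered Gaussians, the earlier one tighter (sigma 0.75 vs 1.5):
        activation appears to expand outward from the shared center.
    spiral_like
        Two anisotropic Gaussians with orthogonal major axes (cov
        diag(4, 0.25) then diag(0.25, 4)), centers offset by one unit on
        each axis: latencies sweep around the array corner-to-corner.
    """
    if kind not in _PATTERNS:
        raise ValueError(f"unknown pattern kind {kind!r}; choose from {_PATTERNS}")
    if kind == "plane":
        c1, c2 = np.array([-1.0, 0.0]), np.array([1.0, 0.0])
        cov1 = cov2 = np.eye(2)
    elif kind == "radial":
        c1 = c2 = np.zeros(2)
        cov1 = np.eye(2) * 0.75**2
        cov2 = np.eye(2) * 1.5**2
    else:  # spiral_like
        c1, c2 = np.array([-0.5, -0.5]), np.array([0.5, 0.5])
        cov1 = np.diag([2.0**2, 0.5**2])
        cov2 = np.diag([0.5**2, 2.0**2])
    mk = lambda c, cov, ph: SpatioTemporalSource(
        center_x=c,
        spatial_scale=cov,
        temporal_mode="periodic",
        frequency=frequency,
        phase=ph,
        amplitude=1.0 / float(np.sqrt(np.linalg.det(cov))),
    )
    return SourcePair(mk(c1, cov1, -dphi / 2.0), mk(c2, cov2, dphi / 2.0))


def pattern_latency_map(
    kind: str, extent: float = 2.0, n_side: int = 21
) -> tuple[np.ndarray, np.ndarray, float]:
    """Latency map and PLDC for a 2D pattern on a square sampling grid.

    The field is evaluated over one oscillation period (a periodic trace has
    exactly one maximum per cycle, so a one-period window gives a
    wrap-free latency per point).  Returns (points, latencies, pldc); the
    PLDC is the Pearson correlation of latency with distance from the
    earliest-latency point (radial/spiral) or with position along the
    propagation axis (plane).
    """
    from scipy.stats import pearsonr

    pair = make_pattern(kind)
    xs = np.linspace(-extent, extent, n_side)
    X, Y = np.meshgrid(xs, xs)
    pts = np.column_stack([X.ravel(), Y.ravel()])
    period = 1.0 / pair.first.frequency
    t = np.linspace(-period / 2, period / 2, 2001, endpoint=False)
    grid = evaluate_potential(pair, FieldGrid(x=pts, t=t))
    lat = first_max_latency_map(grid)
    if kind == "plane":
        coord = pts[:, 0]
    else:
        start = pts[int(np.argmin(lat))]
        coord = np.hypot(pts[:, 0] - start[0], pts[:, 1] - start[1])
    pldc = float(pearsonr(coord, lat)[0])
    return pts, lat, pldc


# ---------------------------------------------------------------------------
# latency maps and PLDC scans
# ---------------------------------------------------------------------------

def first_max_latency_map(grid: FieldGrid) -> np.ndarray:
    """Per-sample-point latency: time of the first temporal maximum of V.

    The model/EEG-style latency convention; the first strict local temporal
    maximum is used (falling back to the global argmax for monotone traces).
    """
    if grid.potential is None:
        raise ValueError("grid has no evaluated potential")
    V = grid.potential
    lat = np.empty(V.shape[0])
    for i, trace in enumerate(V):
        interior = np.flatnonzero((trace[1:-1] > trace[:-2]) & (trace[1:-1] > trace[2:]))
        idx = interior[0] + 1 if interior.size else int(np.argmax(trace))
        lat[i] = grid.t[idx]
    return lat


def _pldc_1d(x: np.ndarray, lat: np.ndarray) -> float:
    """Pearson correlation of latency with coordinate along the propagation axis."""
    from scipy.stats import pearsonr

    if np.ptp(lat) == 0 or np.ptp(x) == 0:
        return float("nan")
    return float(pearsonr(x, lat)[0])


def pldc_scan(
    dx_values: Sequence[float],
    delay_values: Sequence[float],
    sigma_x: float = 1.0,
    sigma_t: float = 1.0,
    n_x: int = 201,
    n_t: int = 801,
) -> np.ndarray:
    """PLDC over a (dx, delay) grid for the symmetric transient pair.

    For each combination the 1D field is sampled between the sources
    (+- dx/2 +- 2 sigma_x), latencies are first-maximum times, and the PLDC
    is the Pearson correlation of latency with position along the axis.
    Undefined correlations (zero-variance latencies) are returned as NaN.
    """
    out = np.full((len(dx_values), len(delay_values)), np.nan)
    for i, dx in enumerate(dx_values):
        for j, dt in enumerate(delay_values):
            pair = gaussian_pair(dx, sigma_x, dt, sigma_t)
            x = np.linspace(-dx / 2 - 2 * sigma_x, dx / 2 + 2 * sigma_x, n_x)
            st = sigma_t
            t = np.linspace(-abs(dt) / 2 - 4 * st, abs(dt) / 2 + 4 * st, n_t)
            g = evaluate_potential(pair, FieldGrid(x=x, t=t))
            out[i, j] = _pldc_1d(x, first_max_latency_map(g))
    return out
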