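"""Hartigan's dip statistic, bootstrap p-values, and paired LFP/spike comparisons.

The dip of an empirical distribution is the smallest sup-norm distance
between its CDF and any unimodal CDF (convex up to a mode, concave after).
It is the statistic used here to quantify whether one-dimensional onset
samples (LFP phase-crossing times vs. spike or ALSA onset times) deviate
from unimodality: modular, sequentially activated populations give clearly
bimodal onset samples and a large dip, while smoothly graded samples stay
near the 1/(2n) floor.

Implementation notes
--------------------
The statistic is computed with the classical iterative greatest-convex-
minorant / least-concave-majorant refinement: on the current candidate
modal interval the GCM and LCM of the empirical CDF are built (monotone-
chain hulls over (x_i, i)), the largest GCM-LCM separation locates the
next, tighter modal interval, and the deviations of the empirical CDF
from the GCM below it and from the LCM above it accumulate into the dip;
iteration stops when the separation no longer exceeds the accumulated
deviation.  Count-unit distances are halved and scaled by 1/n at the end,
which also yields the 1/(2n) floor.  The implementation is validated in
the test suite against a brute-force linear-programming minimisation over
unimodal CDFs at small n.

The bootstrap null follows the worst-case-unimodal convention: dips of
uniform(0, 1) samples of the same size (n_boot = 500 by default), with the
p-value floored at 1/(n_boot + 1).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .layout import ElectrodeLayout
from .spikes import OnsetSet
from .waves import Wave, compute_plm

__all__ = [
    "DipResult",
    "PairedComparison",
    "dip_statistic",
    "dip_pvalue",
    "paired_comparison",
]


@dataclass(frozen=True)
class DipResult:
    """Dip statistic with its bootstrap p-value."""

    dip: float
    pvalue: float
    n: int
    n_boot: int
    seed: int | None = None

    @property
    def at_floor(self) -> bool:
        """True when p hit the bootstrap resolution floor 1/(n_boot+1)."""
        return self.pvalue <= 1.0 / (self.n_boot + 1)


def _lower_hull(x: np.ndarray, low: int, high: int) -> list[int]:
    """Monotone-chain lower convex hull indices of (x_i, i) on [low, high]."""
    hull = [low]
    for j in range(low + 1, high + 1):
        while len(hull) >= 2:
            i1, i2 = hull[-2], hull[-1]
            if (x[j] - x[i1]) * (i2 - i1) >= (x[i2] - x[i1]) * (j - i1):
                hull.pop()
            else:
                break
        hull.append(j)
    return hull


def _upper_hull(x: np.ndarray, low: int, high: int) -> list[int]:
    """Monotone-chain upper concave hull indices of (x_i, i) on [low, high]."""
    hull = [low]
    for j in range(low + 1, high + 1):
        while len(hull) >= 2:
            i1, i2 = hull[-2], hull[-1]
            if (x[j] - x[i1]) * (i2 - i1) <= (x[i2] - x[i1]) * (j - i1):
                hull.pop()
            else:
                break
        hull.append(j)
    return hull


def dip_statistic(sample: Sequence[float]) -> float:
    """Hartigan & Hartigan's dip of a one-dimensional sample.

    Bounded by 1/(2n) <= dip <= 0.25; invariant under affine maps and
    reflection of the sample (but not general monotone transforms, which
    reshape the spacings the statistic measures).
    """
    x = np.sort(np.asarray(sample, dtype=float))
    n = x.size
    if n < 2:
        raise ValueError("dip requires at least 2 finite values")
    if not np.all(np.isfinite(x)):
        raise ValueError("dip requires finite values")
    if x[0] == x[-1]:
        return 1.0 / (2.0 * n)  # point mass: floor by convention
    low, high = 0, n - 1
    dip = 1.0  # count units; 1 <-> the 1/(2n) floor after scaling
    while True:
        gcm = _lower_hull(x, low, high)[::-1]  # gcm[0] = high ... gcm[-1] = low
        lcm = _upper_hull(x, low, high)  # lcm[0] = low ... lcm[-1] = high
        l_gcm, l_lcm = len(gcm), len(lcm)
        ix, iv = l_gcm - 2, 1
        ig, ih = l_gcm - 1, 0
        d = 0.0
        if l_gcm != 2 or l_lcm != 2:
            # walk both curves from low to high, recording the largest
            # LCM-above-GCM separation and the modal interval attaining it
            while True:
                gcmix, lcmiv = gcm[ix], lcm[iv]
                if gcmix > lcmiv:
                    a = gcm[ix + 1]  # GCM chord [a, gcmix] spans x[lcmiv]
                    if x[gcmix] == x[a]:
                        interp = float(gcmix - a)
                    else:
                        interp = (x[lcmiv] - x[a]) * (gcmix - a) / (x[gcmix] - x[a])
                    dx = (lcmiv - a + 1) - interp
                    iv += 1
                    if dx >= d:
                        d = dx
                        ig, ih = ix + 1, iv - 1
                else:
                    b = lcm[iv - 1]  # LCM chord [b, lcmiv] spans x[gcmix]
                    if x[lcmiv] == x[b]:
                        interp = float(lcmiv - b)
                    else:
                        interp = (x[gcmix] - x[b]) * (lcmiv - b) / (x[lcmiv] - x[b])
                    dx = interp - (gcmix - b - 1)
                    ix -= 1
                    if dx >= d:
                        d = dx
                        ig, ih = ix + 1, iv
                if ix < 0:
                    ix = 0
                if iv > l_lcm - 1:
                    iv = l_lcm - 1
                if gcm[ix] == lcm[iv]:
                    break
        else:
            d = 1.0
        if d <= dip:
            break
        # ecdf deviation from the GCM between the modal edge and low
        dip_l = 0.0
        for j in range(ig, l_gcm - 1):
            jb, je = gcm[j + 1], gcm[j]
            max_t = 1.0
            if je - jb > 1 and x[je] != x[jb]:
                c_slope = (je - jb) / (x[je] - x[jb])
                for jj in range(jb, je + 1):
                    t = (jj - jb + 1) - (x[jj] - x[jb]) * c_slope
                    if t > max_t:
                        max_t = t
            if max_t > dip_l:
                dip_l = max_t
        # ecdf deviation from the LCM between the modal edge and high
        dip_u = 0.0
        for j in range(ih, l_lcm - 1):
            jb, je = lcm[j], lcm[j + 1]
            max_t = 1.0
            if je - jb > 1 and x[je] != x[jb]:
                c_slope = (je - jb) / (x[je] - x[jb])
                for jj in range(jb, je + 1):
                    t = (x[jj] - x[jb]) * c_slope - (jj - jb - 1)
                    if t > max_t:
                        max_t = t
            if max_t > dip_u:
                dip_u = max_t
        dip = max(dip, dip_l, dip_u)
        new_low, new_high = gcm[ig], lcm[ih]
        if new_low == low and new_high == high:
            break
        low, high = new_low, new_high
    return float(dip / (2.0 * n))


def _null_dips(n: int, n_boot: int, rng: np.random.Generator) -> np.ndarray:
    return np.array([dip_statistic(rng.uniform(0.0, 1.0, n)) for _ in range(n_boot)])


def dip_pvalue(
    sample: Sequence[float],
    n_boot: int = 500,
    seed: int = 0,
    _null: np.ndarray | None = None,
) -> DipResult:
    """Bootstrap p-value against the uniform (worst-case unimodal) null.

    p is the proportion of ``n_boot`` uniform(0, 1) samples of the same
    size whose dip is at least the observed dip, floored at
    1/(n_boot + 1).
    """
    x = np.asarray(sample, dtype=float)
    obs = dip_statistic(x)
    if _null is None:
        _null = _null_dips(x.size, n_boot, np.random.default_rng(seed))
    p = float(np.mean(_null >= obs))
    p = max(p, 1.0 / (n_boot + 1))
    return DipResult(dip=obs, pvalue=p, n=x.size, n_boot=len(_null), seed=seed)


@dataclass
class PairedComparison:
    """Per-wave LFP-vs-onset dip results on matched channel subsets."""

    records: list[dict] = field(default_factory=list)
    skipped: list[dict] = field(default_factory=list)

    @property
    def p_lfp(self) -> np.ndarray:
        return np.array([r["p_lfp"] for r in self.records])

    @property
    def p_onset(self) -> np.ndarray:
        return np.array([r["p_onset"] for r in self.records])

    @property
    def median_p_lfp(self) -> float:
        return float(np.median(self.p_lfp)) if self.records else float("nan")

    @property
    def median_p_onset(self) -> float:
        return float(np.median(self.p_onset)) if self.records else float("nan")

    @property
    def median_p_difference(self) -> float:
        """Median over waves of p_lfp - p_onset."""
        if not self.records:
            return float("nan")
        return float(np.median(self.p_lfp - self.p_onset))

    def fraction_lfp_greater(self) -> float:
        """Fraction of waves with p_lfp > p_onset."""
        if not self.records:
            return float("nan")
        return float(np.mean(self.p_lfp > self.p_onset))


def paired_comparison(
    waves: Sequence[Wave],
    layout: ElectrodeLayout,
    onset_sets: Sequence[OnsetSet],
    n_boot: int = 500,
    min_channels: int = 4,
    seed: int = 0,
    wave_ids: Sequence | None = None,
) -> PairedComparison:
    """Dip LFP crossing times vs. onset times on the common channel subset.

    For each wave (paired with its OnsetSet), both samples are restricted
    to channels that have an onset AND a crossing in the wave; waves with
    fewer than ``min_channels`` common channels are skipped with a reason.
    The uniform bootstrap null is cached per sample size within one call.
    """
    if len(waves) != len(onset_sets):
        raise ValueError("waves and onset_sets must pair up one-to-one")
    rng = np.random.default_rng(seed)
    null_cache: dict[int, np.ndarray] = {}
    out = PairedComparison()
    ids = wave_ids if wave_ids is not None else range(len(waves))
    for wid, wave, onsets in zip(ids, waves, onset_sets):
        plm = compute_plm(wave, layout)
        common = sorted(set(plm.latencies) & set(onsets.onsets))
        if len(common) < min_channels:
            out.skipped.append(
                {"wave": wid, "reason": f"only {len(common)} common channels"}
            )
            continue
        lfp_times = np.array([plm.latencies[ch] for ch in common])
        onset_times = np.array([onsets.onsets[ch] for ch in common])
        n = len(common)
        if n not in null_cache:
            null_cache[n] = _null_dips(n, n_boot, rng)
        r_lfp = dip_pvalue(lfp_times, n_boot, _null=null_cache[n])
        r_on = dip_pvalue(onset_times, n_boot, _null=null_cache[n])
        out.records.append(
            {
                "wave": wid,
                "n_channels": n,
                "dip_lfp": r_lfp.dip,
                "p_lfp": r_lfp.pvalue,
                "dip_onset": r_on.dip,
                "p_onset": r_on.pvalue,
                "p_difference": r_lfp.pvalue - r_on.pvalue,
                "onset_kind": onsets.kind,
            }
        )
    return out
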