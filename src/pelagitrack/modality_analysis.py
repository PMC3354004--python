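"""Travel-speed modality: dip test, mode finding, foraging classification.

The scientific question is whether a travel-speed distribution is unimodal
(one transit mode, as for Eastern Pacific leatherbacks) or multimodal (a slow
foraging mode plus a fast transit mode, as in the North Atlantic). The tools:

* :func:`dip_statistic` — Hartigan & Hartigan's dip: the maximum over x of the
  minimal sup-distance between the empirical CDF and the class of unimodal
  CDFs, computed with the greatest-convex-minorant / least-concave-majorant
  iteration on the sorted sample.
* :func:`dip_test` — bootstrap calibration of the dip against the Uniform(0,1)
  null (the classical, least-favourable unimodal null), with an add-one
  p-value.
* :func:`speed_histogram` / :func:`find_modes` / :func:`modal_transiting_speed`
  — frequency-distribution machinery; the modal transiting speed is the mode
  whose histogram band holds the largest share of the data.
* :func:`classify_foraging` — steps at or below a fixed fraction (default
  40 %) of the modal transiting speed are flagged as putative foraging.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from numba import njit

__all__ = [
    "SpeedHistogram",
    "ModalityResult",
    "dip_statistic",
    "dip_test",
    "speed_histogram",
    "find_modes",
    "modal_transiting_speed",
    "classify_foraging",
    "analyze_speeds",
]


# ---------------------------------------------------------------------------
# dip statistic core
# ---------------------------------------------------------------------------
#
# Works on the unique sorted values u with cumulative counts: cl[k] counts
# strictly below u[k] (ECDF left limit * n), cu[k] counts <= u[k]. The
# greatest convex minorant (GCM) of the ECDF on a window is the lower convex
# hull of (u, cl); the least concave majorant (LCM) is the upper hull of
# (u, cu). The iteration shrinks the window to the candidate modal interval
# bracketing the largest GCM-LCM gap, accumulating the sup deviation of the
# ECDF from the convex fit left of it and from the concave fit right of it.
# The dip is half the largest accumulated deviation, in probability units.

@njit(cache=True)
def _dip_from_unique(u, cl, cu):  # pragma: no cover - exercised via wrapper
    m = u.shape[0]
    n = cu[m - 1]
    if m <= 1:
        return 0.0
    lo = 0
    hi = m - 1
    d_best = 0.0
    gidx = np.empty(m, np.int64)
    lidx = np.empty(m, np.int64)
    gval = np.empty(m, np.float64)
    lval = np.empty(m, np.float64)
    while hi - lo >= 1:
        # lower convex hull of (u, cl) over [lo, hi]
        gn = 0
        for k in range(lo, hi + 1):
            while gn >= 2:
                o = gidx[gn - 2]
                a = gidx[gn - 1]
                cross = (u[a] - u[o]) * (cl[k] - cl[o]) \
                    - (cl[a] - cl[o]) * (u[k] - u[o])
                if cross <= 0.0:
                    gn -= 1
                else:
                    break
            gidx[gn] = k
            gn += 1
        # upper concave hull of (u, cu) over [lo, hi]
        ln = 0
        for k in range(lo, hi + 1):
            while ln >= 2:
                o = lidx[ln - 2]
                a = lidx[ln - 1]
                cross = (u[a] - u[o]) * (cu[k] - cu[o]) \
                    - (cu[a] - cu[o]) * (u[k] - u[o])
                if cross >= 0.0:
                    ln -= 1
                else:
                    break
            lidx[ln] = k
            ln += 1
        # evaluate both piecewise-linear hull curves at every sample point
        si = 0
        for k in range(lo, hi + 1):
            while si + 1 < gn and gidx[si + 1] < k:
                si += 1
            j0 = gidx[si]
            j1 = gidx[si + 1] if si + 1 < gn else j0
            if j1 == j0:
                gval[k] = cl[j0]
            else:
                gval[k] = cl[j0] + (cl[j1] - cl[j0]) * (u[k] - u[j0]) \
                    / (u[j1] - u[j0])
        si = 0
        for k in range(lo, hi + 1):
            while si + 1 < ln and lidx[si + 1] < k:
                si += 1
            j0 = lidx[si]
            j1 = lidx[si + 1] if si + 1 < ln else j0
            if j1 == j0:
                lval[k] = cu[j0]
            else:
                lval[k] = cu[j0] + (cu[j1] - cu[j0]) * (u[k] - u[j0]) \
                    / (u[j1] - u[j0])
        # largest gap between the majorant and minorant curves
        d = -1.0
        kstar = lo
        for k in range(lo, hi + 1):
            g = lval[k] - gval[k]
            if g > d:
                d = g
                kstar = k
        if d <= d_best:
            break
        # modal interval: nearest hull vertices bracketing the gap
        newlo = lo
        for si in range(gn):
            if gidx[si] <= kstar:
                newlo = gidx[si]
            else:
                break
        newhi = hi
        for si in range(ln - 1, -1, -1):
            if lidx[si] >= kstar:
                newhi = lidx[si]
            else:
                break
        # sup deviation of the ECDF from the convex fit left of the modal
        # interval, and from the concave fit right of it. The jump at the
        # interval endpoint itself is excluded: a mode placed there absorbs
        # it, and if the mode lands deeper inside, the next iteration
        # re-anchors at this point and re-counts its jump.
        dl = 0.0
        for k in range(lo, newlo):
            t = cu[k] - gval[k]
            if t > dl:
                dl = t
        du = 0.0
        for k in range(newhi + 1, hi + 1):
            t = lval[k] - cl[k]
            if t > du:
                du = t
        if dl > d_best:
            d_best = dl
        if du > d_best:
            d_best = du
        if newlo == lo and newhi == hi:
            break
        lo = newlo
        hi = newhi
    return d_best / (2.0 * n)


@njit(cache=True)
def _dip_sorted(x):  # pragma: no cover - exercised via wrapper
    """Dip of a sorted 1-d sample; collapses ties internally."""
    n = x.shape[0]
    u = np.empty(n, np.float64)
    w = np.empty(n, np.float64)
    m = 0
    for i in range(n):
        if m > 0 and x[i] == u[m - 1]:
            w[m - 1] += 1.0
        else:
            u[m] = x[i]
            w[m] = 1.0
            m += 1
    cu = np.empty(m, np.float64)
    cl = np.empty(m, np.float64)
    tot = 0.0
    for k in range(m):
        cl[k] = tot
        tot += w[k]
        cu[k] = tot
    return _dip_from_unique(u[:m], cl, cu)


@njit(cache=True)
def _dip_batch(xs):  # pragma: no cover
    """Dips of each row of a 2-d array of sorted samples."""
    b = xs.shape[0]
    out = np.empty(b, np.float64)
    for i in range(b):
        out[i] = _dip_sorted(xs[i])
    return out


def dip_statistic(samples) -> float:
    """Hartigan's dip statistic of a sample (n >= 4; ties allowed).

    Invariant under strictly increasing affine transforms of the data, and
    bounded by 1/(2n) <= dip <= 0.25 for samples with at least two distinct
    values.
    """
    x = np.asarray(samples, dtype=float).ravel()
    if x.size < 4:
        raise ValueError("dip_statistic needs at least 4 observations")
    if not np.all(np.isfinite(x)):
        raise ValueError("dip_statistic requires finite values")
    return float(_dip_sorted(np.sort(x)))


@dataclass
class DipResult:
    dip: float
    p_value: float
    n: int
    n_boot: int


def dip_test(samples, n_boot: int = 2000, seed=None,
             rng: np.random.Generator | None = None) -> DipResult:
    """Dip test with a Uniform(0,1) bootstrap null.

    The p-value is the add-one bootstrap tail probability
    ``(1 + #{dip_boot >= dip_obs}) / (n_boot + 1)``, with bootstrap samples of
    the same size as the data drawn from the uniform distribution — the
    classical calibration for the dip (the uniform is the least favourable
    unimodal null, so the test is conservative for peaked unimodal data).
    """
    if n_boot < 100:
        raise ValueError("n_boot must be at least 100")
    x = np.asarray(samples, dtype=float).ravel()
    obs = dip_statistic(x)
    if rng is None:
        rng = np.random.default_rng(seed)
    boot = rng.random((int(n_boot), x.size))
    boot.sort(axis=1)
    boot_dips = _dip_batch(boot)
    p = (1.0 + np.count_nonzero(boot_dips >= obs)) / (n_boot + 1.0)
    return DipResult(dip=obs, p_value=float(p), n=int(x.size),
                     n_boot=int(n_boot))


# ---------------------------------------------------------------------------
# histograms and modes
# ---------------------------------------------------------------------------

@dataclass
class SpeedHistogram:
    """Uniform-width frequency distribution with half-open bins [kw, (k+1)w)."""

    bin_edges: np.ndarray
    counts: np.ndarray
    bin_width: float

    @property
    def bin_centers(self) -> np.ndarray:
        return 0.5 * (self.bin_edges[:-1] + self.bin_edges[1:])

    @property
    def n(self) -> int:
        return int(self.counts.sum())


def speed_histogram(speeds, bin_width: float = 5.0) -> SpeedHistogram:
    """Bin speeds into half-open bins [k*w, (k+1)*w) with the first edge at 0."""
    if bin_width <= 0:
        raise ValueError("bin_width must be positive")
    x = np.asarray(speeds, dtype=float).ravel()
    if x.size == 0:
        return SpeedHistogram(np.array([0.0]), np.array([], dtype=int),
                              bin_width)
    if np.any(x < 0):
        raise ValueError("negative speeds passed to speed_histogram "
                         "(upstream bug)")
    idx = np.floor(x / bin_width).astype(int)
    counts = np.bincount(idx)
    edges = np.arange(counts.size + 1) * bin_width
    return SpeedHistogram(bin_edges=edges, counts=counts, bin_width=bin_width)


def _candidate_peaks(counts: np.ndarray) -> list[int]:
    nb = counts.size
    cands = []
    for i in range(nb):
        left_ok = i == 0 or counts[i] >= counts[i - 1]
        right_ok = i == nb - 1 or counts[i] >= counts[i + 1]
        if left_ok and right_ok and counts[i] > 0:
            # collapse plateaus to their first bin
            if cands and counts[cands[-1]] == counts[i] \
                    and np.all(counts[cands[-1]:i + 1] == counts[i]):
                continue
            cands.append(i)
    return cands


def find_modes(hist: SpeedHistogram, min_prominence: float = 0.05) -> np.ndarray:
    """Bin centers of local maxima prominent above their adjacent troughs.

    A peak survives if its count exceeds the trough separating it from each
    neighbouring peak by at least ``min_prominence`` times the maximum count.
    The weakest failing peak is merged away iteratively. Returns centers
    sorted ascending; a monotone histogram yields its single terminal mode.
    """
    counts = np.asarray(hist.counts, dtype=float)
    if counts.size == 0:
        return np.array([])
    cands = _candidate_peaks(counts)
    thresh = min_prominence * counts.max()
    while len(cands) > 1:
        worst = None
        worst_count = np.inf
        for j, c in enumerate(cands):
            ok = True
            if j > 0:
                trough = counts[cands[j - 1]:c + 1].min()
                if counts[c] - trough < thresh:
                    ok = False
            if j < len(cands) - 1:
                trough = counts[c:cands[j + 1] + 1].min()
                if counts[c] - trough < thresh:
                    ok = False
            if not ok and counts[c] < worst_count:
                worst = j
                worst_count = counts[c]
        if worst is None:
            break
        cands.pop(worst)
    centers = hist.bin_centers
    return np.array(sorted(centers[c] for c in cands))


def modal_transiting_speed(hist: SpeedHistogram,
                           modes: np.ndarray) -> tuple[float, np.ndarray]:
    """Mode whose histogram band holds the most data, plus per-band masses.

    The histogram is partitioned at the minimum-count bin between each pair of
    adjacent modes (leftmost minimum on ties); each mode's band mass is the
    fraction of all counts in its partition. Ties in mass break toward the
    faster mode. A single mode returns mass 1.
    """
    modes = np.asarray(modes, dtype=float)
    if modes.size == 0:
        raise ValueError("modal_transiting_speed needs at least one mode")
    counts = np.asarray(hist.counts, dtype=float)
    centers = hist.bin_centers
    mode_bins = [int(np.argmin(np.abs(centers - m))) for m in np.sort(modes)]
    boundaries = []
    for a, b in zip(mode_bins[:-1], mode_bins[1:]):
        between = counts[a:b + 1]
        boundaries.append(a + int(np.argmin(between)))
    edges = [0] + boundaries + [counts.size]
    total = counts.sum()
    masses = np.array([counts[e0:e1].sum() / total
                       for e0, e1 in zip(edges[:-1], edges[1:])])
    # argmax with tie-break toward the faster (last) mode
    best = int(masses.size - 1 - np.argmax(masses[::-1]))
    return float(np.sort(modes)[best]), masses


def classify_foraging(speeds, modal_speed: float,
                      fraction: float = 0.4) -> tuple[np.ndarray, np.ndarray]:
    """Flag steps at <= ``fraction`` of the modal transiting speed (inclusive).

    Returns ``(mask, relative_speed_percent)`` where relative speed is
    ``100 * speed / modal_speed``.
    """
    if modal_speed <= 0:
        raise ValueError("modal_speed must be positive")
    if not 0 < fraction < 1:
        raise ValueError("fraction must lie in (0, 1)")
    x = np.asarray(speeds, dtype=float)
    rel = 100.0 * x / modal_speed
    return x <= fraction * modal_speed, rel


# ---------------------------------------------------------------------------
# one-stop summary
# ---------------------------------------------------------------------------

@dataclass
class ModalityResult:
    dip: float
    p_value: float
    n: int
    n_boot: int
    modes: np.ndarray
    modal_transiting_speed: float
    foraging_threshold: float
    band_masses: np.ndarray
    bin_width: float

    def to_dict(self) -> dict:
        return {
            "dip": self.dip,
            "p_value": self.p_value,
            "n": self.n,
            "n_boot": self.n_boot,
            "modes_kmd": list(map(float, self.modes)),
            "modal_transiting_speed_kmd": self.modal_transiting_speed,
            "foraging_threshold_kmd": self.foraging_threshold,
            "band_masses": list(map(float, self.band_masses)),
            "bin_width_kmd": self.bin_width,
        }


def analyze_speeds(speeds, bin_width: float = 5.0, n_boot: int = 2000,
                   seed=None, rng: np.random.Generator | None = None,
                   min_prominence: float = 0.05,
                   fraction: float = 0.4) -> ModalityResult:
    """Dip test on the raw speeds plus histogram-based mode selection.

    The dip test runs on the unbinned sample (the statistic is defined on
    empirical CDFs); the histogram only locates modes and band masses.
    """
    x = np.asarray(speeds, dtype=float).ravel()
    res = dip_test(x, n_boot=n_boot, seed=seed, rng=rng)
    hist = speed_histogram(x, bin_width=bin_width)
    modes = find_modes(hist, min_prominence=min_prominence)
    modal, masses = modal_transiting_speed(hist, modes)
    return ModalityResult(dip=res.dip, p_value=res.p_value, n=res.n,
                          n_boot=res.n_boot, modes=modes,
                          modal_transiting_speed=modal,
                          foraging_threshold=fraction * modal,
                          band_masses=masses, bin_width=bin_width)
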