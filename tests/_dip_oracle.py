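"""Exhaustive small-n dip oracle, independent of the production algorithm.

For a candidate mode location m, the distance from the empirical CDF to the
nearest unimodal CDF with mode m is found by linear programming: the unimodal
CDF is represented piecewise linearly with kinks only at the data points and
at m (lossless for this minimax problem, since the ECDF is constant between
data points), with a jump allowed at the mode. Constraints: the CDF stays
within +-eps of the ECDF (both the left limit and the right value at every
jump of the ECDF), is nondecreasing, convex left of the mode and concave
right of it. The dip is the minimum of eps over a fine grid of candidate
modes. Complexity is exponential-ish in grid size, so only for tiny n.
"""

from __future__ import annotations

import numpy as np
from scipy.optimize import linprog


def _eps_for_mode(u, cl, cu, m):
    """Minimal sup-distance to a unimodal CDF with mode at m (LP)."""
    # build point list: (x, lo_limit, hi_value); split the mode into two
    # variables (left/right of a possible jump)
    xs = list(u)
    # ECDF left limit / value at each x
    pts = [(x, cl[i], cu[i]) for i, x in enumerate(xs)]
    if m in u:
        i = list(u).index(m)
        lm, rm = cl[i], cu[i]
        pts = pts[:i] + pts[i + 1:]
    else:
        j = np.searchsorted(u, m)  # F constant at cu[j-1] around m
        lm = rm = cu[j - 1] if j > 0 else 0.0
    left = [p for p in pts if p[0] < m]
    right = [p for p in pts if p[0] > m]
    # variables: u-values for left pts, u_m_minus, u_m_plus, right pts, eps
    nL, nR = len(left), len(right)
    nv = nL + 2 + nR + 1
    ieps = nv - 1
    imL, imR = nL, nL + 1
    xcoord = [p[0] for p in left] + [m, m] + [p[0] for p in right]

    A_ub, b_ub = [], []

    def band(idx, lo_lim, hi_val):
        # |U - lo_lim| <= eps and |U - hi_val| <= eps
        for target in (lo_lim, hi_val):
            row = [0.0] * nv
            row[idx] = 1.0
            row[ieps] = -1.0
            A_ub.append(row)
            b_ub.append(target)          # U - eps <= target
            row = [0.0] * nv
            row[idx] = -1.0
            row[ieps] = -1.0
            A_ub.append(row)
            b_ub.append(-target)         # -U - eps <= -target
    for i, p in enumerate(left):
        band(i, p[1], p[2])
    band(imL, lm, lm)                    # left limit of U at the mode
    band(imR, rm, rm)                    # value of U at the mode
    for i, p in enumerate(right):
        band(imR + 1 + i, p[1], p[2])

    # monotone nondecreasing along all variables in x-order (incl. the jump)
    order = list(range(nL)) + [imL, imR] + [imR + 1 + i for i in range(nR)]
    for a, b in zip(order[:-1], order[1:]):
        row = [0.0] * nv
        row[a] = 1.0
        row[b] = -1.0
        A_ub.append(row)
        b_ub.append(0.0)

    # convex chain: left pts + mode-left; concave chain: mode-right + right
    chainL = list(range(nL)) + [imL]
    chainR = [imR] + [imR + 1 + i for i in range(nR)]

    def curvature(chain, sign):
        # sign=+1 enforces slope(b,c) >= slope(a,b) (convex);
        # sign=-1 the reverse (concave)
        for a, b, c in zip(chain[:-2], chain[1:-1], chain[2:]):
            xa, xb, xc = xcoord[a], xcoord[b], xcoord[c]
            row = [0.0] * nv
            row[a] = -sign / (xb - xa)
            row[b] = sign / (xb - xa) + sign / (xc - xb)
            row[c] = -sign / (xc - xb)
            A_ub.append(row)
            b_ub.append(0.0)
    curvature(chainL, 1.0)   # convex: slopes nondecreasing
    curvature(chainR, -1.0)  # concave: slopes nonincreasing

    cost = [0.0] * nv
    cost[ieps] = 1.0
    bounds = [(0.0, 1.0)] * (nv - 1) + [(0.0, 1.0)]
    res = linprog(cost, A_ub=np.array(A_ub), b_ub=np.array(b_ub),
                  bounds=bounds, method="highs")
    if not res.success:  # pragma: no cover
        raise RuntimeError(f"oracle LP failed for mode {m}: {res.message}")
    return res.fun


def dip_oracle(samples, modes_per_gap: int = 31) -> float:
    """Brute-force dip: minimize over candidate modes on a fine grid."""
    x = np.sort(np.asarray(samples, dtype=float))
    n = x.size
    u, counts = np.unique(x, return_counts=True)
    cum = np.cumsum(counts) / n
    cl = cum - counts / n
    cu = cum
    span = u[-1] - u[0] if u.size > 1 else 1.0
    grid = set(u)
    for a, b in zip(u[:-1], u[1:]):
        grid.update(np.linspace(a, b, modes_per_gap + 2)[1:-1])
    grid.add(u[0] - 0.05 * span)
    grid.add(u[-1] + 0.05 * span)
    best = np.inf
    for m in sorted(grid):
        best = min(best, _eps_for_mode(u, cl, cu, m))
    return float(best)
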