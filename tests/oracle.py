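"""Independent brute-force oracle for the local independence test.

A literal, per-cell, set-based transcription of the window recursion
and the statistic, written without any of the package's vectorised
machinery. Used only as the comparison target in tests.
"""

import math

import numpy as np
from scipy.stats import rankdata


def _sd(vals):
    return float(np.std(vals, ddof=1)) if len(vals) >= 2 else 0.0


def oracle_neighborhood(xv, yv, j, q0=0.1, max_iter=10):
    """Final bins (as sorted index lists) for center cell j."""
    n = len(xv)
    qx = rankdata(xv) / n
    qy = rankdata(yv) / n
    bx = {i for i in range(n) if abs(qx[i] - qx[j]) <= q0 / 2}
    by = {i for i in range(n) if abs(qy[i] - qy[j]) <= q0 / 2}
    # iteration 1: widths from the opposite gene's bin
    wx = _sd([xv[i] for i in by])
    wy = _sd([yv[i] for i in bx])
    bx = {i for i in range(n) if abs(xv[i] - xv[j]) <= wx}
    by = {i for i in range(n) if abs(yv[i] - yv[j]) <= wy}
    bx1, by1 = set(bx), set(by)
    converged = False
    for _t in range(2, max_iter + 1):
        if len(bx) <= 1 or len(by) <= 1:
            return sorted(bx1), sorted(by1), False
        wx = _sd([xv[i] for i in by])
        wy = _sd([yv[i] for i in bx])
        nbx = {i for i in range(n) if abs(xv[i] - xv[j]) <= wx}
        nby = {i for i in range(n) if abs(yv[i] - yv[j]) <= wy}
        if nbx == bx and nby == by:
            converged = True
            bx, by = nbx, nby
            break
        bx, by = nbx, nby
    if not converged:
        return sorted(bx1), sorted(by1), False
    return sorted(bx), sorted(by), True


def oracle_z(xv, yv, j, q0=0.1, max_iter=10):
    """z statistic for center cell j, gene pair (x, y)."""
    n = len(xv)
    bx, by, _ = oracle_neighborhood(xv, yv, j, q0, max_iter)
    nx, ny = len(bx), len(by)
    nxy = len(set(bx) & set(by))
    rho = nxy / n - nx * ny / (n * n)
    sig2 = nx * ny * (n - nx) * (n - ny) / (float(n) ** 4 * (n - 1))
    if xv[j] == 0 or yv[j] == 0 or sig2 == 0:
        return 0.0
    return rho / math.sqrt(sig2)


def oracle_network(values, j, q0=0.1, max_iter=10):
    """Full symmetric gene x gene z matrix for cell j."""
    g = values.shape[0]
    out = np.zeros((g, g))
    for x in range(g):
        for y in range(x + 1, g):
            out[x, y] = out[y, x] = oracle_z(values[x], values[y], j, q0, max_iter)
    return out
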