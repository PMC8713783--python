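"""Cell-specific coexpression networks from a local independence test.

For one cell j and one gene pair (x, y), define one-dimensional bins of
cells centred at cell j's expression values,

    B_x(j) = {i : |X_ix - X_jx| <= w_x},   n_x(j) = |B_x(j)|
    B_y(j) = {i : |X_iy - X_jy| <= w_y},   n_y(j) = |B_y(j)|
    B_xy(j) = B_x(j) ∩ B_y(j),             n_xy(j) = |B_xy(j)|

and compare the local joint frequency with the product of the marginals:

    rho_xy(j)   = n_xy(j)/N - n_x(j) n_y(j) / N^2
    sigma_xy(j)^2 = n_x(j) n_y(j) (N - n_x(j)) (N - n_y(j)) / (N^4 (N-1))
    z_xy(j)     = rho_xy(j) / sigma_xy(j)

z is asymptotically standard normal when x and y are independent near
cell j. As a preprocessing rule, z_xy(j) is fixed to 0 whenever cell j
has zero expression in either gene (dropout makes the local position of
such a cell uninformative). The window widths are chosen cell by cell by
an iterative local-SD rule: starting from rank-quantile bins of half
width q0/2, each iteration sets w_x to the SD of x over the *opposite*
gene's current bin (and vice versa), then rebuilds both bins; iteration
stops when both memberships are unchanged. If the iteration does not
converge within ``max_iter`` rounds, the iteration-1 bins are used.

Thresholding each z at the upper-alpha Gaussian quantile gives a 0/1
adjacency per cell; averaging adjacencies over the cells of one group
gives the fraction of cells rejecting independence per gene pair, a
coexpression-intensity estimate in [0, 1].

Networks should be built within homogeneous cell groups (one cell type,
or one pseudotime bin): pooling heterogeneous groups invites spurious
edges through Simpson's paradox when marker genes shift jointly across
types. N in all statistics is always the analysed group's size.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import squareform
from scipy.stats import norm, rankdata

from .io import ExpressionMatrix

__all__ = [
    "NeighborhoodState",
    "TestStatistic",
    "CellNetworkSet",
    "AvgNetwork",
    "find_neighborhood",
    "local_test_statistic",
    "compute_cell_network",
    "compute_group_networks",
    "threshold_adjacency",
    "average_network",
]


@dataclass
class NeighborhoodState:
    """Window state for one (cell, gene pair) local test."""

    cell_index: int
    gene_x: int
    gene_y: int
    w_x: float
    w_y: float
    bin_x: np.ndarray  # sorted cell indices in B_x(j)
    bin_y: np.ndarray
    n_x: int
    n_y: int
    n_xy: int
    iterations: int
    converged: bool


@dataclass
class TestStatistic:
    rho: float
    sigma: float
    z: float


@dataclass
class CellNetworkSet:
    """Per-cell network statistics for one homogeneous cell group.

    ``z`` holds the upper-triangle test statistics as an
    ``(n_cells, n_pairs)`` array in row-major pair order
    ((0,1), (0,2), ..., (1,2), ...); ``adjacency`` is the thresholded
    0/1 version once :func:`threshold_adjacency` has been applied.
    """

    gene_ids: list[str]
    cell_ids: list[str]
    z: np.ndarray | None
    group: str | None = None
    alpha: float | None = None
    adjacency: np.ndarray | None = None

    @property
    def n_cells(self) -> int:
        return len(self.cell_ids)

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    def z_matrix(self, cell: int) -> np.ndarray:
        """Symmetric gene x gene z matrix (zero diagonal) for one cell."""
        if self.z is None:
            raise ValueError("this network set stores adjacency only")
        return squareform(self.z[cell])

    def adjacency_matrix(self, cell: int) -> np.ndarray:
        if self.adjacency is None:
            raise ValueError("call threshold_adjacency first")
        return squareform(self.adjacency[cell].astype(float))

    def subset_cells(self, idx: list[int] | np.ndarray,
                     group: str | None = None) -> "CellNetworkSet":
        """Restrict to a cell subset (e.g. split a pooled computation
        into the two arms of a two-sample comparison). The statistics
        are untouched: they remain conditional on the full pooled
        sample they were computed in."""
        idx = np.asarray(idx, dtype=int)
        return CellNetworkSet(
            gene_ids=list(self.gene_ids),
            cell_ids=[self.cell_ids[i] for i in idx],
            z=None if self.z is None else self.z[idx],
            group=self.group if group is None else group,
            alpha=self.alpha,
            adjacency=None if self.adjacency is None else self.adjacency[idx],
        )

    def subset_genes(self, keep: list[int] | np.ndarray) -> "CellNetworkSet":
        """Restrict to a gene subset (pair statistics are unaffected by
        genes outside the pair, so this equals recomputation on the
        subset)."""
        keep = np.unique(np.asarray(keep, dtype=int))  # sorted, deduplicated
        g = self.n_genes
        iu, ju = np.triu_indices(g, k=1)
        pos = -np.ones(g, dtype=int)
        pos[keep] = np.arange(keep.size)
        sel = np.flatnonzero(np.isin(iu, keep) & np.isin(ju, keep))
        # reorder selected pairs to row-major order of the new indexing
        key = pos[iu[sel]] * keep.size + pos[ju[sel]]
        sel = sel[np.argsort(key)]
        return CellNetworkSet(
            gene_ids=[self.gene_ids[i] for i in keep],
            cell_ids=list(self.cell_ids),
            z=None if self.z is None else self.z[:, sel],
            group=self.group,
            alpha=self.alpha,
            adjacency=None if self.adjacency is None else self.adjacency[:, sel],
        )


@dataclass
class AvgNetwork:
    """Per-pair fraction of cells whose test rejects independence."""

    gene_ids: list[str]
    matrix: np.ndarray  # symmetric (G, G), zero diagonal, entries in [0, 1]
    n_cells: int
    alpha: float


# ---------------------------------------------------------------------------
# window iteration


def _row_sd(mask: np.ndarray, v: np.ndarray) -> np.ndarray:
    """Sample SD (ddof=1) of v over each boolean row of mask; 0 if <2 members."""
    n = mask.sum(axis=1)
    s = mask @ v
    ss = mask @ (v * v)
    with np.errstate(invalid="ignore", divide="ignore"):
        var = (ss - s * s / np.maximum(n, 1)) / np.maximum(n - 1, 1)
    var = np.where(n >= 2, np.maximum(var, 0.0), 0.0)
    return np.sqrt(var)


def _pair_windows(
    xv: np.ndarray,
    yv: np.ndarray,
    q0: float,
    max_iter: int,
    centers: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Iterated window bins for one gene pair, many center cells at once.

    Returns boolean membership matrices ``Bx``, ``By`` of shape (M, N)
    where row m is the final bin (over all N cells) of the m-th center
    (``centers`` defaults to all cells), the final widths ``wx``,
    ``wy``, the per-center iteration count and a convergence flag.
    Non-converged centers (including centers whose bins degenerate to a
    single member after iteration 1) carry their iteration-1 bins, per
    the fallback rule. Each center's iteration is independent of the
    others, so restricting ``centers`` is exact for the retained rows.
    """
    N = xv.size
    if centers is None:
        centers = np.arange(N)
    dx = np.abs(xv[None, :] - xv[centers][:, None])
    dy = np.abs(yv[None, :] - yv[centers][:, None])
    qx = rankdata(xv) / N
    qy = rankdata(yv) / N
    half = q0 / 2.0
    bx0 = np.abs(qx[None, :] - qx[centers][:, None]) <= half
    by0 = np.abs(qy[None, :] - qy[centers][:, None]) <= half
    # iteration 1: widths from the opposite gene's initial bin
    wx1 = _row_sd(by0, xv)
    wy1 = _row_sd(bx0, yv)
    bx1 = dx <= wx1[:, None]
    by1 = dy <= wy1[:, None]
    bx, by = bx1.copy(), by1.copy()
    wx, wy = wx1.copy(), wy1.copy()
    m = centers.size
    iters = np.ones(m, dtype=int)
    converged = np.zeros(m, dtype=bool)
    done = np.zeros(m, dtype=bool)
    for _ in range(2, max_iter + 1):
        act = ~done
        if not act.any():
            break
        # bins that shrank to a single member cannot yield an SD: treat as
        # non-convergence and keep the iteration-1 bins
        deg = act & ((bx.sum(axis=1) <= 1) | (by.sum(axis=1) <= 1))
        if deg.any():
            bx[deg] = bx1[deg]
            by[deg] = by1[deg]
            wx[deg] = wx1[deg]
            wy[deg] = wy1[deg]
            done |= deg
            act &= ~deg
        if not act.any():
            break
        idx = np.flatnonzero(act)
        wx_a = _row_sd(by[idx], xv)
        wy_a = _row_sd(bx[idx], yv)
        nbx = dx[idx] <= wx_a[:, None]
        nby = dy[idx] <= wy_a[:, None]
        same = np.all(nbx == bx[idx], axis=1) & np.all(nby == by[idx], axis=1)
        bx[idx] = nbx
        by[idx] = nby
        wx[idx] = wx_a
        wy[idx] = wy_a
        iters[idx] += 1
        conv_idx = idx[same]
        converged[conv_idx] = True
        done[conv_idx] = True
    # cells that never stabilised fall back to iteration-1 bins
    fb = ~done & ~converged
    bx[fb] = bx1[fb]
    by[fb] = by1[fb]
    wx[fb] = wx1[fb]
    wy[fb] = wy1[fb]
    return bx, by, wx, wy, iters, converged


def _pair_z(
    xv: np.ndarray, yv: np.ndarray, q0: float, max_iter: int
) -> np.ndarray:
    """z statistics for one gene pair, one value per center cell."""
    N = xv.size
    bx, by, _, _, _, _ = _pair_windows(xv, yv, q0, max_iter)
    nx = bx.sum(axis=1).astype(float)
    ny = by.sum(axis=1).astype(float)
    nxy = (bx & by).sum(axis=1).astype(float)
    return _z_from_counts(nx, ny, nxy, N, xv, yv)


def _z_from_counts(nx, ny, nxy, N, xv, yv) -> np.ndarray:
    rho = nxy / N - nx * ny / (N * N)
    sig2 = nx * ny * (N - nx) * (N - ny) / (float(N) ** 4 * (N - 1))
    with np.errstate(invalid="ignore", divide="ignore"):
        z = rho / np.sqrt(sig2)
    z = np.where(sig2 > 0, z, 0.0)
    return np.where((xv == 0) | (yv == 0), 0.0, z)


# ---------------------------------------------------------------------------
# public operations


def find_neighborhood(
    expr: ExpressionMatrix,
    j: int,
    x: int,
    y: int,
    q0: float = 0.1,
    max_iter: int = 10,
) -> NeighborhoodState:
    """Iteratively chosen window bins for cell j and gene pair (x, y).

    ``expr`` must already be restricted to one homogeneous group; N is
    its cell count. Requires N >= 3 (the window SD is meaningless below
    that).
    """
    N = expr.n_cells
    if N < 3:
        raise ValueError("need at least 3 cells to choose a window")
    if not 0 < q0 < 1:
        raise ValueError("q0 must be in (0, 1)")
    if max_iter < 1:
        raise ValueError("max_iter must be >= 1")
    xv = expr.values[x]
    yv = expr.values[y]
    bx, by, wx, wy, iters, conv = _pair_windows(xv, yv, q0, max_iter)
    bxj, byj = bx[j], by[j]
    return NeighborhoodState(
        cell_index=j,
        gene_x=x,
        gene_y=y,
        w_x=float(wx[j]),
        w_y=float(wy[j]),
        bin_x=np.flatnonzero(bxj),
        bin_y=np.flatnonzero(byj),
        n_x=int(bxj.sum()),
        n_y=int(byj.sum()),
        n_xy=int((bxj & byj).sum()),
        iterations=int(iters[j]),
        converged=bool(conv[j]),
    )


def local_test_statistic(
    nb: NeighborhoodState, N: int, x_j: float, y_j: float
) -> TestStatistic:
    """Local independence statistic from window counts.

    rho compares the joint window frequency with the product of the
    marginal frequencies; sigma is its asymptotic null SD; z = rho/sigma.
    z is fixed to 0 when the center cell has zero expression in either
    gene, and when sigma degenerates to 0 (a marginal window that is
    empty or covers all N cells carries no evidence against
    independence).
    """
    nx, ny, nxy = nb.n_x, nb.n_y, nb.n_xy
    if not (0 <= nxy <= min(nx, ny) <= N):
        raise ValueError("inconsistent window counts")
    rho = nxy / N - nx * ny / (N * N)
    sig2 = nx * ny * (N - nx) * (N - ny) / (float(N) ** 4 * (N - 1))
    sigma = float(np.sqrt(sig2))
    if x_j == 0 or y_j == 0 or sigma == 0:
        z = 0.0
    else:
        z = rho / sigma
    return TestStatistic(rho=float(rho), sigma=sigma, z=float(z))


def compute_cell_network(
    expr: ExpressionMatrix,
    j: int,
    q0: float = 0.1,
    max_iter: int = 10,
) -> np.ndarray:
    """Symmetric gene x gene z matrix (zero diagonal) for one cell."""
    if expr.n_genes < 2:
        raise ValueError("need at least 2 genes")
    g = expr.n_genes
    out = np.zeros((g, g), dtype=float)
    for x in range(g):
        for y in range(x + 1, g):
            zs = _pair_z(expr.values[x], expr.values[y], q0, max_iter)
            out[x, y] = out[y, x] = zs[j]
    return out


def compute_group_networks(
    expr: ExpressionMatrix,
    group_by: str = "cell_type",
    q0: float = 0.1,
    max_iter: int = 10,
    pseudotime_bins: np.ndarray | None = None,
) -> dict[str, CellNetworkSet]:
    """Per-cell networks computed separately within each cell group.

    ``group_by`` is ``"cell_type"`` (labels attached to ``expr``) or
    ``"pseudotime_bin"`` (pass per-cell bin labels via
    ``pseudotime_bins``). Groups with fewer than 3 cells are skipped
    with a warning. Within each group, N is the group size.
    """
    if group_by == "cell_type":
        if expr.cell_type is None:
            raise ValueError("cell_type labels are not attached")
        labels = np.asarray(expr.cell_type)
    elif group_by == "pseudotime_bin":
        if pseudotime_bins is None:
            raise ValueError("pseudotime_bins required for pseudotime grouping")
        labels = np.asarray(pseudotime_bins)
    else:
        raise ValueError("group_by must be 'cell_type' or 'pseudotime_bin'")
    out: dict[str, CellNetworkSet] = {}
    for lab in sorted({str(v) for v in labels}):
        idx = np.flatnonzero(labels.astype(str) == lab)
        if idx.size < 3:
            warnings.warn(f"group {lab!r} has {idx.size} cells (<3); skipped")
            continue
        sub = expr.subset_cells(idx)
        out[lab] = _network_set(sub, lab, q0, max_iter)
    return out


def _network_set(
    expr: ExpressionMatrix, group: str | None, q0: float, max_iter: int
) -> CellNetworkSet:
    g = expr.n_genes
    if g < 2:
        raise ValueError("need at least 2 genes")
    n_pairs = g * (g - 1) // 2
    z = np.zeros((expr.n_cells, n_pairs), dtype=float)
    p = 0
    for x in range(g):
        for y in range(x + 1, g):
            z[:, p] = _pair_z(expr.values[x], expr.values[y], q0, max_iter)
            p += 1
    return CellNetworkSet(
        gene_ids=list(expr.gene_ids),
        cell_ids=list(expr.cell_ids),
        z=z,
        group=group,
    )


def threshold_adjacency(
    nets: CellNetworkSet, alpha: float = 0.05, two_sided: bool = False
) -> CellNetworkSet:
    """Threshold z statistics into a 0/1 adjacency per cell.

    An edge is declared when z exceeds the upper-alpha standard normal
    quantile (one-sided by default: averaged networks measure
    coexpression intensity, which is positive by design). With
    ``two_sided``, |z| is compared against the alpha/2 quantile.
    """
    if not 0 < alpha < 1:
        raise ValueError("alpha must be in (0, 1)")
    if nets.z is None:
        raise ValueError("network set has no z statistics")
    if two_sided:
        cut = norm.ppf(1 - alpha / 2)
        adj = (np.abs(nets.z) > cut).astype(np.uint8)
    else:
        cut = norm.ppf(1 - alpha)
        adj = (nets.z > cut).astype(np.uint8)
    return CellNetworkSet(
        gene_ids=list(nets.gene_ids),
        cell_ids=list(nets.cell_ids),
        z=nets.z,
        group=nets.group,
        alpha=alpha,
        adjacency=adj,
    )


def average_network(nets: CellNetworkSet) -> AvgNetwork:
    """Fraction of cells whose test rejects, per gene pair."""
    if nets.adjacency is None:
        raise ValueError("call threshold_adjacency before averaging")
    if nets.n_cells == 0:
        raise ValueError("cannot average an empty network set")
    frac = nets.adjacency.mean(axis=0)
    return AvgNetwork(
        gene_ids=list(nets.gene_ids),
        matrix=squareform(frac),
        n_cells=nets.n_cells,
        alpha=float(nets.alpha),
    )
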