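"""Two-sample tests for differences between group-level networks.

Two complementary tests compare the networks of two cell groups (e.g.
case vs control within one cell type):

* **sLED** — a sparse leading-eigenvalue test on the difference of two
  gene x gene summary matrices (averaged cell-specific networks, or
  Pearson correlation of expression). The statistic is the sparse
  leading eigenvalue of ``s (A2 - A1)`` maximised over the sign
  ``s ∈ {+1, -1}``; per-gene leverage (squared loadings of the argmax
  eigenvector) localises the difference, and the "DN genes"
  (differential-network genes) are the minimal leverage-sorted prefix
  explaining 90% of the signal. Significance comes from a permutation
  null that reshuffles the cell-to-group assignment.
* **DISTp** — an omnibus energy-distance permutation test between the
  two samples of per-cell adjacency vectors; sensitive to generic
  distributional differences but not localising.

Permutation p-values use the add-one correction
``p = (1 + #{T_perm >= T_obs}) / (1 + n_perm)`` and are therefore never
zero and valid under exchangeability.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import cdist, pdist, squareform

from .csn import CellNetworkSet
from .io import ExpressionMatrix

__all__ = [
    "DiffTestResult",
    "sled_statistic",
    "sled_test",
    "distp_statistic",
    "distp_test",
    "adjust_pvalues",
]

DEFAULT_SPARSITY_GRID = (0.0, 0.1, 0.2, 0.3)


@dataclass
class DiffTestResult:
    method: str  # sled_csn | sled_pearson | distp
    statistic: float
    p_value: float
    n_permutations: int
    seed: int
    sparsity: float | None = None
    leverage: np.ndarray | None = None  # per gene, sums to 1 (sLED only)
    dn_genes: list[str] | None = None  # leverage-sorted 90% prefix (sLED only)
    gene_ids: list[str] | None = None


# ---------------------------------------------------------------------------
# sLED statistic


def _sparse_leading(M: np.ndarray, sparsity: float) -> tuple[float, np.ndarray]:
    """Sparse leading eigenvalue/vector of a symmetric matrix.

    ``sparsity`` in [0, 1) is the soft-threshold level as a fraction of
    the largest |component| of the power-iteration update; 0 reduces to
    the dense leading (most positive) eigenpair. Iteration runs on the
    shifted positive-definite matrix so it targets the most positive
    eigenvalue rather than the largest in modulus.
    """
    w, V = np.linalg.eigh(M)
    v = V[:, -1]
    lam = float(w[-1])
    if sparsity == 0.0:
        if v[np.argmax(np.abs(v))] < 0:  # deterministic sign
            v = -v
        return lam, v
    shift = abs(float(w[0])) + 1e-12
    P = M + shift * np.eye(M.shape[0])
    for _ in range(500):
        u = P @ v
        cut = sparsity * np.max(np.abs(u))
        u = np.sign(u) * np.maximum(np.abs(u) - cut, 0.0)
        nrm = np.linalg.norm(u)
        if nrm == 0.0:
            # all components thresholded away: keep the single largest
            u = np.zeros_like(v)
            u[np.argmax(np.abs(P @ v))] = 1.0
            nrm = 1.0
        u /= nrm
        if np.linalg.norm(u - v) < 1e-12:
            v = u
            break
        v = u
    if v[np.argmax(np.abs(v))] < 0:
        v = -v
    return float(v @ M @ v), v


def sled_statistic(
    A1: np.ndarray, A2: np.ndarray, sparsity: float = 0.0
) -> tuple[float, np.ndarray]:
    """Sparse leading eigenvalue of ±(A2 - A1), maximised over sign.

    Returns the statistic and the argmax unit loading vector. With
    ``sparsity`` 0 this equals max(lambda_max(D), -lambda_min(D)) for
    D = A2 - A1. When A1 == A2 the statistic is 0 and the loading is an
    arbitrary unit vector.
    """
    A1 = np.asarray(A1, float)
    A2 = np.asarray(A2, float)
    if A1.shape != A2.shape or A1.ndim != 2 or A1.shape[0] != A1.shape[1]:
        raise ValueError("A1 and A2 must be square matrices of equal shape")
    if not (np.allclose(A1, A1.T) and np.allclose(A2, A2.T)):
        raise ValueError("inputs must be symmetric")
    D = A2 - A1
    best = (-np.inf, None)
    for s in (1.0, -1.0):
        lam, v = _sparse_leading(s * D, sparsity)
        if lam > best[0]:
            best = (lam, v)
    return best[0], best[1]


def _leverage_and_dn(
    v: np.ndarray, gene_ids: list[str], frac: float = 0.9
) -> tuple[np.ndarray, list[str]]:
    lev = v**2
    tot = lev.sum()
    lev = lev / tot if tot > 0 else np.full_like(lev, 1.0 / lev.size)
    order = np.argsort(-lev, kind="stable")
    csum = np.cumsum(lev[order])
    k = int(np.searchsorted(csum, frac - 1e-12) + 1)
    k = min(k, lev.size)
    # include genes tied with the last included leverage value
    last = lev[order[k - 1]]
    while k < lev.size and np.isclose(lev[order[k]], last):
        k += 1
    return lev, [gene_ids[i] for i in order[:k]]


# ---------------------------------------------------------------------------
# group summaries and permutation machinery


def _avg_adjacency_summary(adj: np.ndarray) -> np.ndarray:
    return squareform(adj.mean(axis=0))


def _pearson_summary(values: np.ndarray) -> np.ndarray:
    # values: genes x cells; constant genes yield zero rows, not NaNs
    with np.errstate(invalid="ignore", divide="ignore"):
        c = np.corrcoef(values)
    c = np.nan_to_num(c, nan=0.0)
    np.fill_diagonal(c, 0.0)
    return c


def _check_gene_match(g1: list[str], g2: list[str]) -> None:
    if list(g1) != list(g2):
        raise ValueError("the two groups must share the same gene universe")


def sled_test(
    group1: CellNetworkSet | ExpressionMatrix,
    group2: CellNetworkSet | ExpressionMatrix,
    mode: str = "csn",
    n_perm: int = 500,
    seed: int = 0,
    sparsity: float | None = None,
    n_tune_perm: int = 50,
) -> DiffTestResult:
    """sLED two-sample test between two cell groups.

    ``mode="csn"`` takes two :class:`CellNetworkSet` objects with
    thresholded adjacency and compares the groups' averaged networks
    (permutations re-average the precomputed per-cell adjacencies — the
    networks themselves are never recomputed). ``mode="pearson"`` takes
    two :class:`ExpressionMatrix` groups and compares gene-gene Pearson
    correlation matrices, recomputed per permutation.

    When ``sparsity`` is None, the soft-threshold level is picked from a
    small grid by maximising the observed statistic's standardised
    exceedance over a *separate* batch of tuning permutations, so the
    reported p-value keeps its permutation validity.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    if mode == "csn":
        for g in (group1, group2):
            if not isinstance(g, CellNetworkSet):
                raise TypeError("mode='csn' expects CellNetworkSet inputs")
            if g.adjacency is None:
                raise ValueError("threshold_adjacency must be applied first")
            if g.n_cells < 3:
                raise ValueError("each group needs >= 3 cells")
        _check_gene_match(group1.gene_ids, group2.gene_ids)
        gene_ids = list(group1.gene_ids)
        pool = np.vstack([group1.adjacency, group2.adjacency]).astype(float)
        n1 = group1.n_cells

        def summary(rows: np.ndarray) -> np.ndarray:
            return _avg_adjacency_summary(pool[rows])

        method = "sled_csn"
    elif mode == "pearson":
        for g in (group1, group2):
            if not isinstance(g, ExpressionMatrix):
                raise TypeError("mode='pearson' expects ExpressionMatrix inputs")
            if g.n_cells < 3:
                raise ValueError("each group needs >= 3 cells")
        _check_gene_match(group1.gene_ids, group2.gene_ids)
        gene_ids = list(group1.gene_ids)
        pool = np.hstack([group1.values, group2.values]).T  # cells x genes
        n1 = group1.n_cells

        def summary(rows: np.ndarray) -> np.ndarray:
            return _pearson_summary(pool[rows].T)

        method = "sled_pearson"
    else:
        raise ValueError("mode must be 'csn' or 'pearson'")

    n_tot = pool.shape[0]
    obs_rows1 = np.arange(n1)
    obs_rows2 = np.arange(n1, n_tot)

    def stat_at(lam: float, rows1, rows2) -> tuple[float, np.ndarray]:
        return sled_statistic(summary(rows1), summary(rows2), lam)

    rng = np.random.default_rng(seed)
    if sparsity is None:
        sparsity = _tune_sparsity(stat_at, obs_rows1, obs_rows2, n_tot, n1,
                                  rng, n_tune_perm)
    observed, loading = stat_at(sparsity, obs_rows1, obs_rows2)
    exceed = 0
    for _ in range(n_perm):
        perm = rng.permutation(n_tot)
        t, _ = stat_at(sparsity, perm[:n1], perm[n1:])
        if t >= observed:
            exceed += 1
    p = (1 + exceed) / (1 + n_perm)
    lev, dn = _leverage_and_dn(loading, gene_ids)
    return DiffTestResult(
        method=method,
        statistic=float(observed),
        p_value=float(p),
        n_permutations=n_perm,
        seed=seed,
        sparsity=float(sparsity),
        leverage=lev,
        dn_genes=dn,
        gene_ids=gene_ids,
    )


def _tune_sparsity(stat_at, rows1, rows2, n_tot, n1, rng, n_tune_perm,
                   grid=DEFAULT_SPARSITY_GRID) -> float:
    """Pick the soft-threshold level maximising standardised exceedance."""
    perms = [rng.permutation(n_tot) for _ in range(n_tune_perm)]
    best = (-np.inf, grid[0])
    for lam in grid:
        obs, _ = stat_at(lam, rows1, rows2)
        null = np.array(
            [stat_at(lam, p[:n1], p[n1:])[0] for p in perms]
        )
        sd = null.std()
        score = (obs - null.mean()) / max(sd, 1e-12)
        if score > best[0]:
            best = (score, lam)
    return best[1]


# ---------------------------------------------------------------------------
# DISTp


def distp_statistic(S1: np.ndarray, S2: np.ndarray) -> float:
    """Energy distance between two samples of network vectors.

    E = 2/(nm) ΣΣ d(u_i, v_j) − 1/n² ΣΣ d(u_i, u_i') − 1/m² ΣΣ d(v_j, v_j')
    with d the Euclidean distance; nonnegative, and 0 iff the empirical
    distributions coincide.
    """
    S1 = np.atleast_2d(np.asarray(S1, float))
    S2 = np.atleast_2d(np.asarray(S2, float))
    if S1.shape[0] == 0 or S2.shape[0] == 0:
        raise ValueError("both groups must be nonempty")
    if S1.shape[1] != S2.shape[1]:
        raise ValueError("network vectors must have equal length")
    n, m = S1.shape[0], S2.shape[0]
    cross = cdist(S1, S2).sum()
    within1 = 2.0 * pdist(S1).sum() if n > 1 else 0.0
    within2 = 2.0 * pdist(S2).sum() if m > 1 else 0.0
    return float(2.0 * cross / (n * m) - within1 / n**2 - within2 / m**2)


def distp_test(
    nets1: CellNetworkSet,
    nets2: CellNetworkSet,
    n_perm: int = 500,
    seed: int = 0,
) -> DiffTestResult:
    """Energy-distance permutation test on per-cell adjacency vectors."""
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    for g in (nets1, nets2):
        if g.adjacency is None:
            raise ValueError("threshold_adjacency must be applied first")
        if g.n_cells < 3:
            raise ValueError("each group needs >= 3 cells")
    _check_gene_match(nets1.gene_ids, nets2.gene_ids)
    pool = np.vstack([nets1.adjacency, nets2.adjacency]).astype(float)
    n1 = nets1.n_cells
    n_tot = pool.shape[0]
    # precompute all pairwise distances once; permutations just reindex
    dmat = squareform(pdist(pool))
    observed = _energy_from_dmat(dmat, np.arange(n1), np.arange(n1, n_tot))
    rng = np.random.default_rng(seed)
    exceed = 0
    for _ in range(n_perm):
        perm = rng.permutation(n_tot)
        if _energy_from_dmat(dmat, perm[:n1], perm[n1:]) >= observed:
            exceed += 1
    p = (1 + exceed) / (1 + n_perm)
    return DiffTestResult(
        method="distp",
        statistic=float(observed),
        p_value=float(p),
        n_permutations=n_perm,
        seed=seed,
        gene_ids=list(nets1.gene_ids),
    )


def _energy_from_dmat(dmat: np.ndarray, idx1: np.ndarray, idx2: np.ndarray) -> float:
    n, m = idx1.size, idx2.size
    cross = dmat[np.ix_(idx1, idx2)].sum()
    w1 = dmat[np.ix_(idx1, idx1)].sum()
    w2 = dmat[np.ix_(idx2, idx2)].sum()
    return float(2.0 * cross / (n * m) - w1 / n**2 - w2 / m**2)


def adjust_pvalues(p_values, n_tests: int | None = None) -> np.ndarray:
    """Bonferroni adjustment: min(1, p * n_tests)."""
    p = np.asarray(
        [r.p_value if isinstance(r, DiffTestResult) else float(r) for r in p_values],
        dtype=float,
    )
    if n_tests is None:
        n_tests = p.size
    if n_tests < p.size:
        raise ValueError("n_tests must be >= number of results")
    return np.minimum(1.0, p * n_tests)
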