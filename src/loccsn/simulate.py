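"""Synthetic single-cell expression with controlled coexpression structure.

The generator emulates the statistical features the network method is
sensitive to, via a Gaussian copula: latent multivariate normal vectors
with exchangeable within-block correlation, pushed through lognormal
marginals to nonnegative expression, with independent mean-dependent
dropout (zeros). Two designs are provided:

* :func:`simulate_two_groups` — two cell populations sharing marginals,
  each with its own set of correlated gene blocks (e.g. one population
  in which a block of genes is pairwise correlated and one in which all
  genes are independent).
* :func:`simulate_simpson_mixture` — two cell types in which a marker
  gene pair is independent *within* each type but shifted upward in one
  type, so that pooling the types induces spurious correlation
  (Simpson's paradox).

Dropout probability is logistic in the log of the gene's mean: lowly
expressed genes drop out more often, mimicking scRNA-seq zero
inflation. The defaults (~10% zeros at the default mean) reflect data
of moderate sparsity such as pooled metacell profiles; raw UMI counts
are typically far sparser.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .io import ExpressionMatrix

__all__ = ["BlockSpec", "SimDesign", "simulate_two_groups", "simulate_simpson_mixture"]


@dataclass(frozen=True)
class BlockSpec:
    """A set of genes sharing exchangeable latent correlation rho."""

    genes: tuple[int, ...]
    rho: float

    def __post_init__(self):
        if not 0 <= self.rho < 1:
            raise ValueError("rho must be in [0, 1)")
        if len(set(self.genes)) != len(self.genes):
            raise ValueError("block gene indices must be distinct")


@dataclass
class SimDesign:
    """Design of a two-population coexpression simulation.

    Defaults describe the canonical benchmark: 200 cells per group, 30
    genes, a 10-gene block with latent correlation 0.7 present in group
    1 only, lognormal marginals of mean 2 (log-scale SD 0.5), and
    mean-dependent dropout.
    """

    n_cells: tuple[int, int] = (200, 200)
    n_genes: int = 30
    blocks_group1: tuple[BlockSpec, ...] = (BlockSpec(tuple(range(10)), 0.7),)
    blocks_group2: tuple[BlockSpec, ...] = ()
    base_mean: float | np.ndarray = 2.0
    log_sd: float = 0.5
    dropout_midpoint: float = np.log(0.5)  # log-mean at which dropout = 50%
    dropout_steepness: float = 1.5
    seed: int = 0

    def __post_init__(self):
        for blocks in (self.blocks_group1, self.blocks_group2):
            seen: set[int] = set()
            for b in blocks:
                if seen & set(b.genes):
                    raise ValueError("blocks within a group must be disjoint")
                seen |= set(b.genes)
                if max(b.genes, default=-1) >= self.n_genes:
                    raise ValueError("block gene index out of range")
        means = np.broadcast_to(
            np.asarray(self.base_mean, dtype=float), (self.n_genes,)
        )
        if np.any(means <= 0):
            raise ValueError("base means must be > 0")

    @property
    def gene_means(self) -> np.ndarray:
        return np.broadcast_to(
            np.asarray(self.base_mean, dtype=float), (self.n_genes,)
        ).copy()


def dropout_probability(
    mean: np.ndarray, midpoint: float, steepness: float
) -> np.ndarray:
    """P(zero) as a decreasing logistic function of log(mean)."""
    return 1.0 / (1.0 + np.exp(steepness * (np.log(mean) - midpoint)))


def _latent_block_normal(
    rng: np.random.Generator,
    n_cells: int,
    n_genes: int,
    blocks: tuple[BlockSpec, ...],
) -> np.ndarray:
    """Latent (n_genes, n_cells) N(0,1) draws, exchangeable rho in blocks."""
    z = rng.standard_normal((n_genes, n_cells))
    for b in blocks:
        if b.rho == 0 or len(b.genes) < 2:
            continue
        shared = rng.standard_normal(n_cells)
        g = np.asarray(b.genes)
        z[g] = np.sqrt(b.rho) * shared[None, :] + np.sqrt(1 - b.rho) * z[g]
    return z


def _lognormal_from_latent(
    z: np.ndarray, means: np.ndarray, log_sd: float
) -> np.ndarray:
    # location chosen so the marginal mean equals `means`
    mu = np.log(means) - 0.5 * log_sd**2
    return np.exp(mu[:, None] + log_sd * z)


def simulate_two_groups(design: SimDesign) -> ExpressionMatrix:
    """Two-population expression matrix with group-specific gene blocks.

    Cells of group g have latent exchangeable correlation ``rho`` within
    each of that group's blocks and are independent otherwise; marginals
    are identical across groups, so any detected network difference is
    purely a coexpression difference. Deterministic given
    ``design.seed``. Cell types are labelled ``"group1"``/``"group2"``.
    """
    rng = np.random.default_rng(design.seed)
    means = design.gene_means
    pdrop = dropout_probability(
        means, design.dropout_midpoint, design.dropout_steepness
    )
    mats = []
    labels = []
    for gi, (n, blocks) in enumerate(
        zip(design.n_cells, (design.blocks_group1, design.blocks_group2)), 1
    ):
        z = _latent_block_normal(rng, n, design.n_genes, blocks)
        x = _lognormal_from_latent(z, means, design.log_sd)
        drop = rng.random((design.n_genes, n)) < pdrop[:, None]
        x[drop] = 0.0
        mats.append(x)
        labels += [f"group{gi}"] * n
    values = np.concatenate(mats, axis=1)
    n_tot = values.shape[1]
    return ExpressionMatrix(
        values=values,
        gene_ids=[f"g{i}" for i in range(design.n_genes)],
        cell_ids=[f"c{i}" for i in range(n_tot)],
        cell_type=np.asarray(labels, dtype=object),
    )


def simulate_simpson_mixture(
    n_per_type: int = 500,
    shift: float = 2.0,
    n_genes: int = 2,
    log_sd: float = 0.5,
    base_mean: float = 2.0,
    seed: int = 0,
) -> ExpressionMatrix:
    """Two cell types with a marker pair independent within each type.

    Genes 0 and 1 (the marker pair) are independent of everything within
    both types, but their latent means are raised by ``shift`` latent-SD
    units in type 2. Pooling the two types then shows spurious marker
    correlation (for a balanced mixture the pooled latent correlation is
    (shift^2/4) / (shift^2/4 + 1), i.e. 0.5 at shift=2), while each type
    alone shows none. No dropout is applied: the paradox is a
    mixture effect, not a sparsity effect.
    """
    if shift < 0:
        raise ValueError("shift must be >= 0")
    if n_genes < 2:
        raise ValueError("need at least the marker pair")
    rng = np.random.default_rng(seed)
    means = np.full(n_genes, float(base_mean))
    mats = []
    for t, delta in ((1, 0.0), (2, float(shift))):
        z = rng.standard_normal((n_genes, n_per_type))
        z[0] += delta
        z[1] += delta
        mats.append(_lognormal_from_latent(z, means, log_sd))
    values = np.concatenate(mats, axis=1)
    labels = ["type1"] * n_per_type + ["type2"] * n_per_type
    return ExpressionMatrix(
        values=values,
        gene_ids=[f"g{i}" for i in range(n_genes)],
        cell_ids=[f"c{i}" for i in range(2 * n_per_type)],
        cell_type=np.asarray(labels, dtype=object),
    )
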