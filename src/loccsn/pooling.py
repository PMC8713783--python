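"""Metacell pooling and pseudotime binning.

Sparse single-cell profiles defeat a local independence test: most
statistics hit the zero rule. Pooling similar cells of one type into
metacells — disjoint groups whose expression is the member mean —
alleviates the sparsity while preserving within-type structure, and the
metacells are then treated as cells for network construction. Grouping
here is within-type agglomerative clustering (Ward linkage) in the
expression space of the analysed genes, cut at roughly
``n_cells / target_size`` clusters; every metacell is pure in cell type
by construction. Pseudotime (when present) is averaged per metacell.

For trajectory-resolved networks, metacells are subsequently divided
into equal-count pseudotime bins within each cell type, and a network
set is computed per bin.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.cluster import AgglomerativeClustering

from .io import ExpressionMatrix

__all__ = ["MetacellMap", "pool_metacells", "bin_by_pseudotime"]


@dataclass
class MetacellMap:
    """Partition of cells into pure-cell-type metacells."""

    members: list[np.ndarray]  # cell indices per metacell, disjoint, exhaustive
    cell_type: list[str]  # one label per metacell
    metacell_ids: list[str]


def pool_metacells(
    expr: ExpressionMatrix, target_size: int = 20
) -> tuple[ExpressionMatrix, MetacellMap]:
    """Pool cells into metacells of ~``target_size`` within each type.

    Returns the metacell expression matrix (per-gene mean of members;
    pseudotime averaged likewise when present) and the membership map.
    Requires cell-type labels.
    """
    if expr.cell_type is None:
        raise ValueError("pool_metacells requires cell_type labels")
    if target_size < 1:
        raise ValueError("target_size must be >= 1")
    labels = np.asarray(expr.cell_type)
    members: list[np.ndarray] = []
    types: list[str] = []
    for lab in sorted({str(v) for v in labels}):
        idx = np.flatnonzero(labels.astype(str) == lab)
        n = idx.size
        n_groups = max(1, int(round(n / target_size)))
        if n_groups >= n:
            assign = np.arange(n)
            n_groups = n
        elif n_groups == 1:
            assign = np.zeros(n, dtype=int)
        else:
            model = AgglomerativeClustering(n_clusters=n_groups, linkage="ward")
            assign = model.fit_predict(expr.values[:, idx].T)
        # deterministic metacell order: by lowest member index
        order = sorted(range(n_groups), key=lambda g: int(idx[assign == g].min()))
        for g in order:
            members.append(idx[assign == g])
            types.append(lab)
    mc_ids = [f"mc{i}" for i in range(len(members))]
    values = np.column_stack(
        [expr.values[:, m].mean(axis=1) for m in members]
    )
    pt = None
    if expr.pseudotime is not None:
        pt = np.asarray([expr.pseudotime[m].mean() for m in members])
    meta = ExpressionMatrix(
        values=values,
        gene_ids=list(expr.gene_ids),
        cell_ids=mc_ids,
        cell_type=np.asarray(types, dtype=object),
        pseudotime=pt,
    )
    return meta, MetacellMap(members=members, cell_type=types, metacell_ids=mc_ids)


def bin_by_pseudotime(expr: ExpressionMatrix, n_bins: int = 8) -> np.ndarray:
    """Equal-count pseudotime bin label per (meta)cell, within cell type.

    Within each cell type, cells are ordered by pseudotime (stable in
    the original index on ties) and split into ``n_bins`` contiguous
    groups whose sizes differ by at most one. Returned labels are
    ``"<type>/bin<k>"`` with k ordered by pseudotime; without cell-type
    labels a single global binning is used (labels ``"bin<k>"``).
    """
    if expr.pseudotime is None:
        raise ValueError("bin_by_pseudotime requires pseudotime")
    if n_bins < 1:
        raise ValueError("n_bins must be >= 1")
    out = np.empty(expr.n_cells, dtype=object)
    if expr.cell_type is None:
        groups = [("", np.arange(expr.n_cells))]
    else:
        labels = np.asarray(expr.cell_type)
        groups = [
            (f"{lab}/", np.flatnonzero(labels.astype(str) == lab))
            for lab in sorted({str(v) for v in labels})
        ]
    for prefix, idx in groups:
        order = idx[np.argsort(expr.pseudotime[idx], kind="stable")]
        for k, chunk in enumerate(np.array_split(order, n_bins)):
            out[chunk] = f"{prefix}bin{k}"
    return out
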