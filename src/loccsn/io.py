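"""Reading and validating expression matrices; network triplet files.

Expression matrices are genes x cells, on any nonnegative monotone scale
(the downstream test is rank/threshold-local, so library normalisation or
log transformation upstream are both acceptable). No normalisation is
performed here. Cells whose expression is all zero across the analysed
genes are retained: the zero rule downstream gives them empty network
rows, and dropping them would destabilise cell indexing.

Supported formats:

* Matrix Market (``.mtx``) with 10x-style sidecars ``genes.tsv`` and
  ``barcodes.tsv`` in the same directory (one ID per line, first column
  used if tab-separated).
* Dense CSV/TSV with gene IDs in the first column and cell IDs in the
  header row.
* Per-cell label and pseudotime files as two-column TSV
  ``cell_id<TAB>value`` without a header.
* Network triplet files: ``#``-prefixed header lines declaring the gene
  ID order and value semantics, then ``cell_id<TAB>i<TAB>j<TAB>value``
  rows with 0-based gene indices, i < j.
"""

from __future__ import annotations

import os
import warnings
from dataclasses import dataclass, replace
from typing import Iterator, Mapping

import numpy as np
import pandas as pd
from scipy import io as spio
from scipy import sparse


class ExpressionFormatError(ValueError):
    """Structural problem in an input file (shape/ID mismatch)."""


class ExpressionValidationError(ValueError):
    """Values violate the expression-matrix invariants."""


@dataclass
class ExpressionMatrix:
    """Genes x cells nonnegative expression with optional annotations.

    Parameters
    ----------
    values
        Dense ``(n_genes, n_cells)`` float array, all entries finite
        and >= 0.
    gene_ids, cell_ids
        Unique ordered identifiers matching the matrix dimensions.
    cell_type
        Optional per-cell group label (string), e.g. a cell type from
        upstream clustering, or a pseudotime bin.
    pseudotime
        Optional per-cell scalar ordering along a trajectory.
    """

    values: np.ndarray
    gene_ids: list[str]
    cell_ids: list[str]
    cell_type: np.ndarray | None = None
    pseudotime: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ExpressionFormatError("expression matrix must be 2-D")
        g, c = self.values.shape
        self.gene_ids = [str(x) for x in self.gene_ids]
        self.cell_ids = [str(x) for x in self.cell_ids]
        if len(self.gene_ids) != g:
            raise ExpressionFormatError(
                f"{len(self.gene_ids)} gene IDs for {g} matrix rows"
            )
        if len(self.cell_ids) != c:
            raise ExpressionFormatError(
                f"{len(self.cell_ids)} cell IDs for {c} matrix columns"
            )
        if len(set(self.gene_ids)) != g:
            raise ExpressionFormatError("gene IDs are not unique")
        if len(set(self.cell_ids)) != c:
            raise ExpressionFormatError("cell IDs are not unique")
        if not np.all(np.isfinite(self.values)):
            raise ExpressionValidationError("non-finite expression value")
        if np.any(self.values < 0):
            raise ExpressionValidationError("negative expression value")
        if self.cell_type is not None:
            self.cell_type = np.asarray(self.cell_type, dtype=object)
            if self.cell_type.shape != (c,):
                raise ExpressionFormatError("cell_type length mismatch")
        if self.pseudotime is not None:
            self.pseudotime = np.asarray(self.pseudotime, dtype=float)
            if self.pseudotime.shape != (c,):
                raise ExpressionFormatError("pseudotime length mismatch")
            if not np.all(np.isfinite(self.pseudotime)):
                raise ExpressionValidationError("non-finite pseudotime")

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_cells(self) -> int:
        return self.values.shape[1]

    def subset_cells(self, idx: np.ndarray) -> "ExpressionMatrix":
        """New matrix restricted to the cells in ``idx`` (index array)."""
        idx = np.asarray(idx)
        return ExpressionMatrix(
            values=self.values[:, idx],
            gene_ids=list(self.gene_ids),
            cell_ids=[self.cell_ids[i] for i in idx],
            cell_type=None if self.cell_type is None else self.cell_type[idx],
            pseudotime=None if self.pseudotime is None else self.pseudotime[idx],
        )

    def iter_groups(self) -> Iterator[tuple[str, "ExpressionMatrix"]]:
        """Yield ``(label, submatrix)`` per cell type, in label order."""
        if self.cell_type is None:
            raise ValueError("cell_type labels are not attached")
        labels = np.asarray(self.cell_type)
        for lab in sorted(set(labels.tolist())):
            yield lab, self.subset_cells(np.flatnonzero(labels == lab))


def read_expression(
    path: str | os.PathLike,
    fmt: str | None = None,
    transpose: bool = False,
) -> ExpressionMatrix:
    """Read an expression matrix from MTX (with sidecars) or CSV/TSV.

    ``fmt`` is inferred from the suffix when omitted. ``transpose``
    coerces a cells x genes file to the genes x cells orientation.
    """
    path = os.fspath(path)
    if fmt is None:
        fmt = "mtx" if path.endswith(".mtx") else "csv"
    if fmt == "mtx":
        mat = spio.mmread(path)
        if sparse.issparse(mat):
            mat = mat.toarray()
        mat = np.asarray(mat, dtype=float)
        d = os.path.dirname(path)
        gene_ids = _read_id_column(os.path.join(d, "genes.tsv"))
        cell_ids = _read_id_column(os.path.join(d, "barcodes.tsv"))
    elif fmt == "csv":
        sep = "\t" if path.endswith((".tsv", ".txt")) else ","
        df = pd.read_csv(path, sep=sep, index_col=0)
        mat = df.to_numpy(dtype=float)
        gene_ids = [str(x) for x in df.index]
        cell_ids = [str(x) for x in df.columns]
    else:
        raise ValueError(f"unknown format {fmt!r}")
    if transpose:
        mat = mat.T
        gene_ids, cell_ids = cell_ids, gene_ids
    return ExpressionMatrix(values=mat, gene_ids=gene_ids, cell_ids=cell_ids)


def _read_id_column(path: str) -> list[str]:
    if not os.path.exists(path):
        raise ExpressionFormatError(f"missing sidecar file {path}")
    ids = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if line:
                ids.append(line.split("\t")[0])
    return ids


def read_cell_annotation(path: str | os.PathLike) -> dict[str, str]:
    """Read a two-column TSV (cell_id, value) into a dict."""
    df = pd.read_csv(path, sep="\t", header=None, dtype=str)
    if df.shape[1] < 2:
        raise ExpressionFormatError("annotation file needs two columns")
    return dict(zip(df[0], df[1]))


def attach_labels(
    expr: ExpressionMatrix,
    labels: Mapping[str, str],
    drop_unlabeled: bool = False,
) -> ExpressionMatrix:
    """Attach cell-type labels; returns a new ExpressionMatrix.

    Every cell must be labelled unless ``drop_unlabeled`` is set, in
    which case unlabelled cells are removed. Labels for unknown cell IDs
    raise a warning and are ignored.
    """
    known = set(expr.cell_ids)
    extra = [k for k in labels if k not in known]
    if extra:
        warnings.warn(f"{len(extra)} label(s) for unknown cell IDs ignored")
    missing = [c for c in expr.cell_ids if c not in labels]
    if missing and not drop_unlabeled:
        raise ExpressionFormatError(
            f"{len(missing)} cell(s) without a label (e.g. {missing[0]!r}); "
            "pass drop_unlabeled=True to drop them"
        )
    keep = [i for i, c in enumerate(expr.cell_ids) if c in labels]
    out = expr.subset_cells(np.asarray(keep, dtype=int)) if missing else expr
    out = replace(
        out,
        cell_type=np.asarray([labels[c] for c in out.cell_ids], dtype=object),
    )
    return out


def attach_pseudotime(
    expr: ExpressionMatrix, pseudotime: Mapping[str, float]
) -> ExpressionMatrix:
    """Attach per-cell pseudotime values (all cells must be covered)."""
    missing = [c for c in expr.cell_ids if c not in pseudotime]
    if missing:
        raise ExpressionFormatError(
            f"{len(missing)} cell(s) without pseudotime (e.g. {missing[0]!r})"
        )
    return replace(
        expr,
        pseudotime=np.asarray(
            [float(pseudotime[c]) for c in expr.cell_ids], dtype=float
        ),
    )


# ---------------------------------------------------------------------------
# network triplet files


def write_networks(nets, path: str | os.PathLike, kind: str = "z") -> None:
    """Write a CellNetworkSet as a plain-text triplet TSV.

    Header lines (``#``-prefixed) declare the gene ID order, the value
    semantics (``z`` statistics or 0/1 ``adjacency``), the group label
    and, for adjacency, the significance level used. Each data row is
    ``cell_id  i  j  value`` with 0-based gene indices against the
    declared order and i < j (matrices are symmetric; only the upper
    triangle is stored). z values round-trip to <= 1e-12 relative,
    adjacency exactly.
    """
    from .csn import CellNetworkSet  # local import to avoid a cycle

    if not isinstance(nets, CellNetworkSet):
        raise TypeError("write_networks expects a CellNetworkSet")
    if kind not in ("z", "adjacency"):
        raise ValueError("kind must be 'z' or 'adjacency'")
    if kind == "adjacency" and nets.adjacency is None:
        raise ValueError("network set has no thresholded adjacency")
    vals = nets.z if kind == "z" else nets.adjacency
    iu, ju = np.triu_indices(len(nets.gene_ids), k=1)
    with open(path, "w") as fh:
        fh.write("# loccsn network triplets v1\n")
        fh.write(f"# kind: {kind}\n")
        fh.write(f"# genes: {','.join(nets.gene_ids)}\n")
        fh.write(f"# cells: {','.join(nets.cell_ids)}\n")
        fh.write(f"# group: {nets.group if nets.group is not None else ''}\n")
        if nets.alpha is not None:
            fh.write(f"# alpha: {nets.alpha!r}\n")
        for ci, cell in enumerate(nets.cell_ids):
            row = vals[ci]
            nz = np.flatnonzero(row)
            for p in nz:
                v = row[p]
                sval = f"{int(v)}" if kind == "adjacency" else repr(float(v))
                fh.write(f"{cell}\t{iu[p]}\t{ju[p]}\t{sval}\n")


def read_networks(path: str | os.PathLike):
    """Read a triplet TSV written by :func:`write_networks`."""
    from .csn import CellNetworkSet

    kind = None
    gene_ids: list[str] = []
    declared: list[str] | None = None
    group: str | None = None
    alpha: float | None = None
    rows: list[tuple[str, int, int, float]] = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line:
                continue
            if line.startswith("#"):
                body = line[1:].strip()
                if body.startswith("kind:"):
                    kind = body.split(":", 1)[1].strip()
                elif body.startswith("genes:"):
                    gene_ids = body.split(":", 1)[1].strip().split(",")
                elif body.startswith("cells:"):
                    cells_declared = body.split(":", 1)[1].strip()
                    declared = cells_declared.split(",") if cells_declared else []
                elif body.startswith("group:"):
                    group = body.split(":", 1)[1].strip() or None
                elif body.startswith("alpha:"):
                    alpha = float(body.split(":", 1)[1])
                continue
            cell, i, j, v = line.split("\t")
            i, j = int(i), int(j)
            if j <= i:
                raise ExpressionFormatError("triplet indices must satisfy i < j")
            rows.append((cell, i, j, float(v)))
    if kind not in ("z", "adjacency") or not gene_ids:
        raise ExpressionFormatError("missing or invalid triplet header")
    if declared is not None:
        cell_order = list(declared)
        seen = {c: i for i, c in enumerate(cell_order)}
        unknown = [c for c, *_ in rows if c not in seen]
        if unknown:
            raise ExpressionFormatError(
                f"triplet for undeclared cell {unknown[0]!r}"
            )
    else:  # legacy files without a cells header: order of first appearance
        cell_order = []
        seen = {}
        for cell, *_ in rows:
            if cell not in seen:
                seen[cell] = len(cell_order)
                cell_order.append(cell)
    g = len(gene_ids)
    n_pairs = g * (g - 1) // 2
    iu, ju = np.triu_indices(g, k=1)
    pair_pos = {(int(a), int(b)): p for p, (a, b) in enumerate(zip(iu, ju))}
    vals = np.zeros((len(cell_order), n_pairs), dtype=float)
    filled: set[tuple[int, int, int]] = set()
    for cell, i, j, v in rows:
        ci = seen[cell]
        key = (ci, i, j)
        if key in filled:
            raise ExpressionFormatError(f"duplicate triplet for {key}")
        filled.add(key)
        vals[ci, pair_pos[(i, j)]] = v
    net = CellNetworkSet(
        gene_ids=gene_ids, cell_ids=cell_order, z=vals, group=group, alpha=alpha
    )
    if kind == "adjacency":
        net.adjacency = vals.astype(np.uint8)
        net.z = None
    return net
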