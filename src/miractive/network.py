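"""The signed miRNA-influence design matrix.

The interaction network is encoded as a sparse genes x miRNAs matrix N with
N[g, j] = -1 when miRNA j targets gene g and 0 otherwise.  The -1 encodes
the canonical repressive direction of miRNA action: a positive influence
coefficient on a miRNA column therefore pushes its targets' differential
expression down.  No interaction strengths are assumed — every retained edge
contributes exactly -1.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import scipy.io
import scipy.sparse as sp

from .io import EdgeList, ValidationError

logger = logging.getLogger(__name__)

__all__ = [
    "SignedTargetMatrix",
    "build_influence_matrix",
    "target_degree_summary",
    "export_mtx",
]


@dataclass(frozen=True)
class SignedTargetMatrix:
    """Sparse genes x miRNAs design matrix with entries in {-1, 0}.

    ``pruned_mirna_ids`` records miRNAs dropped because none of their targets
    appear in the gene space: their influence would be unidentifiable, and
    downstream consensus reports them as not assessable rather than inactive.
    """

    matrix: sp.csc_matrix
    gene_ids: tuple[str, ...]
    mirna_ids: tuple[str, ...]
    pruned_mirna_ids: tuple[str, ...] = field(default=())

    def __post_init__(self) -> None:
        if self.matrix.shape != (len(self.gene_ids), len(self.mirna_ids)):
            raise ValidationError("matrix shape inconsistent with id lists")
        if self.matrix.nnz and self.matrix.data.min() != -1:
            raise ValidationError("entries must be exactly -1 or 0")
        if self.matrix.nnz and self.matrix.data.max() != -1:
            raise ValidationError("entries must be exactly -1 or 0")
        col_nnz = np.diff(self.matrix.indptr)
        if np.any(col_nnz == 0):
            empty = [self.mirna_ids[j] for j in np.flatnonzero(col_nnz == 0)]
            raise ValidationError(f"all-zero miRNA columns present: {empty[:10]}")

    @property
    def shape(self) -> tuple[int, int]:
        return self.matrix.shape

    @property
    def n_edges(self) -> int:
        return int(self.matrix.nnz)

    def dense(self) -> np.ndarray:
        """Dense Fortran-ordered copy, the layout the solver wants."""
        return np.asfortranarray(self.matrix.toarray())

    def target_counts(self) -> np.ndarray:
        return np.diff(self.matrix.indptr)


def build_influence_matrix(
    edges: EdgeList,
    gene_order: Sequence[str],
    mirna_order: Sequence[str],
) -> SignedTargetMatrix:
    """Assemble the signed design matrix over given gene and miRNA orders.

    Edges whose miRNA or gene id falls outside the supplied vocabularies are
    dropped (count logged); miRNA columns left without any retained target
    are removed and recorded in ``pruned_mirna_ids``.
    """
    if not gene_order or not mirna_order:
        raise ValidationError("gene_order and mirna_order must be non-empty")
    gene_idx = {g: i for i, g in enumerate(gene_order)}
    mirna_idx = {m: j for j, m in enumerate(mirna_order)}
    if len(gene_idx) != len(gene_order) or len(mirna_idx) != len(mirna_order):
        raise ValidationError("gene_order and mirna_order must be duplicate-free")

    rows, cols = [], []
    dropped = 0
    for m, g in edges.edges:
        gi = gene_idx.get(g)
        mj = mirna_idx.get(m)
        if gi is None or mj is None:
            dropped += 1
            continue
        rows.append(gi)
        cols.append(mj)
    if dropped:
        logger.info("dropped %d edges outside the given id vocabularies", dropped)
    if not rows:
        raise ValidationError("no edges retained; cannot build an influence matrix")

    mat = sp.csc_matrix(
        (np.full(len(rows), -1.0), (rows, cols)),
        shape=(len(gene_order), len(mirna_order)),
    )
    col_nnz = np.diff(mat.indptr)
    keep = np.flatnonzero(col_nnz > 0)
    pruned = tuple(mirna_order[j] for j in np.flatnonzero(col_nnz == 0))
    if pruned:
        logger.info(
            "pruned %d miRNAs without targets in the gene space", len(pruned)
        )
        mat = mat[:, keep]
    if mat.shape[1] == 0:
        raise ValidationError("all miRNA columns empty after pruning")
    return SignedTargetMatrix(
        matrix=mat.tocsc(),
        gene_ids=tuple(gene_order),
        mirna_ids=tuple(mirna_order[j] for j in keep),
        pruned_mirna_ids=pruned,
    )


def target_degree_summary(matrix: SignedTargetMatrix) -> tuple[dict[str, int], float]:
    """Per-miRNA target counts and the median count over miRNAs."""
    counts = matrix.target_counts()
    per_mirna = {m: int(c) for m, c in zip(matrix.mirna_ids, counts)}
    return per_mirna, float(np.median(counts))


def export_mtx(matrix: SignedTargetMatrix, path: str | Path) -> None:
    """Dump the sparse design matrix in MatrixMarket format for audit."""
    scipy.io.mmwrite(str(path), matrix.matrix)
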