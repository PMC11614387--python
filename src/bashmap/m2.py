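"""Mutate-and-map heatmaps from a randomly point-mutated probing pool.

Row m of the heatmap is the misincorporation-rate profile computed from the
subset of full-length reads that carry a mutation at position m; stacking the
rows gives an L x L matrix in which an interaction between m and j appears as
elevated rate at column j of row m.  Because baseline rates differ wildly
between columns, each column is Z-scored across rows; only positive Z
(reactivity increases caused by the installed mutation) are kept in the
clipped variant used for display and detection.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .io_formats import ReadSet

__all__ = ["M2Matrix", "m2_matrix", "column_zscore"]


@dataclass
class M2Matrix:
    """L x L mutate-and-map matrices (1-based axes: row=mutation, col=mapped).

    ``raw`` holds rates (NaN on the diagonal and for rows with fewer than
    ``min_reads`` mutated reads); ``z``/``clipped`` are filled by
    :func:`column_zscore`.
    """

    raw: np.ndarray
    row_counts: np.ndarray
    min_reads: int
    z: np.ndarray | None = None
    clipped: np.ndarray | None = None

    @property
    def L(self) -> int:
        return self.raw.shape[0]

    def row_missing(self) -> np.ndarray:
        return self.row_counts < self.min_reads


def m2_matrix(rs: ReadSet, min_reads: int = 50) -> M2Matrix:
    """Build the mutate-and-map rate matrix from full-length reads.

    Row m pools every read with bit 1 at m; reads carrying several mutations
    therefore contribute to several rows.  The diagonal (the installed
    mutation itself) is set missing, as are rows supported by fewer than
    ``min_reads`` reads.
    """
    if not rs.all_full_length():
        raise ValueError("m2_matrix requires full-length reads")
    bits = rs.to_matrix().astype(np.int64)
    counts = bits.sum(axis=0)  # reads mutated at each position
    co = bits.T @ bits  # co[m, j] = reads mutated at both m and j
    with np.errstate(invalid="ignore", divide="ignore"):
        raw = co / np.maximum(counts[:, None], 1)
    raw = raw.astype(float)
    raw[counts == 0, :] = np.nan
    np.fill_diagonal(raw, np.nan)
    raw[counts < min_reads, :] = np.nan
    return M2Matrix(raw=raw, row_counts=counts, min_reads=min_reads)


def column_zscore(mm: M2Matrix) -> M2Matrix:
    """Z-score each column over its non-missing rows; clip negatives to 0.

    A constant column (zero spread) maps to all-zero Z rather than blowing
    up.  Returns a new M2Matrix with ``z`` and ``clipped`` filled.
    """
    raw = mm.raw
    z = np.full_like(raw, np.nan)
    finite = np.isfinite(raw)
    for j in range(mm.L):
        col = raw[:, j]
        ok = finite[:, j]
        if ok.sum() == 0:
            continue
        mu = col[ok].mean()
        sd = col[ok].std()
        z[ok, j] = (col[ok] - mu) / sd if sd > 0 else 0.0
    clipped = np.where(np.isfinite(z), np.maximum(z, 0.0), np.nan)
    return M2Matrix(
        raw=raw,
        row_counts=mm.row_counts,
        min_reads=mm.min_reads,
        z=z,
        clipped=clipped,
    )
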