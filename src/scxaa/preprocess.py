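"""Quality control and counts -> FPKM conversion."""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .datamodel import CellMatrix, GeneAnnotation, QcConfig

__all__ = ["counts_to_fpkm", "qc_filter", "QcReport"]

log = logging.getLogger(__name__)


def counts_to_fpkm(matrix: CellMatrix, annotation: GeneAnnotation) -> CellMatrix:
    """Convert a raw-count matrix to FPKM.

    FPKM(g, c) = count(g, c) * 1e9 / (length_bp(g) * total_counts(c)).

    Raises if any gene lacks an annotated length or any cell has zero total
    counts (such cells should have been removed by QC first).
    """
    if matrix.unit != "count":
        raise ValueError("counts_to_fpkm expects a count matrix")
    lengths = annotation.gene_lengths(matrix.gene_ids).to_numpy(float)
    totals = matrix.values.sum(axis=0).to_numpy(float)
    zero_cells = matrix.cell_ids[totals == 0]
    if len(zero_cells):
        raise ValueError(
            f"{len(zero_cells)} cell(s) with zero total counts, e.g. "
            f"{list(zero_cells[:5])}"
        )
    fpkm = matrix.values.to_numpy(float) * 1e9 / (lengths[:, None] * totals[None, :])
    return CellMatrix(
        values=pd.DataFrame(fpkm, index=matrix.gene_ids, columns=matrix.cell_ids),
        unit="FPKM",
        tissue=matrix.tissue,
        donor=matrix.donor,
    )


@dataclass
class QcReport:
    """Outcome of cell/tissue quality control."""

    n_cells_in: int
    n_cells_removed: int
    n_cells_out: int
    tissue_excluded: bool


def qc_filter(matrix: CellMatrix, cfg: QcConfig) -> tuple[CellMatrix, QcReport]:
    """Drop low-quality cells, then flag the tissue if too few remain.

    A cell is removed when it detects strictly fewer than
    ``cfg.min_genes_per_cell`` genes (entries > 0); the whole matrix is
    flagged excluded when strictly fewer than ``cfg.min_cells_per_tissue``
    cells survive.  The (possibly empty) filtered matrix is always returned
    alongside the report.  Idempotent.
    """
    detected = (matrix.values.to_numpy() > 0).sum(axis=0)
    keep = detected >= cfg.min_genes_per_cell
    kept = matrix.values.loc[:, keep]
    report = QcReport(
        n_cells_in=matrix.n_cells,
        n_cells_removed=int((~keep).sum()),
        n_cells_out=int(keep.sum()),
        tissue_excluded=bool(keep.sum() < cfg.min_cells_per_tissue),
    )
    log.info(
        "QC %s: %d cells in, %d removed (<%d genes), %d kept%s",
        matrix.tissue or "<matrix>",
        report.n_cells_in,
        report.n_cells_removed,
        cfg.min_genes_per_cell,
        report.n_cells_out,
        " — tissue EXCLUDED" if report.tissue_excluded else "",
    )
    out = CellMatrix(values=kept, unit=matrix.unit, tissue=matrix.tissue, donor=matrix.donor)
    return out, report
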