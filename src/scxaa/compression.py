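"""Quantify sparsity and compression of single-cell data against bulk.

Per-cell OLS of log2 cell FPKM on log2 bulk FPKM (over genes above an
expression threshold in both profiles) summarizes compression: slopes
below 1 mean fold changes measured in bulk shrink in the cell.  A
one-sided Wilcoxon signed-rank test asks whether slopes sit below 1.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .datamodel import CellMatrix, ExpressionProfile

__all__ = [
    "CellRegression",
    "regress_cell_on_bulk",
    "regress_matrix_on_bulk",
    "sparsity_profile",
    "test_slopes_below_one",
]


@dataclass
class CellRegression:
    cell_id: str
    slope: float
    intercept: float
    pearson_r: float
    p_value: float
    n_genes_used: int
    threshold: float


def regress_cell_on_bulk(
    cell: ExpressionProfile, bulk: ExpressionProfile, threshold: float = 0.0
) -> CellRegression:
    """OLS of log2(cell) on log2(bulk) over genes > threshold in both."""
    common = cell.gene_ids.intersection(bulk.gene_ids)
    c = cell.values.loc[common].to_numpy()
    b = bulk.values.loc[common].to_numpy()
    use = (c > threshold) & (b > threshold)
    n = int(use.sum())
    if n < 2:
        raise ValueError(
            f"cell {cell.sample_id!r}: only {n} genes exceed threshold "
            f"{threshold} in both profiles; need >= 2"
        )
    res = stats.linregress(np.log2(b[use]), np.log2(c[use]))
    return CellRegression(
        cell_id=cell.sample_id,
        slope=float(res.slope),
        intercept=float(res.intercept),
        pearson_r=float(res.rvalue),
        p_value=float(res.pvalue),
        n_genes_used=n,
        threshold=float(threshold),
    )


def regress_matrix_on_bulk(
    cells: CellMatrix,
    bulk: ExpressionProfile,
    thresholds: tuple[float, ...] = (0.0, 1.0, 2.0, 5.0, 10.0),
    min_genes: int = 2,
) -> pd.DataFrame:
    """Per-cell regressions at each threshold; cells with too few usable
    genes at a threshold are skipped (counted via the returned rows)."""
    rows = []
    for t in thresholds:
        for cell_id in cells.cell_ids:
            try:
                reg = regress_cell_on_bulk(cells.cell(cell_id), bulk, t)
            except ValueError:
                continue
            if reg.n_genes_used >= min_genes:
                rows.append(reg.__dict__)
    return pd.DataFrame(rows)


def sparsity_profile(
    cells: CellMatrix, thresholds: tuple[float, ...] = (0.0, 1.0, 2.0, 5.0, 10.0)
) -> pd.DataFrame:
    """Fraction of genes exceeding each FPKM threshold, per cell.

    Returns a tidy frame (cell_id, threshold, fraction_detected); the
    denominator is every gene in the matrix.
    """
    vals = cells.values.to_numpy()
    rows = []
    for t in thresholds:
        frac = (vals > t).mean(axis=0)
        rows.append(
            pd.DataFrame(
                {"cell_id": cells.cell_ids, "threshold": t, "fraction_detected": frac}
            )
        )
    return pd.concat(rows, ignore_index=True)


def test_slopes_below_one(regressions: pd.DataFrame) -> pd.DataFrame:
    """One-sided Wilcoxon signed-rank of per-cell slopes against 1.

    One test per threshold; the summary also reports the maximum p-value
    across thresholds (the conservative display convention).
    """
    if len(regressions) == 0:
        raise ValueError("no regressions supplied")
    rows = []
    for t, grp in regressions.groupby("threshold"):
        diffs = grp["slope"].to_numpy() - 1.0
        if np.allclose(diffs, 0):
            p = 1.0
        else:
            p = float(stats.wilcoxon(diffs, alternative="less").pvalue)
        rows.append(
            {
                "threshold": t,
                "n_cells": len(grp),
                "median_slope": float(grp["slope"].median()),
                "p_value": p,
            }
        )
    out = pd.DataFrame(rows)
    out["max_p_across_thresholds"] = out["p_value"].max()
    return out
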