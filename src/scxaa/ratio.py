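"""X:AA expression-ratio estimators.

Two gene-selection strategies precede the ratio of median X-linked to
median autosomal expression within one transcriptional profile:

* **filter-by-expression** — keep every gene with FPKM strictly above an
  absolute threshold.  When X expression is truly halved this removes
  proportionally more X genes and inflates the ratio toward (or past) 1.
* **filter-by-fraction** — compute the fraction of genes above the
  threshold separately for X and autosomes, take the smaller fraction f,
  and keep the top f of *each* group ranked by expression.  Unbiased on
  bulk data with exact halving (returns 0.5).

The module also provides the Xe (X-inactivation escape) halving
sensitivity analysis and a per-cell sweep with the associated one-sided
and paired signed-rank tests.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .datamodel import CellMatrix, ExpressionProfile, GeneAnnotation

__all__ = [
    "XaaResult",
    "xaa_by_expression",
    "xaa_by_fraction",
    "halve_xe",
    "xaa_sweep",
    "xaa_columns",
]

STRATEGIES = ("by_expression", "by_fraction")
DEFAULT_THRESHOLDS = (0.0, 1.0, 2.0, 5.0, 10.0)


@dataclass
class XaaResult:
    profile_id: str
    strategy: str
    threshold: float
    xaa: float  # NaN when undefined (empty selection)
    n_x_used: int
    n_a_used: int
    fraction_used: float = np.nan  # by_fraction only


def _median_of_top(sorted_cols: np.ndarray, k: np.ndarray) -> np.ndarray:
    """Median of the k largest values per column of an ascending-sorted array.

    Vectorized: the top-k slice of column c is rows [n-k, n); its median is
    the midpoint of the middle one or two order statistics.
    """
    n, ncol = sorted_cols.shape
    k = np.asarray(k)
    cols = np.arange(ncol)
    safe_k = np.maximum(k, 1)
    lo = n - safe_k + (safe_k - 1) // 2
    hi = n - safe_k + safe_k // 2
    med = 0.5 * (sorted_cols[lo, cols] + sorted_cols[hi, cols])
    return np.where(k > 0, med, np.nan)


def xaa_columns(
    x_block: np.ndarray,
    a_block: np.ndarray,
    strategy: str,
    thresholds: tuple[float, ...],
) -> pd.DataFrame:
    """Vectorized X:AA for genes x cells blocks (one column per profile).

    Returns a tidy frame with one row per (column, threshold) carrying the
    ratio, group sizes used, and (for by_fraction) the selected fraction.
    Gene-count from fraction uses round-half-away-from-zero with a floor
    of one gene whenever the fraction is positive.
    """
    if strategy not in STRATEGIES:
        raise ValueError(f"unknown strategy {strategy!r}")
    x_sorted = np.sort(np.asarray(x_block, float), axis=0)
    a_sorted = np.sort(np.asarray(a_block, float), axis=0)
    nx, ncol = x_sorted.shape
    na = a_sorted.shape[0]
    rows = []
    for t in thresholds:
        mx = (x_sorted > t).sum(axis=0)
        ma = (a_sorted > t).sum(axis=0)
        if strategy == "by_expression":
            kx, ka = mx, ma
            frac = np.full(ncol, np.nan)
        else:
            f = np.minimum(mx / nx, ma / na)
            kx = np.where(f > 0, np.maximum(np.floor(f * nx + 0.5).astype(int), 1), 0)
            ka = np.where(f > 0, np.maximum(np.floor(f * na + 0.5).astype(int), 1), 0)
            frac = f
        med_x = _median_of_top(x_sorted, kx)
        med_a = _median_of_top(a_sorted, ka)
        with np.errstate(invalid="ignore", divide="ignore"):
            xaa = med_x / med_a
        xaa = np.where((kx > 0) & (ka > 0) & (med_a > 0), xaa, np.nan)
        rows.append(
            pd.DataFrame(
                {
                    "column": np.arange(ncol),
                    "strategy": strategy,
                    "threshold": t,
                    "xaa": xaa,
                    "n_x_used": kx,
                    "n_a_used": ka,
                    "fraction_used": frac,
                }
            )
        )
    return pd.concat(rows, ignore_index=True)


def _profile_blocks(
    profile: ExpressionProfile, ann: GeneAnnotation
) -> tuple[np.ndarray, np.ndarray]:
    x_ids = ann.x_genes.intersection(profile.gene_ids)
    a_ids = ann.autosomal_genes.intersection(profile.gene_ids)
    if len(x_ids) == 0 or len(a_ids) == 0:
        raise ValueError("profile has no annotated X or autosomal genes")
    x = profile.values.loc[x_ids].to_numpy()[:, None]
    a = profile.values.loc[a_ids].to_numpy()[:, None]
    return x, a


def _single(profile, ann, threshold, strategy) -> XaaResult:
    x, a = _profile_blocks(profile, ann)
    row = xaa_columns(x, a, strategy, (threshold,)).iloc[0]
    return XaaResult(
        profile_id=profile.sample_id,
        strategy=strategy,
        threshold=float(threshold),
        xaa=float(row["xaa"]),
        n_x_used=int(row["n_x_used"]),
        n_a_used=int(row["n_a_used"]),
        fraction_used=float(row["fraction_used"]),
    )


def xaa_by_expression(
    profile: ExpressionProfile, ann: GeneAnnotation, threshold: float = 0.0
) -> XaaResult:
    """X:AA with all genes strictly above an absolute FPKM threshold."""
    return _single(profile, ann, threshold, "by_expression")


def xaa_by_fraction(
    profile: ExpressionProfile, ann: GeneAnnotation, threshold: float = 0.0
) -> XaaResult:
    """X:AA from the top min-fraction of each gene group (see module doc)."""
    return _single(profile, ann, threshold, "by_fraction")


def halve_xe(profile: ExpressionProfile, ann: GeneAnnotation) -> ExpressionProfile:
    """Return a copy with every X-inactivation-escape gene's FPKM halved."""
    xe = ann.xe_genes.intersection(profile.gene_ids)
    values = profile.values.copy()
    values.loc[xe] = values.loc[xe] * 0.5
    return ExpressionProfile(f"{profile.sample_id}_xe_halved", values)


def _one_sided_tests(values: np.ndarray) -> dict:
    """Wilcoxon signed-rank of per-cell X:AA against 0.5 and against 1."""
    out = {"n_defined": int(np.isfinite(values).sum())}
    v = values[np.isfinite(values)]
    for name, null, alt in (("p_gt_0.5", 0.5, "greater"), ("p_lt_1", 1.0, "less")):
        if len(v) == 0 or np.allclose(v - null, 0):
            out[name] = 1.0
        else:
            out[name] = float(stats.wilcoxon(v - null, alternative=alt).pvalue)
    return out


def xaa_sweep(
    matrix: CellMatrix,
    ann: GeneAnnotation,
    strategies: tuple[str, ...] = STRATEGIES,
    thresholds: tuple[float, ...] = DEFAULT_THRESHOLDS,
    test_xe_halving: bool = False,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-cell X:AA across strategies and thresholds, with tests.

    Returns ``(results, tests)``: per-cell tidy results (including an
    ``xe_halved`` flag when the halving analysis is requested) and a test
    table with one-sided comparisons against 0.5 and 1, plus — when
    ``test_xe_halving`` — a paired signed-rank test between original and
    Xe-halved per-cell ratios.  Cells with undefined X:AA are excluded
    from the tests and counted via ``n_defined``.
    """
    if matrix.unit != "FPKM":
        raise ValueError("xaa_sweep requires an FPKM matrix")
    x_ids = ann.x_genes.intersection(matrix.gene_ids)
    a_ids = ann.autosomal_genes.intersection(matrix.gene_ids)
    if len(x_ids) == 0 or len(a_ids) == 0:
        raise ValueError("matrix has no annotated X or autosomal genes")
    variants = {False: matrix.values}
    if test_xe_halving:
        xe = ann.xe_genes.intersection(matrix.gene_ids)
        halved = matrix.values.copy()
        halved.loc[xe] = halved.loc[xe] * 0.5
        variants[True] = halved

    frames = []
    for halved_flag, vals in variants.items():
        xb = vals.loc[x_ids].to_numpy()
        ab = vals.loc[a_ids].to_numpy()
        for strat in strategies:
            df = xaa_columns(xb, ab, strat, thresholds)
            df["profile_id"] = matrix.cell_ids[df["column"]].to_numpy()
            df["xe_halved"] = halved_flag
            frames.append(df.drop(columns="column"))
    results = pd.concat(frames, ignore_index=True)

    test_rows = []
    for (strat, t, halved_flag), grp in results.groupby(
        ["strategy", "threshold", "xe_halved"]
    ):
        xa = grp["xaa"].to_numpy()
        row = {
            "strategy": strat,
            "threshold": t,
            "xe_halved": halved_flag,
            "median_xaa": float(np.nanmedian(xa)) if np.isfinite(xa).any() else np.nan,
        }
        row.update(_one_sided_tests(xa))
        if test_xe_halving and not halved_flag:
            orig = grp.set_index("profile_id")["xaa"]
            halv = (
                results[
                    (results["strategy"] == strat)
                    & (results["threshold"] == t)
                    & results["xe_halved"]
                ]
                .set_index("profile_id")["xaa"]
                .reindex(orig.index)
            )
            d = (orig - halv).to_numpy()
            d = d[np.isfinite(d)]
            if len(d) == 0 or np.allclose(d, 0):
                row["p_halving_decreases"] = 1.0
            else:
                row["p_halving_decreases"] = float(
                    stats.wilcoxon(d, alternative="greater").pvalue
                )
        test_rows.append(row)
    return results, pd.DataFrame(test_rows)
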