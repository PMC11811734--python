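"""Expression noise: CV, distance-to-median (DM), and group comparisons.

A gene's noise is its coefficient of variation (sd/mean of FPKM across
cells, zeros included).  Because CV depends strongly on the mean, each
gene's CV is corrected by the median CV of the ``window`` genes nearest
in expression rank (half below, half above, clipped at the extremes so
the window size is preserved): ``DM = CV − expected CV``.  DM is the
noise measure compared between X-linked and autosomal genes; genes with
DM > 1 are classified dosage-insensitive.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd
from numpy.lib.stride_tricks import sliding_window_view

from ._random import substream
from .datamodel import CellMatrix

__all__ = [
    "compute_cv",
    "compute_dm",
    "DmDifference",
    "dm_difference",
    "classify_sensitivity",
    "housekeeping_overlap",
    "InflationEstimate",
    "calibrate_inflation",
    "select_top_fraction",
]


def compute_cv(matrix: CellMatrix, ddof: int = 1) -> pd.DataFrame:
    """Per-gene mean and CV of FPKM across all cells (zeros included).

    Uses the sample standard deviation (``ddof=1``) by default; genes with
    mean 0 get CV = NaN and are excluded downstream.
    """
    if matrix.n_cells < 2:
        raise ValueError("need at least 2 cells to compute a CV")
    vals = matrix.values.to_numpy()
    mean = vals.mean(axis=1)
    sd = vals.std(axis=1, ddof=ddof)
    with np.errstate(invalid="ignore", divide="ignore"):
        cv = np.where(mean > 0, sd / mean, np.nan)
    return pd.DataFrame({"mean_fpkm": mean, "cv": cv}, index=matrix.gene_ids)


def _window_blocks(sorted_values: np.ndarray, window: int) -> tuple[np.ndarray, np.ndarray]:
    """For each rank i, the contiguous block of window+1 ranks containing i,
    as centered as possible; returns (block matrix, focal position in block)."""
    n = len(sorted_values)
    half = window // 2
    starts = np.clip(np.arange(n) - half, 0, n - window - 1)
    blocks = sliding_window_view(sorted_values, window + 1)[starts]
    focal_pos = np.arange(n) - starts
    return blocks, focal_pos


def compute_dm(table: pd.DataFrame, window: int = 100) -> pd.DataFrame:
    """Expected CV and DM for a per-gene (mean_fpkm, cv) table.

    Genes are sorted by mean (ties broken by gene ID); each focal gene's
    expected CV is the median CV of the ``window`` rank-nearest genes —
    ``window/2`` below and above in the interior, the deficit taken from
    the available side at the extremes — with the focal gene excluded from
    its own window.  Genes with undefined CV are left out of the ranking
    and get NaN DM.
    """
    if window < 2 or window % 2:
        raise ValueError("window must be an even integer >= 2")
    defined = table["cv"].notna() & table["mean_fpkm"].notna()
    n = int(defined.sum())
    if n < window + 1:
        raise ValueError(f"need at least window+1={window + 1} genes with CV, got {n}")
    sub = table.loc[defined]
    order = np.lexsort((sub.index.to_numpy(), sub["mean_fpkm"].to_numpy()))
    cv_sorted = sub["cv"].to_numpy()[order]
    blocks, focal_pos = _window_blocks(cv_sorted, window)
    blocks = blocks.astype(float).copy()
    blocks[np.arange(n), focal_pos] = np.nan  # exclude focal gene
    expected_sorted = np.nanmedian(blocks, axis=1)
    expected = np.empty(n)
    expected[order] = expected_sorted
    out = table.copy()
    out["expected_cv"] = np.nan
    out.loc[defined, "expected_cv"] = expected
    out["dm"] = out["cv"] - out["expected_cv"]
    out["window"] = window
    return out


def select_top_fraction(
    x_means: np.ndarray, a_means: np.ndarray, threshold: float
) -> tuple[np.ndarray, np.ndarray, float]:
    """Filter-by-fraction selection on per-gene means.

    Returns index arrays (into the X and A inputs) of the top-``f``
    most-expressed genes of each group, where f is the smaller of the two
    groups' fractions of genes above the threshold; rounding matches the
    X:AA estimator (half away from zero, floor one gene).
    """
    nx, na = len(x_means), len(a_means)
    f = min((x_means > threshold).mean(), (a_means > threshold).mean())
    if f == 0:
        return np.array([], dtype=int), np.array([], dtype=int), 0.0
    kx = max(1, int(np.floor(f * nx + 0.5)))
    ka = max(1, int(np.floor(f * na + 0.5)))
    ix = np.argsort(x_means, kind="stable")[::-1][:kx]
    ia = np.argsort(a_means, kind="stable")[::-1][:ka]
    return ix, ia, float(f)


@dataclass
class DmDifference:
    difference: float  # median(DM_X) - median(DM_A)
    ci_low: float
    ci_high: float
    n_x: int
    n_a: int
    threshold: float
    fraction_used: float


def dm_difference(
    x_table: pd.DataFrame,
    a_table: pd.DataFrame,
    threshold: float = 0.0,
    n_boot: int = 1000,
    ci: float = 0.90,
    rng: np.random.Generator | None = None,
    seed: int = 0,
) -> DmDifference:
    """Median DM of X genes minus median DM of autosomal genes.

    Both tables need ``mean_fpkm`` and ``dm`` columns; the filter-by-
    fraction selection is applied to the means before taking medians.
    The CI is a percentile bootstrap resampling genes with replacement
    within each group.
    """
    rng = rng if rng is not None else substream(seed, "dm_difference")
    xt = x_table.dropna(subset=["dm", "mean_fpkm"])
    at = a_table.dropna(subset=["dm", "mean_fpkm"])
    if len(xt) == 0 or len(at) == 0:
        raise ValueError("empty X or autosomal table")
    ix, ia, f = select_top_fraction(
        xt["mean_fpkm"].to_numpy(), at["mean_fpkm"].to_numpy(), threshold
    )
    if len(ix) == 0 or len(ia) == 0:
        raise ValueError(f"no genes pass threshold {threshold} in one group")
    dm_x = xt["dm"].to_numpy()[ix]
    dm_a = at["dm"].to_numpy()[ia]
    diff = float(np.median(dm_x) - np.median(dm_a))
    lo = hi = np.nan
    if n_boot > 0:
        bx = rng.choice(dm_x, size=(n_boot, len(dm_x)), replace=True)
        ba = rng.choice(dm_a, size=(n_boot, len(dm_a)), replace=True)
        boots = np.median(bx, axis=1) - np.median(ba, axis=1)
        alpha = (1 - ci) / 2
        lo, hi = np.quantile(boots, [alpha, 1 - alpha])
    return DmDifference(
        difference=diff,
        ci_low=float(lo),
        ci_high=float(hi),
        n_x=len(dm_x),
        n_a=len(dm_a),
        threshold=float(threshold),
        fraction_used=f,
    )


def classify_sensitivity(table: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Dosage-sensitivity calls: DM > 1 (strict) is insensitive.

    ``table`` needs ``dm`` and (for the group summary) ``chromosome_class``
    columns.  Returns ``(calls, summary)`` where the summary holds the
    insensitive fraction per chromosome class and the X/autosome quotient
    (values > 1 mean the X chromosome is enriched for insensitive genes).
    """
    t = table.dropna(subset=["dm"])
    calls = pd.DataFrame(
        {
            "dm": t["dm"],
            "call": np.where(t["dm"] > 1.0, "insensitive", "sensitive"),
        },
        index=t.index,
    )
    if "chromosome_class" in t.columns:
        calls["chromosome_class"] = t["chromosome_class"]
        summary = (
            calls.groupby("chromosome_class")["call"]
            .apply(lambda s: float((s == "insensitive").mean()))
            .rename("fraction_insensitive")
            .reset_index()
        )
        frac = dict(zip(summary["chromosome_class"], summary["fraction_insensitive"]))
        if frac.get("autosome", 0) > 0 and "X" in frac:
            summary.attrs["x_over_a_quotient"] = frac["X"] / frac["autosome"]
    else:
        summary = pd.DataFrame(
            {"chromosome_class": ["all"],
             "fraction_insensitive": [float((calls["call"] == "insensitive").mean())]}
        )
    return calls, summary


def housekeeping_overlap(
    tables: Mapping[str, pd.DataFrame],
    hk_threshold: float = 2.0,
    n_boot: int = 200,
    seed: int = 0,
) -> pd.DataFrame:
    """Sensitivity of housekeeping genes across tissues.

    Housekeeping genes are those with mean FPKM strictly above
    ``hk_threshold`` in EVERY tissue table.  Returns per-tissue fractions
    of housekeeping genes called sensitive (DM <= 1), with a bootstrap
    standard error over genes.  An empty housekeeping set yields an empty
    frame (flagged via attrs).
    """
    if not tables:
        raise ValueError("need at least one tissue table")
    hk: pd.Index | None = None
    for df in tables.values():
        genes = df.index[df["mean_fpkm"] > hk_threshold]
        hk = genes if hk is None else hk.intersection(genes)
    out_rows = []
    rng = substream(seed, "housekeeping")
    for tissue, df in tables.items():
        sub = df.loc[df.index.intersection(hk)].dropna(subset=["dm"])
        if len(sub) == 0:
            out_rows.append(
                {"tissue": tissue, "n_housekeeping": 0, "fraction_sensitive": np.nan,
                 "se": np.nan}
            )
            continue
        sens = (sub["dm"] <= 1.0).to_numpy()
        boots = rng.choice(sens.astype(float), size=(n_boot, len(sens))).mean(axis=1)
        out_rows.append(
            {
                "tissue": tissue,
                "n_housekeeping": len(sub),
                "fraction_sensitive": float(sens.mean()),
                "se": float(boots.std(ddof=1)),
            }
        )
    out = pd.DataFrame(out_rows)
    out.attrs["n_housekeeping_genes"] = 0 if hk is None else len(hk)
    out.attrs["empty_housekeeping_set"] = hk is None or len(hk) == 0
    return out


@dataclass
class InflationEstimate:
    percent: float
    extrapolated: bool


def calibrate_inflation(
    observed_difference: float,
    factors: np.ndarray,
    median_differences: np.ndarray,
) -> InflationEstimate:
    """Invert a simulated inflation-factor -> DM-difference curve.

    ``factors`` are CV multipliers (e.g. 1.0, 1.05, 1.10); the returned
    percent is the CV excess implied by the observed X−A DM difference via
    monotone linear interpolation.  Observations outside the simulated
    range are clamped and flagged as extrapolated.
    """
    factors = np.asarray(factors, float)
    diffs = np.asarray(median_differences, float)
    if len(factors) != len(diffs) or len(factors) < 2:
        raise ValueError("calibration curve needs >= 2 (factor, difference) nodes")
    order = np.argsort(diffs)
    diffs_s, factors_s = diffs[order], factors[order]
    if np.any(np.diff(diffs_s) <= 0) or np.any(np.diff(factors_s) <= 0):
        raise ValueError("calibration curve must be strictly monotone")
    extrapolated = bool(
        observed_difference < diffs_s[0] or observed_difference > diffs_s[-1]
    )
    factor = float(np.interp(observed_difference, diffs_s, factors_s))
    return InflationEstimate(percent=(factor - 1.0) * 100.0, extrapolated=extrapolated)
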