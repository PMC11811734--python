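"""Simulation of chromosome-scale expression-noise differences.

Starting from a per-gene (mean FPKM, CV) base table of autosomal genes,
each replicate builds:

* ``A'`` — the autosomal means with each gene's CV replaced by one drawn
  at random from the CVs of the ``window`` genes nearest in mean (half
  below, half above, focal excluded);
* ``X'`` — a random X-chromosome-sized subset of ``A'``;
* ``X-halved'`` — the ``X'`` means halved, CVs re-drawn from the window
  of genes whose (unhalved) means are closest to the halved value;
* noisy variants — the ``X'`` / ``X-halved'`` CVs multiplied by an
  inflation factor, capped at the maximum CV observed across all genes.

Each dataset pair is reduced to the filter-by-fraction X−A DM difference
at each expression threshold, which measures whether DM can detect a
chromosome-wide CV change despite sparsity and compression.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable

import numpy as np
import pandas as pd
from scipy import stats

from ._random import substream
from .datamodel import CellMatrix, GeneAnnotation
from .noise import compute_dm, select_top_fraction

__all__ = [
    "NoiseSimConfig",
    "NoiseReplicate",
    "build_noise_datasets",
    "run_noise_experiment",
    "variance_comparison",
    "detection_threshold",
    "base_from_matrix",
]

DEFAULT_THRESHOLDS = (0.0, 1.0, 2.0, 5.0, 10.0)


@dataclass
class NoiseSimConfig:
    """Parameters of the noise simulation."""

    n_replicates: int = 1000
    window: int = 100
    inflation_factors: tuple[float, ...] = (1.05, 1.10, 1.15)
    deflation_factors: tuple[float, ...] = (0.98, 0.96, 0.94)
    include_deflation: bool = False
    halve_means: bool = True
    n_x_genes: int = 508
    thresholds: tuple[float, ...] = DEFAULT_THRESHOLDS
    seed: int = 0

    def __post_init__(self) -> None:
        for f in tuple(self.inflation_factors) + tuple(self.deflation_factors):
            if f <= 0:
                raise ValueError("factors must be positive")
        if self.window < 2 or self.window % 2:
            raise ValueError("window must be an even integer >= 2")
        if self.n_replicates < 1:
            raise ValueError("n_replicates must be >= 1")


def base_from_matrix(matrix: CellMatrix, ann: GeneAnnotation) -> pd.DataFrame:
    """Autosomal per-gene (mean_fpkm, cv) base table from an FPKM matrix."""
    from .noise import compute_cv

    cv = compute_cv(matrix)
    a_ids = ann.autosomal_genes.intersection(matrix.gene_ids)
    return cv.loc[a_ids].dropna(subset=["cv"])


def _value_window_starts(
    sorted_means: np.ndarray, queries: np.ndarray, window: int
) -> np.ndarray:
    """Start of the size-``window`` block of sorted means around each query:
    half below and half above the query's insertion position, shifted at the
    extremes to preserve the window size (the same rank-window convention
    the expected-CV correction uses)."""
    n = len(sorted_means)
    if window > n:
        raise ValueError("window larger than pool")
    pos = np.searchsorted(sorted_means, queries)
    return np.clip(pos - window // 2, 0, n - window)


class _Pool:
    """Sorted base pool with precomputed resampling windows."""

    def __init__(self, base: pd.DataFrame, window: int):
        base = base.dropna(subset=["mean_fpkm", "cv"])
        if len(base) <= window:
            raise ValueError(
                f"base table has {len(base)} genes; need more than window={window}"
            )
        order = np.lexsort((base.index.to_numpy(), base["mean_fpkm"].to_numpy()))
        self.means = base["mean_fpkm"].to_numpy()[order]
        self.cvs = base["cv"].to_numpy()[order]
        self.n = len(self.means)
        self.window = window
        self.max_cv = float(self.cvs.max())
        half = window // 2
        ranks = np.arange(self.n)
        # rank-window (focal excluded): block of window+1 ranks containing i
        self.rank_starts = np.clip(ranks - half, 0, self.n - window - 1)
        # window around each gene's halved mean (no focal exclusion)
        self.halved_starts = _value_window_starts(self.means, self.means / 2.0, window)

    def resample_rank_window(
        self, ranks: np.ndarray, rng: np.random.Generator
    ) -> np.ndarray:
        """One CV per rank, uniform over its window excluding the focal gene."""
        s = self.rank_starts[ranks]
        j = rng.integers(0, self.window, size=len(ranks))
        pick = s + j + (j >= ranks - s)
        return self.cvs[pick]

    def resample_halved_window(
        self, ranks: np.ndarray, rng: np.random.Generator
    ) -> np.ndarray:
        """One CV per rank, uniform over the window around the halved mean."""
        s = self.halved_starts[ranks]
        pick = s + rng.integers(0, self.window, size=len(ranks))
        return self.cvs[pick]


@dataclass
class NoiseReplicate:
    """One replicate's simulated datasets (means and CVs, sorted-pool order)."""

    replicate: int
    means_a: np.ndarray
    cv_a: np.ndarray
    x_idx: np.ndarray  # indices of X' genes within the A' pool
    means_x: np.ndarray
    cv_x: np.ndarray
    means_x_halved: np.ndarray
    cv_x_halved: np.ndarray
    max_cv: float

    def noisy_cv(self, factor: float, halved: bool = False) -> np.ndarray:
        """CVs multiplied by ``factor``, capped at the global maximum CV."""
        base = self.cv_x_halved if halved else self.cv_x
        return np.minimum(base * factor, self.max_cv)


def _make_replicate(pool: _Pool, cfg: NoiseSimConfig, rep: int) -> NoiseReplicate:
    if cfg.n_x_genes > pool.n:
        raise ValueError("n_x_genes exceeds the autosomal pool size")
    rng = substream(cfg.seed, "noise_sim", rep)
    all_ranks = np.arange(pool.n)
    cv_a = pool.resample_rank_window(all_ranks, rng)
    x_idx = rng.choice(pool.n, size=cfg.n_x_genes, replace=False)
    cv_x = pool.resample_rank_window(x_idx, rng)
    cv_xh = pool.resample_halved_window(x_idx, rng)
    return NoiseReplicate(
        replicate=rep,
        means_a=pool.means,
        cv_a=cv_a,
        x_idx=x_idx,
        means_x=pool.means[x_idx],
        cv_x=cv_x,
        means_x_halved=pool.means[x_idx] / 2.0,
        cv_x_halved=cv_xh,
        max_cv=pool.max_cv,
    )


def build_noise_datasets(
    base: pd.DataFrame, cfg: NoiseSimConfig, replicates: Iterable[int] | None = None
) -> list[NoiseReplicate]:
    """Build the per-replicate simulated datasets from a base table."""
    pool = _Pool(base, cfg.window)
    reps = range(cfg.n_replicates) if replicates is None else replicates
    return [_make_replicate(pool, cfg, r) for r in reps]


def _dm_diffs(
    means_a: np.ndarray,
    cv_a: np.ndarray,
    means_x: np.ndarray,
    cv_x: np.ndarray,
    window: int,
    thresholds: tuple[float, ...],
) -> dict[float, float]:
    """Filter-by-fraction X−A DM difference at each threshold.

    DM (expected CVs) is computed on the merged A+X table so both groups
    share one mean–CV reference.
    """
    merged = pd.DataFrame(
        {
            "mean_fpkm": np.concatenate([means_a, means_x]),
            "cv": np.concatenate([cv_a, cv_x]),
        }
    )
    dm = compute_dm(merged, window)["dm"].to_numpy()
    dm_a, dm_x = dm[: len(means_a)], dm[len(means_a):]
    out = {}
    for t in thresholds:
        ix, ia, _ = select_top_fraction(means_x, means_a, t)
        if len(ix) == 0 or len(ia) == 0:
            out[t] = np.nan
            continue
        out[t] = float(np.median(dm_x[ix]) - np.median(dm_a[ia]))
    return out


def run_noise_experiment(base: pd.DataFrame, cfg: NoiseSimConfig) -> pd.DataFrame:
    """Per-replicate DM differences for every condition and threshold.

    Conditions: ``baseline`` (X' vs A'), ``halved`` (X-halved' vs A'),
    ``noisy`` and ``halved_noisy`` at each inflation (and, when enabled,
    deflation) factor.  Returns a tidy frame with columns
    (replicate, condition, factor, threshold, dm_difference).
    """
    pool = _Pool(base, cfg.window)
    factors = tuple(cfg.inflation_factors)
    if cfg.include_deflation:
        factors = factors + tuple(cfg.deflation_factors)
    rows = []
    for rep in range(cfg.n_replicates):
        r = _make_replicate(pool, cfg, rep)

        def emit(condition: str, factor: float, means_x, cv_x):
            for t, d in _dm_diffs(
                r.means_a, r.cv_a, means_x, cv_x, cfg.window, cfg.thresholds
            ).items():
                rows.append(
                    {
                        "replicate": rep,
                        "condition": condition,
                        "factor": factor,
                        "threshold": t,
                        "dm_difference": d,
                    }
                )

        emit("baseline", 1.0, r.means_x, r.cv_x)
        if cfg.halve_means:
            emit("halved", 1.0, r.means_x_halved, r.cv_x_halved)
        for f in factors:
            emit("noisy", f, r.means_x, r.noisy_cv(f))
            if cfg.halve_means:
                emit("halved_noisy", f, r.means_x_halved, r.noisy_cv(f, halved=True))
    return pd.DataFrame(rows)


def variance_comparison(diffs_a: np.ndarray, diffs_b: np.ndarray) -> dict:
    """Levene test (median-centered) for equal variance of two replicate
    DM-difference distributions."""
    a = np.asarray(diffs_a, float)
    b = np.asarray(diffs_b, float)
    a, b = a[np.isfinite(a)], b[np.isfinite(b)]
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each sample needs at least 2 finite values")
    if np.ptp(a) == 0 and np.ptp(b) == 0:
        return {"statistic": np.nan, "p_value": np.nan, "degenerate": True}
    stat, p = stats.levene(a, b, center="median")
    return {"statistic": float(stat), "p_value": float(p), "degenerate": False}


@dataclass
class DetectionResult:
    smallest_percent: float | None  # None when nothing is detectable
    alpha: float
    per_factor_p: dict = field(default_factory=dict)


def detection_threshold(
    experiment: pd.DataFrame,
    alpha: float = 0.01,
    condition: str = "noisy",
    threshold: float = 0.0,
) -> DetectionResult:
    """Smallest tested inflation whose DM-difference distribution is
    significantly > 0 (one-sided Wilcoxon across replicates)."""
    sub = experiment[
        (experiment["condition"] == condition)
        & (experiment["threshold"] == threshold)
    ]
    per_factor_p: dict[float, float] = {}
    smallest: float | None = None
    for f in sorted(sub["factor"].unique()):
        d = sub.loc[sub["factor"] == f, "dm_difference"].dropna().to_numpy()
        if len(d) == 0 or np.allclose(d, 0):
            p = 1.0
        else:
            p = float(stats.wilcoxon(d, alternative="greater").pvalue)
        per_factor_p[float(f)] = p
        if p < alpha and smallest is None:
            smallest = abs(float(f) - 1.0) * 100.0
    return DetectionResult(smallest_percent=smallest, alpha=alpha, per_factor_p=per_factor_p)
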