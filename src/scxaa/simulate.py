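"""Synthetic transcriptome generator with known ground truth.

Emulates the two features of Smart-seq2 single-cell data that bias X:AA
estimation relative to bulk RNA-seq:

* **sparsity** — each cell detects only a small fraction of genes
  (~15% by default), with detection probability increasing with bulk
  expression;
* **compression** — detected expression is shrunk toward the middle of the
  dynamic range through the log-linear map
  ``FPKM_sc = 2 ** (slope * log2(FPKM_bulk) + intercept)`` with default
  slope 0.26 and intercept 3.75 (a two-fold bulk difference compresses to
  ``2**slope``-fold in the cell).

Two dosage models are supported: a *compensated* model in which X-linked
gene expression is drawn from the autosomal pool unchanged, and a
*noncompensated* model in which every X gene's bulk value is exactly half
its donor autosomal value (halving applied before the compression
transform).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterator, Literal

import numpy as np
import pandas as pd
from scipy import stats

from ._random import substream
from .datamodel import CellMatrix, ExpressionProfile, GeneAnnotation

__all__ = [
    "GeneratorConfig",
    "GroundTruth",
    "SimReplicate",
    "generate_bulk_profile",
    "sc_transform",
    "degrade_to_cell",
    "degrade_to_matrix",
    "build_model_datasets",
    "iter_model_datasets",
    "fit_generator_to_real",
]

Model = Literal["compensated", "noncompensated"]

#: intrinsic per-gene log2-sd range used when a generated dataset stands in
#: for an empirical mean/CV base table (noise experiments): single-cell
#: expression typically varies ~0.1–1.2 log2 units across cells at fixed
#: mean, and genes differ widely in where they sit in that range.
NOISE_BASE_SD_RANGE = (0.1, 1.2)


@dataclass
class GeneratorConfig:
    """Parameters of the synthetic bulk + single-cell generator.

    Defaults reflect a human Smart-seq2 study: ~18,500 autosomal and 508
    X-linked protein-coding genes, 100 cells per simulated dataset, ~15%
    of genes detected per cell, and the compression constants 0.26 / 3.75.
    """

    n_autosomal_genes: int = 18500
    n_x_genes: int = 508
    n_cells: int = 100
    bulk_log2_mean: float = 2.0
    bulk_log2_sd: float = 2.5
    compression_slope: float = 0.26
    compression_intercept: float = 3.75
    detected_fraction_mean: float = 0.15
    detected_fraction_sd: float = 0.05
    detection_steepness: float = 1.0
    # per-gene intrinsic expression-noise heterogeneity: each gene's
    # cell-to-cell log2 sd is drawn uniformly from this range.  (0, 0)
    # makes a detected cell value exactly the transformed bulk value, the
    # construction used for the ratio simulations; the noise experiments
    # enable it to emulate the wide CV scatter of real data at fixed mean.
    expression_noise_log2_sd: tuple[float, float] = (0.0, 0.0)
    seed: int = 0
    # fitted-generator extras: when present they override the parametric
    # detection model / detected-fraction law in degrade_to_cell
    empirical_detection_weights: pd.Series | None = None
    empirical_detected_fractions: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.n_x_genes > self.n_autosomal_genes:
            raise ValueError("n_x_genes cannot exceed n_autosomal_genes")
        if not (0 < self.detected_fraction_mean <= 1):
            raise ValueError("detected_fraction_mean must be in (0, 1]")
        if self.detected_fraction_sd < 0:
            raise ValueError("detected_fraction_sd must be >= 0")
        if not (0 < self.compression_slope <= 1):
            raise ValueError("compression_slope must be in (0, 1]")
        lo, hi = self.expression_noise_log2_sd
        if lo < 0 or hi < lo:
            raise ValueError("expression_noise_log2_sd must be 0 <= lo <= hi")


@dataclass
class GroundTruth:
    """What the generator actually did, attached to every replicate."""

    model: Model
    x_gene_ids: pd.Index
    cv_inflation_factor: float = 1.0
    true_mean: pd.Series | None = None  # per-gene bulk FPKM after any halving
    true_cv: pd.Series | None = None

    def __post_init__(self) -> None:
        if self.cv_inflation_factor <= 0:
            raise ValueError("cv_inflation_factor must be positive")


@dataclass
class SimReplicate:
    """One simulated dataset: a bulk profile and optionally degraded cells."""

    index: int
    model: Model
    kind: Literal["bulk", "sc"]
    bulk: ExpressionProfile
    annotation: GeneAnnotation
    truth: GroundTruth
    cells: CellMatrix | None = None


def generate_bulk_profile(
    cfg: GeneratorConfig, rng: np.random.Generator | None = None
) -> tuple[ExpressionProfile, GeneAnnotation]:
    """Draw one synthetic bulk profile containing autosomal and X genes.

    Autosomal FPKMs follow a log-normal law (normal on log2 scale with the
    configured mean/sd); X-gene values are a without-replacement sample of
    the autosomal values, so under the compensated model the two groups are
    exchangeable by construction.
    """
    rng = rng if rng is not None else np.random.default_rng(cfg.seed)
    a_vals = 2.0 ** rng.normal(cfg.bulk_log2_mean, cfg.bulk_log2_sd, cfg.n_autosomal_genes)
    x_vals = rng.choice(a_vals, size=cfg.n_x_genes, replace=False)
    a_ids = [f"A{i:06d}" for i in range(cfg.n_autosomal_genes)]
    x_ids = [f"X{i:05d}" for i in range(cfg.n_x_genes)]
    values = pd.Series(
        np.concatenate([a_vals, x_vals]), index=pd.Index(a_ids + x_ids, name="gene_id")
    )
    ann = GeneAnnotation(
        pd.DataFrame(
            {
                "chromosome_class": ["autosome"] * cfg.n_autosomal_genes
                + ["X"] * cfg.n_x_genes
            },
            index=values.index,
        )
    )
    return ExpressionProfile("synthetic_bulk", values), ann


def sc_transform(
    fpkm_bulk, slope: float = 0.26, intercept: float = 3.75
):
    """Log-linear compression map from bulk FPKM to single-cell FPKM.

    ``2 ** (slope * log2(x) + intercept)``; strictly monotone, defined only
    for positive input (zeros arise downstream solely through dropout).
    """
    x = np.asarray(fpkm_bulk, dtype=float)
    if np.any(x <= 0):
        raise ValueError("sc_transform requires strictly positive FPKM")
    out = 2.0 ** (slope * np.log2(x) + intercept)
    return out if out.ndim else float(out)


def _detection_weights(values: np.ndarray, cfg: GeneratorConfig) -> np.ndarray:
    """Per-gene detection probability: logistic in log2 bulk FPKM."""
    log2v = np.log2(values)
    center = np.median(log2v)
    return 1.0 / (1.0 + np.exp(-cfg.detection_steepness * (log2v - center)))


def _draw_detected_fraction(cfg: GeneratorConfig, rng: np.random.Generator) -> float:
    if cfg.empirical_detected_fractions is not None:
        return float(rng.choice(cfg.empirical_detected_fractions))
    if cfg.detected_fraction_sd == 0:
        return cfg.detected_fraction_mean
    lo, hi = 1e-9, 1.0
    a = (lo - cfg.detected_fraction_mean) / cfg.detected_fraction_sd
    b = (hi - cfg.detected_fraction_mean) / cfg.detected_fraction_sd
    return float(
        stats.truncnorm.rvs(
            a, b, loc=cfg.detected_fraction_mean, scale=cfg.detected_fraction_sd,
            random_state=rng,
        )
    )


def _weighted_sample_without_replacement(
    weights: np.ndarray, k: int, rng: np.random.Generator
) -> np.ndarray:
    """Indices of ``k`` items drawn without replacement ∝ ``weights``.

    Exponential-key top-k (Efraimidis–Spirakis), equivalent to sequential
    weighted draws with renormalization.
    """
    if not np.any(weights > 0):
        raise ValueError("degenerate detection weights: all zero")
    keys = np.full(len(weights), np.inf)
    pos = weights > 0
    keys[pos] = rng.exponential(size=int(pos.sum())) / weights[pos]
    return np.argpartition(keys, k - 1)[:k]


def degrade_to_cell(
    profile: ExpressionProfile,
    cfg: GeneratorConfig,
    rng: np.random.Generator,
) -> ExpressionProfile:
    """Degrade a bulk profile into one simulated cell.

    Draws the cell's detected fraction, selects that many genes without
    replacement with expression-dependent detection weights, maps the
    selected genes through :func:`sc_transform` and zeroes the rest.
    """
    vals = profile.values.to_numpy()
    if np.any(vals <= 0):
        raise ValueError("bulk profile must be strictly positive on its support")
    weights = _gene_weights(profile, cfg)
    f = _draw_detected_fraction(cfg, rng)
    k = max(1, int(np.floor(f * len(vals) + 0.5)))
    idx = _weighted_sample_without_replacement(weights, k, rng)
    out = np.zeros_like(vals)
    out[idx] = sc_transform(vals[idx], cfg.compression_slope, cfg.compression_intercept)
    sigma = _gene_noise_sd(cfg, len(vals), rng)
    if sigma is not None:
        out[idx] *= 2.0 ** rng.normal(0.0, sigma[idx])
    return ExpressionProfile(f"{profile.sample_id}_cell", pd.Series(out, index=profile.gene_ids))


def _gene_noise_sd(
    cfg: GeneratorConfig, n_genes: int, rng: np.random.Generator
) -> np.ndarray | None:
    """Per-gene intrinsic log2 noise sd, or None when heterogeneity is off."""
    lo, hi = cfg.expression_noise_log2_sd
    if hi == 0:
        return None
    return rng.uniform(lo, hi, n_genes)


def _gene_weights(profile: ExpressionProfile, cfg: GeneratorConfig) -> np.ndarray:
    if cfg.empirical_detection_weights is not None:
        w = cfg.empirical_detection_weights.reindex(profile.gene_ids).fillna(0.0)
        return w.to_numpy(float)
    return _detection_weights(profile.values.to_numpy(), cfg)


def degrade_to_matrix(
    profile: ExpressionProfile,
    cfg: GeneratorConfig,
    n_cells: int,
    rng: np.random.Generator,
    tissue: str = "synthetic",
) -> CellMatrix:
    """Degrade one bulk profile into ``n_cells`` independent cells."""
    vals = profile.values.to_numpy()
    if np.any(vals <= 0):
        raise ValueError("bulk profile must be strictly positive on its support")
    weights = _gene_weights(profile, cfg)
    transformed = sc_transform(vals, cfg.compression_slope, cfg.compression_intercept)
    sigma = _gene_noise_sd(cfg, len(vals), rng)  # one draw per dataset
    out = np.zeros((len(vals), n_cells))
    for c in range(n_cells):
        f = _draw_detected_fraction(cfg, rng)
        k = max(1, int(np.floor(f * len(vals) + 0.5)))
        idx = _weighted_sample_without_replacement(weights, k, rng)
        out[idx, c] = transformed[idx]
        if sigma is not None:
            out[idx, c] *= 2.0 ** rng.normal(0.0, sigma[idx])
    df = pd.DataFrame(
        out, index=profile.gene_ids, columns=[f"cell{c:04d}" for c in range(n_cells)]
    )
    return CellMatrix(values=df, unit="FPKM", tissue=tissue)


def iter_model_datasets(
    cfg: GeneratorConfig,
    model: Model,
    n_replicates: int,
    kind: Literal["bulk", "sc"] = "sc",
) -> Iterator[SimReplicate]:
    """Stream ``n_replicates`` simulated datasets for one dosage model.

    Each replicate draws a fresh bulk profile; under the noncompensated
    model X-gene values are halved *before* the compression transform.
    The ``sc`` kind additionally degrades the profile into ``cfg.n_cells``
    cells.  Randomness derives from ``cfg.seed`` via per-replicate
    substreams, so any replicate can be regenerated in isolation.
    """
    if n_replicates < 1:
        raise ValueError("n_replicates must be >= 1")
    for i in range(n_replicates):
        rng = substream(cfg.seed, "model_datasets", model, kind, i)
        profile, ann = generate_bulk_profile(cfg, rng)
        values = profile.values.copy()
        x_ids = ann.x_genes
        if model == "noncompensated":
            values.loc[x_ids] = values.loc[x_ids] * 0.5
        bulk = ExpressionProfile(f"{model}_{kind}_rep{i}", values)
        truth = GroundTruth(model=model, x_gene_ids=x_ids, true_mean=values)
        cells = None
        if kind == "sc":
            cells = degrade_to_matrix(bulk, cfg, cfg.n_cells, rng)
        yield SimReplicate(
            index=i, model=model, kind=kind, bulk=bulk, annotation=ann,
            truth=truth, cells=cells,
        )


def build_model_datasets(
    cfg: GeneratorConfig,
    model: Model,
    n_replicates: int,
    kind: Literal["bulk", "sc"] = "sc",
) -> list[SimReplicate]:
    """Materialize :func:`iter_model_datasets` as a list."""
    return list(iter_model_datasets(cfg, model, n_replicates, kind))


def fit_generator_to_real(
    bulk: ExpressionProfile, cells: CellMatrix, base: GeneratorConfig | None = None
) -> GeneratorConfig:
    """Calibrate the generator against a matched bulk + single-cell pair.

    Estimates the compression slope/intercept as the median over per-cell
    OLS regressions of log2 cell FPKM on log2 bulk FPKM (jointly positive
    genes), the per-gene empirical detection frequency, and the per-cell
    detected-fraction distribution.  The returned config reproduces these
    when used by :func:`degrade_to_cell`.
    """
    if cells.n_cells < 2:
        raise ValueError("need at least 2 cells to fit the generator")
    common = bulk.gene_ids.intersection(cells.gene_ids)
    bulk_vals = bulk.values.loc[common].to_numpy()
    mat = cells.values.loc[common].to_numpy()
    detected_any = (mat > 0).any(axis=1) & (bulk_vals > 0)
    if int(detected_any.sum()) < 50:
        raise ValueError(
            f"only {int(detected_any.sum())} genes jointly detected; need >= 50"
        )
    slopes, intercepts = [], []
    log2_bulk = np.where(bulk_vals > 0, np.log2(np.where(bulk_vals > 0, bulk_vals, 1)), np.nan)
    for c in range(mat.shape[1]):
        col = mat[:, c]
        use = (col > 0) & (bulk_vals > 0)
        if use.sum() < 2:
            continue
        res = stats.linregress(log2_bulk[use], np.log2(col[use]))
        slopes.append(res.slope)
        intercepts.append(res.intercept)
    if not slopes:
        raise ValueError("no cell had >= 2 genes jointly positive with bulk")
    detection_freq = pd.Series((mat > 0).mean(axis=1), index=common)
    fractions = (mat > 0).mean(axis=0)
    base = base if base is not None else GeneratorConfig()
    return replace(
        base,
        compression_slope=float(np.clip(np.median(slopes), 1e-6, 1.0)),
        compression_intercept=float(np.median(intercepts)),
        detected_fraction_mean=float(np.mean(fractions)),
        detected_fraction_sd=float(np.std(fractions, ddof=1)),
        empirical_detection_weights=detection_freq,
        empirical_detected_fractions=np.asarray(fractions, dtype=float),
    )
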