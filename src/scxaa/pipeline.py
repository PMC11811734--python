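"""End-to-end orchestration: simulate → estimate → test → report.

Every run derives all randomness from one top-level seed via named
substreams, writes tidy TSV artifacts with provenance headers (config,
seed, package version), and can be summarized into endpoint tables with
:func:`make_report`.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from ._random import substream
from .datamodel import GeneAnnotation, QcConfig
from .io import read_annotation, read_cell_matrix, read_gene_list
from .noise import classify_sensitivity, compute_cv, compute_dm, dm_difference
from .noisesim import (
    NoiseSimConfig,
    base_from_matrix,
    detection_threshold,
    run_noise_experiment,
    variance_comparison,
)
from .preprocess import counts_to_fpkm, qc_filter
from .ratio import DEFAULT_THRESHOLDS, STRATEGIES, xaa_columns, xaa_sweep
from .simulate import NOISE_BASE_SD_RANGE, GeneratorConfig, iter_model_datasets

__all__ = [
    "RunConfig",
    "run",
    "make_report",
    "run_xaa_simulation",
    "write_tsv",
    "read_tsv",
]

log = logging.getLogger(__name__)

MODES = ("xaa_sim", "xaa_empirical", "noise_sim", "noise_empirical", "full")


@dataclass
class RunConfig:
    """Configuration of one pipeline run."""

    mode: str = "xaa_sim"
    seed: int = 0
    n_replicates: int = 200
    thresholds: tuple[float, ...] = DEFAULT_THRESHOLDS
    strategies: tuple[str, ...] = STRATEGIES
    generator: GeneratorConfig = field(default_factory=GeneratorConfig)
    noise: NoiseSimConfig = field(default_factory=NoiseSimConfig)
    qc: QcConfig = field(default_factory=QcConfig)
    # empirical-mode inputs
    matrix_path: str | None = None
    matrix_format: str = "dense_tsv"
    genes_path: str | None = None
    cells_path: str | None = None
    matrix_unit: str = "FPKM"
    annotation_path: str | None = None
    xe_path: str | None = None

    def validate(self) -> None:
        if self.mode not in MODES:
            raise ValueError(f"unknown mode {self.mode!r}")
        if self.mode in ("xaa_empirical", "noise_empirical"):
            for name in ("matrix_path", "annotation_path"):
                p = getattr(self, name)
                if p is None:
                    raise ValueError(f"mode {self.mode} requires {name}")
                if not Path(p).exists():
                    raise FileNotFoundError(f"{name}: {p}")
            for name in ("genes_path", "cells_path", "xe_path"):
                p = getattr(self, name)
                if p is not None and not Path(p).exists():
                    raise FileNotFoundError(f"{name}: {p}")


def _meta(cfg: RunConfig, stage: str) -> dict:
    gen = {
        k: v
        for k, v in dataclasses.asdict(cfg.generator).items()
        if not isinstance(v, (pd.Series, np.ndarray)) and v is not None
    }
    return {
        "stage": stage,
        "scxaa_version": __version__,
        "seed": cfg.seed,
        "mode": cfg.mode,
        "config": json.dumps(
            {
                "n_replicates": cfg.n_replicates,
                "thresholds": list(cfg.thresholds),
                "strategies": list(cfg.strategies),
                "generator": gen,
            },
            sort_keys=True,
        ),
    }


def write_tsv(df: pd.DataFrame, path: str | Path, meta: dict | None = None) -> None:
    """Write a tidy TSV with ``# key: value`` provenance header lines."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        for k, v in (meta or {}).items():
            fh.write(f"# {k}: {v}\n")
        df.to_csv(fh, sep="\t", index=False)


def read_tsv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#")


def run_xaa_simulation(
    gen_cfg: GeneratorConfig,
    n_replicates: int,
    models: tuple[str, ...] = ("compensated", "noncompensated"),
    kinds: tuple[str, ...] = ("bulk", "sc"),
    strategies: tuple[str, ...] = STRATEGIES,
    thresholds: tuple[float, ...] = DEFAULT_THRESHOLDS,
) -> pd.DataFrame:
    """Per-replicate X:AA for every model/kind/strategy/threshold.

    Bulk replicates contribute one profile-level ratio; single-cell
    replicates contribute the median of the per-cell ratios, following
    the per-cell-then-median summary convention.
    """
    rows = []
    for model in models:
        for kind in kinds:
            for rep in iter_model_datasets(gen_cfg, model, n_replicates, kind):
                ann = rep.annotation
                if kind == "bulk":
                    vals = rep.bulk.values
                    xb = vals.loc[ann.x_genes].to_numpy()[:, None]
                    ab = vals.loc[ann.autosomal_genes].to_numpy()[:, None]
                else:
                    vals = rep.cells.values
                    xb = vals.loc[ann.x_genes].to_numpy()
                    ab = vals.loc[ann.autosomal_genes].to_numpy()
                for strat in strategies:
                    res = xaa_columns(xb, ab, strat, thresholds)
                    summary = res.groupby("threshold")["xaa"].median()
                    for t, v in summary.items():
                        rows.append(
                            {
                                "replicate": rep.index,
                                "model": model,
                                "kind": kind,
                                "strategy": strat,
                                "threshold": t,
                                "xaa": v,
                            }
                        )
    return pd.DataFrame(rows)


def _run_xaa_sim(cfg: RunConfig, out: Path) -> None:
    gen = dataclasses.replace(cfg.generator, seed=cfg.seed)
    df = run_xaa_simulation(
        gen, cfg.n_replicates, strategies=cfg.strategies, thresholds=cfg.thresholds
    )
    write_tsv(df, out / "xaa_sim_replicates.tsv", _meta(cfg, "xaa_sim"))


def _run_noise_sim(cfg: RunConfig, out: Path) -> None:
    gen = dataclasses.replace(cfg.generator, seed=cfg.seed)
    noise_cfg = dataclasses.replace(
        cfg.noise, seed=cfg.seed, thresholds=cfg.thresholds
    )
    # base mean/CV table from one simulated compensated single-cell dataset;
    # intrinsic noise heterogeneity on, emulating an empirical mean/CV table
    if gen.expression_noise_log2_sd == (0.0, 0.0):
        gen = dataclasses.replace(gen, expression_noise_log2_sd=NOISE_BASE_SD_RANGE)
    rep = next(iter_model_datasets(gen, "compensated", 1, "sc"))
    base = base_from_matrix(rep.cells, rep.annotation)
    noise_cfg = dataclasses.replace(
        noise_cfg, n_x_genes=min(noise_cfg.n_x_genes, gen.n_x_genes)
    )
    df = run_noise_experiment(base, noise_cfg)
    write_tsv(df, out / "noise_sim_replicates.tsv", _meta(cfg, "noise_sim"))


def _load_empirical(cfg: RunConfig):
    matrix = read_cell_matrix(
        cfg.matrix_path,
        cfg.matrix_format,
        genes_path=cfg.genes_path,
        cells_path=cfg.cells_path,
        unit=cfg.matrix_unit,
    )
    ann = read_annotation(cfg.annotation_path)
    if cfg.xe_path is not None:
        xe = set(read_gene_list(cfg.xe_path))
        table = ann.table.copy()
        table["is_xe"] = table.index.isin(xe)
        ann = GeneAnnotation(table)
    matrix, report = qc_filter(matrix, cfg.qc)
    if report.tissue_excluded:
        log.warning("tissue excluded by QC (%d cells remain)", report.n_cells_out)
    if matrix.unit == "count":
        matrix = counts_to_fpkm(matrix, ann)
    # drop genes absent from the annotation
    keep = matrix.gene_ids.intersection(ann.gene_ids)
    dropped = matrix.n_genes - len(keep)
    if dropped:
        log.info("dropping %d genes absent from annotation", dropped)
        matrix.values = matrix.values.loc[keep]
    return matrix, ann, report


def _run_xaa_empirical(cfg: RunConfig, out: Path) -> None:
    matrix, ann, _ = _load_empirical(cfg)
    results, tests = xaa_sweep(
        matrix,
        ann,
        strategies=cfg.strategies,
        thresholds=cfg.thresholds,
        test_xe_halving=cfg.xe_path is not None,
    )
    write_tsv(results, out / "xaa_per_cell.tsv", _meta(cfg, "xaa_empirical"))
    write_tsv(tests, out / "xaa_tests.tsv", _meta(cfg, "xaa_empirical"))


def _run_noise_empirical(cfg: RunConfig, out: Path) -> None:
    matrix, ann, _ = _load_empirical(cfg)
    table = compute_dm(compute_cv(matrix), cfg.noise.window)
    table["chromosome_class"] = ann.table.loc[table.index, "chromosome_class"]
    write_tsv(
        table.reset_index(names="gene_id"), out / "noise_table.tsv",
        _meta(cfg, "noise_empirical"),
    )
    x_t = table[table["chromosome_class"] == "X"]
    a_t = table[table["chromosome_class"] == "autosome"]
    rows = []
    for t in cfg.thresholds:
        try:
            d = dm_difference(x_t, a_t, threshold=t, seed=cfg.seed)
        except ValueError:
            continue
        rows.append(dataclasses.asdict(d))
    write_tsv(pd.DataFrame(rows), out / "dm_differences.tsv", _meta(cfg, "noise_empirical"))
    calls, summary = classify_sensitivity(table)
    write_tsv(
        calls.reset_index(names="gene_id"), out / "sensitivity_calls.tsv",
        _meta(cfg, "noise_empirical"),
    )
    if "x_over_a_quotient" in summary.attrs:
        summary["x_over_a_quotient"] = summary.attrs["x_over_a_quotient"]
    write_tsv(summary, out / "sensitivity_summary.tsv", _meta(cfg, "noise_empirical"))


def run(cfg: RunConfig, out_dir: str | Path) -> Path:
    """Execute the configured mode; returns the run directory.

    Stage outputs carry provenance headers; a failing stage aborts with
    the stage named while earlier outputs are preserved.
    """
    cfg.validate()
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    stages = {
        "xaa_sim": [_run_xaa_sim],
        "noise_sim": [_run_noise_sim],
        "xaa_empirical": [_run_xaa_empirical],
        "noise_empirical": [_run_noise_empirical],
        "full": [_run_xaa_sim, _run_noise_sim],
    }[cfg.mode]
    for stage in stages:
        log.info("running stage %s", stage.__name__)
        try:
            stage(cfg, out)
        except Exception as exc:
            raise RuntimeError(f"stage {stage.__name__.lstrip('_')} failed: {exc}") from exc
    make_report(out)
    return out


def make_report(run_dir: str | Path) -> list[Path]:
    """Aggregate replicate-level artifacts into endpoint summary tables.

    Idempotent: re-running overwrites the same summary files.
    """
    run_dir = Path(run_dir)
    written = []
    xaa_path = run_dir / "xaa_sim_replicates.tsv"
    if xaa_path.exists():
        df = read_tsv(xaa_path)
        summary = (
            df.groupby(["model", "kind", "strategy", "threshold"])["xaa"]
            .agg(
                median_xaa="median",
                q05=lambda s: s.quantile(0.05),
                q95=lambda s: s.quantile(0.95),
                n_replicates="count",
            )
            .reset_index()
        )
        if (summary["n_replicates"] < 2).any():
            summary.loc[summary["n_replicates"] < 2, ["q05", "q95"]] = np.nan
        p = run_dir / "xaa_sim_summary.tsv"
        write_tsv(summary, p)
        written.append(p)
    noise_path = run_dir / "noise_sim_replicates.tsv"
    if noise_path.exists():
        df = read_tsv(noise_path)
        summary = (
            df.groupby(["condition", "factor", "threshold"])["dm_difference"]
            .agg(median_dm_difference="median", variance="var", n_replicates="count")
            .reset_index()
        )
        p = run_dir / "noise_sim_summary.tsv"
        write_tsv(summary, p)
        written.append(p)
        extras = {}
        det = detection_threshold(df)
        extras["smallest_detectable_inflation_percent"] = det.smallest_percent
        extras["per_factor_p"] = json.dumps(det.per_factor_p)
        # variance comparison only at thresholds > 0: at threshold 0 the
        # shared-window construction pins both medians at zero by design
        lev_p = {}
        for t in sorted(df["threshold"].unique()):
            if t <= 0:
                continue
            base_d = df.query("condition == 'baseline' and threshold == @t")["dm_difference"]
            halv_d = df.query("condition == 'halved' and threshold == @t")["dm_difference"]
            if len(base_d) >= 2 and len(halv_d) >= 2:
                lev = variance_comparison(base_d.to_numpy(), halv_d.to_numpy())
                lev_p[float(t)] = lev["p_value"]
        if lev_p:
            extras["levene_halved_vs_baseline_p"] = json.dumps(lev_p)
        p2 = run_dir / "noise_sim_tests.tsv"
        write_tsv(pd.DataFrame([extras]), p2)
        written.append(p2)
    return written
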