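"""Readers and writers for expression matrices, annotations and gene lists.

Two on-disk dialects are supported for expression matrices:

* ``dense_tsv`` — first column gene ID, header row of cell IDs, tab
  separated;
* ``triplet_mtx`` — MatrixMarket coordinate format (1-based indices) with
  companion plain-text gene-ID and cell-ID sidecar files, one ID per line.

Annotation tables and gene lists are header-bearing TSV.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse

from .datamodel import CellMatrix, ExpressionProfile, GeneAnnotation

__all__ = [
    "read_cell_matrix",
    "write_cell_matrix",
    "read_bulk_profile",
    "write_bulk_profile",
    "read_annotation",
    "write_annotation",
    "read_gene_list",
]


def _read_id_file(path: Path, what: str) -> list[str]:
    ids = [line.strip() for line in Path(path).read_text().splitlines() if line.strip()]
    if len(set(ids)) != len(ids):
        raise ValueError(f"duplicate {what} IDs in {path}")
    return ids


def read_cell_matrix(
    path: str | Path,
    format: str = "dense_tsv",
    genes_path: str | Path | None = None,
    cells_path: str | Path | None = None,
    unit: str = "FPKM",
    tissue: str = "",
    donor: str = "",
) -> CellMatrix:
    """Read a genes x cells expression matrix.

    Parameters
    ----------
    path:
        The matrix file (TSV or MatrixMarket ``.mtx``).
    format:
        ``"dense_tsv"`` or ``"triplet_mtx"``; the sparse dialect requires
        ``genes_path`` and ``cells_path`` sidecar ID files.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if format == "dense_tsv":
        df = pd.read_csv(path, sep="\t", index_col=0, comment="#")
        if df.index.has_duplicates:
            dup = df.index[df.index.duplicated()].unique()
            raise ValueError(f"duplicate gene ID(s) in {path}: {list(dup[:5])}")
        df.index = df.index.astype(str)
        df.columns = df.columns.astype(str)
        df.index.name = "gene_id"
    elif format == "triplet_mtx":
        if genes_path is None or cells_path is None:
            raise ValueError("triplet_mtx requires genes_path and cells_path")
        genes = _read_id_file(Path(genes_path), "gene")
        cells = _read_id_file(Path(cells_path), "cell")
        try:
            mat = scipy.io.mmread(path)
        except ValueError as exc:  # malformed header / entries
            raise ValueError(f"cannot parse MatrixMarket file {path}: {exc}") from exc
        mat = scipy.sparse.coo_matrix(mat)
        if mat.shape[0] != len(genes):
            raise ValueError(
                f"{path}: declared {mat.shape[0]} rows but gene-ID file "
                f"lists {len(genes)} genes"
            )
        if mat.shape[1] != len(cells):
            raise ValueError(
                f"{path}: declared {mat.shape[1]} columns but cell-ID file "
                f"lists {len(cells)} cells"
            )
        df = pd.DataFrame(mat.toarray(), index=genes, columns=cells, dtype=float)
        df.index.name = "gene_id"
    else:
        raise ValueError(f"unknown matrix format {format!r}")
    return CellMatrix(values=df, unit=unit, tissue=tissue, donor=donor)


def write_cell_matrix(
    matrix: CellMatrix,
    path: str | Path,
    format: str = "dense_tsv",
    genes_path: str | Path | None = None,
    cells_path: str | Path | None = None,
) -> None:
    """Write a matrix in either dialect (inverse of :func:`read_cell_matrix`)."""
    path = Path(path)
    if format == "dense_tsv":
        matrix.values.to_csv(path, sep="\t", index_label="gene_id")
    elif format == "triplet_mtx":
        if genes_path is None or cells_path is None:
            raise ValueError("triplet_mtx requires genes_path and cells_path")
        sparse = scipy.sparse.coo_matrix(matrix.values.to_numpy())
        scipy.io.mmwrite(str(path), sparse)
        Path(genes_path).write_text("\n".join(matrix.gene_ids) + "\n")
        Path(cells_path).write_text("\n".join(matrix.cell_ids) + "\n")
    else:
        raise ValueError(f"unknown matrix format {format!r}")


def read_bulk_profile(path: str | Path, sample_id: str | None = None) -> ExpressionProfile:
    """Read a two-column (gene_id, fpkm) TSV as a bulk profile."""
    path = Path(path)
    df = pd.read_csv(path, sep="\t", comment="#")
    if df.shape[1] < 2:
        raise ValueError(f"{path}: expected two columns (gene_id, fpkm)")
    values = pd.Series(df.iloc[:, 1].to_numpy(float), index=df.iloc[:, 0].astype(str))
    return ExpressionProfile(sample_id or path.stem, values)


def write_bulk_profile(profile: ExpressionProfile, path: str | Path) -> None:
    df = pd.DataFrame({"gene_id": profile.gene_ids, "fpkm": profile.values.to_numpy()})
    df.to_csv(path, sep="\t", index=False)


def read_annotation(path: str | Path) -> GeneAnnotation:
    """Read a gene annotation TSV (gene_id, chromosome_class, flags, length)."""
    df = pd.read_csv(path, sep="\t", comment="#")
    if "gene_id" not in df.columns:
        raise ValueError(f"{path}: annotation must have a gene_id column")
    df = df.set_index("gene_id")
    df.index = df.index.astype(str)
    return GeneAnnotation(df)


def write_annotation(ann: GeneAnnotation, path: str | Path) -> None:
    ann.table.to_csv(path, sep="\t", index_label="gene_id")


def read_gene_list(path: str | Path) -> list[str]:
    """Read a one-ID-per-line gene list (e.g. Xe or housekeeping genes)."""
    return _read_id_file(Path(path), "gene")
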