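"""Core domain types shared by every analysis stage.

The analyses operate on three kinds of objects: a single transcriptional
profile (one bulk sample or one cell), a genes x cells expression matrix,
and a per-gene annotation table assigning each gene to the X chromosome,
an autosome, or neither.  All expression values are FPKM (or raw counts
for matrices awaiting conversion) and are required to be finite and
nonnegative.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "ExpressionProfile",
    "CellMatrix",
    "GeneAnnotation",
    "QcConfig",
    "classify_chromosome",
]

#: allowed chromosome classes in annotation tables
CHROMOSOME_CLASSES = ("X", "autosome", "other")


def classify_chromosome(name: str) -> str:
    """Map a raw chromosome name to one of {X, autosome, other}.

    Accepts ``chr``-prefixed names; numeric chromosomes are autosomes,
    ``X`` is X, everything else (Y, MT, scaffolds) is ``other``.
    """
    s = str(name)
    if s.lower().startswith("chr"):
        s = s[3:]
    if s.upper() == "X":
        return "X"
    if s.isdigit():
        return "autosome"
    return "other"


def _validate_values(values: np.ndarray, what: str) -> None:
    if not np.all(np.isfinite(values)):
        raise ValueError(f"{what}: non-finite expression values present")
    if np.any(values < 0):
        raise ValueError(f"{what}: negative expression values present")


@dataclass
class ExpressionProfile:
    """One sample's gene -> FPKM map (a bulk sample or a single cell)."""

    sample_id: str
    values: pd.Series  # index: gene_id (unique), values: FPKM >= 0

    def __post_init__(self) -> None:
        if not isinstance(self.values, pd.Series):
            self.values = pd.Series(self.values, dtype=float)
        self.values = self.values.astype(float)
        if self.values.index.has_duplicates:
            dups = self.values.index[self.values.index.duplicated()].unique()
            raise ValueError(f"duplicate gene IDs in profile: {list(dups[:5])}")
        _validate_values(self.values.to_numpy(), f"profile {self.sample_id!r}")

    @property
    def gene_ids(self) -> pd.Index:
        return self.values.index

    def __len__(self) -> int:
        return len(self.values)


@dataclass
class CellMatrix:
    """A genes x cells expression matrix with identity metadata.

    ``values`` is a DataFrame whose index is gene IDs and whose columns are
    cell IDs; ``unit`` records whether entries are raw counts or FPKM.
    """

    values: pd.DataFrame
    unit: str = "FPKM"  # "count" or "FPKM"
    tissue: str = ""
    donor: str = ""

    def __post_init__(self) -> None:
        if self.unit not in ("count", "FPKM"):
            raise ValueError(f"unknown unit {self.unit!r}")
        if self.values.index.has_duplicates:
            raise ValueError("duplicate gene IDs in matrix")
        if self.values.columns.has_duplicates:
            raise ValueError("duplicate cell IDs in matrix")
        self.values = self.values.astype(float)
        _validate_values(self.values.to_numpy(), "cell matrix")

    @property
    def gene_ids(self) -> pd.Index:
        return self.values.index

    @property
    def cell_ids(self) -> pd.Index:
        return self.values.columns

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_cells(self) -> int:
        return self.values.shape[1]

    def cell(self, cell_id: str) -> ExpressionProfile:
        """Extract one cell as an :class:`ExpressionProfile`."""
        return ExpressionProfile(cell_id, self.values[cell_id])


@dataclass
class GeneAnnotation:
    """Per-gene chromosome class, coding/ortholog/escape flags and length.

    Wraps a DataFrame indexed by gene ID with columns ``chromosome_class``
    (one of X/autosome/other), ``protein_coding``, ``ortholog_1to1``,
    ``is_xe`` (escapes X inactivation) and ``gene_length_bp``.
    Genes of class ``other`` are excluded from every X:AA and DM
    computation downstream.
    """

    table: pd.DataFrame

    REQUIRED = ("chromosome_class",)
    DEFAULTS = {
        "protein_coding": True,
        "ortholog_1to1": False,
        "is_xe": False,
        "gene_length_bp": 1000,
    }

    def __post_init__(self) -> None:
        t = self.table.copy()
        if t.index.has_duplicates:
            raise ValueError("duplicate gene IDs in annotation")
        for col in self.REQUIRED:
            if col not in t.columns:
                raise ValueError(f"annotation missing column {col!r}")
        bad = set(t["chromosome_class"].unique()) - set(CHROMOSOME_CLASSES)
        if bad:
            raise ValueError(f"unknown chromosome classes: {sorted(bad)}")
        for col, default in self.DEFAULTS.items():
            if col not in t.columns:
                t[col] = default
        for col in ("protein_coding", "ortholog_1to1", "is_xe"):
            t[col] = t[col].astype(bool)
        t["gene_length_bp"] = t["gene_length_bp"].astype(int)
        if (t["gene_length_bp"] <= 0).any():
            raise ValueError("gene lengths must be positive")
        self.table = t

    @property
    def gene_ids(self) -> pd.Index:
        return self.table.index

    def genes_of_class(self, cls: str, coding_only: bool = True) -> pd.Index:
        mask = self.table["chromosome_class"] == cls
        if coding_only:
            mask &= self.table["protein_coding"]
        return self.table.index[mask]

    @property
    def x_genes(self) -> pd.Index:
        return self.genes_of_class("X")

    @property
    def autosomal_genes(self) -> pd.Index:
        return self.genes_of_class("autosome")

    @property
    def xe_genes(self) -> pd.Index:
        return self.table.index[self.table["is_xe"]]

    def gene_lengths(self, gene_ids: pd.Index) -> pd.Series:
        missing = gene_ids.difference(self.table.index)
        if len(missing):
            raise KeyError(
                f"{len(missing)} genes missing from annotation, e.g. "
                f"{list(missing[:5])}"
            )
        return self.table.loc[gene_ids, "gene_length_bp"]


@dataclass
class QcConfig:
    """Quality-control thresholds for cells and tissues.

    A cell must detect at least ``min_genes_per_cell`` genes (value > 0 in
    raw counts) to be kept; a tissue must retain at least
    ``min_cells_per_tissue`` cells or the whole matrix is flagged excluded.
    """

    min_genes_per_cell: int = 1500
    min_cells_per_tissue: int = 50

    def __post_init__(self) -> None:
        if self.min_genes_per_cell <= 0 or self.min_cells_per_tissue <= 0:
            raise ValueError("QC thresholds must be positive")
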