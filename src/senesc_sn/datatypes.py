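"""Core in-memory containers shared by every pipeline stage.

The central object is :class:`CountMatrix`, a genes × nuclei sparse matrix of
UMI counts (or, after normalization, of floats) carrying gene and cell
identifiers. Cell-level metadata travels separately as a pandas DataFrame
(the "cell table") with the columns listed in :data:`CELL_TABLE_COLUMNS`.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.sparse as sp

__all__ = [
    "CountMatrix",
    "GeneSet",
    "CELL_TABLE_COLUMNS",
    "ConfigError",
    "AlignmentError",
    "CohortParseError",
]

#: Required columns of a cell table, in canonical order.
CELL_TABLE_COLUMNS = ("cell_id", "sample_id", "condition", "cell_type", "is_doublet")


class ConfigError(ValueError):
    """Invalid configuration (simulation, QC, scoring or pipeline)."""


class AlignmentError(ValueError):
    """Matrix columns and metadata rows do not describe the same cells."""


class CohortParseError(ValueError):
    """A cohort directory or file could not be parsed."""


@dataclass
class CountMatrix:
    """Sparse genes × nuclei matrix with identifiers.

    Parameters
    ----------
    X : scipy.sparse matrix, genes in rows, cells in columns.
    gene_ids : unique gene identifiers, one per row.
    cell_ids : unique cell barcodes, one per column.
    """

    X: sp.csc_matrix
    gene_ids: np.ndarray
    cell_ids: np.ndarray

    def __post_init__(self) -> None:
        self.X = sp.csc_matrix(self.X)
        self.gene_ids = np.asarray(self.gene_ids, dtype=object)
        self.cell_ids = np.asarray(self.cell_ids, dtype=object)
        if self.X.shape != (len(self.gene_ids), len(self.cell_ids)):
            raise AlignmentError(
                f"matrix shape {self.X.shape} does not match "
                f"{len(self.gene_ids)} genes x {len(self.cell_ids)} cells"
            )
        if len(set(self.gene_ids)) != len(self.gene_ids):
            raise CohortParseError("duplicate gene identifiers")
        if len(set(self.cell_ids)) != len(self.cell_ids):
            raise CohortParseError("duplicate cell identifiers")

    # -- basic queries -------------------------------------------------
    @property
    def n_genes(self) -> int:
        return self.X.shape[0]

    @property
    def n_cells(self) -> int:
        return self.X.shape[1]

    def cell_totals(self) -> np.ndarray:
        """Per-cell total counts (column sums)."""
        return np.asarray(self.X.sum(axis=0)).ravel()

    def genes_detected(self) -> np.ndarray:
        """Per-cell number of genes with non-zero count."""
        return np.diff(self.X.indptr) if isinstance(self.X, sp.csc_matrix) else np.asarray(
            (self.X != 0).sum(axis=0)
        ).ravel()

    def cells_detected(self) -> np.ndarray:
        """Per-gene number of cells with non-zero count."""
        return np.asarray((self.X != 0).sum(axis=1)).ravel()

    def gene_index(self, ids) -> np.ndarray:
        """Row positions of the given gene ids (raises on unknown ids)."""
        lookup = {g: i for i, g in enumerate(self.gene_ids)}
        try:
            return np.array([lookup[g] for g in ids], dtype=int)
        except KeyError as exc:
            raise KeyError(f"unknown gene id {exc.args[0]!r}") from None

    def cell_index(self, ids) -> np.ndarray:
        lookup = {c: i for i, c in enumerate(self.cell_ids)}
        try:
            return np.array([lookup[c] for c in ids], dtype=int)
        except KeyError as exc:
            raise KeyError(f"unknown cell id {exc.args[0]!r}") from None

    # -- subsetting ----------------------------------------------------
    def subset_cells(self, ids) -> "CountMatrix":
        idx = self.cell_index(ids)
        return CountMatrix(self.X[:, idx], self.gene_ids, self.cell_ids[idx])

    def subset_genes(self, ids) -> "CountMatrix":
        idx = self.gene_index(ids)
        return CountMatrix(self.X[idx, :], self.gene_ids[idx], self.cell_ids)

    def toarray(self) -> np.ndarray:
        return self.X.toarray()

    def copy(self) -> "CountMatrix":
        return CountMatrix(self.X.copy(), self.gene_ids.copy(), self.cell_ids.copy())


@dataclass
class GeneSet:
    """A named list of gene identifiers (e.g. a SASP signature)."""

    name: str
    genes: list = field(default_factory=list)

    def __post_init__(self) -> None:
        self.genes = [str(g) for g in self.genes]
        if len(set(self.genes)) != len(self.genes):
            raise ConfigError(f"gene set {self.name!r} contains duplicate genes")

    def __len__(self) -> int:
        return len(self.genes)

    def __iter__(self):
        return iter(self.genes)


def validate_cell_table(table: pd.DataFrame) -> pd.DataFrame:
    """Check required columns and unique cell ids; returns the table."""
    missing = [c for c in CELL_TABLE_COLUMNS if c not in table.columns]
    if missing:
        raise AlignmentError(f"cell table missing columns: {missing}")
    if table["cell_id"].duplicated().any():
        raise AlignmentError("cell table contains duplicate cell ids")
    return table


def check_aligned(matrix: CountMatrix, table: pd.DataFrame) -> None:
    """Require the table rows to match matrix columns one-to-one, in order."""
    validate_cell_table(table)
    if len(table) != matrix.n_cells or not np.array_equal(
        np.asarray(table["cell_id"], dtype=object), matrix.cell_ids
    ):
        raise AlignmentError("cell table rows do not match matrix columns")
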