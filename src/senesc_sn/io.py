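"""Readers and writers for cohort directories and gene-set files.

A cohort directory is a 10x-style MatrixMarket triplet — ``matrix.mtx``
(genes × cells, integer coordinate format, 1-based indices on disk),
``features.tsv`` (one gene id per line, optionally with extra columns) and
``barcodes.tsv`` — plus ``cells.tsv``, a tab-separated metadata table with
columns ``cell_id, sample_id, condition, cell_type, is_doublet``. Toy dense
inputs can instead be a single TSV with genes in rows. Gene sets are read
from GMT files or one-gene-per-line lists.
"""

from __future__ import annotations

import io as _io
import json
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp

from .datatypes import (
    CELL_TABLE_COLUMNS,
    AlignmentError,
    CohortParseError,
    CountMatrix,
    GeneSet,
    check_aligned,
)

__all__ = [
    "read_cohort",
    "write_cohort",
    "read_dense_tsv",
    "read_gene_set",
    "read_gmt",
    "write_gmt",
    "write_tsv",
]


def _read_id_column(path: Path) -> np.ndarray:
    ids = []
    with open(path, encoding="utf-8") as fh:
        for line_no, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                raise CohortParseError(f"{path.name}:{line_no}: empty line")
            ids.append(line.split("\t")[0])
    return np.array(ids, dtype=object)


def read_cohort(path) -> tuple:
    """Read a cohort directory; returns ``(CountMatrix, cell table)``.

    The matrix is oriented genes × cells on return regardless of the on-disk
    orientation (detected from the features/barcodes lengths; ambiguous
    square inputs are rejected).
    """
    path = Path(path)
    mtx = path / "matrix.mtx"
    for required in ("matrix.mtx", "features.tsv", "barcodes.tsv", "cells.tsv"):
        if not (path / required).exists():
            raise CohortParseError(f"missing {required} in {path}")
    genes = _read_id_column(path / "features.tsv")
    barcodes = _read_id_column(path / "barcodes.tsv")
    if len(set(genes)) != len(genes):
        raise CohortParseError("features.tsv contains duplicate gene ids")
    try:
        X = scipy.io.mmread(mtx)
    except Exception as exc:
        raise CohortParseError(f"{mtx.name}: malformed MatrixMarket file: {exc}") from exc
    X = sp.csc_matrix(X)
    if X.shape == (len(genes), len(barcodes)):
        pass
    elif X.shape == (len(barcodes), len(genes)):
        if len(genes) == len(barcodes):
            raise CohortParseError(
                "square matrix with equal feature and barcode counts: orientation is ambiguous"
            )
        X = sp.csc_matrix(X.T)
    else:
        raise CohortParseError(
            f"matrix shape {X.shape} matches neither {len(genes)} genes x "
            f"{len(barcodes)} barcodes nor its transpose"
        )
    matrix = CountMatrix(X, genes, barcodes)

    table = pd.read_csv(path / "cells.tsv", sep="\t", dtype={"cell_id": str})
    missing_cols = [c for c in CELL_TABLE_COLUMNS if c not in table.columns]
    if missing_cols:
        raise CohortParseError(f"cells.tsv missing columns {missing_cols}")
    if "is_doublet" in table.columns:
        table["is_doublet"] = table["is_doublet"].astype(bool)
    if set(table["cell_id"]) != set(barcodes):
        n_extra = len(set(table["cell_id"]) - set(barcodes))
        n_missing = len(set(barcodes) - set(table["cell_id"]))
        raise AlignmentError(
            f"cells.tsv does not match barcodes.tsv ({n_missing} barcodes missing, "
            f"{n_extra} unknown cell ids)"
        )
    table = table.set_index("cell_id", drop=False).loc[barcodes].reset_index(drop=True)
    check_aligned(matrix, table)
    return matrix, table


def write_cohort(path, matrix: CountMatrix, table: pd.DataFrame, truth=None) -> None:
    """Write the MatrixMarket triplet + ``cells.tsv`` (+ ``truth.tsv``)."""
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    check_aligned(matrix, table)
    X = sp.coo_matrix(matrix.X)
    if not np.all(X.data == np.round(X.data)):
        scipy.io.mmwrite(str(path / "matrix.mtx"), X)
    else:
        scipy.io.mmwrite(str(path / "matrix.mtx"), X.astype(np.int64))
    with open(path / "features.tsv", "w", encoding="utf-8") as fh:
        for g in matrix.gene_ids:
            fh.write(f"{g}\t{g}\tGene Expression\n")
    with open(path / "barcodes.tsv", "w", encoding="utf-8") as fh:
        for c in matrix.cell_ids:
            fh.write(f"{c}\n")
    write_tsv(path / "cells.tsv", table)
    if truth is not None:
        write_tsv(path / "truth.tsv", truth.cells)


def read_dense_tsv(path) -> CountMatrix:
    """Read a toy dense genes × cells TSV (first column gene ids, header row
    of cell ids)."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    return CountMatrix(
        sp.csc_matrix(df.to_numpy()), df.index.to_numpy(dtype=object), df.columns.to_numpy(dtype=object)
    )


def write_tsv(path, frame: pd.DataFrame) -> None:
    """UTF-8 TSV with header and no index column."""
    frame.to_csv(path, sep="\t", index=False, encoding="utf-8")


def read_gene_set(path, name: str | None = None) -> GeneSet:
    """One-gene-per-line list (blank lines and ``#`` comments ignored)."""
    path = Path(path)
    genes = []
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            line = line.strip()
            if line and not line.startswith("#"):
                genes.append(line)
    return GeneSet(name or path.stem, genes)


def read_gmt(path) -> dict:
    """GMT file -> {set name: GeneSet}; column 2 (description) ignored."""
    out = {}
    with open(path, encoding="utf-8") as fh:
        for line_no, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise CohortParseError(f"{Path(path).name}:{line_no}: GMT rows need >= 3 columns")
            out[fields[0]] = GeneSet(fields[0], [g for g in fields[2:] if g])
    return out


def write_gmt(path, gene_sets: dict) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for name in sorted(gene_sets):
            genes = list(gene_sets[name])
            fh.write("\t".join([name, ""] + genes) + "\n")
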