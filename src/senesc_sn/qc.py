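"""Nucleus- and gene-level quality control.

Three per-nucleus metrics drive filtering: the number of genes with non-zero
counts, the total UMI count, and the mitochondrial read fraction. A nucleus
is retained when it passes every enabled rule:

* genes detected strictly greater than ``min_genes_exclusive`` (default 600);
* total UMIs strictly greater than ``min_umis_exclusive`` (default 950);
* mitochondrial fraction strictly below ``median + mito_mad_multiplier × MAD``
  (default multiplier 5), the median and MAD computed per library by default,
  over the population present before threshold-based removal.

The MAD here is the raw median absolute deviation, without the 1.4826
normal-consistency constant; the large multiplier absorbs the scale.
Doublet-flagged nuclei are removed first when ``drop_doublets``. After cell
filtering, genes with non-zero counts in fewer than ``min_cells_per_gene``
retained nuclei (default 20) are dropped; gene filtering never feeds back
into cell filtering.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .datatypes import ConfigError, CountMatrix, check_aligned

__all__ = ["QCThresholds", "compute_cell_qc", "filter_cells", "filter_genes", "run_qc"]

logger = logging.getLogger(__name__)

MITO_PREFIX = "mt-"


@dataclass
class QCThresholds:
    min_genes_exclusive: int = 600
    min_umis_exclusive: int = 950
    mito_mad_multiplier: float = 5.0
    min_cells_per_gene: int = 20
    drop_doublets: bool = True
    mito_scope: str = "per_library"  # or "global"

    def __post_init__(self) -> None:
        for name in ("min_genes_exclusive", "min_umis_exclusive", "mito_mad_multiplier", "min_cells_per_gene"):
            if getattr(self, name) < 0:
                raise ConfigError(f"{name} must be >= 0")
        if self.mito_scope not in ("per_library", "global"):
            raise ConfigError("mito_scope must be 'per_library' or 'global'")


def compute_cell_qc(matrix: CountMatrix, table: pd.DataFrame, mito_prefix: str = MITO_PREFIX) -> pd.DataFrame:
    """Per-nucleus QC metrics on the raw matrix.

    Returns a DataFrame aligned with the matrix columns with columns
    ``cell_id, sample_id, total_umi, genes_detected, mito_fraction``.
    ``mito_fraction`` is 0 for empty (all-zero) nuclei. Mitochondrial genes
    are identified by a case-insensitive id prefix.
    """
    check_aligned(matrix, table)
    totals = matrix.cell_totals().astype(float)
    genes_detected = matrix.genes_detected().astype(int)
    mito_mask = np.array(
        [str(g).lower().startswith(mito_prefix.lower()) for g in matrix.gene_ids]
    )
    mito_counts = (
        np.asarray(matrix.X[mito_mask, :].sum(axis=0)).ravel()
        if mito_mask.any()
        else np.zeros(matrix.n_cells)
    )
    with np.errstate(invalid="ignore", divide="ignore"):
        mito_fraction = np.where(totals > 0, mito_counts / np.maximum(totals, 1e-300), 0.0)
    return pd.DataFrame(
        {
            "cell_id": matrix.cell_ids,
            "sample_id": table["sample_id"].to_numpy(),
            "total_umi": totals,
            "genes_detected": genes_detected,
            "mito_fraction": mito_fraction,
        }
    )


def _mad(x: np.ndarray) -> float:
    """Raw median absolute deviation (no consistency constant)."""
    med = np.median(x)
    return float(np.median(np.abs(x - med)))


def _mito_pass(mito: np.ndarray, multiplier: float) -> np.ndarray:
    """Strict mito rule within one population; degenerate MAD=0 relaxes the
    strict bound to ``<= median`` so identical cells are not annihilated."""
    med = float(np.median(mito))
    mad = _mad(mito)
    bound = med + multiplier * mad
    if mad == 0.0:
        logger.warning(
            "mitochondrial MAD is 0 (bound equals the median %.4g); "
            "passing cells at or below the median", med
        )
        return mito <= med
    return mito < bound


def filter_cells(qc: pd.DataFrame, table: pd.DataFrame, thresholds: QCThresholds) -> list:
    """Return the ids of nuclei passing every rule, in input order.

    ``qc`` must have been computed on the raw (pre-filter) matrix. Doublets
    are removed first when requested; the mitochondrial median/MAD are then
    computed over the remaining population (per library under the default
    scope) before any threshold-based removal.
    """
    qc = qc.set_index("cell_id", drop=False)
    table = table.set_index("cell_id", drop=False)
    ids = qc["cell_id"].to_numpy(dtype=object)
    keep = np.ones(len(qc), dtype=bool)
    if thresholds.drop_doublets and "is_doublet" in table.columns:
        keep &= ~table.loc[ids, "is_doublet"].to_numpy(dtype=bool)

    genes_ok = qc["genes_detected"].to_numpy() > thresholds.min_genes_exclusive
    umis_ok = qc["total_umi"].to_numpy() > thresholds.min_umis_exclusive

    mito = qc["mito_fraction"].to_numpy(dtype=float)
    mito_ok = np.zeros(len(qc), dtype=bool)
    if thresholds.mito_scope == "global":
        if keep.any():
            mito_ok[keep] = _mito_pass(mito[keep], thresholds.mito_mad_multiplier)
    else:
        for sample_id, idx in qc.groupby("sample_id", sort=False).indices.items():
            pop = np.asarray(idx)[keep[np.asarray(idx)]]
            if len(pop) == 0:
                logger.warning("library %s has no nuclei entering QC; none retained", sample_id)
                continue
            mito_ok[pop] = _mito_pass(mito[pop], thresholds.mito_mad_multiplier)

    keep &= genes_ok & umis_ok & mito_ok
    return list(ids[keep])


def filter_genes(matrix: CountMatrix, min_cells_per_gene: int = 20) -> list:
    """Ids of genes with non-zero counts in at least ``min_cells_per_gene``
    nuclei of the given (already cell-filtered) matrix."""
    ncells = matrix.cells_detected()
    return list(matrix.gene_ids[ncells >= min_cells_per_gene])


def run_qc(
    matrix: CountMatrix,
    table: pd.DataFrame,
    thresholds: QCThresholds | None = None,
    mito_prefix: str = MITO_PREFIX,
):
    """Full QC pass: doublet removal -> cell thresholds -> gene filter.

    Returns ``(filtered_matrix, filtered_table, report, summary)`` where
    ``report`` is the per-nucleus metric table with per-rule pass flags and
    ``summary`` counts nuclei/genes before and after and per-rule failures.
    """
    thresholds = thresholds or QCThresholds()
    qc = compute_cell_qc(matrix, table, mito_prefix=mito_prefix)
    retained_cells = filter_cells(qc, table, thresholds)
    retained_set = set(retained_cells)

    cell_matrix = matrix.subset_cells(retained_cells)
    retained_genes = filter_genes(cell_matrix, thresholds.min_cells_per_gene)
    out_matrix = cell_matrix.subset_genes(retained_genes)
    out_table = table[table["cell_id"].isin(retained_set)].reset_index(drop=True)

    report = qc.copy()
    report["pass_genes"] = report["genes_detected"] > thresholds.min_genes_exclusive
    report["pass_umis"] = report["total_umi"] > thresholds.min_umis_exclusive
    is_dbl = (
        table.set_index("cell_id").loc[report["cell_id"], "is_doublet"].to_numpy(dtype=bool)
        if "is_doublet" in table.columns
        else np.zeros(len(report), bool)
    )
    report["is_doublet"] = is_dbl
    report["retained"] = report["cell_id"].isin(retained_set)

    summary = {
        "nuclei_before": int(matrix.n_cells),
        "nuclei_after": int(out_matrix.n_cells),
        "genes_before": int(matrix.n_genes),
        "genes_after": int(out_matrix.n_genes),
        "failed_doublet": int(is_dbl.sum()) if thresholds.drop_doublets else 0,
        "failed_genes_rule": int((~report["pass_genes"]).sum()),
        "failed_umis_rule": int((~report["pass_umis"]).sum()),
    }
    return out_matrix, out_table, report, summary
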