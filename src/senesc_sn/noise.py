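"""Transcriptional noise (cell-to-cell heterogeneity) per cell type.

The procedure, applied to a QC-filtered cohort:

1. **Library downsampling** — every nucleus is downsampled without
   replacement (multivariate hypergeometric) to a common UMI total, by
   default the smallest per-nucleus total among the cells entering the
   analysis, so no cell is dropped.
2. **Cell subsampling** — at most ``max_cells_per_type`` nuclei (default 300)
   per (cell type, condition) group; smaller groups keep all nuclei.
3. **Stable-gene selection** — per cell type, on the pooled cells of both
   conditions: genes are ranked by mean downsampled expression, split into
   ``n_expression_blocks`` (default 10) contiguous equal-size blocks
   (remainder to the highest-expression block), and within each block the
   lowest ``cv_keep_fraction`` (default 10%) of coefficients of variation
   are kept.
4. **Distances** — per (type, condition) group, expression of the stable
   genes is log1p-transformed and each nucleus's Euclidean distance to the
   group centroid is computed (``mean_pairwise`` offered as an alternative);
   the group's noise is the mean per-nucleus distance.

A type's heterogeneity shift is reported as ``log2(noise_HP / noise_LP)``;
types with fewer than ``min_cells_per_group`` nuclei (default 10) in either
condition after subsampling are skipped.
"""

from __future__ import annotations

import logging
import math
import zlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy.spatial.distance import pdist

from .datatypes import ConfigError, CountMatrix, check_aligned

__all__ = [
    "NoiseParams",
    "NoiseResult",
    "downsample_library",
    "subsample_cells",
    "select_stable_genes",
    "noise_distances",
    "transcriptional_noise",
]

logger = logging.getLogger(__name__)


@dataclass
class NoiseParams:
    min_cells_per_group: int = 10
    max_cells_per_type: int = 300
    n_expression_blocks: int = 10
    cv_keep_fraction: float = 0.10
    library_target: int | str = "min_retained"  # or a fixed UMI total
    distance_mode: str = "to_centroid"  # or "mean_pairwise"
    log_transform: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 < self.cv_keep_fraction <= 1):
            raise ConfigError("cv_keep_fraction must lie in (0, 1]")
        if self.n_expression_blocks < 1:
            raise ConfigError("n_expression_blocks must be >= 1")
        if self.min_cells_per_group < 2:
            raise ConfigError("min_cells_per_group must be >= 2")
        if self.distance_mode not in ("to_centroid", "mean_pairwise"):
            raise ConfigError("distance_mode must be 'to_centroid' or 'mean_pairwise'")
        if isinstance(self.library_target, str) and self.library_target != "min_retained":
            raise ConfigError("library_target must be 'min_retained' or an integer")
        if isinstance(self.library_target, int) and self.library_target < 1:
            raise ConfigError("fixed library_target must be >= 1")


@dataclass
class NoiseResult:
    per_group: pd.DataFrame  # cell_type, condition, n_cells, n_genes, noise
    ratios: pd.DataFrame  # cell_type, log2_ratio
    skipped_types: list = field(default_factory=list)
    library_target: int = 0
    dropped_cells: list = field(default_factory=list)


def downsample_library(matrix: CountMatrix, target: int, seed: int):
    """Downsample every nucleus to exactly ``target`` UMIs without replacement.

    Nuclei with fewer than ``target`` total UMIs are dropped and reported.
    Returns ``(downsampled CountMatrix, dropped cell-id list)``.
    """
    if target < 1:
        raise ConfigError("downsampling target must be >= 1")
    totals = matrix.cell_totals()
    keep = totals >= target
    if not keep.any():
        raise ConfigError(f"no nucleus reaches the downsampling target {target}")
    dropped = list(matrix.cell_ids[~keep])
    X = sp.csc_matrix(matrix.X)
    cols = []
    for j in np.flatnonzero(keep):
        col = X[:, j]
        colors = col.data.astype(np.int64)
        total = int(colors.sum())
        if total == target:
            cols.append(col)
            continue
        # per-cell stream keyed on the cell id: the draw for a cell does not
        # depend on the order cells are stored in
        rng = np.random.default_rng([seed, zlib.crc32(str(matrix.cell_ids[j]).encode())])
        drawn = rng.multivariate_hypergeometric(colors, target, method="marginals")
        nz = drawn > 0
        new = sp.csc_matrix(
            (drawn[nz], (col.indices[nz], np.zeros(nz.sum(), int))), shape=(matrix.n_genes, 1)
        )
        cols.append(new)
    out = sp.hstack(cols, format="csc")
    return CountMatrix(out, matrix.gene_ids, matrix.cell_ids[keep]), dropped


def subsample_cells(table: pd.DataFrame, max_per_type: int, seed: int) -> list:
    """Uniform without-replacement sample of at most ``max_per_type`` nuclei
    per (cell type, condition) group; smaller groups keep every nucleus."""
    kept = []
    for (cell_type, condition), group in table.groupby(["cell_type", "condition"], sort=True):
        ids = np.sort(group["cell_id"].to_numpy(dtype=object))
        if len(ids) <= max_per_type:
            kept.extend(ids)
        else:
            # group-keyed stream over id-sorted cells: the chosen subset does
            # not depend on the table's row order
            rng = np.random.default_rng(
                [seed, zlib.crc32(f"{cell_type}|{condition}".encode())]
            )
            kept.extend(rng.choice(ids, size=max_per_type, replace=False))
    order = {c: i for i, c in enumerate(table["cell_id"])}
    return sorted(kept, key=order.__getitem__)


def select_stable_genes(matrix: CountMatrix, params: NoiseParams) -> list:
    """Low-CV genes within contiguous mean-expression blocks.

    Genes with zero mean are excluded; the remainder are sorted by mean
    (ascending; ties broken by gene id), split into ``n_expression_blocks``
    equal-size blocks with the remainder assigned to the highest-expression
    block, and within each block the ``ceil(cv_keep_fraction × block size)``
    genes with the smallest CV (sample sd / mean, ties by gene id) are kept.
    """
    # canonical column order: float summation is not associative, so gene
    # means/CVs (and hence block boundaries) must not depend on cell order
    matrix = matrix.subset_cells(sorted(matrix.cell_ids))
    dense = matrix.toarray().astype(float)
    means = dense.mean(axis=1)
    nonzero = means > 0
    gene_ids = matrix.gene_ids[nonzero]
    means_nz = means[nonzero]
    if len(gene_ids) < params.n_expression_blocks:
        raise ConfigError(
            f"{len(gene_ids)} expressed genes < {params.n_expression_blocks} blocks"
        )
    sds = dense[nonzero].std(axis=1, ddof=1)
    cvs = sds / means_nz

    order = np.lexsort((gene_ids, means_nz))  # ascending mean, ties by id
    nb = params.n_expression_blocks
    base = len(order) // nb
    kept = []
    start = 0
    for b in range(nb):
        size = base if b < nb - 1 else len(order) - base * (nb - 1)
        block = order[start : start + size]
        start += size
        k = math.ceil(params.cv_keep_fraction * size)
        inner = np.lexsort((gene_ids[block], cvs[block]))
        kept.extend(gene_ids[block][inner[:k]])
    return sorted(kept)


def noise_distances(values: np.ndarray, mode: str = "to_centroid") -> np.ndarray:
    """Per-nucleus heterogeneity of a (cells × genes) expression block.

    ``to_centroid``: Euclidean distance of each nucleus to the group mean
    vector. ``mean_pairwise``: each nucleus's mean Euclidean distance to all
    other nuclei of the group.
    """
    values = np.asarray(values, dtype=float)
    if values.ndim != 2 or values.shape[0] < 1:
        raise ValueError("values must be a non-empty 2-D (cells x genes) array")
    if mode == "to_centroid":
        centroid = values.mean(axis=0)
        return np.sqrt(((values - centroid) ** 2).sum(axis=1))
    if mode == "mean_pairwise":
        n = values.shape[0]
        if n == 1:
            return np.zeros(1)
        full = np.zeros((n, n))
        cond = pdist(values, metric="euclidean")
        iu = np.triu_indices(n, 1)
        full[iu] = cond
        full += full.T
        return full.sum(axis=1) / (n - 1)
    raise ConfigError(f"unknown distance mode {mode!r}")


def transcriptional_noise(
    matrix: CountMatrix, table: pd.DataFrame, params: NoiseParams | None = None
) -> NoiseResult:
    """Full noise pipeline on a QC-filtered cohort.

    Stage order is fixed: library downsampling, cell subsampling, per-type
    stable-gene selection on the pooled conditions, per-group distances.
    """
    params = params or NoiseParams()
    check_aligned(matrix, table)

    totals = matrix.cell_totals()
    if params.library_target == "min_retained":
        target = int(totals.min())
    else:
        target = int(params.library_target)
    down, dropped = downsample_library(matrix, target, seed=params.seed)
    down_table = table[table["cell_id"].isin(set(down.cell_ids))].reset_index(drop=True)

    kept_ids = subsample_cells(down_table, params.max_cells_per_type, seed=params.seed + 1)
    sub = down.subset_cells(kept_ids)
    sub_table = down_table[down_table["cell_id"].isin(set(kept_ids))].reset_index(drop=True)

    rows, ratio_rows, skipped = [], [], []
    for cell_type in sorted(sub_table["cell_type"].unique()):
        t_mask = sub_table["cell_type"] == cell_type
        group_sizes = {
            cond: int(((sub_table["condition"] == cond) & t_mask).sum()) for cond in ("LP", "HP")
        }
        if any(n < params.min_cells_per_group for n in group_sizes.values()):
            skipped.append(cell_type)
            logger.warning(
                "skipping %s: group sizes %s below minimum %d",
                cell_type, group_sizes, params.min_cells_per_group,
            )
            continue
        pooled = sub.subset_cells(sub_table.loc[t_mask, "cell_id"])
        stable = select_stable_genes(pooled, params)
        noise_by_cond = {}
        for cond in ("LP", "HP"):
            ids = sorted(sub_table.loc[t_mask & (sub_table["condition"] == cond), "cell_id"])
            block = pooled.subset_genes(stable).subset_cells(ids).toarray().T.astype(float)
            if params.log_transform:
                block = np.log1p(block)
            dists = noise_distances(block, mode=params.distance_mode)
            noise_by_cond[cond] = float(dists.mean())
            rows.append(
                {
                    "cell_type": cell_type,
                    "condition": cond,
                    "n_cells": block.shape[0],
                    "n_genes": len(stable),
                    "noise": noise_by_cond[cond],
                }
            )
        lp, hp = noise_by_cond["LP"], noise_by_cond["HP"]
        if lp == 0 and hp > 0:
            logger.warning("%s: zero LP noise with non-zero HP noise; ratio set to +inf", cell_type)
            ratio = math.inf
        elif lp == 0 and hp == 0:
            ratio = 0.0
        else:
            ratio = math.log2(hp / lp)
        ratio_rows.append({"cell_type": cell_type, "log2_ratio": ratio})

    return NoiseResult(
        per_group=pd.DataFrame(rows, columns=["cell_type", "condition", "n_cells", "n_genes", "noise"]),
        ratios=pd.DataFrame(ratio_rows, columns=["cell_type", "log2_ratio"]),
        skipped_types=skipped,
        library_target=target,
        dropped_cells=dropped,
    )
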