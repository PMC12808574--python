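"""Gene-set module scoring with expression-bin-matched control genes.

The module score of a gene set in a nucleus is the mean normalized
expression of the set's genes minus the mean expression of a pool of
control genes drawn to match the set's expression profile: all genes are
binned into ``n_expression_bins`` equal-frequency bins by their mean
normalized expression across nuclei, and each set gene contributes
``n_control_per_gene`` control genes sampled uniformly without replacement
from its own bin (set genes excluded from eligibility). A positive score
therefore means the set is expressed above expectation for genes of its
expression level in that nucleus.

Built on this primitive:

* **pathway scores** — SASP / DNA-damage / inflammation-style signatures
  supplied as gene lists;
* **diversity score** — each nucleus scored against its own cell type's
  highly variable gene (HVG) set derived from the reference (LP) condition;
  loss of cell-type identity shows up as a drop in this score;
* **HVG selection** — per type, genes ranked by variance of log-normalized
  expression standardized against a mean–variance trend (median variance in
  20 mean-ranked bins).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.sparse as sp

from .datatypes import ConfigError, CountMatrix, GeneSet, check_aligned

__all__ = [
    "ScoreParams",
    "normalize_log1p",
    "module_score",
    "select_hvgs_per_type",
    "diversity_score",
    "pathway_scores",
]

logger = logging.getLogger(__name__)


@dataclass
class ScoreParams:
    n_expression_bins: int = 24
    n_control_per_gene: int = 100
    normalization_scale: float = 10_000.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_expression_bins < 2:
            raise ConfigError("n_expression_bins must be >= 2")
        if self.n_control_per_gene < 1:
            raise ConfigError("n_control_per_gene must be >= 1")
        if self.normalization_scale <= 0:
            raise ConfigError("normalization_scale must be > 0")


def normalize_log1p(matrix: CountMatrix, scale: float = 10_000.0) -> CountMatrix:
    """Scale each nucleus to ``scale`` total counts, then log(1+x).

    All-zero nuclei map to all-zero columns. Returns a new float matrix."""
    X = sp.csc_matrix(matrix.X, dtype=float, copy=True)
    totals = np.asarray(X.sum(axis=0)).ravel()
    factors = np.where(totals > 0, scale / np.maximum(totals, 1e-300), 0.0)
    X = X @ sp.diags(factors)
    X.data = np.log1p(X.data)
    return CountMatrix(X, matrix.gene_ids, matrix.cell_ids)


def _expression_bins(gene_ids: np.ndarray, means: np.ndarray, n_bins: int) -> list:
    """Equal-frequency bins of gene indices by mean expression (ties by id)."""
    order = np.lexsort((gene_ids, means))
    return [np.asarray(chunk) for chunk in np.array_split(order, n_bins)]


def module_score(
    norm_matrix: CountMatrix, gene_set: GeneSet, params: ScoreParams | None = None
) -> pd.Series:
    """Per-nucleus module score of a gene set on a normalized matrix.

    Deterministic for a fixed ``params.seed``. Set genes absent from the
    matrix are dropped with a warning; an empty intersection is an error.
    """
    params = params or ScoreParams()
    present = [g for g in gene_set.genes if g in set(norm_matrix.gene_ids)]
    missing = sorted(set(gene_set.genes) - set(present))
    if not present:
        raise ConfigError(f"no gene of set {gene_set.name!r} is present in the matrix")
    if missing:
        logger.warning("set %s: %d genes absent from the matrix", gene_set.name, len(missing))

    X = sp.csr_matrix(norm_matrix.X)
    means = np.asarray(X.mean(axis=1)).ravel()
    bins = _expression_bins(norm_matrix.gene_ids, means, params.n_expression_bins)
    bin_of = np.empty(norm_matrix.n_genes, dtype=int)
    for b, idx in enumerate(bins):
        bin_of[idx] = b

    set_idx = norm_matrix.gene_index(present)
    set_mask = np.zeros(norm_matrix.n_genes, dtype=bool)
    set_mask[set_idx] = True

    rng = np.random.default_rng(params.seed)
    control_idx = []
    for gi in set_idx:
        eligible = bins[bin_of[gi]]
        eligible = eligible[~set_mask[eligible]]
        if len(eligible) == 0:
            logger.warning(
                "set %s: no eligible control genes in the bin of gene %s",
                gene_set.name, norm_matrix.gene_ids[gi],
            )
            continue
        k = min(params.n_control_per_gene, len(eligible))
        control_idx.append(rng.choice(np.sort(eligible), size=k, replace=False))
    if not control_idx:
        raise ConfigError(f"set {gene_set.name!r}: no control genes could be drawn")
    control_idx = np.concatenate(control_idx)

    set_mean = np.asarray(X[set_idx, :].mean(axis=0)).ravel()
    ctrl_mean = np.asarray(X[control_idx, :].mean(axis=0)).ravel()
    return pd.Series(set_mean - ctrl_mean, index=norm_matrix.cell_ids, name=gene_set.name)


def select_hvgs_per_type(
    norm_matrix: CountMatrix,
    table: pd.DataFrame,
    condition: str = "LP",
    n_hvg: int = 200,
    n_trend_bins: int = 20,
) -> dict:
    """Per-cell-type highly variable gene sets from one reference condition.

    For each type with >= 2 cells in ``condition``: per-gene mean and sample
    variance of log-normalized expression are computed over that type's
    reference cells; the variance is standardized against a mean–variance
    trend (median variance within ``n_trend_bins`` equal-frequency mean
    bins) and the top ``n_hvg`` genes by standardized variance are returned.
    Constant (zero-variance) genes are never selected.
    """
    check_aligned(norm_matrix, table)
    if condition not in set(table["condition"]):
        raise ConfigError(f"reference condition {condition!r} absent from the table")
    out = {}
    for cell_type, group in table[table["condition"] == condition].groupby("cell_type", sort=True):
        if len(group) < 2:
            logger.warning("type %s has < 2 reference cells; skipped", cell_type)
            continue
        sub = norm_matrix.subset_cells(group["cell_id"]).toarray().astype(float)
        means = sub.mean(axis=1)
        variances = sub.var(axis=1, ddof=1)
        nonconstant = variances > 0
        if not nonconstant.any():
            logger.warning("type %s: all genes constant; skipped", cell_type)
            continue
        ids = norm_matrix.gene_ids[nonconstant]
        m, v = means[nonconstant], variances[nonconstant]
        bins = _expression_bins(ids, m, min(n_trend_bins, len(ids)))
        trend = np.empty(len(ids))
        for idx in bins:
            trend[idx] = max(np.median(v[idx]), 1e-12)
        std_var = v / trend
        order = np.lexsort((ids, -std_var))
        k = min(n_hvg, len(order))
        if n_hvg > len(order):
            logger.warning(
                "type %s: requested %d HVGs but only %d non-constant genes", cell_type, n_hvg, len(order)
            )
        out[cell_type] = GeneSet(f"hvg_{cell_type}", list(ids[order[:k]]))
    return out


def diversity_score(
    norm_matrix: CountMatrix,
    table: pd.DataFrame,
    hvg_sets: dict,
    params: ScoreParams | None = None,
) -> pd.DataFrame:
    """Each nucleus scored with its own cell type's HVG set.

    Returns a DataFrame (cell_id, cell_type, condition, score); nuclei of
    types without an HVG set get a missing score and are reported."""
    params = params or ScoreParams()
    check_aligned(norm_matrix, table)
    out = table[["cell_id", "cell_type", "condition"]].copy()
    out["score"] = np.nan
    for cell_type, gene_set in sorted(hvg_sets.items()):
        scores = module_score(norm_matrix, gene_set, params)
        mask = out["cell_type"] == cell_type
        out.loc[mask, "score"] = scores.loc[out.loc[mask, "cell_id"]].to_numpy()
    n_missing = int(out["score"].isna().sum())
    if n_missing:
        logger.warning("%d nuclei belong to types without an HVG set", n_missing)
    return out


def pathway_scores(
    norm_matrix: CountMatrix,
    table: pd.DataFrame,
    gene_sets: dict,
    params: ScoreParams | None = None,
) -> pd.DataFrame:
    """One module-score column per named gene set (long format).

    Returns a DataFrame (cell_id, set, score, condition, cell_type)."""
    params = params or ScoreParams()
    check_aligned(norm_matrix, table)
    frames = []
    meta = table.set_index("cell_id")
    for name in sorted(gene_sets):
        gs = gene_sets[name]
        if not isinstance(gs, GeneSet):
            gs = GeneSet(name, list(gs))
        scores = module_score(norm_matrix, gs, params)
        frames.append(
            pd.DataFrame(
                {
                    "cell_id": scores.index,
                    "set": name,
                    "score": scores.to_numpy(),
                    "condition": meta.loc[scores.index, "condition"].to_numpy(),
                    "cell_type": meta.loc[scores.index, "cell_type"].to_numpy(),
                }
            )
        )
    return pd.concat(frames, ignore_index=True)
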