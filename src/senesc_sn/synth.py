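"""Synthetic snRNA-seq cohort generator.

Emulates a two-condition dietary cohort (low-protein ``LP`` vs high-protein
``HP`` epididymal white adipose tissue) with replicate libraries, ~13 cell
types, negative-binomial UMI counts over type-specific expression profiles,
lognormal library sizes, a mitochondrial gene subset, a condition-dependent
composition shift (adipocytes collapse, macrophages expand under HP), a
senescence/SASP gene module upregulated in HP adipocytes, and an inflated
cell-to-cell heterogeneity factor in HP adipocytes.

Generative model, per cell:

1. the cell type is a draw from its condition's composition vector;
2. the expected expression is the type's relative-expression profile
   (marker genes elevated ``marker_fold``-fold in their own type; mitochondrial
   genes hold a fixed share of the profile) scaled to a lognormal library
   size;
3. HP adipocytes multiply senescence-module gene means by
   ``2**senescence_log2fc_hp_adipocyte``;
4. a per-cell, per-gene multiplicative lognormal jitter with mean 1 models
   biological cell-to-cell variability: variance ``base_jitter_var`` for
   most genes, ``marker_jitter_var`` for a type's own marker genes (identity
   programs fluctuate more within a type, which is what gives HVG-derived
   identity scores their signal), the whole row scaled by
   ``heterogeneity_factor_hp_adipocyte`` in HP adipocytes;
5. counts are negative-binomial with size parameter ``nb_dispersion``
   (variance mu + mu^2/dispersion; ``inf`` gives Poisson).

Identical configuration (including seed) yields bit-identical output.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np
import pandas as pd
import scipy.sparse as sp

from .datatypes import CELL_TABLE_COLUMNS, ConfigError, CountMatrix, GeneSet, check_aligned

__all__ = ["SimConfig", "SimTruth", "simulate_cohort", "inject_doublets", "DEFAULT_TYPE_NAMES"]

#: The major cell types of the emulated adipose-tissue atlas. Adipocyte and
#: macrophage carry the printed composition shift; the remaining types share
#: the residual mass evenly.
DEFAULT_TYPE_NAMES = (
    "adipocyte",
    "macrophage",
    "preadipocyte",
    "endothelial",
    "lymphatic_endothelial",
    "pericyte",
    "smooth_muscle",
    "mesothelial",
    "t_cell",
    "b_cell",
    "nk_cell",
    "dendritic_cell",
    "neutrophil",
)

CONDITIONS = ("LP", "HP")


def _default_composition(n_types: int, adipocyte: float, macrophage: float) -> np.ndarray:
    rest = (1.0 - adipocyte - macrophage) / (n_types - 2)
    return np.array([adipocyte, macrophage] + [rest] * (n_types - 2))


@dataclass
class SimConfig:
    """Configuration of a synthetic cohort.

    Defaults emulate the study conditions: 2 conditions × 2 replicate
    libraries, 13 cell types, adipocytes at 35.5% (LP) vs 8.4% (HP) and
    macrophages at 18.0% (LP) vs 27.8% (HP) of nuclei.
    """

    n_cell_types: int = 13
    type_names: tuple = DEFAULT_TYPE_NAMES
    n_genes: int = 2000
    n_marker_genes_per_type: int = 20
    marker_fold: float = 5.0
    mito_gene_fraction: float = 0.01
    mito_expression_fraction: float = 0.02
    mean_library_size: float = 3000.0
    library_size_cv: float = 0.5
    nb_dispersion: float = 10.0
    composition_lp: np.ndarray = None
    composition_hp: np.ndarray = None
    n_samples_per_condition: int = 2
    n_cells_per_sample: int = 5000
    senescence_module: Optional[GeneSet] = None
    n_senescence_genes: int = 50
    senescence_log2fc_hp_adipocyte: float = 1.0
    heterogeneity_factor_hp_adipocyte: float = 2.0
    base_jitter_var: float = 0.3
    marker_jitter_var: float = 1.0
    identity_shrink_hp_adipocyte: float = 0.0
    doublet_rate: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.composition_lp is None:
            self.composition_lp = _default_composition(self.n_cell_types, 0.355, 0.180)
        if self.composition_hp is None:
            self.composition_hp = _default_composition(self.n_cell_types, 0.084, 0.278)
        self.composition_lp = np.asarray(self.composition_lp, dtype=float)
        self.composition_hp = np.asarray(self.composition_hp, dtype=float)
        self.type_names = tuple(self.type_names)
        self.validate()

    def validate(self) -> None:
        if len(self.type_names) != self.n_cell_types:
            raise ConfigError("type_names length must equal n_cell_types")
        for name, comp in (("composition_lp", self.composition_lp), ("composition_hp", self.composition_hp)):
            if comp.shape != (self.n_cell_types,):
                raise ConfigError(f"{name} must have length n_cell_types")
            if np.any(comp < 0) or abs(comp.sum() - 1.0) > 1e-9:
                raise ConfigError(f"{name} entries must be >= 0 and sum to 1 within 1e-9")
        if self.n_cell_types < 1 or self.n_genes < 1 or self.n_marker_genes_per_type < 1:
            raise ConfigError("counts must be >= 1")
        if self.n_samples_per_condition < 1:
            raise ConfigError("n_samples_per_condition must be >= 1")
        if self.n_cells_per_sample < 0:
            raise ConfigError("n_cells_per_sample must be >= 0")
        if not (self.nb_dispersion > 0):
            raise ConfigError("nb_dispersion must be > 0")
        if self.heterogeneity_factor_hp_adipocyte < 1:
            raise ConfigError("heterogeneity_factor_hp_adipocyte must be >= 1")
        if not (0 <= self.mito_gene_fraction <= 1):
            raise ConfigError("mito_gene_fraction must lie in [0, 1]")
        if not (0 <= self.doublet_rate < 1):
            raise ConfigError("doublet_rate must lie in [0, 1)")
        if not (0 <= self.identity_shrink_hp_adipocyte <= 1):
            raise ConfigError("identity_shrink_hp_adipocyte must lie in [0, 1]")
        if self.base_jitter_var < 0 or self.marker_jitter_var < 0:
            raise ConfigError("jitter variances must be >= 0")
        n_mito = math.ceil(self.mito_gene_fraction * self.n_genes)
        reserved = n_mito + self.n_cell_types * self.n_marker_genes_per_type
        if self.senescence_module is None:
            reserved += self.n_senescence_genes
        if reserved > self.n_genes:
            raise ConfigError(
                f"n_genes={self.n_genes} too small for {n_mito} mito + "
                f"{self.n_cell_types * self.n_marker_genes_per_type} marker "
                f"(+ default senescence) genes"
            )

    @property
    def n_mito_genes(self) -> int:
        return math.ceil(self.mito_gene_fraction * self.n_genes)

    def gene_names(self) -> np.ndarray:
        """Deterministic gene identifiers; mitochondrial genes carry an ``mt-`` prefix."""
        n_mito = self.n_mito_genes
        names = [f"mt-g{i:04d}" for i in range(n_mito)]
        names += [f"g{i:04d}" for i in range(n_mito, self.n_genes)]
        return np.array(names, dtype=object)

    def marker_gene_map(self) -> dict:
        """Map cell type -> list of its marker gene ids."""
        names = self.gene_names()
        start = self.n_mito_genes
        m = self.n_marker_genes_per_type
        return {
            t: list(names[start + k * m : start + (k + 1) * m])
            for k, t in enumerate(self.type_names)
        }

    def default_senescence_module(self) -> GeneSet:
        """The 50 (by default) synthetic genes immediately after the marker block."""
        names = self.gene_names()
        start = self.n_mito_genes + self.n_cell_types * self.n_marker_genes_per_type
        return GeneSet("senescence_sasp", list(names[start : start + self.n_senescence_genes]))

    def resolved_senescence_module(self) -> GeneSet:
        return self.senescence_module if self.senescence_module is not None else self.default_senescence_module()


@dataclass
class SimTruth:
    """Ground truth of a simulated cohort."""

    cells: pd.DataFrame  # cell_id, sample_id, condition, cell_type, is_doublet, library_size
    type_proportions: pd.DataFrame  # index: cell type, columns: LP, HP (configured truth)
    gene_base_mean: pd.Series  # per-gene relative base expression (mean profile over types)
    senescence_genes: list = field(default_factory=list)
    heterogeneity_factor: float = 1.0


def _type_profiles(config: SimConfig, rng: np.random.Generator) -> np.ndarray:
    """Relative-expression profiles, one row per type, each summing to 1.

    A shared lognormal baseline across types, with each type's marker genes
    elevated ``marker_fold``-fold; the mitochondrial block holds a fixed share
    ``mito_expression_fraction`` of every profile.
    """
    base = rng.lognormal(mean=0.0, sigma=1.0, size=config.n_genes)
    profiles = np.tile(base, (config.n_cell_types, 1))
    start = config.n_mito_genes
    m = config.n_marker_genes_per_type
    for k in range(config.n_cell_types):
        sl = slice(start + k * m, start + (k + 1) * m)
        profiles[k, sl] *= config.marker_fold
    n_mito = config.n_mito_genes
    mf = config.mito_expression_fraction if n_mito > 0 else 0.0
    for k in range(config.n_cell_types):
        row = profiles[k]
        if n_mito > 0:
            row[:n_mito] *= mf / row[:n_mito].sum()
            row[n_mito:] *= (1.0 - mf) / row[n_mito:].sum()
        else:
            row /= row.sum()
    return profiles


def _lognormal_params(mean: float, var: float) -> tuple:
    """(mu, sigma) of a lognormal with the given mean and variance."""
    if mean <= 0:
        raise ValueError("mean must be > 0")
    sigma2 = math.log1p(var / mean**2)
    return math.log(mean) - sigma2 / 2.0, math.sqrt(sigma2)


def simulate_cohort(config: SimConfig):
    """Generate a seeded synthetic cohort.

    Returns
    -------
    (CountMatrix, cell table DataFrame, SimTruth)
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    gene_ids = config.gene_names()
    profiles = _type_profiles(config, rng)
    type_names = list(config.type_names)
    adip_idx = type_names.index("adipocyte") if "adipocyte" in type_names else None

    sen_module = config.resolved_senescence_module()
    unknown = sorted(set(sen_module.genes) - set(gene_ids))
    if unknown:
        raise ConfigError(f"senescence module references unknown genes: {unknown[:5]}")
    gene_pos = {g: i for i, g in enumerate(gene_ids)}
    sen_idx = np.array([gene_pos[g] for g in sen_module.genes], dtype=int)

    # HP-adipocyte profile variant: identity (marker) genes optionally shrunk
    # toward the across-type mean profile, senescence module boosted.
    hp_adip_profile = None
    if adip_idx is not None:
        hp_adip_profile = profiles[adip_idx].copy()
        s = config.identity_shrink_hp_adipocyte
        if s > 0:
            global_mean = profiles.mean(axis=0)
            hp_adip_profile = (1.0 - s) * hp_adip_profile + s * global_mean

    lib_mu, lib_sigma = _lognormal_params(
        config.mean_library_size, (config.library_size_cv * config.mean_library_size) ** 2
    )

    blocks, meta_rows = [], []
    compositions = {"LP": config.composition_lp, "HP": config.composition_hp}
    for condition in CONDITIONS:
        comp = compositions[condition]
        for s_idx in range(config.n_samples_per_condition):
            sample_id = f"{condition}_{s_idx + 1}"
            n = config.n_cells_per_sample
            type_counts = rng.multinomial(n, comp) if n > 0 else np.zeros(len(comp), int)
            type_codes = np.repeat(np.arange(config.n_cell_types), type_counts)
            lib_sizes = rng.lognormal(lib_mu, lib_sigma, size=n)
            mu = profiles[type_codes] * lib_sizes[:, None]  # cells x genes
            is_hp_adip = (
                (condition == "HP") & (type_codes == adip_idx)
                if adip_idx is not None
                else np.zeros(n, bool)
            )
            if adip_idx is not None and is_hp_adip.any():
                mu[is_hp_adip] = hp_adip_profile * lib_sizes[is_hp_adip, None]
                mu[np.ix_(is_hp_adip, sen_idx)] *= 2.0**config.senescence_log2fc_hp_adipocyte
            if n > 0 and (config.base_jitter_var > 0 or config.marker_jitter_var > 0):
                # per-cell x gene lognormal jitter variance: identity (marker)
                # genes fluctuate more within their own type, so HVG-based
                # identity scores have signal; HP adipocytes scale the whole
                # row by the heterogeneity factor
                V = np.full(mu.shape, config.base_jitter_var)
                m = config.n_marker_genes_per_type
                start = config.n_mito_genes
                for k in range(config.n_cell_types):
                    rows = type_codes == k
                    if rows.any():
                        V[rows, start + k * m : start + (k + 1) * m] = config.marker_jitter_var
                V[is_hp_adip] *= config.heterogeneity_factor_hp_adipocyte
                sig = np.sqrt(np.log1p(V))
                log_jit = rng.normal(0.0, 1.0, size=mu.shape) * sig
                mu *= np.exp(log_jit - sig**2 / 2.0)
            if np.isinf(config.nb_dispersion):
                counts = rng.poisson(mu)
            else:
                lam = rng.gamma(config.nb_dispersion, mu / config.nb_dispersion)
                counts = rng.poisson(lam)
            blocks.append(sp.csc_matrix(counts.T))  # genes x cells
            for j in range(n):
                meta_rows.append(
                    (
                        f"{sample_id}:c{j:05d}",
                        sample_id,
                        condition,
                        type_names[type_codes[j]],
                        False,
                        float(lib_sizes[j]),
                    )
                )

    if blocks and sum(b.shape[1] for b in blocks) > 0:
        X = sp.hstack(blocks, format="csc")
    else:
        X = sp.csc_matrix((config.n_genes, 0), dtype=np.int64)
    table = pd.DataFrame(meta_rows, columns=list(CELL_TABLE_COLUMNS) + ["library_size"])
    matrix = CountMatrix(X, gene_ids, table["cell_id"].to_numpy(dtype=object))

    truth = SimTruth(
        cells=table.copy(),
        type_proportions=pd.DataFrame(
            {"LP": config.composition_lp, "HP": config.composition_hp}, index=type_names
        ),
        gene_base_mean=pd.Series(profiles.mean(axis=0), index=gene_ids),
        senescence_genes=list(sen_module.genes),
        heterogeneity_factor=config.heterogeneity_factor_hp_adipocyte,
    )
    table = table[list(CELL_TABLE_COLUMNS)]

    if config.doublet_rate > 0 and matrix.n_cells > 0:
        matrix, table = inject_doublets(
            matrix, table, config.doublet_rate, seed=config.seed + 1_000_003
        )
    return matrix, table, truth


def inject_doublets(matrix: CountMatrix, table: pd.DataFrame, rate: float, seed: int):
    """Append synthetic doublets: column sums of two same-sample cells.

    ``round(rate * n_sample)`` doublets are appended per sample; original
    columns are untouched. Appended rows carry ``is_doublet=True`` and record
    their parent cell ids in ``doublet_parent_a`` / ``doublet_parent_b``.
    """
    if not (0 <= rate < 1):
        raise ConfigError("doublet rate must lie in [0, 1)")
    check_aligned(matrix, table)
    if rate == 0 or matrix.n_cells == 0:
        return matrix, table
    rng = np.random.default_rng(seed)
    new_cols, new_rows = [], []
    for sample_id, group in table.groupby("sample_id", sort=True):
        n = len(group)
        n_dbl = int(round(rate * n))
        if n < 2 or n_dbl == 0:
            continue
        pos = matrix.cell_index(group["cell_id"])
        for k in range(n_dbl):
            a, b = rng.choice(n, size=2, replace=False)
            ia, ib = pos[a], pos[b]
            new_cols.append(matrix.X[:, ia] + matrix.X[:, ib])
            new_rows.append(
                {
                    "cell_id": f"{sample_id}:dbl{k:04d}",
                    "sample_id": sample_id,
                    "condition": group["condition"].iloc[0],
                    "cell_type": group["cell_type"].iloc[a],
                    "is_doublet": True,
                    "doublet_parent_a": group["cell_id"].iloc[a],
                    "doublet_parent_b": group["cell_id"].iloc[b],
                }
            )
    if not new_rows:
        return matrix, table
    X = sp.hstack([matrix.X] + new_cols, format="csc")
    extra = pd.DataFrame(new_rows)
    out_table = pd.concat([table, extra], ignore_index=True)
    if "doublet_parent_a" in out_table.columns:
        out_table["doublet_parent_a"] = out_table.get("doublet_parent_a")
        out_table["doublet_parent_b"] = out_table.get("doublet_parent_b")
    cell_ids = out_table["cell_id"].to_numpy(dtype=object)
    return CountMatrix(X, matrix.gene_ids, cell_ids), out_table
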