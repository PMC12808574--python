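"""Shared fixtures: reduced-size cohort configurations and toy matrices.

Simulation-based tests run on cohorts with the default composition,
replication and library-depth structure but fewer genes and nuclei, so the
whole suite stays fast; the full-size defaults are exercised by the
acceptance checks.
"""

import numpy as np
import pandas as pd
import pytest
import scipy.sparse as sp

from senesc_sn.datatypes import CountMatrix
from senesc_sn.synth import SimConfig, simulate_cohort


def reduced_config(**overrides) -> SimConfig:
    """Default-structure cohort at reduced gene/cell counts."""
    base = dict(
        n_genes=400,
        n_marker_genes_per_type=5,
        n_senescence_genes=30,
        n_cells_per_sample=800,
    )
    base.update(overrides)
    return SimConfig(**base)


def tiny_composition_config(**overrides) -> SimConfig:
    """Minimal gene space for tests that only consume cell-type labels."""
    base = dict(
        n_genes=30,
        n_marker_genes_per_type=1,
        n_senescence_genes=4,
        mean_library_size=200.0,
    )
    base.update(overrides)
    return SimConfig(**base)


@pytest.fixture(scope="session")
def small_cohort():
    """One reduced cohort shared by read-only tests."""
    return simulate_cohort(reduced_config(seed=42))


def dense_matrix(values, gene_ids=None, cell_ids=None) -> CountMatrix:
    values = np.asarray(values)
    gene_ids = gene_ids or [f"g{i}" for i in range(values.shape[0])]
    cell_ids = cell_ids or [f"c{j}" for j in range(values.shape[1])]
    return CountMatrix(sp.csc_matrix(values), np.array(gene_ids, object), np.array(cell_ids, object))


def make_table(cell_ids, sample_ids=None, conditions=None, cell_types=None, doublets=None):
    n = len(cell_ids)
    return pd.DataFrame(
        {
            "cell_id": list(cell_ids),
            "sample_id": sample_ids if sample_ids is not None else ["s1"] * n,
            "condition": conditions if conditions is not None else ["LP"] * n,
            "cell_type": cell_types if cell_types is not None else ["t"] * n,
            "is_doublet": doublets if doublets is not None else [False] * n,
        }
    )
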