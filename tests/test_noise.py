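"""Noise pipeline: downsampling, subsampling, stable genes, distances."""

import math

import numpy as np
import pandas as pd
import pytest
from scipy.stats import spearmanr

from senesc_sn.datatypes import ConfigError
from senesc_sn.noise import (
    NoiseParams,
    downsample_library,
    noise_distances,
    select_stable_genes,
    subsample_cells,
    transcriptional_noise,
)
from senesc_sn.synth import simulate_cohort

from conftest import dense_matrix, make_table, reduced_config


# -- library downsampling ---------------------------------------------

def test_cell_already_at_target_unchanged():
    m = dense_matrix([[3], [4], [2]])
    out, dropped = downsample_library(m, target=9, seed=0)
    assert dropped == []
    assert np.array_equal(out.toarray().ravel(), [3, 4, 2])


def test_column_sums_equal_target_and_small_cells_dropped():
    rng = np.random.default_rng(0)
    m = dense_matrix(rng.integers(0, 6, size=(30, 40)))
    target = 40
    out, dropped = downsample_library(m, target=target, seed=1)
    assert np.all(out.cell_totals() == target)
    small = set(m.cell_ids[m.cell_totals() < target])
    assert set(dropped) == small
    assert np.all(out.toarray() <= m.subset_cells(out.cell_ids).toarray())  # without replacement


def test_downsampling_mean_matches_hypergeometric_oracle():
    """A (8,2) cell downsampled to 5: over 10,000 independent draws the mean
    retained count of gene 1 is within 3 SE of the hypergeometric mean 4.0."""
    n_rep = 10_000
    m = dense_matrix(np.tile([[8], [2]], (1, n_rep)))
    out, _ = downsample_library(m, target=5, seed=2)
    counts = out.toarray()[0]
    # hypergeometric: N=10, K=8, n=5 -> mean 4, var n*(K/N)*(1-K/N)*(N-n)/(N-1)
    var = 5 * 0.8 * 0.2 * (10 - 5) / (10 - 1)
    se = math.sqrt(var / n_rep)
    assert abs(counts.mean() - 4.0) < 3 * se


def test_unreachable_target_is_an_error():
    m = dense_matrix([[1], [1]])
    with pytest.raises(ConfigError):
        downsample_library(m, target=10, seed=0)


# -- cell subsampling --------------------------------------------------

def test_small_groups_kept_entirely_and_boundary_is_identity():
    ids = [f"c{i}" for i in range(420)]
    table = make_table(ids, cell_types=["a"] * 120 + ["b"] * 300)
    kept = subsample_cells(table, max_per_type=300, seed=0)
    assert kept == ids  # 120 <= 300 all kept; 300 == 300 identity


def test_large_group_subsampled_to_cap_seed_dependent():
    ids = [f"c{i}" for i in range(1000)]
    table = make_table(ids)
    kept_a = subsample_cells(table, max_per_type=300, seed=1)
    kept_b = subsample_cells(table, max_per_type=300, seed=2)
    assert len(kept_a) == len(kept_b) == 300
    assert len(set(kept_a)) == len(set(kept_b)) == 300
    assert set(kept_a) != set(kept_b)


# -- stable-gene selection --------------------------------------------

def test_block_arithmetic_keeps_one_gene_per_block():
    rng = np.random.default_rng(4)
    m = dense_matrix(rng.integers(1, 50, size=(20, 12)))
    kept = select_stable_genes(m, NoiseParams())
    assert len(kept) == 10  # ceil(0.1 * 2) per block x 10 blocks


def test_cv_tie_broken_lexicographically():
    # two identical-profile genes in one block: the lexicographically smaller
    # id must win
    values = np.array([[5, 7, 6], [5, 7, 6]])
    m = dense_matrix(values, gene_ids=["gb", "ga"])
    kept = select_stable_genes(m, NoiseParams(n_expression_blocks=1, cv_keep_fraction=0.5))
    assert kept == ["ga"]


def _brute_force_stable(matrix, n_blocks, frac):
    matrix = matrix.subset_cells(sorted(matrix.cell_ids))  # canonical order
    dense = matrix.toarray().astype(float)
    means = dense.mean(axis=1)
    keep = means > 0
    ids, means, rows = matrix.gene_ids[keep], means[keep], dense[keep]
    cvs = rows.std(axis=1, ddof=1) / means
    order = sorted(range(len(ids)), key=lambda i: (means[i], ids[i]))
    base = len(order) // n_blocks
    sizes = [base] * (n_blocks - 1) + [len(order) - base * (n_blocks - 1)]
    out, start = [], 0
    for size in sizes:
        block = order[start : start + size]
        start += size
        block_sorted = sorted(block, key=lambda i: (cvs[i], ids[i]))
        out.extend(ids[i] for i in block_sorted[: math.ceil(frac * size)])
    return sorted(out)


def test_selection_matches_brute_force_on_random_fixtures():
    rng = np.random.default_rng(5)
    for trial in range(5):
        m = dense_matrix(rng.poisson(3.0, size=(100, 25)))
        params = NoiseParams(n_expression_blocks=10, cv_keep_fraction=0.1)
        assert select_stable_genes(m, params) == _brute_force_stable(m, 10, 0.1)


def test_fewer_genes_than_blocks_rejected():
    m = dense_matrix(np.ones((3, 4), dtype=int))
    with pytest.raises(ConfigError):
        select_stable_genes(m, NoiseParams(n_expression_blocks=10))


# -- distances ---------------------------------------------------------

def test_identical_nuclei_have_zero_noise():
    values = np.tile([1.0, 2.0], (5, 1))
    assert np.allclose(noise_distances(values), 0.0)
    assert np.allclose(noise_distances(values, mode="mean_pairwise"), 0.0)


def test_centroid_distances_match_hand_arithmetic():
    # 3 nuclei x 2 genes; centroid (2, 2)
    values = np.array([[1.0, 2.0], [2.0, 1.0], [3.0, 3.0]])
    expected = [1.0, math.sqrt(1.0), math.sqrt(2.0)]
    assert np.allclose(noise_distances(values), expected, atol=1e-12)


def test_mean_pairwise_matches_hand_arithmetic():
    values = np.array([[0.0], [3.0], [6.0]])
    # distances: 0-3:3, 0-6:6, 3-6:3 -> per-nucleus means (4.5, 3, 4.5)
    assert np.allclose(noise_distances(values, mode="mean_pairwise"), [4.5, 3.0, 4.5], atol=1e-12)


def test_distance_homogeneity():
    rng = np.random.default_rng(6)
    values = rng.random((8, 5))
    assert np.allclose(noise_distances(values * 3.0), 3.0 * noise_distances(values), atol=1e-12)


def test_noise_invariant_to_cell_permutation():
    cfg = reduced_config(seed=9, n_cells_per_sample=300)
    m, table, _ = simulate_cohort(cfg)
    params = NoiseParams(max_cells_per_type=50, seed=1)
    res_a = transcriptional_noise(m, table, params)
    perm = np.random.default_rng(0).permutation(m.n_cells)
    m_perm = m.subset_cells(m.cell_ids[perm])
    table_perm = table.iloc[perm].reset_index(drop=True)
    res_b = transcriptional_noise(m_perm, table_perm, params)
    a = res_a.per_group.set_index(["cell_type", "condition"])["noise"]
    b = res_b.per_group.set_index(["cell_type", "condition"])["noise"]
    assert set(a.index) == set(b.index)
    assert np.allclose(a, b.loc[a.index], atol=1e-12)


def test_centroid_noise_is_deterministic_and_groups_reported(small_cohort):
    m, table, _ = small_cohort
    params = NoiseParams(max_cells_per_type=80, seed=3)
    res_a = transcriptional_noise(m, table, params)
    res_b = transcriptional_noise(m, table, params)
    pd.testing.assert_frame_equal(res_a.per_group, res_b.per_group)
    assert set(res_a.per_group["condition"]) == {"LP", "HP"}
    assert (res_a.per_group["noise"] >= 0).all()
    assert (res_a.per_group["n_cells"] <= 80).all()


def test_small_groups_skipped():
    cfg = reduced_config(seed=10, n_cells_per_sample=60)
    m, table, _ = simulate_cohort(cfg)
    params = NoiseParams(min_cells_per_group=30, max_cells_per_type=300, seed=0)
    res = transcriptional_noise(m, table, params)
    sizes = table.groupby(["cell_type", "condition"]).size().unstack()
    too_small = sizes[(sizes < 30).any(axis=1)].index
    assert set(res.skipped_types) >= set(too_small)
    assert set(res.ratios["cell_type"]).isdisjoint(res.skipped_types)


def test_pairwise_and_centroid_modes_rank_groups_alike():
    """The two distance definitions order (type, condition) groups nearly
    identically on simulated cohorts."""
    rhos = []
    for seed in range(20):
        cfg = reduced_config(seed=seed, n_cells_per_sample=300, n_genes=200,
                             n_marker_genes_per_type=3)
        m, table, _ = simulate_cohort(cfg)
        res_c = transcriptional_noise(m, table, NoiseParams(max_cells_per_type=50, seed=seed))
        res_p = transcriptional_noise(
            m, table, NoiseParams(max_cells_per_type=50, seed=seed, distance_mode="mean_pairwise")
        )
        a = res_c.per_group.set_index(["cell_type", "condition"])["noise"]
        b = res_p.per_group.set_index(["cell_type", "condition"])["noise"].loc[a.index]
        rhos.append(spearmanr(a, b).statistic)
    assert np.mean(rhos) > 0.9
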