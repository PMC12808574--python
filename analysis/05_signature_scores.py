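#!/usr/bin/env python
"""Senescence-module and diversity scores per nucleus.

Expression-bin-matched module scoring of the cohort's senescence/SASP gene
module, plus the diversity score (each nucleus scored against its own cell
type's LP-derived HVG set). Writes per-group means to
``results/05_scores_summary.tsv``.
"""

from pathlib import Path

import pandas as pd

from senesc_sn.datatypes import GeneSet
from senesc_sn.io import read_cohort, write_tsv
from senesc_sn.signatures import (
    ScoreParams,
    diversity_score,
    normalize_log1p,
    pathway_scores,
    select_hvgs_per_type,
)
from senesc_sn.synth import SimConfig

ROOT = Path(__file__).resolve().parents[1]

matrix, table = read_cohort(ROOT / "scratch" / "cohort_qc")
# the module the generator planted (gene lists are configuration, not code)
module = SimConfig(n_genes=1200, seed=1).default_senescence_module()
params = ScoreParams(seed=1)

norm = normalize_log1p(matrix, params.normalization_scale)
sasp = pathway_scores(norm, table, {"senescence_sasp": module}, params)
hvgs = select_hvgs_per_type(norm, table, condition="LP", n_hvg=200)
diversity = diversity_score(norm, table, hvgs, params)

summary = pd.concat(
    [
        sasp.groupby(["set", "cell_type", "condition"])["score"].mean().reset_index(),
        diversity.assign(set="diversity")
        .groupby(["set", "cell_type", "condition"])["score"].mean().reset_index(),
    ],
    ignore_index=True,
)
(ROOT / "results").mkdir(exist_ok=True)
write_tsv(ROOT / "results" / "05_scores_summary.tsv", summary)

adip = summary[(summary["cell_type"] == "adipocyte")].pivot_table(
    index="set", columns="condition", values="score"
)
print("mean adipocyte scores:")
print(adip.round(3).to_string())
shift = adip.loc["senescence_sasp", "HP"] - adip.loc["senescence_sasp", "LP"]
print(f"\nsenescence module HP - LP shift in adipocytes: {shift:+.3f}")
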