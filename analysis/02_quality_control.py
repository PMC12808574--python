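#!/usr/bin/env python
"""Apply the nucleus- and gene-level QC rules to the working cohort.

Doublets are dropped, then nuclei must show >600 detected genes, >950 UMIs
and a mitochondrial fraction under the per-library median + 5 x MAD; genes
seen in fewer than 20 retained nuclei are removed. The filtered cohort goes
to ``scratch/cohort_qc``; per-rule failure counts to
``results/02_qc_summary.tsv``.
"""

from pathlib import Path

import pandas as pd

from senesc_sn.io import read_cohort, write_cohort, write_tsv
from senesc_sn.qc import QCThresholds, run_qc

ROOT = Path(__file__).resolve().parents[1]

matrix, table = read_cohort(ROOT / "scratch" / "cohort")
thresholds = QCThresholds()  # the study's rules: 600 / 950 / 5xMAD / 20
fmatrix, ftable, report, summary = run_qc(matrix, table, thresholds)

write_cohort(ROOT / "scratch" / "cohort_qc", fmatrix, ftable)
(ROOT / "results").mkdir(exist_ok=True)
write_tsv(ROOT / "results" / "02_qc_summary.tsv", pd.DataFrame([summary]))

print(f"nuclei {summary['nuclei_before']} -> {summary['nuclei_after']} "
      f"(doublets {summary['failed_doublet']}, "
      f"<{thresholds.min_genes_exclusive+1} genes {summary['failed_genes_rule']}, "
      f"<{thresholds.min_umis_exclusive+1} UMIs {summary['failed_umis_rule']})")
print(f"genes {summary['genes_before']} -> {summary['genes_after']}")
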