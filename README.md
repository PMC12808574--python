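# senesc-sn

Single-nucleus RNA-seq analysis of diet-induced adipose senescence:
quality-control filtering, transcriptional-noise (cell-to-cell
heterogeneity) estimation, differential cell-type abundance with the local
true sign rate (LTSR), and expression-bin-matched gene-set scoring —
together with a seeded synthetic cohort generator that reproduces the
statistical structure of a two-diet (low-protein vs high-protein) mouse
adipose cohort.

It is written for computational biologists who want the bespoke statistics
of this kind of study as reusable, tested library code rather than a
one-off script pile: every step is a plain function over a sparse
genes × nuclei count matrix and a pandas cell table.

## The statistics in brief

* **QC** — keep nuclei with genes detected > 600, UMIs > 950 and
  mitochondrial fraction < median + 5·MAD (per library, raw MAD); drop
  genes seen in < 20 retained nuclei.
* **Transcriptional noise** — downsample every nucleus to equal library
  size (hypergeometric), cap groups at 300 nuclei, keep the lowest-10%-CV
  genes within 10 mean-expression blocks, then average each nucleus's
  Euclidean distance to its (type, condition) centroid; report
  log2(noise_HP / noise_LP) per type.
* **Abundance** — per type, a Poisson GLM of per-sample counts with
  log-total offset gives a log2 fold-change and quasi-Poisson SE;
  LTSR = Φ(|log2FC|/SE) is the probability the estimated direction is
  correct, and types with LTSR > 0.9 are called.
* **Module scores** — mean expression of a gene set minus the mean of
  expression-bin-matched control genes (24 bins, 100 controls per set
  gene) in log1p-normalized space; the *diversity score* applies this with
  each type's LP-derived highly-variable-gene set.

See `docs/methods.md` for the models, defaults and their rationale.

## Worked example

The numbered scripts under `analysis/` run the full study on a synthetic
cohort (4 libraries, 8,400 nuclei, 1,200 genes, 5% doublets) and write
their tables under `results/`:

```bash
python analysis/01_simulate_cohort.py
python analysis/02_quality_control.py
python analysis/03_composition_shift.py
python analysis/04_transcriptional_noise.py
python analysis/05_signature_scores.py
```

which prints, among other things:

```
LP: adipocyte 36.8% (configured 35.5%), macrophage 16.6% (configured 18.0%)
HP: adipocyte 8.5% (configured 8.4%), macrophage 28.6% (configured 27.8%)
nuclei 8400 -> 6963 (doublets 400, <601 genes 998, <951 UMIs 112)
adipocyte: log2FC -2.12 (LTSR 1.000) — collapse under the HP diet
adipocyte log2(HP/LP) heterogeneity ratio: 0.056 (positive = noisier under HP)
senescence module HP - LP shift in adipocytes: +0.584
```

i.e. the generator realizes the configured compositions, QC removes the
injected doublets and the low-depth tail, the abundance model recovers the
adipocyte collapse (8.4% vs 35.5% of nuclei) and macrophage expansion, the
noise statistic detects the doubled heterogeneity planted in HP
adipocytes, and the senescence module scores higher in HP adipocytes.

The same stages are available as a CLI (`senesc-sn simulate|qc|score|
noise|abundance|run`) over cohort directories in 10x-style MatrixMarket
format, and as `run_pipeline()` for a single seeded, hash-reproducible
JSON report.

```python
from senesc_sn import SimConfig, simulate_cohort, abundance_analysis

matrix, cells, truth = simulate_cohort(SimConfig(seed=1))
print(abundance_analysis(cells)[["log2fc", "se", "ltsr", "called"]])
```

## Layout

```
src/senesc_sn/    library: synth, qc, noise, composition, signatures, io, pipeline
analysis/         numbered narrative drivers (simulate → QC → abundance → noise → scores)
tests/            pytest suite, including statistical acceptance checks
scripts/          acceptance.py
docs/methods.md   models, defaults, limitations
```
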