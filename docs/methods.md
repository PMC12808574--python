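# Methods

This package re-implements, as tested library code, the bespoke
single-nucleus RNA-seq computations used to characterize diet-induced
adipose-tissue senescence: nucleus/gene quality control, a
transcriptional-noise (cell-to-cell heterogeneity) estimator, a
Poisson/LTSR differential cell-type abundance statistic, and
expression-bin-matched gene-set scoring. Because the underlying cohort is
not publicly deposited, a seeded synthetic cohort generator stands in for
the data; it is first-class, tested code, and its defaults encode the
published study conditions.

## Synthetic cohort generator (`senesc_sn.synth`)

The generator emulates a two-diet epididymal white-adipose-tissue cohort:
two conditions (low-protein LP, high-protein HP) × two replicate libraries,
13 cell types. Per cell:

1. the type is a multinomial draw from the condition's composition vector —
   defaults put adipocytes at 35.5% (LP) vs 8.4% (HP) and macrophages at
   18.0% vs 27.8%, the remaining mass split evenly over the other 11 types
   (only those two pairs of fractions are published constraints);
2. expected expression is a type-specific relative profile (a shared
   lognormal baseline, the type's `n_marker_genes_per_type = 20` marker
   genes elevated `marker_fold = 5`-fold, mitochondrial genes holding
   `mito_expression_fraction = 2%` of the profile) scaled to a lognormal
   library size (`mean_library_size = 3000` UMIs, CV 0.5 — nuclear-library
   depths that clear the study's QC floors for most nuclei while leaving a
   realistic failure tail);
3. HP adipocytes multiply senescence-module gene means by
   `2**senescence_log2fc_hp_adipocyte` (default 1.0) — the module defaults
   to 50 synthetic gene ids; real SASP/DNA-damage/inflammation lists are
   configuration inputs, never code;
4. multiplicative lognormal per-cell × gene jitter (mean 1) models
   biological variability: variance `base_jitter_var = 0.3` for ordinary
   genes and `marker_jitter_var = 1.0` for a type's own markers. The larger
   marker jitter encodes that identity programs fluctuate between cells of
   a type (e.g. adipocyte maturation gradients); it is what makes
   HVG-derived identity sets contain identity genes, and hence what gives
   the diversity score signal. HP adipocytes scale their whole jitter
   variance row by `heterogeneity_factor_hp_adipocyte` (default 2.0), the
   knob the noise statistic is meant to recover;
5. counts are negative-binomial via a gamma–Poisson mixture with size
   parameter `nb_dispersion = 10` (variance μ + μ²/10; `inf` gives Poisson
   exactly).

A lognormal-jitter-on-the-mean formulation (rather than inflating the NB
dispersion) was chosen deliberately: the heterogeneity statistic below is a
Euclidean distance between nuclei, which responds directly to per-cell mean
perturbations.

Doublets are synthesized by summing the counts of two same-sample nuclei
and appending them with `is_doublet = True`; detection is out of scope (the
flag is consumed as input, as upstream tools would provide it).

Determinism: one PCG64 stream per cohort, consumed in a fixed order —
identical configuration (including seed) is bit-identical. The
`identity_shrink_hp_adipocyte` knob (default 0) linearly shrinks the HP
adipocyte profile toward the across-type mean profile, an "identity loss"
scenario used by the diversity-score tests.

What the generator does **not** emulate: ambient RNA, batch effects beyond
sample identity, read-level artifacts, cell-cycle structure, or any
correlation structure between genes beyond the type profiles. Passing
recovery tests therefore show the estimators respond to the effects they
target under a clean generative model — not that they are robust to every
artifact of real tissue.

## Quality control (`senesc_sn.qc`)

Nuclei are retained iff they pass all of: genes detected **>** 600, total
UMIs **>** 950, and mitochondrial fraction **<** median + 5 × MAD
(inequalities deliberately strict, matching the rules' wording). The MAD is
the raw median absolute deviation — no 1.4826 normality constant — since
the ×5 multiplier already absorbs scale; the multiplier is configurable.
The median/MAD population is per library by default (libraries differ
technically; a pooled `global` scope is available), computed after doublet
removal but before any threshold-based removal. Degenerate edge: when
MAD = 0 the strict bound equals the median and would annihilate identical
populations; the rule then relaxes to ≤ median with a logged warning.
After cell filtering, genes with non-zero counts in fewer than 20 retained
nuclei are dropped; gene filtering never feeds back into cell retention
(single pass). Mitochondrial genes are recognized by a case-insensitive
`mt-` id prefix, mirroring mouse nomenclature.

## Transcriptional noise (`senesc_sn.noise`)

Stage order is fixed: (1) every nucleus is downsampled **without
replacement** (multivariate hypergeometric) to a common UMI total — by
default the smallest per-nucleus total among cells entering the analysis,
so no cell is discarded; a fixed target is configurable; (2) at most 300
nuclei per (type, condition), groups under 10 nuclei skip the type; (3) per
type, on the pooled LP+HP cells, genes are ranked by mean expression, split
into 10 contiguous equal-size blocks (remainder to the highest-expression
block) and the lowest 10% of CVs (sample sd/mean on untransformed
downsampled counts; ties by gene id) per block are kept; (4) expression of
those stable genes is log1p-transformed and each nucleus's Euclidean
distance to its group centroid is averaged into the group's noise; a type's
shift is `log2(noise_HP / noise_LP)`.

Choices where the procedure is underdetermined: stable genes are selected
on the pooled conditions so the HP/LP ratio compares like with like; the
distance is to the group centroid (O(n), the common usage in the aging
literature; mean pairwise distance is available and rank-agrees with it on
simulated cohorts); CV is computed on the count scale, distances on the
log scale to temper outliers. Per-cell downsampling randomness is keyed to
the cell id (not stream order), making every noise value invariant to cell
permutation. Gene means/CVs are computed over a canonical cell ordering so
block boundaries cannot flip with column order through float rounding.

## Differential abundance and LTSR (`senesc_sn.composition`)

Per type, per-sample nucleus counts follow a Poisson log-linear GLM with a
condition indicator and `log(per-sample total)` offset; the condition
coefficient is the natural-log fold-change of relative abundance, reported
in log2. With only two replicate libraries per condition a per-sample
random intercept is not identifiable, so the "mixed" aspect is realized as
a fixed-effect fit whose Wald SE is inflated by a quasi-Poisson dispersion
factor `max(1, Pearson χ²/df)` whenever residual degrees of freedom exist;
a true random-intercept fit is a documented extension point. The local
true sign rate — the probability that the estimated direction of the
fold-change is correct given its mean and variance — is the Wald-normal
`Φ(|log2FC|/SE)`, clipped just below 1; types are called at LTSR
strictly > 0.9. Types with zero counts in one condition get a
Haldane-style +0.5 added to every cell of their type × sample subtable
(flagged in output) so rare types stay reportable.

Calibration note: `LTSR > 0.9` is equivalent to `|z| > 1.28`, so under a
perfectly calibrated normal null it fires in ≈20% of replicates by
construction (≈12–18% here after multinomial underdispersion and the
truncated dispersion factor). The threshold is a discovery heuristic, not
a 10% error-rate guarantee; the acceptance suite's composition-null check
documents the measured rates.

## Gene-set scoring (`senesc_sn.signatures`)

Scoring runs in a global-scaling log1p space (each nucleus scaled to
10,000 counts): module scores depend on relative, not absolute,
normalization, and the study's variance-stabilizing transform is out of
scope. The module score bins all genes into 24 equal-frequency bins by
mean normalized expression and, per set gene, draws 100 control genes
uniformly without replacement from its bin (set genes excluded from
eligibility); the score is mean set-gene expression minus the mean over the
pooled control draw, per nucleus. Bin count and control count reproduce
the documented defaults of the score function this re-implements; both are
configurable, and draws are seeded and reproducible.

Per-type HVG sets are derived from the LP (reference) condition only:
per-gene variance of log-normalized expression standardized against a
mean–variance trend (median variance within 20 mean-ranked bins), top 200
by standardized variance, zero-variance genes excluded. The diversity
score scores each nucleus with its own type's HVG set; the reference
asymmetry (LP-derived sets) is part of the definition and is tested.

## Pipeline and I/O (`senesc_sn.pipeline`, `senesc_sn.io`)

Cohorts are 10x-style MatrixMarket triplets (genes × cells, 1-based
indices on disk, 0-based in memory) plus a `cells.tsv` metadata table;
orientation is fixed at the I/O boundary from the features/barcodes
lengths, with ambiguous square inputs rejected. The pipeline runs
QC → scores → noise → abundance on one retained-nucleus set; a single
global seed fans out to stages through a SHA-256 hash of the stage name,
and the report body (JSON) is byte-identical across reruns of the same
configuration, with timestamps outside the hashed body. Emitted TSVs are
UTF-8 with headers and deterministic row order.

## Problem sizes in tests

The test and acceptance suites run the full stack on cohorts with the
default composition, replication and library-depth structure but fewer
genes (200–400) and nuclei (300–2,500 per sample); quantities that depend
only on the multinomial composition (realized fractions, abundance fits)
use a minimal 30-gene space. Statistical checks use seeded replicates
(20 seeds for recovery, 50–200 for calibration) with thresholds stated in
each test.

## Known limitations

* The abundance model is a fixed-effect quasi-Poisson approximation of a
  mixed model; with more replicates a random-intercept fit would be
  preferable.
* The LTSR is a Wald approximation with no shrinkage across types; see the
  calibration note above.
* The noise statistic measures total within-group dispersion; it does not
  decompose technical vs biological components beyond the library-size
  downsampling.
* Shipped gene modules are synthetic placeholders; scientific conclusions
  require supplying curated SASP / DNA-damage / inflammation lists via the
  gene-set file interfaces.
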