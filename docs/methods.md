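# Methods

## Assay model

MRE-Seq with SacII reads out the unmethylated fraction of each CCGCGG site:
the enzyme cuts only unmethylated sites, a p5 adapter ligates to the cut
end, and sequencing depth at the site after UMI deduplication is
proportional to how often that site was unmethylated in the input cfDNA.
The package treats the assay as a generative model with three layers:

1. **Methylation atlas.** Control methylation `m_control(s)` is drawn per
   site from Beta(8, 2) (mean 0.8 — most CpG-dense SacII sites are
   methylated in plasma-dominant hematopoietic DNA). Each cancer class
   copies the control row, subtracts a global hypomethylation shift δ
   (clipped at 0), and forces a class-specific subset of sites to a low
   methylation level. The class-specific subsets differ between cancer
   classes; that difference is what makes cancer-signal-origin
   classification possible, while the shared global shift is what makes
   cancer-vs-control detection possible.
2. **Plasma mixture.** A sample with tumor fraction `tf` has per-site cut
   probability `p = (1 − tf)·(1 − m_control) + tf·(1 − m_class)`.
   Tumor fraction, not stage, is the generative driver of detectability;
   stages map to tf windows that rise from stage I to IV, so
   stage-stratified sensitivity curves are monotone by construction in
   expectation, not by fiat.
3. **Library emulation.** Deduplicated site depth is Poisson(D·p) plus a
   Poisson off-target background. The read-level path emits, per molecule:
   a fragment starting at the cut terminus (motif start + 2, so read 1
   begins `GCGG`), length uniform on [200, 550] bp, a random 10-bp UMI
   (first ten cycles of read 2 and a `UMI:Z:` header tag), 1 + k PCR
   duplicate copies with k ~ Poisson(mean − 1), and independent per-base
   substitution errors. Off-target molecules start at uniform random
   genome positions. The on-target molecule counts share their random
   stream with the direct depth path, so with error rate 0 and off-target
   rate 0 the two paths agree exactly — a cross-path identity the tests
   assert.

## Default parameters

| parameter | default | rationale |
|---|---|---|
| control methylation | Beta(8, 2) per site | high-methylation background typical of plasma cfDNA |
| global shift δ | 0.1 | mild genome-wide hypomethylation; separability then comes mostly from tf |
| class-specific demethylated sites | 5% of sites at level 0.05 | sparse strong markers on top of the global shift |
| stage → tf windows | I (0.05–0.15), II (0.10–0.25), III (0.20–0.40), IV (0.30–0.60) | rising shed fraction with tumor burden |
| mean site depth D | 30 | modest depth consistent with a targeted assay |
| PCR duplication mean | 2.0 | reproduces a ~50% dedup-retained read ratio |
| off-target rate | 0.1 | keeps the on-target ratio well below 1 |
| UMI length | 10 bp | assay design |
| fragment window | 200–550 bp | size-selection window |
| read length | 100 bp | paired-end sequencing |
| cohort plan | 126 controls / 96 colorectal / 95 lung with stage frequencies from the clinical table | matches the study design the evaluation machinery expects |

The default cohort composition and stage frequencies mirror the clinical
cohort this pipeline is designed for; all other generative values are this
package's own assumptions, stated here because the assay publications do
not quantify them.

## Preprocessing contracts

- **QC.** Reads are dropped if either mate is shorter than 20 bp, if a mate
  is missing, or if the UMI (first 10 cycles of read 2) contains an N or a
  Q0 base. Each drop reason is counted.
- **Site assignment.** A read belongs to a site iff its 5′-most aligned
  base equals the site's cut terminus (motif start + 2). Alignment is
  externalized: positions come from the simulator's truth table or from an
  external SAM/BAM; re-implementing an aligner is out of scope.
- **UMI deduplication** uses directional clustering: UMI u absorbs v when
  their Hamming distance is ≤ 1 and count(u) ≥ 2·count(v) − 1, expanding
  from UMIs in descending count order. This is the accepted standard for
  UMI error correction; the assay description says UMIs were
  error-corrected but names no algorithm.
- **On-target** means the deduplicated molecule's genome-facing read begins
  `GCGG`; the on-target ratio is computed at molecule level (the ratio is
  defined against deduplicated reads).
- **Trimmed-mean normalization** sorts a sample's site-depth vector,
  removes floor(0.05·n) values from each tail (10% of outliers in total,
  read as symmetric; a one-tailed reading is possible but less standard),
  averages the rest, and divides the raw row by that mean. Rows shorter
  than 10 fall back to the plain mean with a warning; all-zero rows are an
  error. Values are left on the linear scale (no log), the plainest reading
  of "normalized by a trimmed mean".

## Scoring model and cross-validation

The network is input → 64 ReLU → 64 ReLU → 2-way softmax, trained with
cross-entropy for exactly 120 epochs by Adam (lr 10⁻³, batch 16). The
optimizer, learning rate, and batch size are fixed across folds for
reproducibility; a hyperparameter search on the inner validation split is
deliberately not the default. Features are standardized with training-fold
statistics only, so no scoring sample leaks into its scaler. The whole
model is plain numpy with explicit seeding: the same configuration, data,
and seed give bitwise-identical scores, and a full CV run is reproducible
bit-for-bit from its master seed.

The repeated nested CV protocol: per repetition, stratified 5 outer folds;
within each outer-training set, stratified 5 inner folds each train one
network (the held-back inner part is a validation split whose loss is
logged); all 5 inner models score the outer test fold. One repetition thus
yields 5 out-of-training scores per sample and 20 repetitions yield 100 —
the only scheme consistent with "5 inner scoring models" and "test samples
excluded from the training set". Every fold assignment is recorded, and
`CancerScoreSet.audit_leakage()` re-checks exhaustively that no sample was
ever scored by a model that trained on it.

A sample's cancer score is the mean of its out-of-training scores; its IQR
(Q3 − Q1, linear-interpolation quantiles) measures stability across models.

## Evaluation

- **AUC** is computed by scikit-learn (trapezoidal over all thresholds,
  ties ½); the test suite cross-checks it against the normalized
  Mann–Whitney U statistic and a brute-force pairwise count.
- **Anchored specificity.** The decision threshold is placed midway between
  the k-th and (k+1)-th largest control scores (for k = 0, midway between
  the maximum and 1). Tied controls straddling the cut pull the threshold
  onto the tie so false positives stay ≤ k, with a warning. Calls are
  strict (score > threshold).
- **Wilson score intervals** (via statsmodels) are used for all proportion
  CIs; this method exactly reproduces the printed interval arithmetic of
  the evaluation tables the pipeline is modeled on (e.g. 75/96 →
  68.9–85.2%, 125/126 → 95.6–99.9%), which is how the method was
  identified.
- **CSO cascade.** Plain (non-nested) stratified 5-fold CV; the cancer gate
  defaults to probability 0.5 rather than the anchored threshold, because
  the cascade operates at a different (more sensitive) point than the
  anchored per-cancer evaluation. Per-type true-positive rates are computed
  among forwarded true positives only.

## Interpretation

- Marker discovery uses pooled-variance Student t-tests per site ("Student"
  read literally; Welch available via flag) against a fixed P < 10⁻⁷
  selection cutoff with no multiplicity correction, matching the practice
  it reproduces; Benjamini–Hochberg can be applied downstream.
- Feature importance defaults to AUC-drop permutation importance;
  a sampling-based Shapley estimator (marginal contributions over random
  feature orderings against the column-mean background) is available and
  preferable for small feature counts. The contract is the ranking.
- Region annotation takes promoter = [TSS − 2000, TSS + 500) on the
  annotated strand (a common convention; the window is configurable in the
  module constants), with precedence promoter > 5′UTR > exon > intron >
  intergenic. The exact region percentages of any published census depend
  on the annotation release and are not asserted.
- PCA batch checks run on the normalized matrix (centered per feature);
  the PC1 outlier threshold is data-specific and therefore a parameter,
  not a constant.

## Numerical and degenerate-input choices

- Single-class training sets, all-zero depth rows, inconsistent site sets,
  unknown atlas classes, and out-of-range rates raise errors naming the
  offending object; empty genomes, empty site tables, short rows, stray
  contigs, and tied anchored cuts warn and proceed with the documented
  fallback.
- Fragments running past a contig end are length-resampled (counted and
  warned); a site too close to the end to fit even the minimum fragment is
  clamped to the contig end.
- Softmax is computed with max-subtraction; cross-entropy adds 10⁻¹² inside
  the log. Zero-variance features standardize to zero (sd replaced by 1).

## Problem sizes used by tests and the acceptance script

Desk-scale runs use 500–2,000 sites and 40–120 samples: the full 20×5(×5)
protocol on a 40-sample, 500-site cohort (500 network fits), and a complete
FASTQ → matrix → CV → report run at 2,000 sites × 60 samples with mean site
depth 8 and 2 CV repetitions. These sizes exercise every code path at full
protocol fidelity; they are not the cohort scale of a clinical study.

## What passing tests do and do not show

The synthetic generator reproduces the statistical *structure* the method
assumes — global hypomethylation scaled by tumor fraction, class-specific
demethylated sites, UMI/PCR duplication, size-selected fragments — but not
real cfDNA biology: no fragmentation-pattern or end-motif structure, no
sequencer quality-score model or indels, no hematopoietic copy-number or
coverage bias, no batch chemistry effects, and tumor fraction windows per
stage are assumptions rather than measurements. Passing tests therefore
validate the pipeline's correctness and its behavior under the assumed
signal model; they do not certify clinical performance numbers, which
require real cohorts at sequencing scale.

## Known limitations

- The enzymology offset is phenomenological: SacII cleaves CCGC^GG leaving
  3′ overhangs, and the observed read start `GCGG` at motif + 2 is adopted
  as-is so the simulator and the on-target definition are self-consistent.
- UMI collisions (two molecules drawing the same 10-mer at one site) merge
  under deduplication; at desk-scale depths this is negligible but it is a
  real (small) downward bias at high depth.
- The permutation-null AUC of mean nested-CV scores is wider than a
  binomial approximation suggests, because scores from models with
  overlapping training sets are correlated; single-permutation null AUCs
  of ±0.15 around ½ are unremarkable on 120-sample cohorts.
- `sample_size_sweep` subsamples without replacement once per ratio; for
  confidence bands over subsampling noise, run it across seeds.
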