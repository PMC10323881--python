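# Methods

## Model and procedure

The predictor combines two independent lines of evidence that a gene is
regulated by a given transcription factor (TF):

1. **Sequence evidence.** The TF's binding preference, given as a
   position frequency matrix (PFM, JASPAR text dialect), is converted to
   a log2-odds position weight matrix (PWM) and slid base-by-base over
   each gene's promoter. Every length-*n* window receives the score
   *k* = Σᵢ a(m(xᵢ), i), where a is the 4×*n* scoring matrix (rows in
   A, T, C, G order) and m maps the window's *i*-th base to its row.
   Promoters are summarised by k_max1 (best window), k_max3 (sum of the
   three best) and k_total (sum over all windows).
2. **Expression evidence.** For every candidate gene the Pearson
   correlation with the TF is computed within each sample group (one
   group per cancer type) and reduced to the R-score, the maximum across
   groups. The rationale for a maximum rather than a pooled or averaged
   correlation is that TF–target coupling is often tissue-specific: a
   true target may track the TF in one malignancy and be silent in the
   rest, and pooling would dilute that signal.

A gene is predicted as a target when both scores exceed their cutoffs.
Predictions are evaluated against a reference set derived from ChIP-seq:
peaks passing an enrichment filter are assigned to genes by
promoter-window overlap, and the standard set-cardinality metrics
(sensitivity, specificity, precision, P/C) plus a ROC sweep over R-score
cutoffs are computed.

### Assumptions

- Expression values are correlated as given; any transform (log, TPM…)
  is the caller's responsibility and should be applied before loading.
  Missing values are rejected at read time so the correlation is
  unambiguous; there is no pairwise deletion.
- The promoter is a fixed-length upstream window (default 5000 bp); no
  chromatin accessibility, methylation or higher-order sequence model is
  used.
- ChIP-seq peaks arrive pre-called with a fold-change and a
  (deduplicated) read count per peak; peak calling and input-control
  enrichment happen upstream of this package.
- Coordinates are 0-based half-open everywhere; the caller must supply
  genome, annotation and peaks on one consistent assembly (no liftover).

## Parameters that matter

| parameter | default | meaning / rationale |
|---|---|---|
| `upstream_length` | 5000 bp | promoter extent upstream of the TSS; deliberately generous relative to the classical 100–1000 bp core promoter so distal proximal-promoter sites are not missed |
| `pseudocount` | 0.8 | background-weighted Laplace smoothing in the PFM→PWM log-odds conversion; the convention of the motif-tool ecosystem the matrices come from |
| `background` | uniform (0.25×4) | genomic base composition used in the log-odds denominator; user-settable for AT/GC-skewed genomes |
| `scan_reverse_strand` | on | windows of the reverse complement are pooled with the forward windows, since a binding site is readable on either strand; a forward-only flag reproduces a literal single-strand reading |
| `min_fold_change` / `min_reads` | 1.5 / 10 | reference-peak filter: strictly greater than 1.5-fold enrichment and at least 10 distinct reads |
| `window_upstream` / `window_downstream` | 5000 / 1000 bp | strand-aware promoter-proximity window for assigning peaks to genes; echoes the promoter definition, downstream slack covers TSS-straddling peaks |
| `r_cutoff`, `pwm_cutoff` | 0.7, 8 (k_max1) | combined prediction thresholds; both accept percentile specs (e.g. 75th) resolved over the joined table's own distribution |
| `MIN_GROUP_SIZE` | 3 | smallest group for which a Pearson r is computed; below that (or at zero variance) the group is recorded as missing with a reason code |

## Synthetic benchmark: what it emulates, what it does not

`tfotf.simulate` generates the full input bundle with a known truth set:

- **Genome/annotation.** Promoters are i.i.d. background sequence; each
  true target receives one exact copy of the motif consensus at a
  uniform random offset and strand. Gene slots are spaced so that
  default promoter-proximity windows of neighbouring genes never
  overlap, which makes reference construction exactly identifiable.
- **Expression.** TF expression is standard normal; true targets are
  y = ρ·tf + √(1−ρ²)·ε within every group, so their population
  correlation with the TF is exactly ρ (default 0.8); non-targets are
  independent noise. Gaussian rather than count-distributed values are
  used because Pearson r is the statistic of interest and is
  distribution-compatible; a negative-binomial generator would be an
  extension, not a default.
- **Peaks.** One passing peak per true target inside its promoter, plus
  decoys failing the enrichment filter and passing intergenic peaks in
  the inter-slot margins.

Defaults are 1000 genes, 50 true targets, 5 groups × 100 samples,
ρ = 0.8, 9-bp motif, 5000 bp promoters. Every generator is a
deterministic function of the configuration (seed included).

Because of this construction, passing tests demonstrate correctness of
the machinery — coordinate arithmetic, strand handling, score
summaries, metric formulas, threshold semantics and end-to-end
recovery of a planted signal — but **not** performance on real data:
real promoters are not i.i.d. sequence (repeats, CpG islands), real
motif occurrences are degenerate rather than exact consensus copies,
real expression has batch structure and heavy tails, real ChIP-seq
reference sets are noisy and incomplete, and real TF–target coupling is
weaker and sparser than ρ = 0.8 in every cohort. Near-perfect benchmark
metrics therefore say the implementation is right, not that the method
will separate real targets that cleanly.

## Numerical choices

- **Percentiles** use linear interpolation between order statistics
  (numpy's default, the "type-7" convention), fixed and documented
  because percentile cutoffs must be bit-reproducible.
- **Threshold comparisons** are strict `>` everywhere (a gene exactly at
  the cutoff fails), with a single switch flipping every comparison to
  `≥`. The peak filter is the one deliberate mix: `>` for fold change,
  `≥` for read count, matching the "more than"/"at least" semantics of
  the filter's definition.
- **Windows containing N** are skipped, not scored: the per-base score
  is defined only for A, C, G, T. A promoter with no scorable window
  reports zeros with an explicit `no_windows` flag rather than being
  dropped, keeping downstream joins total. Characters outside the
  A,C,G,T,N alphabet are normalised to N at genome load (with a logged
  count), so IUPAC-coded genomes still load.
- **k_max3 with fewer than three windows** is the sum of what exists.
  Note that with log-odds (signed) matrices the sum of the top three
  window scores can fall below the top one when the 2nd/3rd scores are
  negative; the ordering k_total ≥ k_max3 ≥ k_max1 is guaranteed only
  for nonnegative scoring matrices.
- **Pearson r** is computed with the two-pass closed form and clamped to
  [−1, 1], which returns exactly ±1 on perfectly (anti)correlated
  vectors.
- **R-score ties** (two groups attaining the same maximum) resolve to
  the lexicographically first group label, making `best_group`
  deterministic.
- **ROC/AUC**: P(t) = {genes with r > t}; the automatic grid is every
  distinct observed score plus sentinels beyond both extremes; the AUC
  is trapezoidal after augmenting the curve with (0,0) and (1,1). This
  equals the Mann–Whitney rank statistic (ties counted half), which the
  tests verify to 1e-9.
- **Undefined ratios** (precision with |P| = 0, sensitivity and P/C with
  |C| = 0, specificity with A = C) surface as explicit `None`, never 0 —
  the precision/P-C behaviour at extreme cutoffs depends on the
  distinction.
- **Prediction table ordering**: (pass_all desc, r_score desc, gene_id
  asc) with a stable sort, so output is reproducible byte-for-byte.

## Design choices

- **Signed maximum by default** for the R-score; the absolute mode
  (max |r|, signed value retained per group) exists because repressive
  TFs anticorrelate with their targets.
- **Promoter-window peak assignment** instead of full nearest-feature
  genome annotation: a deliberate simplification with configurable
  window sizes. Users with an externally annotated target list can load
  it directly as a one-column gene-id file and skip assignment.
- **Genes present in only one score table** (PWM but no R-score, or
  vice versa) are excluded from the joined prediction table and counted
  in the join report, mirroring the restriction of the evaluation
  universe to genes present in the expression data.
- **"Distinct reads"** is taken to be the peak table's read-count
  column; read deduplication is upstream of this tool.
- **Exact consensus planting** in the generator (not probabilistic motif
  sampling) keeps each true target's minimum attainable k_max1
  analytically known — the consensus self-score — so oracle bounds are
  assertable in tests.

## Known limitations

- No statistical calibration of PWM scores (p-values) and no
  dinucleotide or higher-order motif models.
- The correlation carries no significance testing or confounder
  adjustment; the R-score is a screening statistic, not an inference.
- Promoter-window peak assignment will differ from annotation-package
  output near gene-dense loci, where a peak can sit in several windows
  or closer to a gene body than to any TSS.
- Epigenetic context (accessibility, methylation) is ignored, so
  sequence-favourable but chromatin-silenced sites score as well as
  active ones.
- The test-suite problem sizes (1000-gene benchmark, 20-seed sweeps)
  were chosen to keep the default run fast on a single CPU; the
  generators scale to larger instances via `SimulationConfig`.
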