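# Methods

`tcrars` implements a repertoire-level diagnostic pipeline for autoimmune
disease built from TCRβ CDR3 sequencing data, together with a synthetic
cohort generator carrying full ground truth so that every stage can be
validated end to end.  This note records the model, the parameters that
matter, the numerical choices, and what the synthetic experiments do and
do not demonstrate.

## Pipeline overview

1. **Ingestion and reduction** (`repertoire_io`).  Each subject's
   rearrangement table (AIRR TSV or a minimal `cdr3/v/j/freq` dialect) is
   read, counts are converted to within-repertoire frequencies, quality
   control retains canonical-alphabet junctions of length 6–30 with
   positive frequency, and the subject is reduced to the `n = 2000` most
   frequent clonotypes (ties broken lexicographically so selection is
   deterministic).  Cohorts are split train/validation 4:1 *at the
   individual level*, stratified by label, so no subject's TCRs appear on
   both sides.
2. **TCR-level classifier** (`encoding`, `classifier`).  Training-subject
   representative TCRs are pooled into one table, one row per
   (subject, clonotype), each row labeled by its donor.  Identical TCRs
   from donors of opposite labels are both kept: the pooled construction
   deliberately accepts noisy instance labels, and the classifier's
   asymptotic target is P(case | TCR), which is exactly what repertoire
   aggregation needs.  CDR3s are tokenised over the 20-letter alphabet
   (alphabetical indices 1–20) with *leading* zero padding to a global
   length; index 0 serves both as padding and as the occlusion mask, and
   its embedding row is pinned to the zero vector so that masking truly
   nullifies a residue.  The V gene (or V family) enters as a single
   categorical index with an UNK entry for labels unseen in training.
3. **Architecture.**  A token embedding feeds two parallel branches: a
   stack of four 1-D convolution blocks, each an additive residual skip
   (1×1 projection where channel counts differ) around a same-padded
   convolution followed by ReLU, summarised by a global position-wise max
   pool; and a stack of three bidirectional LSTM layers with inter-layer
   dropout, summarised by the final hidden states of both directions.
   The two summaries, concatenated with the flattened gene embedding,
   pass through one dense ReLU layer to a single logistic output.
   The network is written directly in numpy (float32) with hand-derived
   backpropagation, verified against central-difference gradients in the
   test suite, and trained with Adam on class-weighted binary
   cross-entropy with early stopping on a held-out slice of the pool.
4. **Risk scoring** (`ars`).  A subject's Autoimmune Risk Score is the
   unweighted mean of classifier probabilities over the representative
   set — invariant to clonotype order and to frequency rescaling; top-k
   and frequency-weighted aggregators are available.  Subject-level
   k-fold cross-validation re-trains the classifier per fold on the
   training subjects' pooled TCRs and scores each subject strictly out of
   fold.
5. **Occlusion saliency** (`saliency`).  For the analyzed sequences (the
   top-scoring 2000 per validation case, i.e. all of a 500-clonotype
   representative set), every contiguous 3-mer window and every gapped
   window X\*XX / XX\*X is occluded by writing the mask token over the X
   positions (the \* position is untouched), and the motif's contribution
   is delta = P(original) − P(masked).  Deltas are aggregated per distinct
   motif (mean over occurrences; median available); essential motifs are
   those at or above the 98.5th percentile of aggregated deltas *and*
   recurring at least `min_count` times (defaults 300 contiguous / 20
   gapped, following the published thresholds; scaled to 50 / 10 in the
   synthetic experiments whose analyzed sets are ~30× smaller).
   Occurrences are profiled positionally: boundaries at floor(L/3) and
   floor(2L/3) of the unpadded length, an occurrence assigned to the
   segment containing its start index.
6. **Statistics** (`stats`).  ROC AUC via the rank-based Mann–Whitney
   statistic (ties counted half); Welch's t-test by default (the Student
   variant falls back to Welch, with a warning, under degenerate pooled
   variance); Pearson and Spearman correlations; one-way ANOVA with full
   Tukey HSD pairwise tables; per-subject J-gene usage enrichment; and a
   composite disease-activity report (score vs SLEDAI, Active/Silent at
   the SLEDAI ≥ 5 cutoff, anti-dsDNA status, damage-count groups, C3, C4).
   No multiple-testing correction is applied by default; a
   Benjamini–Hochberg helper is provided.

## Classifier hyperparameters

Only the topology is fixed (four residual conv blocks; three BiLSTM
layers; gene embedding; dense head).  Widths are package defaults sized
for single-CPU numpy training, all configurable via `ModelConfig`:
embedding 16, conv channels 32 (kernel 3), LSTM hidden 16 per direction,
gene embedding 8, dense 32, dropout 0.2, Adam lr 2·10⁻³, batch 256.
Two training profiles are used:

- **Cross-validation profile** (`pipeline.cv_profile`): 6 epochs,
  patience 2 with best-epoch restoration, pool subsampled to 12 000 TCRs.
  Subject-level discrimination saturates within ~2 epochs because the ARS
  averages ~500 per-TCR probabilities, so fold training is kept short.
- **Mining profile** (`ModelConfig.for_mining`): 8 epochs, batch 128,
  full pool, dropout 0, final-epoch parameters kept.  Occlusion deltas
  measure per-motif carrier confidence, which keeps sharpening long after
  the noisy-label validation loss plateaus; inter-layer dropout measurably
  blurs it for gapped (wildcard) patterns (carrier confidence ~0.70 with
  dropout 0.2 vs ~0.85–0.91 without, at equal budget), so the saliency
  model trains without it.

## Out-of-fold score harmonization

Each CV fold's model is an independent training run with its own score
calibration; per-fold offsets (~0.03) exceed the within-fold
between-subject signal (~0.013) and would swamp pooled cross-fold
correlations even when within-fold rank agreement with ground-truth
burden is 0.94–0.99.  `ars.harmonize_cv_ars` therefore centres each
fold's out-of-fold scores on the mean score of that fold's held-out
controls, re-expressing every ARS as elevation above the healthy
baseline.  Clinical-association analyses use harmonized scores; fold
AUCs, being within-fold, never need it.

## The synthetic cohort generator

`synthetic.generate_cohort` emulates the data structure the analysis
assumes, with full ground truth:

- **Junctions.**  C…F-anchored strings, length ~N(14.5, 2²) truncated to
  [8, 24], interiors drawn from a fixed Gly/Ser-rich composition over all
  20 residues approximating human CDR3β interiors (C rare at 1.5%, F
  modest at 4%).  Using a composition with C/F entirely absent makes
  every occlusion window overlapping a planted motif a never-diluted
  unique motif name and floods the top-quantile rule with singleton
  artifacts; the all-residue composition is both more realistic and the
  reason motif recovery is a stable property of the method here.
- **Planted signal.**  Default scenario: 60 cases / 60 controls, 500
  clonotypes each, six signal motifs — four contiguous (AFF, LFF, IYF,
  YTF) and two gapped (I\*DR, SM\*L) — planted into case clonotypes at a
  per-case rate drawn around 0.15 (uniform ±2/3 relative spread, so
  burden varies across cases) against a 0.01 background in controls.
  The gapped motifs use rare interior residues so that chance matches do
  not dominate their positional profiles.  Windows start uniformly within
  the tail third, never overwriting the anchor residues; junctions too
  short to satisfy this are left unplanted (and so flagged).  Planted
  clonotypes receive a motif-specific J call (e.g. AFF → TRBJ1-1\*01),
  emulating J-segment-encoded tails; all others draw uniformly from a
  13-gene TRBJ panel.
- **Clone sizes.**  Zipf-like: frequency ∝ rank^(−1.2), assigned in a
  random order so planting is independent of clone size.  Note the top
  clone then carries ~20% of a repertoire — which is exactly why
  frequency-weighted J-usage statistics are noisy (see below).
- **Clinical covariates.**  Latent activity A = 3.5·burden + N(0, 0.1²);
  SLEDAI = round(max(0, 10A)) (placing the Active cutoff of 5 near the
  case median), C3 = 120 − 40A + N(0, 8²), C4 = 30 − 10A + N(0, 3²),
  dsDNA-positive iff A above the case median, damage count from activity
  quintiles.  Controls get SLEDAI 0, healthy-baseline complements, no
  damage.  This is the smallest model reproducing the sign pattern the
  analysis is meant to detect (positive SLEDAI/damage association,
  negative complement association).

What passing these simulations shows: the pipeline recovers planted
repertoire-level signal, localizes the responsible motifs, and
reproduces the constructed clinical sign structure, with a type-I control
(equal planting rates) holding pooled out-of-fold AUC near chance.  What
it does not show: performance on real repertoires — the generator has no
VDJ recombination statistics, no shared public clones, no HLA structure,
and its label signal is by construction motif-shaped.

## Numerical and design notes

- Scoring is deterministic at fixed parameters; batched and one-by-one
  scoring agree to ≤ 10⁻⁶ (no batch-coupled operations anywhere).
- The occlusion delta equals a rebuild-from-string-re-encode-rescore
  oracle exactly, because masking operates on the same token vector the
  encoder produces.
- Frequency renormalization after QC/selection is exact to 10⁻⁹;
  representative selection is idempotent and monotone.
- `jgene_enrichment` defaults to frequency-weighted usage; under
  heavy-tailed clone sizes a single dominant clone makes this statistic
  noisy, so the clone-count variant (`weighted=False`) is provided and is
  the one with reliable power in the planted-J experiments.
- Experiment sizes in the test-suite and acceptance runs (12 000-TCR
  training subsample for CV folds, 10 null seeds at 20 subjects × 300
  clonotypes with 2-fold CV) are the package's standard desk-scale
  configuration; all are configurable upward.
- Serialized checkpoints bundle parameters, config, and the vocabulary
  with its hash; scoring refuses inputs encoded against a different
  vocabulary.

## Known limitations

- The classifier is a compact numpy implementation; it is CPU-bound and
  not intended for million-TCR corpora.
- TCR-level AUC on subject-labeled pools is intrinsically bounded near
  0.5 + (enrichment − background)/2 under label noise; subject-level
  aggregation, not TCR-level accuracy, is the meaningful endpoint.
- Epitope/antigen annotation of exported high-scoring sequences is out of
  scope; `ars.export_top_sequences` writes a TSV consumable by external
  annotation tools.
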