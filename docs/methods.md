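# Methods

## Features

A peptide `S` of length `N` over the standard alphabet
`A = ACDEFGHIKLMNPQRSTVWY` is summarized by raw adjacent k-mer counts for
k = 1, 2, 3: 20 unigram, 400 dipeptide and 8000 tripeptide columns, 8420
counts in all (8421 with the binary label). For standard-residue input the
counts conserve window totals: `sum(uni) = N`, `sum(bi) = N−1`,
`sum(tri) = N−2`. Column order is this package's convention — alphabetical
residues, k-mers flattened row-major with the first residue slowest — and
is emitted as header names by the feature-CSV writer, so a column can
always be mapped back to its k-mer.

Nonstandard residues (X, B, Z, U, O, J, `*`) are handled by policy:
`skip` (default) omits any window containing one, keeping the conservation
laws valid over scanned windows; `error` rejects the record; `drop-sequence`
removes it from the table. Sequences shorter than 3 residues are legal;
higher-order count blocks are simply zero.

Counts are stored sparse (CSR). A typical 40-residue peptide touches at
most ~115 of the 8420 columns, so sparsity is what makes the GA fitness
and classifier fits cheap.

## Stage-1 GA: partition selection

A candidate solution is a training subset with *equal* per-class counts;
the train:test ratio `tr` (default 0.7) fixes the subset size, rounded to
preserve the equal split. With a 1:4 class imbalance this rule caps the
usable `tr` (the minority class must keep at least one test row); configs
on imbalanced data lower `tr` accordingly.

Fitness of a partition, per feature dimension: the other class's sample
standard deviation `s_b` (denominator `n−1`) acts as a center, and the
score is the deviation of the current class's values around that center
(denominator `m−1`). Per-dimension values are averaged over the 8420
dimensions, then over the two class directions. The formula is positively
homogeneous of degree one and needs at least two training rows per class.
Internally it is evaluated from first and second column moments so sparse
matrices never densify; a literal scalar-loop transliteration serves as
the test oracle.

The GA loop is mark/regenerate, not crossover-based: every iteration
regenerates each solution marked `to_be_modified` by fresh stratified
sampling, accepting a candidate only when its fitness exceeds the running
best (CVV); after at most `max_regen = 50` attempts the best rejected
candidate fills the slot, guaranteeing termination. Solutions with fitness
above `mean(fitness) × Mu` survive unchanged. The global best partition is
tracked separately, so the reported fitness trace is monotone
non-decreasing by construction. `selection_rate` and `crossover_rate`
exist in `GAConfig` for completeness but are unused — the implemented
procedure has no pairwise selection or crossover step.

## Stage-2 GA: length selection

Candidate solutions are integer truncation lengths in `[SLmin, SLmax]`,
the observed length range across both partitions. Scoring a length:
truncate every sequence to that *prefix* (shorter sequences pass through
whole; truncation is idempotent), re-extract the full n-gram features, fit
a linear-kernel SVC (C = 1.0, seeded) on the training partition, and take
test accuracy. The same mark/regenerate loop runs with accuracy in place
of variance (running best CA, threshold `mean(accuracy) × Mu`). Scores are
cached per length within a run — fitness is deterministic given the SVC
seed — so the number of SVC fits is bounded by the number of distinct
lengths sampled.

Scoring candidates on the stage-1 test partition is the published
procedure and is what the default reproduces; it lets the selection peek
at the evaluation data. The `inner_split` option scores candidates on a
validation slice carved from the training partition instead, for unbiased
selection. "Selection" here picks a sequence length, not a subset of the
8420 columns; prefix truncation is the literal reading of the procedure,
and no column-wise filtering is performed.

## Ensemble

Base classifiers and their fixed hyperparameters: 1-nearest neighbor
(k = 1), random forest (100 estimators, seeded), logistic regression
(L-BFGS solver), SVM (stopping tolerance 1e-4, i.e. 0.01%; kernel
unspecified upstream, scikit-learn's RBF default used). All four fit the
same training matrix independently.

On a calibration set, the correctly-classified index sets `C_knn, C_rf,
C_lr, C_svm` are recorded; `C_final` is their deduplicated union and
`|C_final| / n_test` is the **union accuracy**. This is an oracle-style
quantity — it counts a peptide as correct if *any* classifier got it
right — and by construction dominates every individual accuracy. It is
reported as printed, alongside the honest metric below, and the two are
never conflated.

**Routing**: a new peptide's feature vector is correlated against every
stored correct instance; each classifier's score is its *maximum* pairwise
correlation (the nearest-match reading of the procedure), and the argmax
classifier predicts, with exact ties resolved in the fixed order
knn > rf > lr > svm. A classifier with no correct instances is never
chosen. Pearson correlation is the default: the printed form
`Σ(diff)/sqrt(Σ diff²)` is unbounded (Cauchy–Schwarz only gives ±sqrt(n)),
which makes a 0.999 gate ill-posed; it remains selectable as
`correlation_mode="as_printed"` and both modes define the 0/0 case of
identical vectors as 1.0. Pearson of a constant vector is 0.0 unless the
vectors are identical.

**Self-augmentation**: when the routed maximum correlation strictly
exceeds 0.999, the peptide joins the training pool with its *predicted*
label (the true label is not assumed known at inference — this is
self-training) and the model is flagged stale until refit. The pool only
ever grows.

**Honest evaluation**: the pipeline fits a second ensemble whose correct
sets come from a held-out calibration slice of the training partition
(default 25%), and routes the test set through it; that yields the
**routed accuracy** and the precision/recall/F/AUC report. Union accuracy
may exceed or trail routed accuracy; no ordering is guaranteed. AUC needs
scores the routed ensemble does not natively produce, so each instance
contributes its routed classifier's positive-class probability (decision
function for the SVM); the mixture of scales is a documented compromise.

## Synthetic data

The generator draws residues i.i.d. from a background distribution
(uniform by default) at lengths uniform in `length_range` (default 8–40,
a realistic peptide-benchmark range), then plants signal by overwriting a
random window with a chosen k-mer — insertion rather than frequency
reweighting, so the per-sequence effect size is explicit. An enrichment
weight of 3.0 writes three copies into each targeted-class sequence
(fractional weights insert probabilistically). Labels flip with
probability `noise`. Everything flows from one seeded generator.

Named fixtures: `separable` (1000 peptides, 500/500, dipeptide "WY"
planted 3× per positive, no noise), `random` (400, no signal),
`imbalanced` (100 positives : 400 negatives, weaker signal), `short_seqs`
(lengths 1–5). The generator emulates class-dependent composition bias,
variable lengths and imbalance — not epitope biology (no motif grammar,
no surface accessibility). Passing tests therefore demonstrate that the
machinery recovers compositional signal it is pointed at, not clinical
performance on real epitope data.

## Problem sizes and numerical choices

Whole-pipeline checks and the acceptance script run the GA at ns=6, ni=4
(stage 1) and ns=5, ni=3 (stage 2) on the 1000-peptide fixture — enough
for both searches to explore while keeping a full pipeline run to a few
seconds on one CPU; the library defaults remain the published table
(population 100, 100 iterations, mutation rate 0.2). Variance fitness
clips tiny negative moment differences at zero before square roots.
Degenerate inputs are errors, not silent defaults: fewer than two training
rows per class, single-class training sets, empty calibration sets,
infeasible `tr`. JSON artifacts are written with sorted keys and full
float repr, so a rerun with the same config and seed is byte-identical.

## Limitations

- Union accuracy is not an achievable classifier accuracy; treat the
  routed numbers as the method's honest performance.
- Default stage-2 scoring inherits the published selection-on-test
  optimism (see `inner_split`).
- Routing by maximum correlation against stored instances approaches
  1-NN behavior as the calibration set grows, so the routed ensemble's
  ceiling is tied to its strongest instance-matching member.
- Only binary labels are supported end-to-end; the variance fitness is
  written k-class generic but is tested for k = 2.
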