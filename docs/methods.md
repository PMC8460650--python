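# Methods

## Problem and model

`lpidf` predicts lncRNA–protein interactions (LPIs) from sequence alone.
The known interactions over `n` lncRNAs and `m` proteins form a binary
matrix `Y`, `Y_ij = 1` for an experimentally supported interaction and `0`
for unknown status. A zero is never treated as a verified non-interaction;
wherever the method needs negatives (balanced training, balanced test
folds), they are sampled uniformly without replacement from the zero
entries. Candidate pairs are represented by the concatenation of an lncRNA
feature vector and a protein feature vector, and scored by a cascade deep
forest.

### lncRNA featurization: k-mer composition

A canonical nucleotide sequence (upper-cased, U→T) of length `x` has
`x − k + 1` overlapping windows of length `k`; the feature vector is the
relative frequency of each of the `4^k` k-mers, indexed lexicographically
with A<C<G<T so that indices are stable across runs and implementations.
Frequencies rather than raw counts make sequences of different lengths
comparable. Default `k = 4` (256 features). Sequences shorter than `k`
yield the all-zero vector with a logged warning. Reverse complements are
*not* folded: composition is strand-specific by design, and the tests guard
against accidental canonical-k-mer folding.

### Protein featurization: segment hashing + autoencoder bottleneck

A protein of length `L` is cut by a sliding window of size `K` (default 3)
into `L − K + 1` overlapping segments. Each segment is hashed
deterministically by the polynomial

    h(s) = ( Σ_{i=0..K−1} code(s_i) · 31^i ) mod vocab_size

where `code` is the alphabetical index of the residue (A=0 … Y=19, with a
dedicated code 20 for the optional "unknown" residue X) and `vocab_size`
defaults to the prime 8191 to spread collisions. The hash sequence is
truncated/right-padded to a fixed length `M`, with real hashes shifted to
`[1, vocab_size]` so the pad value 0 stays distinguishable, and scaled to
[0, 1].

These vectors train a feed-forward autoencoder — one hidden encoder layer
`M → d_p`, a mirrored decoder, ReLU activations, squared-error
reconstruction loss, Adam at learning rate 1e-3 for a fixed 100-epoch
budget, fully seeded — and the hidden bottleneck activations are the
protein embedding. The default bottleneck width is `d_p = 544` so the pair
feature dimension is 256 + 544 = 800; `M` defaults to 1024 so the hidden
layer is an actual bottleneck (`d_p < M`). The autoencoder is trained once
per dataset on all protein hash vectors; this is unsupervised and uses no
interaction labels, so it cannot leak labels into cold-start evaluation
(test *sequences* do inform the embedding space, the usual transductive
convention for unsupervised featurizers).

### Cascade deep forest

Each cascade layer is a bank of four heterogeneous classifiers in fixed
order: logistic regression, XGBoost, random forest, extremely randomized
trees. The tree ensembles use 70 trees and a minimum of 5 samples to split
— the one set of printed tree hyperparameters the method prescribes — and
the other two members run at library defaults; every member is seeded
deterministically from the run seed via a documented formula
(`classifier_seed`). Within a forest member, the per-tree class
distributions are averaged (e.g. tree votes (0.3750, 0.6250),
(0.5556, 0.4444), (1.0000, 0.0000) average to (0.6435, 0.3565)).

For each sample, the bank's four `(p_pos, p_neg)` pairs concatenate into an
8-dimensional class vector, which is appended to the **original** input
features — never the previous layer's augmented vector — so the layer input
is always `d + 8` columns (808 for the default 800).

Training proceeds as follows:

1. A stratified `validation_fraction` (default 0.2) of the training pairs
   is held out for depth control.
2. At each layer, class vectors for training rows are generated
   *out-of-fold* (default 3 folds): each row is scored only by classifiers
   that never saw it, the established cascade-forest practice that stops
   the class vector from memorizing labels. Validation rows are scored by
   the fold models' average; the four refitted-on-all-training classifiers
   are stored for prediction.
3. The layer's validation score is the AUC of its mean positive-class
   probability. Growth stops when the score fails to improve on the best
   previous layer by at least `epsilon` (default 1e-3, patience 1) or at
   `max_layers` (default 20); the best-scoring prefix of layers is kept.
   The stopping rule makes the qualitative criterion "no significant
   improvement" concrete as an epsilon threshold.
4. After training, per-feature importance is aggregated over layers as the
   bank mean of normalized importances — impurity importance for the tree
   members, |coefficient| for the logistic member — and features with
   aggregate importance exactly zero are dropped (at least one is always
   kept). Coefficients of columns constant in the training data are forced
   to zero before aggregation: a constant column carries no information and
   any weight on it is optimizer noise absorbed by the intercept. The mask
   is honored at prediction time by zeroing dropped columns, which cannot
   change any tree member's output (those features are never split on).

At prediction time a sample propagates through every kept layer with
augmentation; the final score is the last layer's mean positive-class
probability over the bank. Hard labels use the 0.5 threshold, with an exact
tie classified positive.

## Evaluation protocols

* **CV1** partitions lncRNA rows into folds: a fold's test set is the masked
  rows' positives plus an equal number of negatives sampled from those same
  rows (so the cold-start test set is itself balanced), and training pairs
  come only from the remaining rows. **CV2** is the same over protein
  columns. **CV3** samples one balanced labeled pool (all positives plus an
  equal number of sampled negatives) and partitions it into stratified
  folds.
* Each repeat redraws negatives and folds from `base_seed + repeat`;
  re-sampling is the meaningful source of run-to-run variation and is what
  the reported ± std measures. Metrics (precision, recall, accuracy, F1 at
  threshold 0.5; rank-based AUC; AUPR) are averaged over folds first, then
  mean ± std over repeats. Degenerate denominators (no predicted or no
  actual positives) yield 0 with a warning rather than NaN so fold averages
  stay defined.
* AUPR uses the step-wise rule `Σ (R_n − R_{n−1}) · P_n` over descending
  score thresholds, with no linear interpolation between PR points (linear
  PR interpolation is known to be optimistic). The implementation is
  checked against a hand-written brute-force threshold sweep; AUC against
  an all-pairs comparison oracle with ties counted half.
* Unknown-pair ranking scores every zero entry (optionally one row/column),
  sorts descending with ties broken lexicographically by
  (lncrna_id, protein_id), 1-based ranks. The "new entity" case-study
  protocol masks all of one lncRNA's (or protein's) known interactions
  before training, then ranks its candidates. The top-N true fraction is
  `100 · (#label-1 pairs in the first N) / N`.

## Synthetic data: what it does and does not emulate

The generator emulates the *shape* of curated LPI benchmarks — hundreds of
lncRNAs, tens of proteins, sparse `Y` — and plants a recoverable signal:
each entity gets one of `n_motif_classes` (default 4) latent compatibility
classes; a class-specific 8-nt motif is repeatedly written into each lncRNA
and a class-specific 6-aa motif into each protein (uniform background
composition, one motif copy per 5 residues at random positions, so the
k-mer composition and segment-hash profile shift with class); pairs
interact with probability 0.6 when classes match and 0.02 otherwise
(defaults), with optional label-flip noise. Motif copies are planted
densely because at desk scale (150 sequences, hundreds of residues) the
composition shift must dominate sampling noise for the signal to be
recoverable at all; real binding motifs are sparser, and real sequences
have codon bias, domain structure and length–function correlations that the
generator does not attempt. Passing the fixture experiments therefore shows
the pipeline recovers planted compatibility structure end to end — not that
it attains any particular accuracy on curated benchmark data.

Two canonical fixtures (`lpidf.experiments`) pin the package's validation
conditions:

* the **strong fixture**: the generator defaults above on a 150×20 matrix;
* the **null fixture**: identical but match = mismatch = 0.165, the strong
  fixture's overall class-mixture density, so the two differ only in
  signal. Cross-validated AUC on the null fixture must stay near chance;
  this calibration guards against information leaking from training to
  test. (Mild excursions above 0.5 can occur legitimately in transductive
  CV3 because entities with more sampled positives are both easier to score
  high and more frequent among test positives; at the fixture's density the
  effect stays within the 0.45–0.55 band.)

## Desk-scale configuration

The fixture experiments and the acceptance script use a reduced
configuration — protein padding `M = 256`, embedding `d_p = 32`, 50
autoencoder epochs, cascade depth cap 2 — chosen so a full repeated-CV
experiment (5 folds × 2 repeats, ~1000 balanced pairs of ~290 features)
runs in a few minutes on one CPU while exercising every stage: both
featurizers, out-of-fold class vectors, depth stopping, pruning, all six
metrics. The dimensional contract (256 + 544 = 800 → 8 → 808) is checked
separately with the full-width encoder on a small fixture. The full-size
defaults remain `M = 1024`, `d_p = 544`, `max_layers = 20`.

## Numerical and design choices

* Nucleotide canonicalization rejects non-ACGT characters by default
  (keeping k-mer semantics clean); amino-acid canonicalization rejects
  B/Z/X/U/O/\* by default with an opt-in mapping to the "unknown" hash code.
* Matrix entries are strictly {0, 1}; 0 means unknown, consistent with the
  negative-sampling framing.
* Hash, window size `K = 3`, `vocab_size = 8191`, `M`, and `d_p` are
  configuration, not biology: the upstream description of the embedding
  scheme leaves them open, and the defaults here favor determinism,
  tractable vocabularies and the 800-dimensional pair contract.
* The autoencoder runs its full epoch budget (`tol = 0`) rather than early
  stopping, trading a little fit for bit-reproducibility.
* Deeper layers re-concatenate the *original* features (d+8 at every
  depth, never accumulating); the alternative reading (augmenting the
  previous layer's augmented vector) would grow width without bound and
  contradicts the fixed 808-column contract.
* Validation-based stopping keeps the best prefix, so a cascade is never
  worse than its best shallow version on the stopping metric.
* Determinism: the full pipeline (featurize → fit → predict) is a pure
  function of (data, config, seed); all base classifiers run single-thread
  with derived seeds.

## Known limitations

* Protein embeddings are position-sensitive: the autoencoder sees hashes at
  absolute positions, so motifs at random offsets blur across positions and
  much of the protein-side discrimination in practice comes from the tree
  members memorizing embedding vectors of seen proteins. Cold-start
  performance on *proteins* (CV2) is therefore expected to trail CV1/CV3 —
  consistent with the much lower published cold-start protein numbers for
  this family of methods — and a translation-invariant (recurrent or
  convolutional) encoder behind the same interface is the natural
  extension.
* Balanced negative sampling inside masked rows/columns requires those rows
  or columns to contain at least as many zeros as positives; extremely
  dense matrices are rejected with an explicit deficit error rather than
  silently unbalancing the fold.
* No redundancy filtering (e.g. sequence-identity clustering) is applied;
  near-duplicate sequences can inflate CV3 estimates on real data.
* Binary interaction only; no affinities, no multi-class support, no GPU
  paths.
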