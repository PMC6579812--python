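# Methods

## Problem and model

`driverfuse` classifies somatic single-nucleotide variants as cancer
**drivers** (positive class) or **passengers** from two complementary
information sources:

1. **Raw nucleotide context.** Each variant is represented as a 2×L symbol
   matrix: row 0 is the reference context of radius w around the variant
   (L = 2w+1) and row 1 is the identical string with the alternate base at
   the centre, so the rows differ in exactly one column.  A small 1-D
   convolutional network reads this matrix (positions as the sequence axis,
   the two rows as channels) and emits a driver probability — the
   **DL score**.
2. **Tabular functional features.** Precomputed functional and conservation
   scores (dbNSFP/dbWGFP-style columns such as RadialSVM, LR, GerpRS,
   SiPhy, PhyloP) enter classical classifiers (random forest, gradient
   boosted trees, RBF SVM).  The DL score joins this table as one more
   numeric feature, and the package measures its marginal contribution via
   feature importance, recursive feature elimination (RFE) and Spearman
   correlation among top features.

A third, structural stage maps predicted driver positions onto residue
interaction networks built from protein structures and reports normalized
betweenness centrality as a post-hoc annotation of mediating residues.

## Sequence encodings

Three encodings of the 2×L matrix are provided; per-row widths are L
(label), 5L (one-hot) and 2L (embedding), which at
w ∈ {10, 50, 100, 500, 5000} give the full set of matrix widths from 21 up
to 50005 columns.

* **Label**: fixed alphabetical IDs a→0, c→1, g→2, n→3, t→4.
* **One-hot**: 5-bit indicator blocks in slot order (n, g, t, c, a), so
  'a' → [0,0,0,0,1] and 'c' → [0,0,0,1,0].  Bijective; `decode` inverts it
  exactly.
* **Embedding**: 2-dimensional vectors per symbol learned by a skip-gram
  over single-nucleotide tokens (context window 5).  Because the vocabulary
  has only five symbols, the full-softmax skip-gram loss depends on the
  data only through the centre/context co-occurrence counts; the trainer
  accumulates those counts once and runs exact batch gradient descent
  (300 iterations, step 0.2), which makes training deterministic under the
  seed.  Symbols absent from the corpus keep a zero vector and a warning is
  logged.

Out-of-chromosome window positions are padded with the missing-place symbol
'n'.  Sequence handling is lowercase on the forward strand; input
coordinates are 1-based (VCF convention).  A reference-base mismatch
between the variant file and the FASTA is rejected by default
(`--on-ref-mismatch warn` keeps the store's base instead).

## CNN and training protocol

The network is implemented directly on numpy: conv1d layers (ReLU), global
max pooling over positions, dense layers (ReLU, inverted dropout 0.25) and
a sigmoid head trained with binary cross-entropy and Adam (lr 1e-3, batch
32).  The first convolution uses a kernel of 3 symbols with a stride of one
symbol block so block encodings stay aligned to symbol boundaries; deeper
convolutions use kernel 3, stride 1.  Gradients are exact (verified against
finite differences in the test suite) and training is bit-reproducible
under a fixed seed.

Protocol: 20% of the data is held out stratified; the training portion is
split into 3 stratified folds; each architecture trains 100 epochs per fold
(fewer in the scaled-down simulations, see below) with validation accuracy,
F1 and AUC recorded after every epoch; a fold's result is its best
validation-F1 epoch, earliest epoch winning ties.  The grid winner
maximises mean fold F1, with mean AUC breaking ties and the smaller
parameter count breaking any remainder.

The default grid crosses 1–3 conv layers × 1–3 dense layers × a shared
width from {2, 4, …, 256}: 72 architectures.  A "tapered" preset of 11
architectures with per-layer decreasing widths is also shipped; its width
lists are interpreted with the trailing 2-node layer as the output head,
the last remaining width as the dense stack and the preceding widths as
conv filters (a single remaining width serves as both).  Both
interpretations are provided because the shared-width reading reproduces
the 72-architecture count while the tapered lists describe individual
networks; neither is claimed to be uniquely correct.

**DL scores without leakage.** Scoring the entire dataset with one model
trained on most of it would leak training labels into a downstream
feature.  By default, training-portion samples are therefore scored
out-of-fold (each sample by the fold model that never saw it) and holdout
samples by a model refit on the full training portion; provenance is
emitted per sample so the exclusion is assertable.  `paper_mode=True`
restores single-model whole-dataset scoring for comparability.

Class imbalance is handled by stratification only; no resampling.

## Evaluation metrics

Accuracy, precision, recall and F1 are computed from confusion counts with
exact rational arithmetic (driver = positive class); precision, recall and
F1 are defined as 0 when their denominator is empty, so the constant
all-passenger predictor on the default 6,389/12,941 composition scores
accuracy 66.95% with F1 = 0.  AUC is the probability that a random driver
outscores a random passenger with ties counting one half (average-rank
statistic), and is verified in the tests against an exhaustive pairwise
oracle and against scikit-learn.  ROC points sweep the unique score values
with ±∞ endpoints.

## Fusion stage

Classifiers: scikit-learn RandomForest (200 trees), GradientBoosting, and
an RBF SVM with probabilities via internal cross-validated calibration;
features are standardized for the SVM only.  Missing values take the
training-split median (fit on the training split only).  The 80/20 split is
seeded and shared across algorithms, so holdout membership is identical in
paired comparisons.

Feature importance defaults to normalized impurity decrease from the tree
ensemble; an auxiliary information-value / weight-of-evidence report
(decile bins, Laplace-smoothed) is provided for workflows that rank
features by that criterion instead.  RFE refits after dropping the single
lowest-importance feature each round and emits the full elimination order.
Spearman correlations use average-rank ties and pairwise-complete rows;
zero-variance columns are reported as NaN with a warning.  The named
profiles `top8` (RadialSVM, LR, DL_score, GerpRS, LRT, verPhyloP, SiPhy,
GerpN) and `top3` (first three) are shipped as column selections.

## Synthetic data

The generator emulates the statistical structure the pipeline assumes, not
real mutational biology:

* **Genome**: i.i.d. uniform {a,c,g,t} background across a configurable
  number of chromosomes, sized automatically so variant windows never
  overlap a neighbour's planted motif.
* **Variants**: default composition 6,389 drivers / 12,941 passengers
  (`SyntheticDatasetSpec.scaled(n)` keeps the ratio at smaller n).  Each
  driver's reference context carries a fixed 6-mer motif (default
  `tgcacg`) with probability q (default 1) at a uniform offset inside the
  window; passengers are never planted, though background motif occurrences
  remain possible and are quantifiable from the emitted ground truth.  A
  6-mer inside a 21-column window is comfortably learnable by stacked
  kernel-3 convolutions while being rare (≈0.4%) in background windows.
* **Feature table**: informative columns are class-conditional Gaussians
  sharing an equicorrelated Gaussian copula (default ρ = 0.6); drivers are
  shifted by a per-column multiple of the SD.  The two ensemble-like
  columns default to a 2.0 SD separation — giving a tabular-only holdout
  AUC near 0.95, the performance scale ensemble predictors reach in
  practice — and five conservation-like columns to 1.0 SD; 25 pure-noise
  columns are class-independent.  The motif and the tabular signal are
  generated independently, so the DL score's marginal contribution in
  fusion is a clean effect.

What passing tests therefore show: the pipeline recovers a planted,
localized sequence signal and integrates it with independent tabular
signal.  What they do not show: performance on real trinucleotide-biased
mutational spectra, gene models, or correlated sequence/annotation
structure, none of which the generator emulates.

## Simulation problem sizes

The recovery experiments run at n = 2000 variants (scaled composition
661/1339), window radius 10, one-hot encoding, a conv(16)/dense(16)
network, and 5 seeds: null-signal pipelines (motif off, separations zeroed,
8 epochs) must give mean AUC within 0.5 ± 0.08; the fully planted motif
(20 epochs) must give DL-score AUC ≥ 0.9; RFE must retain 3 planted
informative columns (1.5 SD among 7 noise columns) in ≥ 4 of 5 runs; and
adding the DL score to the tabular model must increase mean holdout AUC in
a paired comparison.  These sizes were chosen as the smallest at which the
binomial noise of the checks is far from their acceptance bands.

## Residue interaction networks

Nodes are residues; the interaction strength between residues i and j is

    I_ij = 100 · n_ij / √(N_i · N_j)   (percent),

with n_ij the number of heavy-atom pairs within the contact cutoff
(default 4.5 Å) and N_i the total heavy-atom contacts residue i makes in
the structure.  This normalization is one defensible reading of
contact-based interaction strength and is isolated behind the graph
builder's options.  Edges require I_ij > I_min (default 4%);
sequence-adjacent residues are excluded by default so backbone connectivity
does not dominate.  First altlocs are kept; insertion codes are appended to
the residue number.

Betweenness of node i sums g_jk(i)/g_jk over pairs j<k (g_jk = number of
shortest j–k paths, g_jk(i) those passing through i), normalized by
(N−1)(N−2)/2 within i's connected component; components with N < 3 are
assigned 0 (degenerate normalizer, logged).  Path counting uses exact
Brandes accumulation; shortest paths are unweighted by default with an
optional weighted mode (edge length 1/I_ij).  The implementation is checked
against a brute-force path-enumeration oracle and against networkx.
Predicted mutation positions map to centrality values and weak-inequality
percentiles; unresolved positions are listed, not fatal.

## Numerical choices and degenerate inputs

* Epoch/selection ties: earliest epoch, then grid order (stable sort).
* Constant classifier scores: AUC reported as 0.5 (tie convention).
* Zero importance everywhere: importances left unnormalized rather than
  divided by zero.
* Windows extending past chromosome ends: 'n' padding, never an error.
* Seeds are propagated through `numpy.random.SeedSequence` streams so each
  subsystem (genome, variants, features, per-fold networks) draws from an
  independent, reproducible stream below 2^31.

## Known limitations

* The numpy CNN is CPU-only and sized for desk-scale experiments; it is not
  a general deep-learning backend (no padding modes, schedulers, or
  multi-class heads).
* The embedding is per-nucleotide; k-mer vocabularies are out of scope.
* The interaction-strength normalization is an interpretation; absolute
  I_ij values (and hence edge sets at a fixed threshold) depend on it.
* Real-data feature tables must be supplied by the user; the package does
  not retrieve dbWGFP/dbNSFP scores or genome sequences.
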