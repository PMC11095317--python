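# Methods

## Problem

Cell–cell communication (CCC) between cell types is largely mediated by
ligand–receptor interactions (LRIs).  Databases of known LRIs are
incomplete, so CCC inference that relies only on curated pairs misses
signalling routes.  `lrcomm` addresses this in two stages: (1) predict new
LRIs from protein sequence alone with a stacking ensemble trained in a
positive-unlabeled setting, and (2) score communication strength between
cell types from a cell-type-labelled expression matrix using the surviving
LRIs and a three-point (PERT) combination of three complementary scoring
schemes.

## Sequence features

Each protein is encoded as the concatenation of four descriptor blocks:

| block | dims | definition |
|---|---|---|
| AAC | 20 | residue frequencies |
| CKSAAP | 2400 | ordered residue-pair frequencies at gaps k = 0..5, each gap block normalized by L−k−1 |
| CTD | 273 | composition / transition / distribution over 13 physicochemical properties, each partitioning the alphabet into 3 groups |
| conjoint triad | 343 | frequencies of 7-class residue triples over L−2 windows |

Total dimension 3036.  The CTD property groupings (seven hydrophobicity
scales, van der Waals volume, polarity, polarizability, charge, secondary
structure, solvent accessibility) are the published standard tables and are
validated at import time as disjoint covers of the 20-letter alphabet.
Distribution entries are percent positions (of sequence length) of the
first/25%/50%/75%/last occurrence of each group; an absent group yields five
zeros.  Non-canonical residues (U, X, B, ...) are stripped with a warning
rather than rejected, since curated sequence databases contain them at low
frequency.

PCA is fitted once on the union of ligand and receptor vectors — a single
latent space keeps the two halves of a pair vector commensurable — with a
deterministic sign convention (largest-magnitude loading positive).  The
default `d = 200` makes a ligand|receptor pair vector 400-dimensional,
matching the classifier input width.

## Negative selection

With only positive pairs labelled, negatives are constructed from unlabeled
candidates.  The positive centroid `a` and the min/max positive-to-centroid
Euclidean distances define a band that is shrunk symmetrically by a
threshold `pre ∈ [0, 1]`:

    minRange = minDis + (1 − pre)·0.5·disLen
    maxRange = maxDis − (1 − pre)·0.5·disLen,   disLen = maxDis − minDis

A candidate is eligible as a negative only if its distance to `a` is
*strictly* outside `[minRange, maxRange]`; boundary hits count as inside.
`pre` defaults to 0.6.  When more candidates are eligible than requested,
a seeded uniform subsample without replacement is drawn; the default
`n_neg` equals the number of positives for class balance.

## Classifiers

Three base learners are trained on a seeded stratified 70% "basic" split:

- **SVM** — soft-margin, polynomial kernel, C = 2.5, gamma = 0.1,
  tol = 1e-3, with Platt-calibrated class probabilities.
- **1D-CNN** — three stages of (conv → batch-norm → ReLU → 2× max-pool)
  with 32/64/128 filters, kernel 3, stride 1, then dense 128 (ReLU) → 2.
  Convolutions are length-preserving (padding 1), so an input of length L
  reaches the dense head at 128·⌊L/8⌋ features and the minimum input length
  is 8.  Trained 30 epochs, batch 64, Adam lr 1e-3, weight decay 1e-5.
- **MHA** — batch-norm, then 8-head attention in which each sample is a
  single token of width `input_dim` (per-head width `input_dim/8`, i.e. 50
  at the 400-dim default), then dense 256 (ReLU), dropout 0.2, dense 2.
  With one token per sample the attention softmax is over a single key, so
  each head's output reduces to its value projection; the general
  scaled-dot-product operation is exposed and tested separately.  This is
  the only token layout consistent with all the stated dimensions for a
  flat pair vector.

The networks are implemented as compact numpy modules (explicit
forward/backward passes) with Adam (β₁ = 0.9, β₂ = 0.999, ε = 1e-8 — the
standard defaults) and an optional cosine-annealing schedule
lr(t) = lr_min + ½(lr_max − lr_min)(1 + cos(π·t/T_max)).

Base-learner probabilities on the remaining 30% "meta" split form six
meta-features per sample, ordered SVM | CNN | MHA with (y=0, y=1) score
pairs.  The meta-classifier is a perceptron 6→12→8→2 (ReLU, ReLU, softmax)
trained 100 epochs with Adam lr 0.01 annealed to 1e-6 under cross-entropy.
The stated layer widths 12→8→2 are read as hidden widths on a 6-feature
input; this is configurable.  A pair is classified as interacting iff
P(y=1) is strictly greater than P(y=0), so an exact 0.5 tie is
non-interacting.

## CCC scoring

Predicted LRIs are kept when their interaction probability strictly exceeds
θ (default 0.99); curated LRIs bypass the probability threshold.  Both must
have ligand and receptor present in the expression matrix and expressed
("expressed" = strictly positive value) in at least one cell.  For each
ordered cell-type pair (C_j sender, C_p receiver) and each surviving LRI
(u, w), three scores are computed:

1. **cell expression** — (fraction of C_j cells expressing u) ×
   (fraction of C_p cells expressing w);
2. **expression product** — mean expression of u over all C_j cells × mean
   expression of w over all C_p cells (zeros included);
3. **specific expression** — each mean divided by its sum over all m types
   before the product (0 on a zero denominator).

Per-method m×m matrices are the sums over LRIs, each min-max normalized
over its entries (a constant matrix maps to all zeros), and combined
element-wise by the PERT three-point estimate (g_max + 4·g_med + g_min)/6.
The diagonal (self-communication) is computed and reported; consumers may
mask it.  Min-max normalization spans all ordered pairs including the
diagonal.  Per-pair LRI rankings are produced per method and combined; the
combined ranking applies the three-point estimate to the three per-LRI
scores after min-max normalization across the LRIs of that pair, with ties
broken by (score desc, ligand asc, receptor asc).

## Evaluation

Precision, recall, accuracy and F1 follow the standard confusion-count
formulas with 0/0 → 0 conventions so degenerate folds do not propagate
NaN.  ROC-AUC is the pairwise-ordering probability with ties counted one
half; AUPR is the step-wise precision–recall integral.  The CV harness runs
stratified 5-fold cross-validation repeated 20 times (defaults) with a
fresh seeded shuffle per repeat and aggregates fold-level metrics as
mean ± sd.  Stratification is used throughout.

## Synthetic data

The generators define the conditions the tests and the acceptance script
measure under:

- sequences: uniform residues, lengths 50–200 by default;
- pair geometry: positives ~ N(0, I); unlabeled candidates mix true
  negatives displaced by `separation` = 4 cluster-sd along a fixed random
  direction with a 25% share of decoys drawn from the positive cluster.
  The decoy share models the small prior of hidden interactors among
  unlabeled pairs in the positive-unlabeled setting;
- expression: Poisson(λ=1) baseline counts, 3 types × 50 cells × 60 genes
  by default; each planted interaction multiplies the ligand rate in
  sender-type cells and the receptor rate in receiver-type cells by an
  effect (10 in the planted-recovery checks), applied pre-sampling so
  sparsity and the "expressed > 0" rule stay meaningful.

What these fixtures do *not* emulate: sequence homology structure, dropout
and library-size variation of real scRNA-seq, and the extreme class
imbalance of genome-scale candidate-pair tables.  Passing tests therefore
demonstrate correctness of the algorithms and recovery of planted signal
under clean conditions, not benchmark performance on curated LRI datasets.

## Problem sizes and numerical choices

The classifier checks use 400 labelled pairs of 64 features with a
stratified 25% hold-out; this keeps CNN/MHA training to a few seconds in
numpy while leaving the task non-trivial.  The planted-recovery checks use
10 generator seeds.  Probability pairs must sum to 1 within 1e-6;
cross-entropy inputs are clamped to [1e-12, 1 − 1e-12]; PCA orthonormality
is asserted to 1e-8.  Batch-norm uses running statistics at inference.
The single-centroid band rule is implemented exactly as specified even
though it is a degenerate (k = 1) case of K-means-style clustering.

## Known limitations

- The MHA learner's attention is degenerate per-sample (see above); its
  discriminative power comes from the learned projections and the MLP head.
- Platt calibration inside the SVM uses internal cross-validation and is
  the main training cost on larger pair sets.
- The CCC stage requires cell-type labels; no clustering is performed.
- Scores are descriptive strengths, not probabilities; no significance
  testing across conditions is provided.
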