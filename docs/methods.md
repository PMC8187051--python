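# Methods

## Problem and data model

The predictor decides whether the central cytosine of a fixed-length DNA
window is N4-methylated. Windows are 41 nt by default (position 21 = the
candidate C, 1-based); the length and the convention check are
configurable so the encoders remain usable for other geometries. Inputs
are FASTA files, labelled either per file (positives vs negatives) or via
an `id<TAB>label` sidecar. Non-ACGT symbols are handled by policy:
`strict` (default) aborts naming the offending record, `drop` excludes it
and logs. Sequences are treated as given — no reverse-complement
canonicalisation is attempted, since the strand convention of typical
benchmarks is not recorded in their distributions.

## Encodings

* **Kmer (k = 1..5)** — overlapping k-mer frequencies with denominator
  L − k + 1 and no pseudocounts; each k-block sums to 1. Columns are
  lexicographic over A < C < G < T within each block, blocks in ascending
  k; the order is written to a column manifest so fitted models are
  portable across exports.
* **EIIP** — per-position substitution of the nucleotide's electron-ion
  interaction pseudopotential (A 0.1260, C 0.1340, G 0.0806, T 0.1335).
* **multifeature** — concatenation [Kmer | EIIP], 1405 features at L = 41.

No scaling or standardisation is applied by the encoders; learners that
need variance information handle it internally (see the SVM kernel width
below).

## Base learners

All learners satisfy one contract: `fit(X, y, seed)` then `score(X)`
returning P(positive) per row in [0, 1]; fitting is deterministic given
the seed; the decision tie at a threshold goes to the positive class.
Margin-based learners squash their margin through a logistic so the
stacking layer consumes a single score type.

* **bayesnet** — features are supervised-discretized by recursive
  entropy-minimising binary splits with the MDL acceptance rule
  (max depth 3, so ≤ 8 bins; features for which no split is accepted
  collapse to one bin and drop out of the likelihood). Scoring uses
  class-conditional categorical tables with symmetric Dirichlet smoothing
  (0.5 per cell). The default structure is naive-Bayes (the class is each
  feature's only parent); `structure="tan"` augments it with one feature
  parent each via a maximum-spanning tree on class-conditional mutual
  information. The tree search is quadratic in the feature count, so it
  is intended for low-dimensional feature sets; on the 1405-dimensional
  multifeature the naive structure is the practical and default choice.
* **nb_multinomial** — multinomial naive Bayes, Laplace α = 1, on the
  nonnegative frequency/EIIP features.
* **svm** — RBF-kernel SVM, C = 1, with Platt-style sigmoid probability
  calibration (5-fold, single underlying SVM). The kernel width defaults
  to `gamma = 1/(dim · var(X))`: because the encoders do not scale
  features (variances ≪ 1), the unnormalised LibSVM-style `1/dim` width
  makes the kernel numerically constant and the learner uninformative;
  `gamma="auto"` is retained as an option for that behaviour.
* **voted_perceptron** — the Freund–Schapire algorithm with a linear
  (degree-1) kernel and bias handled by input augmentation. Training
  keeps every intermediate weight vector with its survival count; the
  score is sigmoid of the normalised vote margin, whose 0.5 crossing
  equals the majority vote. One epoch by default; the per-epoch data
  order is shuffled from the seed.
* **logistic** (metaclassifier) — L2-regularised logistic regression with
  weak regularisation (C = 100).

Hyperparameters live in the stack configuration (JSON/YAML), so the
learner grid can be changed without code edits, and both the learner and
encoder registries accept third-party plug-ins against their contracts.

## Stacking procedure

1. Split the training set into k = 10 stratified folds (fold sizes differ
   by ≤ 1; per-fold class counts within 1 of proportional). Fold seed
   default 1.
2. For each base learner, train k fold models; stack held-out scores into
   the out-of-fold meta-matrix **A** and average the k fold models'
   test-set scores into **B**. Meta-features are probabilities, not hard
   labels — averaging labels would destroy calibration and ranking.
3. Fit the logistic metaclassifier on (**A**, y).
4. Score the test set (and any new data) by the same path: fold-averaged
   base scores, then the meta model. Base learners are never refitted on
   the full training set, so deployment scoring is exactly the **B**
   construction.

The no-leakage property — every entry of **A** comes from a model whose
training indices exclude that instance — is instrumented (fold models
carry their training-index sets) and machine-checked in the test suite.

Fitted ensembles persist as a versioned bundle: a JSON manifest
(format version, configuration, base order, fold seed) plus joblib
parameter blobs; loading restores bit-identical scoring.

## Evaluation

ACC, Sn, Sp and MCC are computed from the confusion counts; MCC uses the
standard Matthews formula with the value defined as 0 whenever a
denominator factor vanishes. AUC is the trapezoidal area under the
full-resolution ROC curve, which equals the pairwise Mann–Whitney
probability with ties counted one half (the test suite checks the two
routes against each other to 1e-9).

Cross-validation re-runs the *entire* stacking procedure inside every
outer training split (nested folds), so outer-fold instances never
influence base-model fitting; out-of-fold predictions are pooled and the
metrics computed once on the concatenation rather than averaged per fold,
which is robust to fold-size imbalance. Independent-test validation fits
on one window set and reports on a second; overlapping sequences trigger
a warning rather than an error, since degenerate runs are occasionally
useful for debugging.

## Synthetic data generator

The generator emulates the *structure* of a balanced 4mC benchmark — two
classes of 41-nt centre-C windows, 746+746 training and 160+160 test in
the benchmark-shaped preset — with i.i.d. uniform background (composition
configurable) and class signal planted through two mechanisms matching
the two encoder families:

* a positional consensus motif (default `TGACGTCA` starting immediately
  right of the centre), each motif position emitting the consensus base
  with probability `motif_match_prob`;
* a k-mer compositional bias, applied by importance-resampling positives
  from a background pool with weight exp(Σ count·log-enrichment)
  (Gumbel top-k weighted sampling without replacement).

For motif-only signal the Bayes-optimal accuracy has a closed form (a
likelihood-ratio threshold on the binomial number of consensus matches),
implemented as `motif_bayes_accuracy` and cross-checked by simulation.
The named strengths are anchored to it: weak = 0.50 (Bayes ≈ 0.767),
mid = 0.85 (≈ 0.976, the default), strong = 0.95 (≈ 0.995). The mid
default leaves the learners a realistic gap to the optimum, so pipeline
tests exercise genuine learning rather than a trivially separable task.

What passing on synthetic data does *not* show: real 4mC context is not
i.i.d.-background plus a clean motif — composition is non-uniform,
signal is diffuse, and classes are defined by an upstream experimental
pipeline. Synthetic results validate the machinery (encoders, the
out-of-fold construction, the metrics), not biological performance.

## Problem sizes and numerical choices

The test suite runs the full pipeline at the benchmark shape (1492/320)
once for the planted-signal recovery check and once with permuted labels
for the null check; all other pipeline tests use desk-scale datasets
(50–100 windows per class, k = 5 folds), and the stacking-premise
property (stacked AUC within 0.02 of the best single base) is averaged
over 10 seeds at desk scale. Feature-matrix TSV export uses repr-based
float formatting and round-trip parsing so matrices round-trip bit-exactly.
All randomness — fold shuffling, learner internals, the generator —
derives from explicit integer seeds.

## Known limitations

* The comparison encoders (binary position frequency, dinucleotide
  position encoding, physicochemical ring/function/hydrogen codes,
  reverse-complement k-mer, pseudo k-tuple composition) and the panel of
  alternative classifiers are not implemented; the registries are the
  extension points for rebuilding such comparison grids.
* The discrete Bayes network's tree-augmented structure is quadratic in
  the feature count and not practical on the full multifeature vector.
* Upstream dataset construction (redundancy removal, modification
  quality filtering, database queries) is out of scope; the tool consumes
  windows as given.
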