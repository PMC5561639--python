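# Methods

## Model

### Classifier chains and their ensemble

Given a dataset with feature matrix X (n × p) and binary label matrix
(n × m), a classifier chain fixes a permutation π of {0…m−1} and trains one
binary random forest per position: the forest at position i is trained on
`[X | labels at π(0)…π(i−1)]` with target `labels[:, π(i)]`. **True**
upstream labels are used as training inputs; at prediction time the
**predicted hard labels** of earlier positions are appended to the working
feature vector instead, so upstream decisions propagate down the chain.

The ensemble (ECC) trains k chains. Chain c draws — from a random stream
indexed by (seed, c) — a uniform random label order (duplicates across
chains allowed) and a full-size bootstrap (n draws with replacement) of the
training instances, then trains on that resample. Prediction is per-label
voting: `vote[i, j]` is the fraction of chains predicting label j positive
for instance i, and the hard label is `vote >= threshold`. A vote exactly at
the threshold counts positive, so the rule is total.

Design choices where the formulation is genuinely open, and why:

- **Hard labels propagate down a chain**, not vote fractions — this matches
  the original classifier-chain formulation and keeps every intermediate
  quantity binary, which is what the fixed-width augmented feature block
  expects.
- **Per-chain thresholding before voting** (each chain contributes a 0/1
  opinion per label) rather than averaging continuous forest outputs; the
  vote matrix is then exactly a multiple of 1/k and invariant to chain
  order.
- **Per-chain resampling is a full-size bootstrap**, the standard ECC
  choice among the many possible "subsets of training data".
- The non-ensemble chain API (`train_chain`) takes the order explicitly and
  defaults to dataset label order.

### The fixed-shape flat-array random forest

Every tree has depth `depth` and exactly 2^(depth+1) − 1 node slots stored
as three parallel arrays (split feature, split threshold, positive
fraction) in heap order; children of node i are at 2i+1 / 2i+2 by
arithmetic, with `split_feature == −1` marking leaves. Fixing the shape
regardless of the data is what allows a whole model to live in a handful of
dense arrays (see Persistence) and prediction to be a branch-free indexed
descent of at most depth+1 nodes.

Training of one tree:

1. Bootstrap: n instance indices drawn with replacement become the root's
   working set. The data matrix is never copied or reordered — the only
   per-node state is a contiguous slice of this one index array, and each
   split partitions its slice in place (left segment, then right segment).
2. At each internal node, `mtry` candidate features are drawn without
   replacement; the split maximizing the weighted Gini-impurity decrease
   over all midpoints between consecutive distinct feature values is
   chosen. Ties break by lowest feature index, then lowest threshold, so
   the search has a total order and the tree is a pure function of
   (data, params, stream).
3. A node is frozen as a leaf when its slice is smaller than
   `min_node_size`, no split has positive decrease (e.g. a pure node), or
   it sits at maximal depth. Node slots never reached by any training
   instance inherit the parent's positive fraction, so prediction is
   well-defined for every input.

Prediction: instances go left when `value <= threshold`. A tree votes
positive when its leaf fraction is ≥ 0.5; the forest's label is the
majority of tree votes with the 0.5 tie going to positive. Counting hard
votes (rather than averaging leaf fractions) mirrors classical
random-forest majority voting.

Parameters, defaults, and rationale:

| parameter | default | meaning |
|---|---|---|
| `depth` | 10 | fixed tree depth; bounds the array at 2047 slots |
| `mtry` | ⌊√p⁺⌋, min 1 | candidate features per node (p⁺ = augmented width), the classification convention |
| `min_node_size` | 1 | fully-grown trees, the classification convention |
| `forest_size` | 64 | trees per forest (reference workflow default) |
| `ensemble_size` | 20 | chains per ensemble (reference workflow default) |
| `threshold` | 0.5 | ensemble vote threshold, in (0, 1] |

### Reproducibility under parallel schedules

Both training phases are embarrassingly parallel (trees within a forest;
instances at classification). To make results independent of any execution
schedule, every task's randomness is a pure function of its coordinates: a
`numpy SeedSequence` whose spawn key is the (chain, position, tree) path
from the root seed. Building trees in any order — or rebuilding one tree in
isolation from its coordinates — yields bit-identical models. Classification
is side-effect-free throughout.

## Mulan I/O

`read_mulan` consumes the dense Weka ARFF dialect (via `scipy.io.arff`)
plus the Mulan label manifest (`<labels><label name=…/></labels>`, namespace
tolerated). Attributes named in the XML become label columns in XML order
(the XML is the authoritative manifest); all remaining attributes become
feature columns in ARFF order. Accepted attribute kinds are numeric and
{0,1}-nominal (coerced to 0/1) — everything the flat numeric instance
buffer can hold. Missing values, wider nominal domains, strings, and sparse
rows are rejected with the offending attribute and row named; silent
imputation would be worse than a loud failure. Attribute-name matching is
case-sensitive. `write_mulan` emits labels as nominal {0,1} and formats
floats with `repr`, so write-then-read is an exact identity.

## Metrics

For binary prediction and truth matrices of equal shape:
per-label accuracy (column means of agreement), Hamming loss (fraction of
disagreeing cells, identically 1 − mean per-label accuracy), and subset
accuracy (fraction of rows matching exactly, never above the worst
per-label accuracy). This is the minimal standard multi-label triple behind
the CLI's per-label evaluation flag; ranking metrics and F-scores are out
of scope.

## Persistence

A stored model is one self-describing container: magic `ECCM`, a uint32
format version, a JSON header (dimensions, tree parameters, threshold,
attribute names, SHA-256 of the body), and a body holding the chain orders
and the stacked node arrays of every tree in fixed little-endian dtypes.
Loading verifies magic, version, and checksum, and reproduces a model whose
predictions are bit-identical; unknown versions and corrupt or truncated
files fail cleanly. A schema'd binary container was chosen over a
language-native pickle for portability and integrity checking.

## Synthetic data generator

`generate(SyntheticSpec)` emulates the structure that makes chains
worthwhile: label interdependency. Features are standard-normal. *Root*
labels (no incoming dependency edge) are linear-threshold functions — the
sum of a block of `signal_features_per_root_label` features (default 3),
plus optional Gaussian noise of sd `noise_sd` (default 0), thresholded at
zero, giving balanced labels whose oblique decision boundary is learnable
but not trivial for axis-aligned trees. Each *dependent* label copies its
single source label and flips each bit independently with the edge's flip
probability (in [0, 0.5)); the dependency graph must be a DAG with at most
one source per label. Everything is a pure function of the seed.

What it does **not** emulate: real drug-resistance panels or the Mulan
benchmark sets — correlated/categorical features, class imbalance,
many-label regimes, feature noise structure. Passing tests on this
generator show that the engine recovers injected label dependencies and
behaves reproducibly; they do not certify accuracy on any real dataset.

### Benchmark conditions

The dependency-recovery benchmark used by the tests and the acceptance
script: two labels, label 2 a 5%-noisy copy of the separable (noise-free)
label 1, p = 10 features with 3 signal features, 500 training and 300 test
instances, ensemble of 10 chains with 32 depth-6 trees, 10 independent
repetitions; compared against chain-free independent per-label forests
with identical forest parameters on the same splits. These sizes keep the
full benchmark around a minute on one CPU while leaving the chain-vs-no-
chain contrast well resolved.

## Numerical and degenerate-input conventions

- Split thresholds are midpoints of consecutive distinct sorted values;
  `<=` goes left. Both conventions affect bit-exact reproducibility and are
  therefore fixed.
- All vote ties (tree leaf at 0.5, forest at 0.5, ensemble vote equal to
  threshold) resolve positive.
- The split-search cross-check accepts any optimum within 1e-9 of the
  brute-force maximum decrease: distinct (feature, threshold) pairs can tie
  in exact arithmetic, where the documented lowest-index/lowest-threshold
  rule decides.
- A single-instance training set yields an all-leaf tree predicting that
  instance's label; empty training sets, non-permutation chain orders, and
  shape mismatches raise `ValueError`.
- Datasets with missing values or non-binary labels are rejected at load
  time, never repaired.

## Known limitations

- Binary labels only; no regression trees, no multi-class base learners.
- No out-of-bag estimates, probability calibration, or feature importance.
- Resubstitution is the CLI's default evaluation (mirroring the
  train-then-classify-the-same-object demo workflow); use `--holdout` for
  honest error estimates.
- The fixed-shape array grows as 2^(depth+1); depths much beyond ~20 are
  impractical by design.
- Stored models are not compatible with any external tool's format.
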