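# ecchain

Ensemble Classifier Chains (ECC) for multi-label classification, built on a
bespoke fixed-shape, flat-array random forest — with Mulan-format I/O
(`.arff` + `.xml`), multi-label evaluation metrics, exact model persistence,
a synthetic-data generator, and a command-line interface.

## The problem

In multi-label classification each instance carries a *set* of binary labels
L = {l₁, …, l_m} rather than a single class — e.g. an HIV protein sequence
that is simultaneously resistant to several drugs. Labels are rarely
independent: resistance to one drug is often indicative of resistance to a
related one. A **Classifier Chain (CC)** exploits this by fixing an order
over the labels and training one binary classifier per position, where
classifier Cᵢ sees the original features *plus* the labels of C₀…Cᵢ₋₁ (true
labels while training, predicted labels while classifying). Because the
chain order matters and errors propagate, the **Ensemble of Classifier
Chains (ECC)** trains k chains, each with a uniformly random label order on
its own bootstrap resample of the data, and combines them by per-label
voting: label j is assigned when the fraction of chains voting for it
reaches a threshold (default 0.5).

The base learner is a random forest whose trees all have the **exact same
depth and node count**: a tree of depth d is one contiguous array of
2^(d+1) − 1 node records in heap order, so the children of node i sit at the
arithmetically computed slots 2i+1 and 2i+2 and no pointers exist. Training
never copies the data matrix — each tree works through a single reordered
index array (the bootstrap), partitioned in place at every split. This
layout makes every model bit-reproducible from its seed, cheap to serialize,
and friendly to data-parallel execution.

Defaults follow the reference workflow: ensemble size k = 20 chains,
forest size 64 trees.

## Worked example

Generate a small two-label dataset where label `l2` is a 5%-noisy copy of
the separable label `l1`, write it as a Mulan `.arff`/`.xml` pair, then train
and evaluate an ensemble from the shell:

```sh
python -c "
from ecchain import SyntheticSpec, generate, write_mulan
ds = generate(SyntheticSpec(n=400, p=10, m=2, dependency_graph=((0,1,0.05),), seed=42))
write_mulan(ds, 'hivdemo.arff', 'hivdemo.xml')
"
ecchain --inpData hivdemo --eccES 10 --eccFS 32 --depth 6 \
        --holdout 0.25 --seed 1 --evalAllLabels --out demo.ecc
```

which prints:

```
# ecchain: k=10 chains, 32 trees/forest, holdout=0.25
n_eval	100
hamming_loss	0.155000
subset_accuracy	0.800000

label	accuracy
l1	0.880000
l2	0.810000
# model stored at demo.ecc
```

`n_eval` is the held-out instance count (25% of 400); `hamming_loss` is the
fraction of label cells predicted wrongly; `subset_accuracy` is the fraction
of instances whose *entire* label vector is exactly right; the table lists
each label's accuracy. The stored model can later classify new data without
retraining:

```sh
ecchain --inpData hivdemo --classOnly demo.ecc --out predictions.tsv
```

writing one row per instance with the per-label vote fractions and the
thresholded hard labels.

The same workflow is available as a library: `read_mulan` / `write_mulan`,
`train_ecc` / `predict_ecc`, `evaluate`, `store_model` / `load_model`, and
`SyntheticSpec` / `generate` (see `docs/methods.md` for the model details).

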