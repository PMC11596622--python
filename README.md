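# pathassoc

Predicting which biochemical pathways a small molecule participates in,
from structure alone, for every level of a three-tier pathway hierarchy.

Pathway knowledge bases annotate only a fraction of known compounds, and
experimental assignment of pathway involvement is slow and expensive.
`pathassoc` implements a machine-learning pipeline that learns
compound–pathway association from the annotated portion of such a
knowledge base and predicts it for the rest:

1. **Compound features.** Each compound arrives as a CTAB V2000 molfile.
   After removing hydrogens, every atom receives a canonical *color* per
   neighborhood depth — depth 0 is the element (plus any formal charge),
   and the depth-*d* color appends the sorted list of
   `bond_order:neighbor_color` pairs, e.g. `C(1:C,1:O)`. A compound's
   feature vector counts each color of a shared vocabulary; the compound's
   *size* is its number of non-hydrogen atoms.
2. **Pathway features.** Pathways form a 3-level hierarchy: top categories
   (L1), subcategories (L2), individual pathways (L3). Compound
   annotations propagate upward to ancestors, and a pathway's feature
   vector is the element-wise sum of its member compounds' vectors. A
   pathway's size is the summed size of its members.
3. **Pair dataset.** After removing duplicate feature vectors (to keep a
   vector from appearing on both sides of a train/test split), every
   compound is paired with every pathway. The entry for pair *(c, p)* is
   the concatenation of the two feature vectors, labeled 1 iff *c* is
   associated with *p*. The two matrices are stored separately; batches
   gather and concatenate rows on the fly.
4. **Classifier.** A multi-layer perceptron (ReLU hidden layers, sigmoid
   output, binary cross-entropy, Adam) maps the concatenated vector to an
   association probability.
5. **Evaluation.** Repeated stratified train/test cross-validation.
   Alongside each iteration's overall confusion matrix, every test entry's
   outcome is credited to its compound and its pathway, summed across
   iterations, so per-entity metrics are defined even for rarely-positive
   entities. The headline metric is the Matthews correlation coefficient

   MCC = (TP·TN − FP·FN) / √((TP+FP)(TP+FN)(TN+FP)(TN+FN)),

   computed with an exact integer numerator and log-space denominator so
   counts in the tens of millions lose no precision; a metric whose
   denominator is zero is reported as undefined (null), never as 0.

A synthetic-data generator produces complete studies — molfiles, a
hierarchy, annotations — with a *planted* class signal whose strength is
tunable, so the whole pipeline is testable end to end without any
external downloads.

## Worked example

```python
from pathassoc import (
    AssociationMLP, MLPConfig, SynthConfig, generate, mcc, run_cv,
)
from pathassoc.pipeline import build_pair_dataset

study = generate(SynthConfig(seed=1))          # 300 molfiles, 21 pathways
ds, report = build_pair_dataset(
    study.molecules, study.hierarchy, study.direct_annotations, max_depth=1,
)
print(ds.n_compounds, ds.n_pathways, ds.n_entries)
# 300 21 6300

cfg = MLPConfig(hidden_sizes=(256, 64), dropout=0.0, batch_size=256,
                max_epochs=100, patience=15)
cv = run_cv(ds, cfg, n_iterations=2, base_seed=1, test_fraction=0.1)
print(cv.summary())
# Cross-validation analysis (2 iterations)
#   MCC across iterations: mean 0.987, median 0.987, std 0.0090
#   MCC by pathway hierarchy level (summed counts):
#     L1: 1.000
#     L2: 1.000
#     L3: 0.964
```

The synthetic study plants a latent compound class in each molecule's
element composition and ties each individual pathway to one class, so a
correctly wired pipeline recovers the associations almost perfectly
(MCC near 1), while a no-signal control (`class_purity=0.5` with two
classes) yields an MCC near zero. The per-level rows show the aggregated
confusion over all pathways at each hierarchy level — top categories are
easiest because upward propagation makes their labels most redundant.

The same pipeline is available from the shell:

```sh
pathassoc simulate  --out study --seed 1
pathassoc build     --molfiles study/molfiles --hierarchy study/hierarchy.tsv \
                    --annotations study/annotations.tsv --out dataset.h5 --depth 1
pathassoc cv        --dataset dataset.h5 --hierarchy study/hierarchy.tsv --out cv_out
pathassoc report    --cv-dir cv_out
```

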