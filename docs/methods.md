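# Methods

## The prediction task

Given a compound's molecular structure and a pathway's aggregate chemical
profile, predict whether the compound participates in the pathway. The
model operates on every level of a three-tier pathway organization — top
categories (L1), subcategories (L2), and individual pathways (L3) — by
treating each (compound, pathway) pair as one binary-classification entry
of a cross-join dataset.

## Features

**Atom colors.** On the hydrogen-free molecular graph, each atom's
depth-0 color is its element symbol, suffixed with `+n`/`-n` for a
nonzero formal charge. The depth-*d* color is the atom's depth-(d−1)
color followed by the lexicographically sorted list of
`bond_order:neighbor_depth-(d-1)_color` pairs. Two atoms receive the
same color exactly when their rooted bonded neighborhoods are isomorphic
up to the depth, so the per-molecule color multiset is invariant under
atom relabeling (property-tested, and checked against an independent
oracle that explicitly unrolls and canonically serializes each atom's
rooted subtree). Colors from *all* depths 0..D are counted. With
`max_depth=AUTO`, D is the first depth at which the partition of the
molecule's atoms into color classes stops refining; an isolated atom's
color is stable across depths and is counted once. Aromatic bonds keep
their written type (4) as a distinct bond order; no kekulization or
normalization is applied. Formal charges are read from `M  CHG`
property lines (the legacy atom-block charge column is ignored), and
disconnected fragments are kept.

**Vocabulary.** The color vocabulary is the lexicographically sorted
union of all compounds' colors, built once from the full compound set
before any train/test splitting. This mirrors the upstream protocol's
ordering of steps; the feature *definition* therefore sees all compounds,
which is a known and accepted form of leakage in this design. The
pathway feature vocabulary is the compound vocabulary restricted to the
columns positive in at least one pathway; this restriction is our
declared reading of why the full-scale study reports fewer pathway
features than compound features, not a certainty.

**Pathway aggregation.** A pathway's vector is the element-wise *sum* of
its member compounds' vectors (members = compounds whose upward-closed
annotation set contains the pathway). Summation is consistent with the
additive definition of pathway size (summed member heavy-atom counts)
and keeps counts rather than presence flags. Pathways with zero members
are excluded with a warning.

## Dataset construction

Order of operations: strip hydrogens → color and featurize → remove
duplicate compound vectors (keeping the lexicographically smallest id) →
propagate annotations upward → build pathway features → remove duplicate
pathway vectors → cross-join. De-duplication precedes the cross-join so
one feature vector can never appear in both a training and a test fold
under a different identity. The pair dataset never materializes the
concatenated table: it stores the compound matrix (n_c × d_c), the
pathway matrix (n_p × d_p) and the label matrix, with entry *k* mapping
to pair (k ÷ n_p, k mod n_p). Batches are assembled by block-gathering
the two row sets and concatenating — bitwise identical to per-entry
concatenation (oracle-tested).

Size filters remove compounds below a heavy-atom threshold or pathways
below a summed-size threshold; the pathway threshold grid is 5..50 by 5,
60..100 by 10, 120..200 by 20 (20 values). Level filters keep a subset
of {L1, L2, L3} pathways without touching compounds.

## Classifier

A multi-layer perceptron on the raw concatenated counts (no scaling —
fidelity to the upstream protocol, which mentions none): ReLU hidden
layers, inverted dropout, a single sigmoid output, mean binary
cross-entropy, Adam (β₁=0.9, β₂=0.999), mini-batches shuffled by a
seeded generator. Training stops early when the epoch loss has not
improved by `min_loss_delta` (1e-4) for `patience` consecutive epochs. A
non-finite loss aborts with a diagnostic. `max_epochs=0` yields the null
model, which predicts probability 0.5 everywhere; with the ≥-threshold
convention at 0.5 this produces all-positive calls, whose MCC is
undefined and reported as null. Training is exactly reproducible given
(config, seed): all stochastic elements (initialization, shuffling,
dropout masks) flow from one seeded generator.

Package defaults (hidden 512×128, dropout 0.2, learning rate 1e-3,
batch 4096, 20 epochs) are declared desk-scale stand-ins for the
full-scale study's tuned-but-unreported hyperparameters; no claim of
equivalence is made, and every value is configurable. The synthetic
benchmark runs in the tests use a configuration proportionate to its
~6,000-entry datasets (hidden 256×64, no dropout, batch 256, up to 100
epochs, patience 15): with batch 4096 such a dataset yields only two
gradient steps per epoch, which cannot train the network.

## Evaluation protocol

Repeated stratified train/test cross-validation at the *entry* level
(test fraction 0.1 by default; stratification on the binary label only —
the minimal reading of "stratified"). Iteration *i* uses seed
`base_seed + i` for both split and model. Entry-level splitting means a
compound's other entries can appear in training while one of its entries
is in test; grouped (compound-level) splitting is deliberately out of
scope to replicate the upstream protocol, and its consequences are
discussed below.

Per iteration, the overall test confusion matrix is recorded; in
parallel every test entry's outcome is credited to its compound and its
pathway and summed across iterations. Metrics for any scope (a pathway,
a compound, a hierarchy level, an L1 subtree) are always derived from
the summed counts of that scope. The six metrics are MCC, accuracy,
precision, recall, F1, and specificity; any metric whose defining
denominator is zero is UNDEFINED, reported as null (never coerced to 0),
excluded from distributions and correlations. MCC uses an exact integer
numerator and a log-space square root of the marginal product: the
largest reference counts (tens of millions) drive the naive product past
2⁶³, so 64-bit arithmetic would silently overflow. Across-iteration
summaries (mean, median, sample std) are computed from per-iteration
metric values. Size-vs-performance association uses Pearson's r with the
two-sided t-test p-value (the specific p-value method of the reference
analysis is not stated; the t-test is our declared choice). Reported
tables round metrics to 3 decimal places; JSON exports keep full
precision.

## Synthetic data: what it emulates, and what it does not

The generator emits a complete study — V2000 molfiles, a 3-level
hierarchy TSV, an annotation TSV — with a planted, tunable signal:

- **Molecules** are random valence-capped (≤4), chain-biased heavy-atom
  graphs (85% chain growth, otherwise random attachment; up to two
  ring-closing edges; bond orders 1 or 2 with probability 0.8/0.2),
  sizes uniform on 10–30. Every compound belongs to a latent class
  realized as its element composition: half carbon backbone, half a
  class-specific signature element, drawn from a 13-element alphabet
  (C + 12 signature elements). The one-signature-element design makes
  classes separable from depth-0 colors onward, and keeps the *color
  space within a class shared* across its compounds.
- **Hierarchy**: balanced round-robin parents (L2_i under L1_{i mod 3},
  L3_i under L2_{i mod 6}), so every pathway's structural popularity is
  comparable.
- **Annotations**: each compound draws `i = rate × purity` in-class and
  `o = rate × (1 − purity)` off-class L3 annotations (stochastically
  rounded, uniform without replacement), giving expected direct
  annotations = `annotation_rate` and an expected in-class member share
  of exactly `class_purity`. Off-class draws prefer siblings, then
  same-top-category pathways, of the drawn annotations, so each noise
  annotation perturbs the propagated label count minimally. A direct L2
  annotation is occasionally added (rate 0.1) over an already-annotated
  branch, exercising the direct-L2 code path without changing labels.
  With defaults (12 classes ↔ 12 individual pathways, purity 0.9,
  rate 1.11) the cross-join positive fraction is ≈0.15 — the
  negative-dominated regime of real annotation data.

Several of these choices exist specifically to make the *no-signal
control* meaningful. Entry-level splitting lets a model exploit two
signals that have nothing to do with chemistry: (1) per-entity
*propensity* — if compounds differ in how many positive labels they
carry, a model that can identify a compound from its features can learn
its base rate from the ~90% of its entries seen in training; (2)
*membership containment* — a pathway's summed vector componentwise
dominates each member's vector, so with small memberships and
near-unique per-compound colors, membership is readable off the features
themselves. Both effects exist in real data too (the upstream protocol
accepts them by design), but they would mask the difference between a
planted-signal study and a null study. The generator therefore keeps
per-compound annotation counts near-constant, pathway popularities
balanced, and color spaces shared (300 compounds over 21 pathways gives
~50 members per individual pathway, so a single member's contribution to
a pathway sum is not individually detectable). The null control (two
classes, purity 0.5, `annotation_rate=2.0` so the in/off draws are
exactly one each) then carries no learnable signal: a trained model
lands at |MCC| < 0.1 or collapses to the all-negative prediction
(undefined MCC).

Consequently, passing tests demonstrate that the pipeline recovers a
planted compound-class → pathway signal and invents nothing under a null
— they do **not** demonstrate real-world predictive accuracy, which
depends on chemistry the generator does not emulate (realistic valence
and functional groups, skewed size distributions, correlated pathway
memberships, annotation sparsity patterns).

## Numerical and degenerate-input conventions

- Probability threshold 0.5, with ties called positive (`p ≥ t`).
- De-dup tie-break: lexicographically smallest id survives.
- Stratified splits use scikit-learn's stratified shuffle split;
  determinism is per (seed, dataset).
- Zero-member pathways are excluded with a warning; empty molecules,
  all-hydrogen molecules, single-class training labels, and empty filter
  results raise typed errors.
- Molfile dialect: V2000 only; V3000 is rejected with a clear error.

## Problem sizes used in the shipped analyses

The shipped tests and example run the synthetic benchmark at 300
compounds × 21 pathways (≈6,300 entries, features at coloring depth 1)
with 2–5 CV iterations, and verify count identities at the full-scale
cardinalities (6485 × 502) on structurally trivial feature matrices.
These sizes were chosen so the entire analysis reruns from scratch in a
few minutes on a single CPU core while still exercising every stage of
the pipeline at realistic class imbalance.

## Known limitations

- The MLP hyperparameters of the full-scale reference model are not
  public; desk-scale defaults are declared, not tuned equivalents, so
  the reference headline CV performance is not an implementation target.
- Entry-level (not compound-level) splitting overstates generalization
  to genuinely novel compounds; this replicates the upstream protocol.
- The pathway-feature vocabulary restriction (nonzero columns) is an
  assumption; the upstream aggregation function is not fully specified.
- The synthetic molecules are not chemically valid beyond valence-capped
  connectivity; no stereochemistry, coordinates, or kekulization.
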