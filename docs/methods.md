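# Methods

## Model and procedure

`fassl` implements pool-based active semi-supervised learning under the
"reduce and organize once" paradigm. A repetition has two phases:

**Preparation (once).** The dataset is split into test set `Z3`
(`round(0.2·n)` samples, half-up), and a learning set `Z2` whose first
`floor(0.5·|Z2|)` shuffled indices form the unlabeled reservoir `Z2''`
and the rest the annotation pool `Z2'`. Features are min-max scaled with
parameters fitted on `Z2` only (the test set is transformed, never
fitted). The pool is clustered with k-means (`k = 2·nc`, 10 restarts,
best inertia); each non-empty cluster's *root* is the member nearest its
centroid. A pool sample is a *boundary sample* when at least one of its
`n_neighbors` nearest other pool samples (Euclidean; ties broken by
ascending index) belongs to a different cluster. Per cluster, candidates
are listed in increasing distance to the root (RDBS lists hold boundary
members only, RDS lists all members); cross-cluster boundary pairs sorted
by increasing distance form the edge list used by IBE.

**Learning loop.** Iteration 1 annotates the roots (the Rand baseline,
which has no clustering stage, instead draws its first batch uniformly).
Every subsequent iteration asks the strategy for up to `2·nc` candidates,
annotates them through the oracle, draws `round(0.5·2·nc)` fresh rows
from `Z2''` into the (cumulative) unlabeled training set, retrains the
classifier from scratch on everything accumulated, and records accuracy
on `Z3`. The loop stops at `max_iterations`, on candidate exhaustion, or
when an optional target accuracy is reached.

The RDBS/RDS walk: round-robin over cluster lists; within a list, walk
unconsumed samples in ascending root distance and select the first whose
predicted label differs from the root's *oracle-confirmed* label; if the
whole list agrees, select its farthest unconsumed sample instead (the
fallback can be disabled, in which case the list contributes nothing that
iteration). Selected samples are consumed permanently; walked-but-rejected
samples stay available, because a sample an early, weak classifier agreed
with may become informative later. Predictions are made only for walked
samples — never the whole pool — which keeps per-iteration cost
proportional to the batch, not the pool.

YATSI (two-stage) classification: stage 1 fits the base classifier on the
`N` labeled rows and pre-labels the `M` unlabeled rows; stage 2 classifies
a query by the weight-summed vote of its `K` nearest rows in the combined
store, labeled rows at weight 1 and pre-labeled rows at `F·N/M` (so the
unlabeled block as a whole carries the same mass as the labeled block at
`F = 1`). Rows with weight zero are omitted from the store: they could
never carry a vote, but would otherwise occupy neighbor slots and distort
the `F = 0` limit, which must coincide exactly with weighted kNN over the
labeled rows alone.

## Parameters

| parameter | default | meaning |
|---|---|---|
| `test_fraction` / `pool_fraction` | 0.2 / 0.5 | the 80/20 learning-test and 50/50 pool splits |
| `k_multiplier` | 2 | clusters per class; `k = 2·nc` helps the roots cover all classes from iteration 1 |
| `labeled_budget_multiplier` | 2 | annotations per iteration = `2·nc` |
| `unlabeled_fraction` | 0.5 | unlabeled rows drawn per iteration, as a fraction of the labeled budget |
| `n_neighbors` | 5 | boundary-detection neighbor count (distinct from k-means `k`) |
| `F`, `K` | 1.0, 10 | YATSI propagation weight and stage-2 neighbor count |
| `repetitions` | 10 | independent repetitions averaged into the learning curve |

Per-repetition seeds derive as `seed + repetition`; supplying a shared
`split_seed` makes different strategies see identical splits (and, since
the clustering seed also derives from the repetition, identical cluster
structures), so curve differences reflect selection policy only.

## Synthetic data

The generator produces isotropic unit-variance Gaussian blobs, one per
class, with adjacent class means `separation` standard deviations apart
(means on a circle in 2-D, on scaled coordinate axes when `nc ≤ d`). This
captures what the method actually exploits — classes that form clusters,
with informative samples concentrated near cluster borders — but not the
high dimensionality, correlated features or class imbalance of real
gene-expression or image-descriptor tables. Passing tests therefore
demonstrate the mechanics and the direction of the benefits, not effect
sizes on any particular real dataset.

The frozen benchmark for the stochastic directional properties is
`nc=4, per_class=50, d=2, separation=3`, generator seeds 0–9, 10
shared-split repetitions each: large enough overlap that classification
is non-trivial, small enough that a full sweep runs in seconds. Problem
sizes throughout the suite (pools of ≤ 100 candidates, 200-sample
datasets) were chosen as the smallest instances at which every claimed
property is visibly non-degenerate.

## Numerical choices and tie-breaks

- All distances are Euclidean, computed on the scaled features; k-means
  implies the same metric, keeping clustering, reduction, organization
  and YATSI stage 2 mutually consistent.
- Every ordering is made total: neighbor lists and root-distance lists
  break distance ties by ascending candidate index, edge lists
  lexicographically by `(distance, a, b)`, YATSI votes by the configured
  class order (defaults to sorted labels), root-to-centroid ties by
  ascending index. Results are therefore bit-reproducible given seeds.
- `|Z3|` rounds half-up, `|Z2''|` floors; the unlabeled batch rounds
  half-up. Documented rather than principled — any fixed convention works,
  but it must be fixed.
- Empty k-means clusters are dropped (no re-seeding); their budget share
  redistributes naturally through the round-robin over surviving lists.
- If selecting both endpoints of a disagreeing IBE edge would exceed the
  budget, only the lower-index endpoint is taken.
- A labeled set containing a single class degrades the base classifier to
  a constant predictor instead of failing (SVM and RF cannot fit one
  class); this occurs only in pathological first iterations.

## Design choices where the design was open

- **Root realization.** "Root" is inherited from clustering terminology
  without a k-means definition; we use the member nearest the centroid,
  the standard prototype choice.
- **Rand cold start.** Cluster-based strategies annotate roots first;
  the random baseline draws uniformly from iteration 1, since it has no
  clustering stage to provide roots.
- **RDBS fallback.** Whether RDBS inherits RDS's farthest-sample fallback
  is open; we adopt it (so budgets are always met) and expose a strict
  mode that disables it.
- **Consumption.** Unlabeled reservoir draws are without replacement and
  cumulative across iterations, matching the additive budget arithmetic
  (4+2+4+2 = 12 after two iterations at `nc = 2`).
- **Scaling on by default.** Distances on unscaled heterogeneous features
  would be dominated by large-range columns; a flag disables scaling for
  data already on a common scale.
- **Accuracy metric.** Plain exact-match accuracy by default; a balanced
  variant (unweighted mean of per-class recalls) is available for
  imbalanced data.
- **Clu's cluster count** follows the global `k = 2·nc` setting used by
  all clustering-based strategies, for comparability.

## Limitations

- The boundary definition is quadratic in pool size; fine for the small
  tabular datasets targeted here, but an approximate neighbor index would
  be needed beyond ~10^4 candidates.
- The oracle is noiseless; label-noise robustness is untested.
- The base classifiers use library defaults; no per-dataset
  hyperparameter tuning is performed anywhere, so absolute accuracies are
  conservative.
- OPF (optimum-path forest) classifiers are not included; the base
  classifier contract (`fit`/`predict`) accepts third-party drop-ins.
- Directional benchmark properties (boundary sampling ≥ random early;
  semi-supervised ≥ supervised at the end) are majority-of-seeds claims
  on the frozen benchmark, not per-seed guarantees — individual seeds can
  and do go the other way.
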