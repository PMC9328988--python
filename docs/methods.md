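# Methods

This note documents the modelling choices behind `wbbn`: what is computed,
under which assumptions, which knobs matter, and what the synthetic
experiments do and do not demonstrate.

## Data model

A dataset is a list of records over a fixed `AttributeSchema`. Every
discretized value of every attribute is an *item* — a positive integer, with
items forming one contiguous block per attribute (the default breast-cancer
layout puts nine binary attributes on items 1–18 and the benign/malignant
class on 19/20). A complete record holds exactly one item per attribute plus
one class item. Records lacking an item are flagged missing at read time and
must be dropped (`drop_missing`) before modelling; no imputation is
attempted. Readers exist for the LUCS-KDD `.num` dialect, for raw CSV with
schema-driven binning (missing markers `?` and the empty cell), and for the
raw UCI Wisconsin file layout (id column, nine 1–10 values, class codes
2/4).

## Attribute–value weighting

Counts of each attribute item under each class label are densely ranked
*jointly over both labels* (largest count = rank 1, ties share a rank), so
the reported positive-label ranks need not start at 1. Weights are defined
for the positive class only, with two schemes:

* `joint` (default): w(item) = N(item ∧ yes) / N — the joint probability
  P(E ∧ H) assembled from the Bayes-theorem quantities. It is bounded by the
  positive-class prior, anti-monotone with the positive-label counts, and the
  weights of one attribute's items sum exactly to P(yes).
* `posterior`: w(item) = N(item ∧ yes) / N(item) = P(H | E).

A record's weight is the arithmetic mean of its attribute items' weights
(`record_weight_scheme="sum"` switches to the sum; the class item never
contributes). The mean is the default because it keeps record weights on the
same [0, 1] scale regardless of attribute count, which in turn keeps weighted
supports comparable across schemas. With all item weights equal, every
weighted quantity reduces exactly to its classical (uniform-weight)
counterpart — a reduction the test suite checks against plain counting to
1e-12.

## Weighted rule mining

Weighted support WS(X) = Σ_{r ⊇ X} W_r / Σ_r W_r and weighted confidence
WC(A→B) = WS(A∪B)/WS(A). Because each record's weight is fixed before mining,
WS is anti-monotone under itemset containment, so standard Apriori levelwise
pruning is sound; candidates never combine two items of the same attribute
(their joint support is structurally zero). Three mining modes share the one
support primitive: two-attribute rules (single-item antecedent and
consequent), multi-attribute rules (antecedent up to `max_antecedent_size`,
default 3, single attribute-item consequent), and class-label rules
(attribute-set antecedent, single class-item consequent).

Strong-rule selection computes the weighted Bayes confidence
WBC(A→B) = WS(A,B)/WS(A) — identical by definition to WC, and kept as a
separate field because the two thresholds are applied at different stages —
and the weighted Bayes lift WBL = WBC / WS(B). A rule is strong iff
WBC ≥ min_confidence and WBL > min_lift (default 1.0, i.e. any positive
association; the strict inequality makes the independence boundary
non-strong). Rules whose consequent has zero support are dropped with a
warning, since their lift is undefined. Output order is deterministic:
(WBL, WBC) descending, then lexicographic on sorted item lists.

Thresholds default to min_support 0.36 and min_confidence 0.70, the
operating point at which the method's holdout accuracy peaks in the
evaluation sweep; the sweep grid (36/70, 40/80, 26/60, 10/50 crossed with
100/100, 80/20, 70/30 and 60/40 splits) is exposed as
`evaluation.DEFAULT_GRID`.

## Network construction and inference

K2 needs a node ordering. We order the attributes that occur in strong rules
by descending total weight of their strong-rule items (alphabetical
tie-break) and put the class node last, so the attributes most associated
with the positive class become potential ancestors. Candidate parents are
restricted to node pairs that co-occur in at least one strong rule
(`unrestricted_k2` lifts this), and the search greedily adds the single
best-scoring parent under the Cooper–Herskovits marginal likelihood
(uniform Dirichlet(1) prior, computed with log-gamma functions) while the
score strictly improves, up to `max_parents` (default 3 — CPT size control
on datasets of a few hundred records).

CPTs use per-cell Dirichlet smoothing
P(v | pa) = (N(v, pa) + α)/(N(pa) + α·k) with α = 0.5 by default; an
unobserved parent configuration yields the uniform 1/k, and no probability
is ever exactly zero, so every evidence pattern has positive likelihood.
Inference is exact enumeration over unobserved nodes — the networks here
have at most about ten nodes, so approximation is unnecessary. Posterior
ties are broken toward the majority training class. Evidence on attributes
outside the learned network is ignored.

Identifiability caveat: K2 orients edges by the node order. A chain
A→B→class and the fork A←B→class are Markov equivalent, so only the
skeleton (and any v-structures) is recoverable from data; the structure-
recovery experiments therefore score skeleton equality, not arrow-for-arrow
identity.

## Evaluation protocol

Splits are stratified by class and seeded; `train_frac = 1` means train and
test are both the full dataset. All data-driven quantities — weights, rules,
structure, parameters — are computed on the training partition only
(verified by a no-leak test); `paper_mode=True` computes the weight table on
the full dataset instead, mimicking workflows that weight before splitting.
When no rule survives the thresholds there is no network to build; the
pipeline then predicts the majority training class and flags the report row,
so a sweep never aborts mid-grid. Accuracy (exact-match fraction) is the
single reported metric.

## Synthetic data: what it emulates, and what it does not

The generator draws records by ancestral sampling from a planted Bayesian
network of binary attributes plus a binary class, then encodes them in the
contiguous item layout. The default spec mirrors the shape of the Wisconsin
breast-cancer data — nine binary-discretized attributes, a 0.35
positive-class prior (about a third of samples malignant), 683 records —
with two attribute–class dependencies of different strengths and one
attribute–attribute dependency, so synthetic runs exercise the same code
paths and scales as a real analysis. Canned variants: `independent` (no
associations; every population lift is 1), `chain` (att1→att2→class with 90/10
conditionals), and `separable` (three attributes echoing a balanced class at
a 5% flip rate each, Bayes error ≈ 0.007).

For up to 12 binary nodes the planted joint is enumerated exactly, giving
analytic supports, confidences and lifts under uniform record weights
(`expected_strong_rules`) — the population oracle that mined rule sets
converge to as n grows.

What passing these experiments shows: the miner is exactly equivalent to
exhaustive enumeration, the estimators are consistent, structure/parameter
recovery works when the generating process really is a small discrete
Bayesian network. What it does not show: robustness to discretization error,
attribute cardinalities above 2, label noise beyond the planted CPTs,
systematically missing (non-random) cells, or covariate shift — real
clinical data have all of these.

## Numerical and degenerate-input choices

* CPT normalization is asserted to 1e-9 at construction.
* Weighted support caches per-itemset results; supports are sums of
  non-negative floats, so anti-monotonicity holds to machine precision (the
  superset test allows 1e-15 slack).
* Zero total record weight, zero antecedent support, empty datasets and an
  empty strong-rule set raise typed errors rather than returning NaN; the
  pipeline converts only the last of these into the majority fallback.
* All randomness flows through `numpy.random.default_rng(seed)`; the same
  seed gives byte-identical CLI outputs.

## Problem sizes

The test suite and the acceptance script run entirely on generated data at
the study scale: 683-record datasets for pipeline runs, 10 000 records for
independence/lift checks, 5 000 for parameter recovery, 2 000 for structure
recovery, 25 random datasets of ≤ 6 attributes and ≤ 200 records for
miner-vs-enumeration equivalence, and 100 random evidence vectors over ≤ 8
node networks for the inference oracle. The full suite completes in well
under a minute on one CPU, apart from the real-data record-count check,
which requires the (non-redistributed) UCI Wisconsin file.

## Known limitations

* Binary class only for weighting (weights are defined for the positive
  label); multi-class data would need one-vs-rest weight tables.
* Item weights are global, not per-rule; the record-weight construction
  (mean of pair weights) is one defensible choice among several.
* K2's output depends on the node order; with weak data the order-induced
  orientation of edges is arbitrary within the Markov equivalence class.
* Exact enumeration limits inference to networks of roughly 20 nodes;
  within this package's scope (strong-rule attributes only) that is ample.
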