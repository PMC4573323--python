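# Methods

## Problem and model

Given a universe of genes, a seed set `S` of known disease genes, a closed
(ancestor-propagated) annotation set over a three-branch ontology, and an
undirected functional-linkage network whose edges carry an evidence class
and a weight, the pipeline estimates for every gene a posterior that it is
seed-like, via two channels fused by logistic stacking.

### Annotation vocabulary

Annotations are closed under the true-path rule before any counting: a gene
annotated to a term is annotated to all of that term's `is_a` ancestors.
Only `is_a` edges are honored; other relations (`part_of`, regulates, ...)
are ignored as the conservative core of the hierarchy. The functional
vocabulary is the set of **informative terms** — terms annotating between
`min_genes` and `max_genes` genes (default 2–500), excluding both
near-singleton terms (no pair can share them meaningfully) and near-root
terms (shared by construction). Within each branch, kept terms are assigned
to `n_strata` specificity strata (default 4) by annotation-count quantile;
stratum 0 is the most specific. With three branches this yields the 12
(branch × stratum) categories the FL map is built over; both the window and
the stratum count are configuration because no canonical values exist.

### FL map

For each cell `(branch, stratum, evidence class)` the FL map counts, over
the edges of that class, the pairs whose endpoints share at least one
informative term of the cell, and estimates with a Laplace pseudocount
(default 1):

```
p = (n_shared + c) / (n_pairs + 2c)
```

which keeps every probability strictly inside (0, 1) and every likelihood
ratio finite. The background `p₀` per (branch, stratum) is the same
estimator over all unordered pairs of annotated genes — enumerated exactly
when C(n, 2) ≤ 2×10⁶ (a boolean gene×term membership matrix product makes
this cheap), otherwise from 10⁵ seeded uniformly sampled pairs. The cell
weight is the odds ratio `LR = odds(p)/odds(p₀)`; `LR = 1` exactly when the
linked pairs share function at the background rate. Edge weights do not
enter FL estimation — cells are defined by class membership — and act only
as evidence multiplicity during scoring.

### Guilt-by-association scoring

Evidence is single-hop: only edges incident to the scored gene contribute
(no diffusion or random walk). For each edge and each branch, the applied
cell is the **most specific stratum in which the two genes share an
informative term** of that branch, falling back to the branch's least
specific stratum when they share none — specific shared function is the
stronger evidence. A seed neighbor contributes `LR^w`, a non-seed neighbor
`LR^(−w·κ)` with `w = min(edge weight, 1)` (capping prevents unbounded
ratios from redundant rows) and damping `κ = 0.25` (configurable, 0
disables): unlabeled genes are weak, not full, negative evidence, and
undamped negatives would swamp a sparse seed set. Contributions combine
under naive-Bayes independence across edges and branches, the canonical
guilt-by-association combiner in the absence of any stated dependency
structure:

```
posterior odds = prior odds × Π LR_applied,   prior = |S ∩ universe| / |universe|
```

computed in log space and clamped to [10⁻⁹, 1−10⁻⁹]. Genes without edges
score exactly the prior.

### Guilt-by-profiling

The profile channel is a pluggable extractor registry; the defaults are
indicator columns for every informative term, per-branch counts of closed
annotations, and per-evidence-class degree. This registry is a generic,
documented stand-in for whatever richer gene-characteristic set a production
deployment would configure — the original feature families behind this class
of predictor are not recoverable, so the system is designed for
substitution rather than reconstruction. The classifier is an
L2-regularized logistic regression (strength 1.0, lbfgs, tol 10⁻⁸) on seeds
(label 1) versus a seeded uniform sample of non-seeds at 10:1 — a sampled
negative class keeps the imbalance controlled and the fit reproducible in
the absence of any defined negative set.

### Cross-validation, fusion, ranking

Seeds are split into k seeded folds (default 5). Per fold, the profile
model and association scores are recomputed with held-out seeds treated as
non-seeds; held-out seeds additionally never enter the profile model's
negative sample, because a gene must not be fitted — in either label role —
by the model that scores it. The FL map uses no seed labels (it counts
shared-function rates over edges and background pairs), so one estimate
serves all folds. Held-out seeds take their own fold's scores; non-seed
genes take the mean of the k fold models' scores, the standard stacking
reduction. Fold manifests (held-out/trained-on lists per fold) are retained
so leakage absence is auditable.

The combiner is a maximum-likelihood logistic fit of seed membership on the
two channel scores, logit-transformed after clamping to [10⁻⁶, 1−10⁻⁶]
(linear-in-logit fusion, the standard stacking choice), fitted on
out-of-fold scores only — in-fold scores would overstate synergy. A
constant channel receives a near-zero coefficient under the L2 penalty and
a logged warning. Non-seed genes are ranked by (combined score descending,
gene ID ascending) — a deterministic tie-break — shortlisted (default top
300), and triaged by the conjunctive five-criterion filter; criterion
values that are unknown fail, and the filter emits a per-gene, per-criterion
audit. No multiple-testing control applies: the procedure ranks, it does
not test.

### Evaluation

AUC uses the rank-sum formula with average ranks, identical to exhaustive
pairwise comparison with ties counted ½; recall@k counts positives in the
top k of the deterministic ranking. Seeds are excluded from evaluation sets
(they are labels, not predictions).

## Synthetic worlds

The generator emulates the statistical structure the method assumes, not
real-data topology. Per branch it builds a layered random DAG
(`n_terms_per_branch` = 120, depth 5; each non-root term takes 1–2 parents
from shallower layers, acyclic by construction). A module of
`n_seeds + n_hidden_positives` genes (defaults 77 + 30, matching the scale
of a curated seed set) is planted two ways: module genes draw their
`annotation_rate` (6) direct terms with the 20 module terms upweighted
`enrichment_fold` (8×) — module terms are drawn from mid-depth layers so the
signal lives in informative strata — and a stochastic-block network wires
within-module pairs at 0.15 versus 0.01 background, with evidence classes
uniform over a 6-class vocabulary and weights uniform on (0.5, 1]. Each
world consumes a single NumPy generator seeded once, in a fixed draw order,
so a seed determines every output byte.

Benchmark conditions (`seedrank.synthetic`):

- `default_world_config` — the reference recovery condition above.
- `synergy_world_config` — enrichment 4×, module density 0.04: both signals
  planted independently at moderate strength. At the reference condition
  both channels sit near AUC 1 and fusion has no measurable headroom; the
  synergy property (fused ≥ best channel) is only testable where neither
  channel saturates. These values were fixed as part of the benchmark
  design, before measurement.
- `null_world_config` — enrichment 1×, equal densities: no signal, for
  calibration (AUC should sit near 0.5).

What passing on these worlds does **not** show: robustness to real GO
topology, scale-free interactome degree distributions, annotation bias
toward well-studied genes, correlated evidence classes, or noisy/incomplete
seed sets. The generator's independence assumptions match the scorer's
(naive Bayes), so real-data performance will be lower.

## Numerical and degenerate-input choices

- All probabilities clamped before logit/odds transforms (10⁻⁶ combiner,
  10⁻⁹ posterior); posteriors accumulated in log space.
- Quantile strata use `searchsorted(edges, count, side="left")`, so a
  branch whose kept terms all share one count collapses into stratum 0.
- Duplicate network rows keep the maximum weight; self-loops are dropped
  and counted; parsing is invariant to row order and edge direction.
- A fully unannotated world (annotation rate 0) yields an empty vocabulary:
  association scores collapse to the prior and profiling falls back to
  degree features; the pipeline still runs.
- Worlds smaller than ~2 genes per fold, or with fewer than 5 training
  seeds per fold, are rejected with input errors rather than fitted.
- Sub-seeds for folds, negative sampling, and background pair sampling are
  spawned from one `SeedSequence`, keeping runs bit-reproducible.

## Test problem sizes

Module tests run on scaled-down worlds (300–600 genes) for speed; the
end-to-end suite runs the reference condition (1,000 genes, 77 seeds) for
recovery/null properties, 20 synergy worlds, and an exhaustive 50-world
sweep of ≤8-gene toys against enumeration oracles. At the reduced module
scale the per-seed null AUC is noisy because held-out scores within a fold
share one overfitted model, so the module-level permutation check asserts
unbiasedness of the mean; the banded per-seed form runs at reference scale.

## Known limitations

- Single-hop evidence only; no iterative propagation.
- Evidence classes are opaque labels; no class semantics or cross-class
  correlation modelling.
- The default feature registry is deliberately minimal; sequence-,
  expression- and literature-derived features are out of scope.
- The candidate-attribute table for triage is user-supplied; no literature
  mining is performed.
- Gene identifiers are opaque case-sensitive strings; no ID mapping.
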