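"""Guilt-by-profiling: score genes from their own characteristic profile.

Each gene's annotations and network connectivity are turned into a feature
vector through a pluggable extractor registry, and an L2-regularized
logistic classifier trained on seed genes versus a seeded uniform sample of
non-seeds yields P(seed-like | profile). The default extractors — indicator
columns for each informative term, per-branch annotation counts, and
per-evidence-class network degree — are a generic stand-in profile, not a
reconstruction of any particular feature system.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.linear_model import LogisticRegression

from .network import LinkageNetwork
from .ontology import AnnotationSet, InformativeTermSet


@dataclass
class FeatureMatrix:
    genes: list[str]
    features: list[str]
    values: np.ndarray  # genes x features, nonnegative
    extractor_manifest: tuple[str, ...]
    unannotated: np.ndarray  # boolean mask, genes with zero annotations

    def row_of(self, gene: str) -> np.ndarray:
        return self.values[self.genes.index(gene)]


@dataclass
class ProfileModel:
    coefficients: np.ndarray
    intercept: float
    features: list[str]
    extractor_manifest: tuple[str, ...]
    regularization_strength: float
    training_manifest: dict


DEFAULT_EXTRACTORS = ("term_indicators", "branch_counts", "class_degree")


def extract_features(
    universe: list[str],
    ann: AnnotationSet,
    terms: InformativeTermSet,
    net: LinkageNetwork,
    extractors: tuple[str, ...] = DEFAULT_EXTRACTORS,
) -> FeatureMatrix:
    """Build the gene x feature matrix for the configured extractors.

    Column order is deterministic given the extractor manifest. Unknown
    extractor names raise ``ValueError``.
    """
    if not extractors:
        raise ValueError("at least one extractor is required")
    unknown = [e for e in extractors if e not in DEFAULT_EXTRACTORS]
    if unknown:
        raise ValueError(f"unknown extractors: {', '.join(unknown)}")

    genes = list(universe)
    blocks: list[np.ndarray] = []
    names: list[str] = []

    if "term_indicators" in extractors:
        block = np.zeros((len(genes), len(terms.terms)))
        t_idx = {t: j for j, t in enumerate(terms.terms)}
        for i, g in enumerate(genes):
            for t in ann.terms_of(g):
                j = t_idx.get(t)
                if j is not None:
                    block[i, j] = 1.0
        blocks.append(block)
        names += [f"term:{t}" for t in terms.terms]

    if "branch_counts" in extractors:
        block = np.zeros((len(genes), len(terms.branches)))
        b_idx = {b: j for j, b in enumerate(terms.branches)}
        for i, g in enumerate(genes):
            for t in ann.terms_of(g):
                j = b_idx.get(terms.branch.get(t))
                if j is not None:
                    block[i, j] += 1.0
        blocks.append(block)
        names += [f"count:{b}" for b in terms.branches]

    if "class_degree" in extractors:
        deg = net.degree_by_class()
        block = np.zeros((len(genes), len(net.class_vocabulary)))
        for i, g in enumerate(genes):
            for j, c in enumerate(net.class_vocabulary):
                block[i, j] = deg.get(g, {}).get(c, 0)
        blocks.append(block)
        names += [f"degree:{c}" for c in net.class_vocabulary]

    values = np.hstack(blocks)
    unannotated = np.array([len(ann.terms_of(g)) == 0 for g in genes])
    return FeatureMatrix(
        genes=genes,
        features=names,
        values=values,
        extractor_manifest=tuple(extractors),
        unannotated=unannotated,
    )


def train_profile_model(
    X: FeatureMatrix,
    seeds: set[str],
    negative_ratio: float = 10.0,
    reg: float = 1.0,
    rng_seed: int = 0,
    exclude_from_negatives: set[str] = frozenset(),
) -> ProfileModel:
    """Fit the L2 logistic profile classifier, seeds vs sampled non-seeds.

    Negatives are a seeded uniform sample of ``negative_ratio * |seeds|``
    non-seed genes (all non-seeds if fewer are available). Genes in
    *exclude_from_negatives* — e.g. held-out seeds during cross-validation,
    which must not touch the model that scores them — are kept out of the
    sampling pool. Deterministic given *rng_seed*. Requires at least 5
    seeds in the matrix universe.
    """
    seed_idx = [i for i, g in enumerate(X.genes) if g in seeds]
    if len(seed_idx) < 5:
        raise ValueError(f"need >= 5 seeds in the universe, got {len(seed_idx)}")
    non_seed_idx = np.array(
        [
            i
            for i, g in enumerate(X.genes)
            if g not in seeds and g not in exclude_from_negatives
        ]
    )
    rng = np.random.default_rng(rng_seed)
    n_neg = min(int(round(negative_ratio * len(seed_idx))), len(non_seed_idx))
    neg_idx = rng.choice(non_seed_idx, size=n_neg, replace=False)

    rows = np.concatenate([np.array(seed_idx), neg_idx])
    y = np.concatenate([np.ones(len(seed_idx)), np.zeros(n_neg)])
    clf = LogisticRegression(C=1.0 / reg, solver="lbfgs", max_iter=2000, tol=1e-8)
    clf.fit(X.values[rows], y)
    return ProfileModel(
        coefficients=clf.coef_[0].copy(),
        intercept=float(clf.intercept_[0]),
        features=list(X.features),
        extractor_manifest=X.extractor_manifest,
        regularization_strength=reg,
        training_manifest={"rng_seed": rng_seed, "n_seeds": len(seed_idx), "n_neg": n_neg},
    )


def score_profiles(model: ProfileModel, X: FeatureMatrix) -> dict[str, float]:
    """Posterior P(seed-like | profile) for every gene, strictly in (0, 1)."""
    if model.extractor_manifest != X.extractor_manifest or model.features != X.features:
        raise ValueError("feature manifest of model and matrix do not match")
    z = X.values @ model.coefficients + model.intercept
    p = 1.0 / (1.0 + np.exp(-z))
    p = np.clip(p, 1e-12, 1.0 - 1e-12)
    return dict(zip(X.genes, p.tolist()))


def write_scores_tsv(scores: dict[str, float]) -> str:
    lines = ["gene\tscore"]
    lines += [f"{g}\t{scores[g]:.10g}" for g in sorted(scores)]
    return "\n".join(lines) + "\n"
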