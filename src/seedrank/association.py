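"""Guilt-by-association: single-hop label transfer over the linkage network.

Each edge incident to a gene contributes, per GO branch, the FL-map
likelihood ratio of the cell matching that edge's evidence class and the
most specific stratum in which the two genes share an informative term
(falling back to the branch's least specific stratum when they share none).
Contributions combine under naive-Bayes independence: posterior odds =
prior odds x product of applied likelihood ratios. Seed neighbors
contribute lr^w; non-seed neighbors contribute damped negative evidence
lr^(-w*kappa), with edge weights capped at 1 as exponents.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .network import FLMap, LinkageNetwork, gene_cell_terms
from .ontology import AnnotationSet, InformativeTermSet

POSTERIOR_CLAMP = 1e-9


@dataclass(frozen=True)
class Contribution:
    neighbor: str
    evidence_class: str
    branch: str
    stratum: int
    lr_applied: float
    neighbor_is_seed: bool


@dataclass
class AssociationEvidence:
    gene: str
    contributions: list[Contribution]
    prior: float


def _select_stratum(
    cells_a: dict[tuple[str, int], frozenset[str]],
    cells_b: dict[tuple[str, int], frozenset[str]],
    branch: str,
    branch_strata: list[int],
) -> int:
    """Most specific stratum where the genes share a term, else the least
    specific stratum of the branch."""
    for s in branch_strata:  # ascending: 0 is most specific
        ta = cells_a.get((branch, s))
        if ta and not ta.isdisjoint(cells_b.get((branch, s), frozenset())):
            return s
    return branch_strata[-1]


def collect_evidence(
    gene: str,
    seeds: set[str],
    net: LinkageNetwork,
    flmap: FLMap,
    ann: AnnotationSet,
    terms: InformativeTermSet,
    kappa: float = 0.25,
    universe: set[str] | None = None,
) -> AssociationEvidence:
    """Gather per-edge, per-branch likelihood-ratio contributions for *gene*."""
    if universe is None:
        universe = net.nodes | ann.genes | set(seeds)
    if gene not in universe:
        raise ValueError(f"gene {gene} is not in the universe")
    prior = len(seeds & universe) / len(universe)
    gct = gene_cell_terms(ann, terms)
    contribs: list[Contribution] = []
    cells_g = gct.get(gene, {})
    strata_by_branch = {
        b: flmap.strata_of_branch(b) for b in flmap.branches if flmap.strata_of_branch(b)
    }
    for e in net.edges:
        if gene not in (e.a, e.b):
            continue
        nb = e.b if e.a == gene else e.a
        cells_n = gct.get(nb, {})
        w = min(e.weight, 1.0)
        is_seed = nb in seeds
        for branch, strata in strata_by_branch.items():
            s = _select_stratum(cells_g, cells_n, branch, strata)
            lr = flmap.cells[(branch, s, e.evidence_class)].lr_weight
            exponent = w if is_seed else -w * kappa
            contribs.append(
                Contribution(
                    neighbor=nb,
                    evidence_class=e.evidence_class,
                    branch=branch,
                    stratum=s,
                    lr_applied=lr**exponent,
                    neighbor_is_seed=is_seed,
                )
            )
    return AssociationEvidence(gene=gene, contributions=contribs, prior=prior)


def gba_posterior(ev: AssociationEvidence) -> float:
    """Naive-Bayes posterior from prior odds and the product of applied LRs."""
    if not 0.0 < ev.prior < 1.0:
        raise ValueError("prior must lie strictly in (0, 1)")
    log_odds = np.log(ev.prior) - np.log1p(-ev.prior)
    for c in ev.contributions:
        log_odds += np.log(c.lr_applied)
    post = 1.0 / (1.0 + np.exp(-log_odds))
    return float(np.clip(post, POSTERIOR_CLAMP, 1.0 - POSTERIOR_CLAMP))


def _edge_branch_table(
    net: LinkageNetwork,
    flmap: FLMap,
    ann: AnnotationSet,
    terms: InformativeTermSet,
    universe: list[str],
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Seed-independent directed contribution table.

    Returns (gene_idx, neighbor_idx, log_lr, capped_weight) arrays with one
    entry per (edge direction, branch); the FL cell an edge maps to does not
    depend on which genes are seeds, so this is computed once and reused
    across cross-validation folds.
    """
    idx = {g: i for i, g in enumerate(universe)}
    gct = gene_cell_terms(ann, terms)
    gi, ni, ll, ww = [], [], [], []
    strata_by_branch = {b: flmap.strata_of_branch(b) for b in flmap.branches}
    for e in net.edges:
        w = min(e.weight, 1.0)
        ca, cb = gct.get(e.a, {}), gct.get(e.b, {})
        for branch, strata in strata_by_branch.items():
            if not strata:
                continue
            s = _select_stratum(ca, cb, branch, strata)
            log_lr = float(np.log(flmap.cells[(branch, s, e.evidence_class)].lr_weight))
            for g, nb in ((e.a, e.b), (e.b, e.a)):
                gi.append(idx[g])
                ni.append(idx[nb])
                ll.append(log_lr)
                ww.append(w)
    return (
        np.array(gi, dtype=np.intp),
        np.array(ni, dtype=np.intp),
        np.array(ll),
        np.array(ww),
    )


def score_all_gba(
    seeds: set[str],
    net: LinkageNetwork,
    flmap: FLMap,
    ann: AnnotationSet,
    terms: InformativeTermSet,
    kappa: float = 0.25,
    universe: list[str] | None = None,
    _table: tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray] | None = None,
) -> dict[str, float]:
    """Guilt-by-association posterior for every universe gene.

    Genes without network edges score exactly the prior. ``_table`` lets
    callers reuse the seed-independent contribution table across folds.
    """
    if universe is None:
        universe = sorted(net.nodes | ann.genes | set(seeds))
    prior = len(set(seeds) & set(universe)) / len(universe)
    if not 0.0 < prior < 1.0:
        raise ValueError("prior must lie strictly in (0, 1); check the seed list")
    gi, ni, ll, ww = (
        _table
        if _table is not None
        else _edge_branch_table(net, flmap, ann, terms, universe)
    )
    idx = {g: i for i, g in enumerate(universe)}
    seed_mask = np.zeros(len(universe), dtype=bool)
    for s in seeds:
        if s in idx:
            seed_mask[idx[s]] = True
    log_odds = np.full(len(universe), np.log(prior) - np.log1p(-prior))
    if len(gi):
        signed = np.where(seed_mask[ni], ww, -ww * kappa) * ll
        np.add.at(log_odds, gi, signed)
    post = 1.0 / (1.0 + np.exp(-log_odds))
    post = np.clip(post, POSTERIOR_CLAMP, 1.0 - POSTERIOR_CLAMP)
    return dict(zip(universe, post.tolist()))


def write_evidence_tsv(evs: list[AssociationEvidence]) -> str:
    """Per-gene evidence audit table."""
    lines = ["gene\tneighbor\tclass\tbranch\tstratum\tlr_applied\tneighbor_is_seed"]
    for ev in evs:
        for c in ev.contributions:
            lines.append(
                f"{ev.gene}\t{c.neighbor}\t{c.evidence_class}\t{c.branch}"
                f"\t{c.stratum}\t{c.lr_applied:.10g}\t{int(c.neighbor_is_seed)}"
            )
    return "\n".join(lines) + "\n"
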