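"""Functional-linkage networks and FL-map estimation.

The FL (functional-linkage) map is the evidence model behind
guilt-by-association label transfer: for every cell — a GO branch crossed
with a term-specificity stratum and an edge evidence class — it estimates
the probability that two linked genes share an informative term of that
cell, Laplace-smoothed, together with the likelihood-ratio weight of that
cell relative to the background rate over random gene pairs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .ontology import AnnotationSet, InformativeTermSet

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class Edge:
    a: str
    b: str
    evidence_class: str
    weight: float = 1.0


@dataclass
class LinkageNetwork:
    """Undirected multigraph of genes with class-labelled, weighted edges.

    Edges are stored with endpoints in sorted order; at most one edge per
    (gene pair, evidence class). No self-loops.
    """

    nodes: set[str]
    edges: list[Edge]
    class_vocabulary: list[str]
    n_dropped_self_loops: int = 0

    def incident(self) -> dict[str, list[Edge]]:
        out: dict[str, list[Edge]] = {g: [] for g in self.nodes}
        for e in self.edges:
            out[e.a].append(e)
            out[e.b].append(e)
        return out

    def degree_by_class(self) -> dict[str, dict[str, int]]:
        out: dict[str, dict[str, int]] = {g: {} for g in self.nodes}
        for e in self.edges:
            for g in (e.a, e.b):
                out[g][e.evidence_class] = out[g].get(e.evidence_class, 0) + 1
        return out


@dataclass(frozen=True)
class FLCell:
    n_pairs: int
    n_shared: int
    p_shared: float
    p0: float
    lr_weight: float


@dataclass
class FLMap:
    """cells: (branch, stratum, evidence_class) -> FLCell; background p0 per (branch, stratum)."""

    cells: dict[tuple[str, int, str], FLCell]
    background: dict[tuple[str, int], float]
    pseudocount: float = 1.0
    branches: tuple[str, ...] = field(default_factory=tuple)

    def strata_of_branch(self, branch: str) -> list[int]:
        return sorted({s for (b, s, _c) in self.cells if b == branch})


def parse_network(table_text: str, class_vocabulary: list[str]) -> LinkageNetwork:
    """Parse a (gene_a, gene_b, class[, weight]) TSV edge list.

    Undirected: (a, b, c) and (b, a, c) collapse to one edge; duplicate
    (pair, class) rows keep the maximum weight. Self-loops are dropped and
    counted. Raises ``ValueError`` listing evidence classes outside
    *class_vocabulary*.
    """
    vocab = set(class_vocabulary)
    best: dict[tuple[str, str, str], float] = {}
    nodes: set[str] = set()
    self_loops = 0
    offenders: set[str] = set()
    for line in table_text.splitlines():
        if not line.strip() or line.startswith(("#", "!")):
            continue
        fields = line.rstrip("\n").split("\t")
        if fields[0] in ("gene_a", "gene1"):  # optional header
            continue
        if len(fields) < 3:
            raise ValueError(f"network row needs >= 3 columns: {line!r}")
        a, b, cls = fields[0], fields[1], fields[2]
        if cls not in vocab:
            offenders.add(cls)
            continue
        weight = float(fields[3]) if len(fields) > 3 and fields[3] else 1.0
        if a == b:
            self_loops += 1
            continue
        if a > b:
            a, b = b, a
        key = (a, b, cls)
        best[key] = max(best.get(key, 0.0), weight)
        nodes.update((a, b))
    if offenders:
        raise ValueError(
            "evidence classes outside vocabulary: " + ", ".join(sorted(offenders))
        )
    if self_loops:
        logger.info("parse_network: dropped %d self-loops", self_loops)
    edges = [Edge(a, b, c, w) for (a, b, c), w in sorted(best.items())]
    return LinkageNetwork(
        nodes=nodes,
        edges=edges,
        class_vocabulary=list(class_vocabulary),
        n_dropped_self_loops=self_loops,
    )


def write_network_tsv(net: LinkageNetwork) -> str:
    lines = ["gene_a\tgene_b\tclass\tweight"]
    lines += [f"{e.a}\t{e.b}\t{e.evidence_class}\t{e.weight:g}" for e in net.edges]
    return "\n".join(lines) + "\n"


def gene_cell_terms(
    ann: AnnotationSet, terms: InformativeTermSet
) -> dict[str, dict[tuple[str, int], frozenset[str]]]:
    """Per gene, its informative terms grouped by (branch, stratum) cell."""
    cell_of: dict[str, tuple[str, int]] = {
        t: (terms.branch[t], terms.stratum[t]) for t in terms.terms
    }
    out: dict[str, dict[tuple[str, int], frozenset[str]]] = {}
    for gene, ts in ann.assignments.items():
        cells: dict[tuple[str, int], set[str]] = {}
        for t in ts:
            c = cell_of.get(t)
            if c is not None:
                cells.setdefault(c, set()).add(t)
        out[gene] = {c: frozenset(v) for c, v in cells.items()}
    return out


def shared_function(
    gene_a: str,
    gene_b: str,
    ann: AnnotationSet,
    terms: InformativeTermSet,
    branch: str,
    stratum: int,
) -> bool:
    """True iff both genes share >= 1 informative term of (branch, stratum)."""
    cell_terms = {
        t
        for t in ann.terms_of(gene_a)
        if terms.branch.get(t) == branch and terms.stratum.get(t) == stratum
    }
    return not cell_terms.isdisjoint(ann.terms_of(gene_b))


def _odds(p: float) -> float:
    return p / (1.0 - p)


def build_fl_map(
    net: LinkageNetwork,
    ann: AnnotationSet,
    terms: InformativeTermSet,
    pseudocount: float = 1.0,
    pair_budget: int = 2_000_000,
    n_sample_pairs: int = 100_000,
    rng_seed: int = 0,
) -> FLMap:
    """Estimate the FL map from a network and closed annotations.

    For each (branch, stratum, class) cell, ``p_shared`` is the Laplace-
    smoothed fraction of that class's edges whose endpoints share an
    informative term of the cell. The background ``p0`` per (branch,
    stratum) is estimated identically over all unordered pairs of annotated
    genes — exactly when C(n, 2) <= *pair_budget*, otherwise from
    *n_sample_pairs* seeded uniform pairs. ``lr_weight`` is the odds ratio
    p_shared-odds / p0-odds. Requires ``pseudocount > 0`` and a non-empty
    network.
    """
    if not ann.closed:
        raise ValueError("FL map requires a closed AnnotationSet")
    if pseudocount <= 0:
        raise ValueError("pseudocount must be positive")
    if not net.edges:
        raise ValueError("cannot estimate an FL map from an empty network")

    gct = gene_cell_terms(ann, terms)
    all_cells = sorted(terms.cell_terms())
    branches = terms.branches

    # --- per-cell counts over edges, grouped by evidence class
    counts: dict[tuple[str, int, str], list[int]] = {
        (b, s, c): [0, 0] for (b, s) in all_cells for c in net.class_vocabulary
    }
    for e in net.edges:
        ca = gct.get(e.a, {})
        cb = gct.get(e.b, {})
        for b, s in all_cells:
            key = (b, s, e.evidence_class)
            counts[key][0] += 1
            ta = ca.get((b, s))
            if ta and not ta.isdisjoint(cb.get((b, s), frozenset())):
                counts[key][1] += 1

    # --- background sharing rate per (branch, stratum) over annotated genes
    genes = sorted(g for g in ann.assignments if ann.assignments[g])
    n = len(genes)
    background: dict[tuple[str, int], float] = {}
    if n < 2:
        for cell in all_cells:
            background[cell] = 0.5  # pure smoothing
    elif n * (n - 1) // 2 <= pair_budget:
        term_index = {t: i for i, t in enumerate(terms.terms)}
        cols: dict[tuple[str, int], list[int]] = {c: [] for c in all_cells}
        for t in terms.terms:
            cols[(terms.branch[t], terms.stratum[t])].append(term_index[t])
        member = np.zeros((n, len(terms.terms)), dtype=bool)
        for i, g in enumerate(genes):
            for cell, ts in gct.get(g, {}).items():
                for t in ts:
                    member[i, term_index[t]] = True
        n_pairs = n * (n - 1) // 2
        iu = np.triu_indices(n, k=1)
        for cell in all_cells:
            sub = member[:, cols[cell]]
            if sub.shape[1] == 0:
                shared = 0
            else:
                overlap = sub.astype(np.int32) @ sub.astype(np.int32).T
                shared = int(np.count_nonzero(overlap[iu]))
            background[cell] = (shared + pseudocount) / (n_pairs + 2 * pseudocount)
    else:
        rng = np.random.default_rng(rng_seed)
        ii = rng.integers(0, n, size=n_sample_pairs)
        jj = rng.integers(0, n - 1, size=n_sample_pairs)
        jj = np.where(jj >= ii, jj + 1, jj)  # uniform over off-diagonal pairs
        shared_ct = {c: 0 for c in all_cells}
        for i, j in zip(ii, jj):
            ca, cb = gct.get(genes[i], {}), gct.get(genes[j], {})
            for cell in all_cells:
                ta = ca.get(cell)
                if ta and not ta.isdisjoint(cb.get(cell, frozenset())):
                    shared_ct[cell] += 1
        for cell in all_cells:
            background[cell] = (shared_ct[cell] + pseudocount) / (
                n_sample_pairs + 2 * pseudocount
            )

    cells: dict[tuple[str, int, str], FLCell] = {}
    for (b, s, c), (n_pairs, n_shared) in counts.items():
        p = (n_shared + pseudocount) / (n_pairs + 2 * pseudocount)
        p0 = background[(b, s)]
        lr = _odds(p) / _odds(p0)
        cells[(b, s, c)] = FLCell(
            n_pairs=n_pairs, n_shared=n_shared, p_shared=p, p0=p0, lr_weight=lr
        )
    return FLMap(cells=cells, background=background, pseudocount=pseudocount, branches=branches)


def write_fl_map_tsv(flmap: FLMap) -> str:
    lines = ["branch\tstratum\tclass\tn_pairs\tn_shared\tp_shared\tp0\tlr_weight"]
    for (b, s, c), cell in sorted(flmap.cells.items()):
        lines.append(
            f"{b}\t{s}\t{c}\t{cell.n_pairs}\t{cell.n_shared}"
            f"\t{cell.p_shared:.10g}\t{cell.p0:.10g}\t{cell.lr_weight:.10g}"
        )
    return "\n".join(lines) + "\n"
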