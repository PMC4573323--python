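"""Ontology and annotation handling.

Parses OBO 1.2 ontologies and GAF/TSV gene annotations, propagates
annotations up the ``is_a`` DAG (true-path rule), and selects the
"informative" term set — terms whose annotated-gene count falls inside a
configurable window — stratified by specificity within each ontology branch
(namespace). These strata, crossed with network evidence classes, define
the cells of the functional-linkage map.
"""

from __future__ import annotations

import io
import logging
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import obonet

logger = logging.getLogger(__name__)

NAMESPACES = ("biological_process", "cellular_component", "molecular_function")


class OntologyStructureError(ValueError):
    """Raised for cyclic is_a relations or malformed term stanzas."""


class AnnotationConsistencyError(ValueError):
    """Raised when annotations reference terms absent from the ontology."""


@dataclass(frozen=True)
class Ontology:
    """A DAG of terms with one namespace per term and is_a parent links."""

    terms: frozenset[str]
    namespace: dict[str, str]
    parents: dict[str, frozenset[str]]

    def ancestors(self, term: str) -> frozenset[str]:
        """All is_a ancestors of *term* (excluding the term itself)."""
        seen: set[str] = set()
        stack = list(self.parents.get(term, ()))
        while stack:
            t = stack.pop()
            if t not in seen:
                seen.add(t)
                stack.extend(self.parents.get(t, ()))
        return frozenset(seen)

    def roots(self) -> frozenset[str]:
        return frozenset(t for t in self.terms if not self.parents.get(t))


@dataclass
class AnnotationSet:
    """gene -> set of term IDs; ``closed`` is True once ancestor-propagated."""

    assignments: dict[str, set[str]]
    closed: bool = False
    n_dropped: int = 0

    @property
    def genes(self) -> set[str]:
        return set(self.assignments)

    def terms_of(self, gene: str) -> set[str]:
        return self.assignments.get(gene, set())


@dataclass
class InformativeTermSet:
    """Informative terms ordered by (stratum, term ID), with branch labels.

    Stratum 0 is the most specific stratum (fewest annotated genes) within
    its branch; strata are assigned by annotation-count quantile per branch.
    """

    terms: list[str]
    stratum: dict[str, int]
    branch: dict[str, str]
    gene_count: dict[str, int]
    bounds: tuple[int, int]
    n_strata: int
    branches: tuple[str, ...] = field(default=NAMESPACES)

    def cell_terms(self) -> dict[tuple[str, int], frozenset[str]]:
        """(branch, stratum) -> term set for that FL-map cell."""
        cells: dict[tuple[str, int], set[str]] = {}
        for t in self.terms:
            cells.setdefault((self.branch[t], self.stratum[t]), set()).add(t)
        return {k: frozenset(v) for k, v in cells.items()}

    def strata_of_branch(self, branch: str) -> list[int]:
        """Sorted stratum indices present in *branch* (may be empty)."""
        return sorted({self.stratum[t] for t in self.terms if self.branch[t] == branch})


def parse_ontology(obo_text: str) -> Ontology:
    """Parse OBO 1.2 text into an :class:`Ontology`.

    Only ``is_a`` edges are honored; obsolete terms are skipped. Raises
    :class:`OntologyStructureError` on an is_a cycle (naming a member) or a
    term without a namespace.
    """
    graph = obonet.read_obo(io.StringIO(obo_text), ignore_obsolete=True)
    namespace: dict[str, str] = {}
    parents: dict[str, frozenset[str]] = {}
    isa = nx.DiGraph()
    for term, attrs in graph.nodes(data=True):
        ns = attrs.get("namespace")
        if ns is None:
            raise OntologyStructureError(f"term {term} has no namespace")
        namespace[term] = ns
        isa.add_node(term)
    for child, parent, key in graph.edges(keys=True):
        if key == "is_a" and parent in namespace:
            isa.add_edge(child, parent)
    if not nx.is_directed_acyclic_graph(isa):
        cycle = nx.find_cycle(isa)
        raise OntologyStructureError(f"is_a cycle involving term {cycle[0][0]}")
    for term in namespace:
        parents[term] = frozenset(isa.successors(term))
    return Ontology(terms=frozenset(namespace), namespace=namespace, parents=parents)


def _split_annotation_row(line: str) -> tuple[str, str] | None:
    fields = line.rstrip("\n").split("\t")
    if len(fields) >= 5:  # GAF 2.x: DB, DB Object ID, Symbol, Qualifier, GO ID
        return fields[1], fields[4]
    if len(fields) >= 2:
        return fields[0], fields[1]
    return None


def parse_annotations(table_text: str, ontology: Ontology) -> AnnotationSet:
    """Parse GAF 2.x or two-column (gene, term) TSV annotations.

    Lines starting with ``!`` are comments. Rows citing terms missing from
    *ontology* are dropped and counted. Raises ``ValueError`` if nothing
    survives filtering.
    """
    assignments: dict[str, set[str]] = {}
    dropped = 0
    for line in table_text.splitlines():
        if not line.strip() or line.startswith("!"):
            continue
        row = _split_annotation_row(line)
        if row is None:
            continue
        gene, term = row
        if term not in ontology.terms:
            dropped += 1
            continue
        assignments.setdefault(gene, set()).add(term)
    if dropped:
        logger.info("parse_annotations: dropped %d rows with unknown terms", dropped)
    if not assignments:
        raise ValueError("no usable annotation rows after filtering")
    return AnnotationSet(assignments=assignments, closed=False, n_dropped=dropped)


def propagate_annotations(ann: AnnotationSet, ontology: Ontology) -> AnnotationSet:
    """Close an annotation set under the true-path rule.

    Each gene's term set becomes the union of its direct terms and all their
    is_a ancestors. Idempotent. Raises :class:`AnnotationConsistencyError`
    if any annotated term is absent from *ontology*.
    """
    closure_cache: dict[str, frozenset[str]] = {}

    def closure(term: str) -> frozenset[str]:
        if term not in closure_cache:
            closure_cache[term] = ontology.ancestors(term) | {term}
        return closure_cache[term]

    assignments: dict[str, set[str]] = {}
    for gene, terms in ann.assignments.items():
        out: set[str] = set()
        for t in terms:
            if t not in ontology.terms:
                raise AnnotationConsistencyError(
                    f"gene {gene} annotated to unknown term {t}"
                )
            out |= closure(t)
        assignments[gene] = out
    return AnnotationSet(assignments=assignments, closed=True, n_dropped=ann.n_dropped)


def select_informative_terms(
    ann: AnnotationSet,
    ontology: Ontology,
    bounds: tuple[int, int] = (2, 500),
    n_strata: int = 4,
) -> InformativeTermSet:
    """Select terms annotating between ``bounds`` genes and stratify them.

    Requires a closed (propagated) annotation set and ``min_genes >= 2``.
    Within each branch, kept terms are binned into ``n_strata`` specificity
    strata by annotation-count quantile; stratum 0 holds the most specific
    (lowest-count) terms. When all counts in a branch are equal every term
    lands in stratum 0. Raises ``ValueError`` if no term survives.
    """
    if not ann.closed:
        raise ValueError("informative-term selection requires a closed AnnotationSet")
    min_genes, max_genes = bounds
    if min_genes < 2:
        raise ValueError("min_genes must be >= 2")

    counts: dict[str, int] = {}
    for terms in ann.assignments.values():
        for t in terms:
            counts[t] = counts.get(t, 0) + 1

    kept = {t: c for t, c in counts.items() if min_genes <= c <= max_genes}
    if not kept:
        raise ValueError(
            f"no term annotates between {min_genes} and {max_genes} genes; "
            "widen the bounds"
        )

    stratum: dict[str, int] = {}
    branch: dict[str, str] = {}
    for ns in sorted({ontology.namespace[t] for t in kept}):
        ts = sorted(t for t in kept if ontology.namespace[t] == ns)
        vals = np.array([kept[t] for t in ts], dtype=float)
        # interior quantile edges; searchsorted-left puts equal counts in stratum 0
        edges = np.quantile(vals, [i / n_strata for i in range(1, n_strata)])
        strata = np.searchsorted(edges, vals, side="left")
        for t, s in zip(ts, strata):
            stratum[t] = int(s)
            branch[t] = ns

    ordered = sorted(kept, key=lambda t: (stratum[t], t))
    return InformativeTermSet(
        terms=ordered,
        stratum=stratum,
        branch=branch,
        gene_count={t: kept[t] for t in ordered},
        bounds=bounds,
        n_strata=n_strata,
        branches=tuple(ns for ns in NAMESPACES if any(branch[t] == ns for t in ordered)),
    )


def write_annotations_tsv(ann: AnnotationSet) -> str:
    """Serialize an annotation set as sorted two-column (gene, term) TSV."""
    lines = [
        f"{gene}\t{term}"
        for gene in sorted(ann.assignments)
        for term in sorted(ann.assignments[gene])
    ]
    return "\n".join(lines) + "\n"


def write_informative_terms_tsv(terms: InformativeTermSet) -> str:
    """Serialize informative terms as (term, stratum, gene_count) TSV."""
    lines = ["term\tstratum\tgene_count"]
    lines += [
        f"{t}\t{terms.stratum[t]}\t{terms.gene_count[t]}" for t in terms.terms
    ]
    return "\n".join(lines) + "\n"
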