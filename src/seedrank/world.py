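"""The analysis world: parsed, propagated, ready-to-score inputs."""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

from .network import LinkageNetwork, parse_network
from .ontology import (
    AnnotationSet,
    InformativeTermSet,
    Ontology,
    parse_annotations,
    propagate_annotations,
    select_informative_terms,
    parse_ontology,
)


@dataclass
class World:
    """Everything the scoring pipeline needs, with annotations closed."""

    ontology: Ontology
    annotations: AnnotationSet  # closed
    terms: InformativeTermSet
    network: LinkageNetwork
    seeds: set[str]
    universe: list[str]  # sorted gene IDs


def build_world(
    ontology: Ontology,
    raw_annotations: AnnotationSet,
    network: LinkageNetwork,
    seeds: set[str],
    bounds: tuple[int, int] = (2, 500),
    n_strata: int = 4,
    universe: list[str] | None = None,
) -> World:
    """Propagate annotations, select informative terms, fix the universe."""
    ann = (
        raw_annotations
        if raw_annotations.closed
        else propagate_annotations(raw_annotations, ontology)
    )
    if any(ann.assignments.values()):
        terms = select_informative_terms(ann, ontology, bounds=bounds, n_strata=n_strata)
    else:
        # fully unannotated world: no functional vocabulary, association
        # scoring degenerates to the prior and profiling to topology features
        terms = InformativeTermSet(
            terms=[], stratum={}, branch={}, gene_count={},
            bounds=bounds, n_strata=n_strata, branches=(),
        )
    if universe is None:
        universe = sorted(network.nodes | ann.genes | seeds)
    missing = seeds - set(universe)
    if missing:
        raise ValueError(f"seed genes outside the universe: {sorted(missing)[:5]}")
    return World(
        ontology=ontology,
        annotations=ann,
        terms=terms,
        network=network,
        seeds=set(seeds),
        universe=universe,
    )


def load_world(
    obo_path: str | Path,
    annotations_path: str | Path,
    network_path: str | Path,
    seeds_path: str | Path,
    class_vocabulary: list[str],
    bounds: tuple[int, int] = (2, 500),
    n_strata: int = 4,
) -> World:
    """Load a world from the on-disk formats the pipeline reads."""
    ontology = parse_ontology(Path(obo_path).read_text())
    raw = parse_annotations(Path(annotations_path).read_text(), ontology)
    net = parse_network(Path(network_path).read_text(), class_vocabulary)
    seeds = {
        line.strip()
        for line in Path(seeds_path).read_text().splitlines()
        if line.strip() and not line.startswith("#")
    }
    return build_world(ontology, raw, net, seeds, bounds=bounds, n_strata=n_strata)
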