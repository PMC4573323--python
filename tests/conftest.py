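"""Shared fixtures: hand-built toy worlds and small synthetic configurations."""

from __future__ import annotations

import pytest

from seedrank import (
    WorldConfig,
    parse_annotations,
    parse_network,
    parse_ontology,
    propagate_annotations,
    select_informative_terms,
)

TOY_OBO = """format-version: 1.2
ontology: toy

[Term]
id: T:0001
name: bp root
namespace: biological_process

[Term]
id: T:0002
name: bp a
namespace: biological_process
is_a: T:0001

[Term]
id: T:0003
name: bp b
namespace: biological_process
is_a: T:0001

[Term]
id: T:0101
name: cc root
namespace: cellular_component

[Term]
id: T:0102
name: cc a
namespace: cellular_component
is_a: T:0101

[Term]
id: T:0201
name: mf root
namespace: molecular_function

[Term]
id: T:0202
name: mf a
namespace: molecular_function
is_a: T:0201
"""

# six genes; informative (bounds (2, 4)): T:0002, T:0003, T:0102, T:0202
TOY_ANNOTATIONS = "\n".join(
    [
        "g1\tT:0002",
        "g1\tT:0102",
        "g1\tT:0202",
        "g2\tT:0002",
        "g2\tT:0102",
        "g3\tT:0003",
        "g3\tT:0202",
        "g4\tT:0003",
        "g5\tT:0002",
        "g6\tT:0003",
    ]
)

TOY_NETWORK = "\n".join(
    [
        "g1\tg2\tc1\t1.0",  # share T:0002 and T:0102
        "g3\tg4\tc1\t1.0",  # share T:0003
        "g1\tg3\tc1\t1.0",  # share T:0202 only
        "g5\tg6\tc2\t0.8",  # share nothing informative per-branch except bp? g5 T:0002, g6 T:0003 -> no
    ]
)


@pytest.fixture(scope="session")
def toy_ontology():
    return parse_ontology(TOY_OBO)


@pytest.fixture(scope="session")
def toy_world(toy_ontology):
    """Hand-built six-gene world with one informative stratum per branch."""
    raw = parse_annotations(TOY_ANNOTATIONS, toy_ontology)
    ann = propagate_annotations(raw, toy_ontology)
    terms = select_informative_terms(ann, toy_ontology, bounds=(2, 4), n_strata=1)
    net = parse_network(TOY_NETWORK, ["c1", "c2"])
    return {"ontology": toy_ontology, "ann": ann, "terms": terms, "net": net}


def small_config(seed: int = 0, **overrides) -> WorldConfig:
    """A scaled-down planted-module world for fast module-level tests."""
    base = dict(
        n_genes=300,
        n_terms_per_branch=60,
        dag_depth=4,
        n_classes=4,
        n_seeds=30,
        n_hidden_positives=15,
        enrichment_fold=8.0,
        module_edge_prob=0.15,
        background_edge_prob=0.02,
        annotation_rate=6,
        n_module_terms=12,
        rng_seed=seed,
    )
    base.update(overrides)
    return WorldConfig(**base)


def tiny_config(seed: int = 0, **overrides) -> WorldConfig:
    """A <= 8-gene toy world for exhaustive oracle sweeps."""
    base = dict(
        n_genes=8,
        n_terms_per_branch=6,
        dag_depth=3,
        n_classes=2,
        n_seeds=3,
        n_hidden_positives=2,
        enrichment_fold=4.0,
        module_edge_prob=0.5,
        background_edge_prob=0.2,
        annotation_rate=3,
        n_module_terms=4,
        rng_seed=seed,
    )
    base.update(overrides)
    return WorldConfig(**base)
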