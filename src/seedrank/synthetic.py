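"""Synthetic benchmark worlds with a planted disease module.

Generates complete, self-consistent inputs — a three-branch ontology DAG,
gene annotations concentrated on "module" terms for module genes, a
stochastic-block-style linkage network with elevated within-module density,
a seed list, and hidden true positives — so the whole prioritization
pipeline can be exercised and calibrated without any external downloads.
Defaults mirror the study conditions the pipeline targets: 77 seed genes
and 6 edge evidence classes.

A world is produced from a single NumPy generator seeded once; draws occur
in a fixed order (ontology per branch, module terms, annotations, network,
module gene selection), so a seed fully determines every output byte.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .network import Edge, LinkageNetwork
from .ontology import NAMESPACES, AnnotationSet, Ontology
from .world import World, build_world


@dataclass
class WorldConfig:
    n_genes: int = 1000
    n_terms_per_branch: int = 120
    dag_depth: int = 5
    n_classes: int = 6
    n_seeds: int = 77
    n_hidden_positives: int = 30
    enrichment_fold: float = 8.0
    module_edge_prob: float = 0.15
    background_edge_prob: float = 0.01
    annotation_rate: int = 6
    n_module_terms: int = 20
    rng_seed: int = 0

    def __post_init__(self):
        if self.n_seeds + self.n_hidden_positives > self.n_genes:
            raise ValueError("module size exceeds the gene universe")
        if self.module_edge_prob < self.background_edge_prob:
            raise ValueError("module_edge_prob must be >= background_edge_prob")
        for p in (self.module_edge_prob, self.background_edge_prob):
            if not 0.0 < p < 1.0:
                raise ValueError("edge probabilities must lie in (0, 1)")
        if self.dag_depth < 2:
            raise ValueError("dag_depth must be >= 2")

    @property
    def class_vocabulary(self) -> list[str]:
        return [f"class_{i}" for i in range(self.n_classes)]


@dataclass
class WorldTruth:
    seeds: list[str]
    hidden_positives: list[str]
    module_terms: list[str]
    manifest: dict = field(default_factory=dict)


def default_world_config(seed: int) -> WorldConfig:
    """The reference benchmark condition: a 1,000-gene universe, 77 seeds,
    30 hidden positives, 8x annotation enrichment on 20 module terms, and
    module/background edge densities 0.15/0.01."""
    return WorldConfig(rng_seed=seed)


def synergy_world_config(seed: int) -> WorldConfig:
    """Benchmark condition for channel-fusion synergy.

    Annotation enrichment (4x) and module wiring (0.04 vs 0.01) are planted
    independently and kept moderate so that neither channel saturates; at
    the reference condition both channels sit near AUC 1 and a fused score
    has no headroom to measurably improve on the better one.
    """
    return WorldConfig(rng_seed=seed, enrichment_fold=4.0, module_edge_prob=0.04)


def null_world_config(seed: int) -> WorldConfig:
    """Signal-free calibration condition: no annotation enrichment and equal
    module/background edge densities."""
    return WorldConfig(
        rng_seed=seed,
        enrichment_fold=1.0,
        module_edge_prob=0.01,
        background_edge_prob=0.01,
    )


def _gene_ids(cfg: WorldConfig) -> list[str]:
    width = len(str(cfg.n_genes))
    return [f"G{i:0{width}d}" for i in range(1, cfg.n_genes + 1)]


def synthesize_ontology(
    cfg: WorldConfig, rng: np.random.Generator | None = None
) -> tuple[Ontology, dict[str, int]]:
    """Rooted random DAG per branch; each non-root term gets 1-2 parents
    from strictly shallower layers. Returns the ontology and a term->layer
    map (used to place module terms at informative mid-depths)."""
    rng = rng if rng is not None else np.random.default_rng(cfg.rng_seed)
    namespace: dict[str, str] = {}
    parents: dict[str, frozenset[str]] = {}
    layer_of: dict[str, int] = {}
    tid = 0
    for ns in NAMESPACES:
        n = cfg.n_terms_per_branch
        depth = cfg.dag_depth
        layers: list[list[str]] = [[] for _ in range(depth)]
        terms = []
        for j in range(n):
            tid += 1
            terms.append(f"SYN:{tid:07d}")
        layers[0].append(terms[0])  # branch root
        for j, t in enumerate(terms[1:], start=1):
            layers[1 + (j - 1) % (depth - 1)].append(t)
        namespace[terms[0]] = ns
        parents[terms[0]] = frozenset()
        layer_of[terms[0]] = 0
        for d in range(1, depth):
            shallower = [t for lay in layers[:d] for t in lay]
            for t in layers[d]:
                namespace[t] = ns
                layer_of[t] = d
                k = int(rng.integers(1, 3))  # 1 or 2 parents
                k = min(k, len(shallower))
                idx = rng.choice(len(shallower), size=k, replace=False)
                parents[t] = frozenset(shallower[i] for i in idx)
    ontology = Ontology(
        terms=frozenset(namespace), namespace=namespace, parents=parents
    )
    return ontology, layer_of


def _draw_module_terms(
    cfg: WorldConfig,
    ontology: Ontology,
    layer_of: dict[str, int],
    rng: np.random.Generator,
) -> list[str]:
    """Module terms live at mid-depth layers so the planted signal sits in
    informative strata rather than near-root terms."""
    mid = {cfg.dag_depth // 2, min(cfg.dag_depth - 1, cfg.dag_depth // 2 + 1)}
    pool = sorted(t for t in ontology.terms if layer_of[t] in mid)
    k = min(cfg.n_module_terms, len(pool))
    idx = rng.choice(len(pool), size=k, replace=False)
    return sorted(pool[i] for i in idx)


def synthesize_annotations(
    cfg: WorldConfig,
    ontology: Ontology,
    truth: WorldTruth,
    rng: np.random.Generator | None = None,
) -> AnnotationSet:
    """Direct (unpropagated) annotations: every gene draws
    ``annotation_rate`` distinct non-root terms; module genes (seeds plus
    hidden positives) draw with module terms upweighted ``enrichment_fold``.
    """
    rng = rng if rng is not None else np.random.default_rng(cfg.rng_seed)
    genes = _gene_ids(cfg)
    pool = sorted(t for t in ontology.terms if ontology.parents[t])
    module_mask = np.array([t in set(truth.module_terms) for t in pool], dtype=float)
    w_bg = np.ones(len(pool))
    w_mod = np.ones(len(pool)) + (cfg.enrichment_fold - 1.0) * module_mask
    module_genes = set(truth.seeds) | set(truth.hidden_positives)
    assignments: dict[str, set[str]] = {}
    rate = min(cfg.annotation_rate, len(pool))
    for g in genes:
        if rate == 0:
            continue
        w = w_mod if g in module_genes else w_bg
        p = w / w.sum()
        idx = rng.choice(len(pool), size=rate, replace=False, p=p)
        assignments[g] = {pool[i] for i in idx}
    return AnnotationSet(assignments=assignments, closed=False)


def synthesize_network(
    cfg: WorldConfig,
    truth: WorldTruth,
    rng: np.random.Generator | None = None,
) -> LinkageNetwork:
    """Stochastic-block network: within-module pairs wired with
    ``module_edge_prob``, all other pairs with ``background_edge_prob``;
    classes uniform over the vocabulary, weights uniform on (0.5, 1]."""
    rng = rng if rng is not None else np.random.default_rng(cfg.rng_seed)
    genes = _gene_ids(cfg)
    module = set(truth.seeds) | set(truth.hidden_positives)
    in_module = np.array([g in module for g in genes])
    n = len(genes)
    ii, jj = np.triu_indices(n, k=1)
    p = np.where(
        in_module[ii] & in_module[jj], cfg.module_edge_prob, cfg.background_edge_prob
    )
    keep = rng.random(len(p)) < p
    ii, jj = ii[keep], jj[keep]
    classes = rng.integers(0, cfg.n_classes, size=len(ii))
    weights = 1.0 - rng.random(len(ii)) * 0.5  # uniform (0.5, 1]
    vocab = cfg.class_vocabulary
    edges = [
        Edge(genes[a], genes[b], vocab[c], float(w))
        for a, b, c, w in zip(ii, jj, classes, weights)
    ]
    return LinkageNetwork(
        nodes=set(genes), edges=edges, class_vocabulary=vocab
    )


def _generate_raw(
    cfg: WorldConfig,
) -> tuple[Ontology, AnnotationSet, LinkageNetwork, WorldTruth]:
    """One world from one RNG stream; draw order is fixed and documented:
    ontology (per branch), module gene permutation, module terms,
    annotations, network."""
    rng = np.random.default_rng(cfg.rng_seed)
    ontology, layer_of = synthesize_ontology(cfg, rng)
    genes = _gene_ids(cfg)
    perm = rng.permutation(len(genes))
    seeds = sorted(genes[i] for i in perm[: cfg.n_seeds])
    hidden = sorted(
        genes[i] for i in perm[cfg.n_seeds : cfg.n_seeds + cfg.n_hidden_positives]
    )
    truth = WorldTruth(
        seeds=seeds, hidden_positives=hidden, module_terms=[], manifest=asdict(cfg)
    )
    truth.module_terms = _draw_module_terms(cfg, ontology, layer_of, rng)
    ann = synthesize_annotations(cfg, ontology, truth, rng)
    net = synthesize_network(cfg, truth, rng)
    return ontology, ann, net, truth


def synthesize_world(
    cfg: WorldConfig, bounds: tuple[int, int] = (2, 500), n_strata: int = 4
) -> tuple[World, WorldTruth]:
    """Generate a complete in-memory world plus its ground truth."""
    ontology, ann, net, truth = _generate_raw(cfg)
    genes = _gene_ids(cfg)
    seeds = truth.seeds
    world = build_world(
        ontology,
        ann,
        net,
        set(seeds),
        bounds=bounds,
        n_strata=n_strata,
        universe=list(genes),
    )
    return world, truth


def write_obo(ontology: Ontology) -> str:
    """Serialize an ontology as minimal OBO 1.2 (deterministic order)."""
    lines = ["format-version: 1.2", "ontology: synthetic", ""]
    for t in sorted(ontology.terms):
        lines += [f"[Term]", f"id: {t}", f"name: {t}",
                  f"namespace: {ontology.namespace[t]}"]
        for p in sorted(ontology.parents[t]):
            lines.append(f"is_a: {p}")
        lines.append("")
    return "\n".join(lines)


def make_world(cfg: WorldConfig, out_dir: str | Path, force: bool = False) -> dict:
    """Write a full fixture bundle; byte-identical under a fixed seed.

    Files: ``world.obo``, ``annotations.tsv`` (direct two-column),
    ``network.tsv``, ``seeds.txt``, ``truth.yaml``. Refuses a non-empty
    directory unless *force* is set. Returns the path map.
    """
    from .network import write_network_tsv
    from .ontology import write_annotations_tsv

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    if any(out.iterdir()) and not force:
        raise FileExistsError(f"{out} is not empty; pass force=True to overwrite")

    ontology, ann, net, truth = _generate_raw(cfg)
    seeds, hidden = truth.seeds, truth.hidden_positives

    paths = {
        "obo": out / "world.obo",
        "annotations": out / "annotations.tsv",
        "network": out / "network.tsv",
        "seeds": out / "seeds.txt",
        "truth": out / "truth.yaml",
    }
    paths["obo"].write_text(write_obo(ontology))
    paths["annotations"].write_text(write_annotations_tsv(ann))
    paths["network"].write_text(write_network_tsv(net))
    paths["seeds"].write_text("\n".join(seeds) + "\n")
    paths["truth"].write_text(
        yaml.safe_dump(
            {
                "seeds": seeds,
                "hidden_positives": hidden,
                "module_terms": truth.module_terms,
                "manifest": truth.manifest,
            },
            sort_keys=True,
        )
    )
    return {k: str(v) for k, v in paths.items()}


def make_candidate_attributes(
    candidates: list[str],
    n_pass: int,
    rank_cutoff: int | None = None,
) -> pd.DataFrame:
    """Synthetic candidate-attribute table for triage testing.

    The first *n_pass* candidates satisfy all five selection criteria; the
    remainder each fail at least one criterion (which one rotates
    deterministically, including an explicit ``unknown``).
    """
    if rank_cutoff is None:
        rank_cutoff = len(candidates)
    rows = []
    for i, g in enumerate(candidates):
        row = {
            "gene": g,
            "rank_position": i + 1,
            "family_member_known_gene": "true",
            "expression_sites": "cochlea;epithelium",
            "whole_animal_study": "true",
            "auditory_development_link": "true",
        }
        if i >= n_pass:
            failure = (i - n_pass) % 5
            if failure == 0:
                row["rank_position"] = rank_cutoff + 1000 + i
            elif failure == 1:
                row["family_member_known_gene"] = "false"
            elif failure == 2:
                row["expression_sites"] = "liver"
            elif failure == 3:
                row["whole_animal_study"] = "unknown"
            else:
                row["auditory_development_link"] = "false"
        rows.append(row)
    return pd.DataFrame(rows)
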