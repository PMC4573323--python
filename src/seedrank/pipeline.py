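"""End-to-end prioritization runs: cross-validate, fuse, rank, evaluate."""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from .ranking import (
    CombinerModel,
    CrossvalResult,
    combine_scores,
    crossval_scores,
    evaluate,
    fit_combiner,
    rank_candidates,
    shortlist,
)
from .world import World


@dataclass
class PipelineResult:
    table: pd.DataFrame  # gene-indexed: channel scores, combined, rank, fold
    combiner: CombinerModel
    crossval: CrossvalResult
    shortlisted: list[str]
    metrics: dict = field(default_factory=dict)


def run_pipeline(
    world: World,
    k: int = 5,
    rng_seed: int = 0,
    kappa: float = 0.25,
    shortlist_n: int = 300,
    negative_ratio: float = 10.0,
    reg: float = 1.0,
    positives: set[str] | None = None,
    recall_ks: list[int] = (100,),
) -> PipelineResult:
    """Cross-validated channel scores -> logistic fusion -> ranked candidates.

    If *positives* (e.g. the hidden true positives of a synthetic world) is
    given, out-of-fold AUC and recall@k over non-seed genes are added to
    ``metrics`` for the combined and each channel score.
    """
    cv = crossval_scores(
        world, k=k, rng_seed=rng_seed, kappa=kappa,
        negative_ratio=negative_ratio, reg=reg,
    )
    combiner = fit_combiner(cv.table, rng_seed=rng_seed, negative_ratio=negative_ratio)
    table = combine_scores(cv.table, combiner)
    table = rank_candidates(table)
    top = shortlist(table, n=shortlist_n)

    metrics: dict = {}
    if positives:
        for channel in ("combined", "gbp_score", "gba_score"):
            metrics[channel] = evaluate(
                table[channel], positives, ks=recall_ks, exclude=world.seeds
            )
    return PipelineResult(
        table=table, combiner=combiner, crossval=cv, shortlisted=top, metrics=metrics
    )


def write_score_table_tsv(table: pd.DataFrame) -> str:
    out = table.copy()
    out.index.name = "gene"
    return out.to_csv(sep="\t", float_format="%.10g")
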