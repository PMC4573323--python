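"""Cross-validation bookkeeping, logistic fusion, ranking and triage."""

import itertools

import numpy as np
import pandas as pd
import pytest

from seedrank import (
    apply_selection_criteria,
    combine_scores,
    crossval_scores,
    evaluate,
    fit_combiner,
    rank_candidates,
    shortlist,
    synthesize_world,
)
from seedrank.synthetic import make_candidate_attributes

from conftest import small_config


def _score_table(gbp, gba, is_seed):
    genes = [f"g{i:03d}" for i in range(len(gbp))]
    return pd.DataFrame(
        {"gbp_score": gbp, "gba_score": gba, "is_seed": is_seed,
         "fold": [-1] * len(gbp)},
        index=pd.Index(genes, name="gene"),
    )


@pytest.fixture(scope="module")
def small_world():
    return synthesize_world(small_config(0))


def test_no_seed_is_scored_by_a_model_that_saw_it(small_world):
    world, _ = small_world
    cv = crossval_scores(world, k=2, rng_seed=0)
    held = [set(m["held_out"]) for m in cv.fold_manifest.values()]
    trained = [set(m["trained_on"]) for m in cv.fold_manifest.values()]
    # every seed held out exactly once, and never in its own training set
    assert set.union(*held) == world.seeds
    assert sum(len(h) for h in held) == len(world.seeds)
    for h, t in zip(held, trained):
        assert h & t == set()
        assert h | t == world.seeds
    # fold column agrees with the manifest
    for f, m in cv.fold_manifest.items():
        for s in m["held_out"]:
            assert cv.table.loc[s, "fold"] == f


def test_crossval_is_deterministic_under_a_fixed_seed(small_world):
    world, _ = small_world
    a = crossval_scores(world, k=5, rng_seed=11)
    b = crossval_scores(world, k=5, rng_seed=11)
    pd.testing.assert_frame_equal(a.table, b.table)
    assert a.fold_manifest == b.fold_manifest

    with pytest.raises(ValueError, match="exceeds"):
        crossval_scores(world, k=len(world.seeds) + 1)


def test_constant_channel_coefficient_is_shrunk():
    rng = np.random.default_rng(0)
    n = 400
    is_seed = np.zeros(n, dtype=bool)
    is_seed[:40] = True
    gbp = np.clip(rng.random(n) + 0.3 * is_seed, 0.01, 0.99)
    table = _score_table(gbp, np.full(n, 0.5), is_seed)
    model = fit_combiner(table, rng_seed=0)
    assert abs(model.beta_gba) < 0.1
    assert model.warnings  # degenerate channel logged


def test_identical_channels_reproduce_single_channel_ranking():
    rng = np.random.default_rng(1)
    n = 200
    is_seed = np.zeros(n, dtype=bool)
    is_seed[:20] = True
    p = np.clip(rng.random(n) + 0.4 * is_seed, 0.01, 0.99)
    table = _score_table(p, p, is_seed)
    model = fit_combiner(table, rng_seed=0)
    ranked = rank_candidates(combine_scores(table, model))
    cand = table[~table["is_seed"]]
    oracle = sorted(cand.index, key=lambda g: (-cand.loc[g, "gbp_score"], g))
    got = ranked[ranked["rank"].notna()].sort_values("rank").index.tolist()
    assert got == oracle


def test_combiner_synergy_on_independent_channels():
    """Fused out-of-fold score should not trail the best single channel."""
    rng = np.random.default_rng(7)
    gains = []
    for _ in range(20):
        n = 600
        is_seed = np.zeros(n, dtype=bool)
        is_seed[:60] = True
        # two independently informative noisy channels
        z1 = rng.normal(size=n) + 1.2 * is_seed
        z2 = rng.normal(size=n) + 1.2 * is_seed
        expit = lambda z: 1 / (1 + np.exp(-z))
        table = _score_table(expit(z1), expit(z2), is_seed)
        model = fit_combiner(table, rng_seed=0)
        table = combine_scores(table, model)
        pos = set(table.index[is_seed])
        aucs = {
            ch: evaluate(table[ch], pos)["auc"]
            for ch in ("gbp_score", "gba_score", "combined")
        }
        gains.append(aucs["combined"] - max(aucs["gbp_score"], aucs["gba_score"]))
    assert float(np.mean(gains)) >= -0.01
    assert sum(g > 0 for g in gains) >= 14


def test_tie_break_is_lexicographic_and_seeds_are_unranked():
    table = _score_table([0.9, 0.2, 0.9, 0.4], [0.5] * 4,
                         [False, False, False, True])
    table["combined"] = [0.7, 0.1, 0.7, 0.99]
    ranked = rank_candidates(table)
    assert ranked.loc["g000", "rank"] == 1  # tied with g002, smaller ID first
    assert ranked.loc["g002", "rank"] == 2
    assert pd.isna(ranked.loc["g003", "rank"])
    ranks = ranked["rank"].dropna().tolist()
    assert sorted(ranks) == [1, 2, 3]


def test_ranking_matches_stable_sort_oracle_on_1000_genes():
    rng = np.random.default_rng(2)
    n = 1000
    is_seed = rng.random(n) < 0.05
    table = _score_table(rng.random(n), rng.random(n), is_seed)
    # coarse grid of scores forces plenty of ties
    table["combined"] = rng.integers(0, 10, size=n) / 10.0
    ranked = rank_candidates(table)
    cand = table[~table["is_seed"]]
    oracle = sorted(cand.index, key=lambda g: (-cand.loc[g, "combined"], g))
    got = ranked[ranked["rank"].notna()].sort_values("rank").index.tolist()
    assert got == oracle

    assert shortlist(ranked, n=0) == []
    assert shortlist(ranked, n=len(oracle)) == oracle
    assert shortlist(ranked, n=10 * n) == oracle  # clamped, not an error
    top300 = shortlist(ranked, n=300)
    assert top300 == oracle[:300]
    assert set(top300) == set(ranked.index[ranked["rank"] <= 300])


def test_five_criteria_filter_is_a_pure_conjunction():
    genes = [f"c{i:02d}" for i in range(19)]
    attrs = make_candidate_attributes(genes, n_pass=17, rank_cutoff=300)
    finalists, audit = apply_selection_criteria(genes, attrs, rank_cutoff=300)
    assert finalists == genes[:17]
    assert audit["finalist"].sum() == 17

    # row-order invariance
    shuffled = attrs.sample(frac=1.0, random_state=5)
    finalists2, _ = apply_selection_criteria(genes, shuffled, rank_cutoff=300)
    assert set(finalists2) == set(finalists)

    # unknown fails its criterion and the audit names it
    row = attrs.iloc[[0]].copy()
    row.loc[:, "whole_animal_study"] = "unknown"
    _, audit3 = apply_selection_criteria([genes[0]], row, rank_cutoff=300)
    assert not audit3["whole_animal_study"].iloc[0]
    assert not audit3["finalist"].iloc[0]

    with pytest.raises(ValueError, match="no attribute row"):
        apply_selection_criteria(["missing"], attrs, rank_cutoff=300)


def test_expression_site_vocabulary_matching():
    attrs = make_candidate_attributes(["a", "b"], n_pass=2)
    attrs.loc[attrs["gene"] == "b", "expression_sites"] = "liver, kidney"
    finalists, audit = apply_selection_criteria(["a", "b"], attrs, rank_cutoff=10)
    assert finalists == ["a"]
    assert not audit.loc["b", "expression_site_match"]


def _auc_oracle(scores, positives):
    pos = [s for g, s in scores.items() if g in positives]
    neg = [s for g, s in scores.items() if g not in positives]
    total = 0.0
    for p, n in itertools.product(pos, neg):
        total += 1.0 if p > n else (0.5 if p == n else 0.0)
    return total / (len(pos) * len(neg))


def test_evaluate_closed_forms_and_pairwise_oracle():
    scores = {f"g{i}": 1.0 - i / 10 for i in range(10)}
    positives = {"g0", "g1", "g2"}
    m = evaluate(scores, positives, ks=[1, 3, 5])
    assert m["auc"] == pytest.approx(1.0)
    assert m["recall_at"][1] == pytest.approx(1 / 3)
    assert m["recall_at"][3] == pytest.approx(1.0)

    flat = {f"g{i}": 0.5 for i in range(10)}
    assert evaluate(flat, positives)["auc"] == pytest.approx(0.5, abs=1e-12)

    rng = np.random.default_rng(9)
    rand = {f"g{i}": float(rng.integers(0, 6)) / 5 for i in range(60)}
    pos = set(rng.choice(sorted(rand), size=15, replace=False))
    assert evaluate(rand, pos)["auc"] == pytest.approx(
        _auc_oracle(rand, pos), abs=1e-12
    )

    with pytest.raises(ValueError):
        evaluate(scores, set())
    with pytest.raises(ValueError):
        evaluate(scores, set(scores))


def test_held_out_seeds_outscore_background_after_fusion():
    wins = 0
    for seed in range(10):
        world, _ = synthesize_world(small_config(seed))
        cv = crossval_scores(world, k=5, rng_seed=seed)
        model = fit_combiner(cv.table, rng_seed=seed)
        table = combine_scores(cv.table, model)
        seed_mean = table.loc[table["is_seed"], "combined"].mean()
        bg_mean = table.loc[~table["is_seed"], "combined"].mean()
        if seed_mean > bg_mean:
            wins += 1
    assert wins >= 9
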