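"""Score fusion, cross-validation, candidate ranking and criteria triage.

The two channel scores (guilt-by-profiling, guilt-by-association) are fused
by a logistic stacker fitted on out-of-fold scores: combined =
logistic(b0 + b1*logit(gbp) + b2*logit(gba)). Seeds only ever receive
scores from models trained without them; fold manifests make the absence
of leakage auditable. Non-seed candidates are ranked by combined score and
triaged through a five-criterion conjunctive literature filter.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import rankdata
from sklearn.linear_model import LogisticRegression

from .association import _edge_branch_table, score_all_gba
from .network import build_fl_map
from .profiling import extract_features, score_profiles, train_profile_model
from .world import World

LOGIT_CLAMP = 1e-6

#: Expression-site vocabulary for triage criterion 3.
DEFAULT_SITE_VOCABULARY = frozenset({"cochlea", "epithelium", "cilia"})

CRITERION_COLUMNS = (
    "rank_high",
    "family_member_known_gene",
    "expression_site_match",
    "whole_animal_study",
    "auditory_development_link",
)


@dataclass
class CrossvalResult:
    """Out-of-fold channel scores plus the fold bookkeeping that proves it."""

    table: pd.DataFrame  # index: gene; gbp_score, gba_score, is_seed, fold
    fold_manifest: dict[int, dict]  # fold -> {held_out, trained_on, ...}
    k: int
    rng_seed: int


@dataclass
class CombinerModel:
    beta0: float
    beta_gbp: float
    beta_gba: float
    warnings: list[str] = field(default_factory=list)

    def combine(self, gbp: np.ndarray, gba: np.ndarray) -> np.ndarray:
        z = self.beta0 + self.beta_gbp * _logit(gbp) + self.beta_gba * _logit(gba)
        return 1.0 / (1.0 + np.exp(-z))


def _logit(p: np.ndarray | float) -> np.ndarray:
    p = np.clip(np.asarray(p, dtype=float), LOGIT_CLAMP, 1.0 - LOGIT_CLAMP)
    return np.log(p) - np.log1p(-p)


def crossval_scores(
    world: World,
    k: int = 5,
    rng_seed: int = 0,
    kappa: float = 0.25,
    negative_ratio: float = 10.0,
    reg: float = 1.0,
    fl_pseudocount: float = 1.0,
) -> CrossvalResult:
    """Out-of-fold guilt-by-profiling and guilt-by-association scores.

    Seeds are partitioned into *k* seeded folds; for each fold the profile
    classifier and association scorer are retrained treating held-out seeds
    as ordinary non-seeds, except that held-out seeds are barred from the
    profile model's negative sample (a model must never be fitted on a gene
    it will score out-of-fold, in either label role). Held-out seeds take
    their own fold's scores; non-seeds take the mean over the k fold
    models. The FL map itself uses no seed labels, so a single estimate
    serves every fold. Deterministic given *rng_seed*.
    """
    seeds = sorted(world.seeds)
    if k < 2:
        raise ValueError("k must be >= 2")
    if k > len(seeds):
        raise ValueError(f"k={k} exceeds the number of seeds ({len(seeds)})")

    ss = np.random.SeedSequence(rng_seed)
    child_seeds = [int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(k + 1)]
    rng = np.random.default_rng(child_seeds[0])
    perm = rng.permutation(len(seeds))
    fold_of = {seeds[j]: int(i % k) for i, j in enumerate(perm)}

    flmap = build_fl_map(
        world.network, world.annotations, world.terms, pseudocount=fl_pseudocount
    )
    X = extract_features(world.universe, world.annotations, world.terms, world.network)
    gba_table = _edge_branch_table(
        world.network, flmap, world.annotations, world.terms, world.universe
    )

    n = len(world.universe)
    gene_pos = {g: i for i, g in enumerate(world.universe)}
    gbp = np.zeros(n)
    gba = np.zeros(n)
    non_seed_mask = np.array([g not in world.seeds for g in world.universe])
    manifest: dict[int, dict] = {}

    for f in range(k):
        train_seeds = {s for s in seeds if fold_of[s] != f}
        held_out = [s for s in seeds if fold_of[s] == f]
        model = train_profile_model(
            X,
            train_seeds,
            negative_ratio=negative_ratio,
            reg=reg,
            rng_seed=child_seeds[f + 1],
            exclude_from_negatives=set(held_out),
        )
        gbp_f = score_profiles(model, X)
        gba_f = score_all_gba(
            train_seeds,
            world.network,
            flmap,
            world.annotations,
            world.terms,
            kappa=kappa,
            universe=world.universe,
            _table=gba_table,
        )
        gbp_f_arr = np.array([gbp_f[g] for g in world.universe])
        gba_f_arr = np.array([gba_f[g] for g in world.universe])
        gbp[non_seed_mask] += gbp_f_arr[non_seed_mask] / k
        gba[non_seed_mask] += gba_f_arr[non_seed_mask] / k
        for s in held_out:
            gbp[gene_pos[s]] = gbp_f_arr[gene_pos[s]]
            gba[gene_pos[s]] = gba_f_arr[gene_pos[s]]
        manifest[f] = {
            "held_out": held_out,
            "trained_on": sorted(train_seeds),
            "profile_rng_seed": child_seeds[f + 1],
        }

    table = pd.DataFrame(
        {
            "gbp_score": gbp,
            "gba_score": gba,
            "is_seed": ~non_seed_mask,
            "fold": [fold_of.get(g, -1) for g in world.universe],
        },
        index=pd.Index(world.universe, name="gene"),
    )
    return CrossvalResult(table=table, fold_manifest=manifest, k=k, rng_seed=rng_seed)


def fit_combiner(
    table: pd.DataFrame,
    rng_seed: int = 0,
    negative_ratio: float = 10.0,
    reg: float = 1.0,
) -> CombinerModel:
    """Fit the logistic stacker on out-of-fold channel scores.

    Positives are the seeds; negatives a seeded uniform sample of non-seeds
    (``negative_ratio`` per seed). A constant channel simply earns a
    near-zero coefficient under the L2 penalty; a warning is recorded.
    """
    seeds_df = table[table["is_seed"]]
    non_df = table[~table["is_seed"]]
    rng = np.random.default_rng(rng_seed)
    n_neg = min(int(round(negative_ratio * len(seeds_df))), len(non_df))
    neg_rows = non_df.iloc[
        np.sort(rng.choice(len(non_df), size=n_neg, replace=False))
    ]
    design = pd.concat([seeds_df, neg_rows])
    Z = np.column_stack(
        [_logit(design["gbp_score"].to_numpy()), _logit(design["gba_score"].to_numpy())]
    )
    y = design["is_seed"].to_numpy().astype(float)
    warnings = []
    for name, col in zip(("gbp", "gba"), Z.T):
        if np.ptp(col) == 0.0:
            warnings.append(f"channel {name} is constant; coefficient shrunk to ~0")
    clf = LogisticRegression(C=1.0 / reg, solver="lbfgs", max_iter=2000, tol=1e-8)
    clf.fit(Z, y)
    return CombinerModel(
        beta0=float(clf.intercept_[0]),
        beta_gbp=float(clf.coef_[0][0]),
        beta_gba=float(clf.coef_[0][1]),
        warnings=warnings,
    )


def combine_scores(table: pd.DataFrame, model: CombinerModel) -> pd.DataFrame:
    """Return *table* with a ``combined`` posterior column added."""
    out = table.copy()
    out["combined"] = model.combine(
        table["gbp_score"].to_numpy(), table["gba_score"].to_numpy()
    )
    return out


def rank_candidates(table: pd.DataFrame) -> pd.DataFrame:
    """Rank non-seed genes by (combined desc, gene ID asc); seeds unranked."""
    if "combined" not in table.columns:
        raise ValueError("combine scores before ranking")
    out = table.copy()
    out["rank"] = pd.NA
    # mergesort on an ID-sorted frame makes the tie-break (ID ascending) stable
    cand = (
        out[~out["is_seed"]]
        .sort_index()
        .sort_values(by="combined", ascending=False, kind="mergesort")
    )
    out.loc[cand.index, "rank"] = np.arange(1, len(cand) + 1)
    out["rank"] = out["rank"].astype("Int64")
    return out


def shortlist(table: pd.DataFrame, n: int = 300) -> list[str]:
    """Top-*n* ranked candidate genes, in rank order."""
    ranked = table[table["rank"].notna()].sort_values("rank")
    if n > len(ranked):
        n = len(ranked)
    return ranked.index[:n].tolist()


def _as_bool(value) -> bool | None:
    """Parse a criterion value; None means unknown (which fails)."""
    if isinstance(value, bool):
        return value
    if value is None or (isinstance(value, float) and np.isnan(value)):
        return None
    s = str(value).strip().lower()
    if s in {"true", "yes", "1", "t", "y"}:
        return True
    if s in {"false", "no", "0", "f", "n"}:
        return False
    return None


def apply_selection_criteria(
    candidates: list[str],
    attrs: pd.DataFrame,
    rank_cutoff: int,
    site_vocabulary: frozenset[str] = DEFAULT_SITE_VOCABULARY,
) -> tuple[list[str], pd.DataFrame]:
    """Conjunctive five-criterion triage of shortlisted candidates.

    A candidate is kept iff it (1) ranks at or above *rank_cutoff*, (2) has
    a gene-family member among the known disease genes, (3) is expressed in
    at least one site of *site_vocabulary*, (4) has whole-animal (not only
    cell-line) evidence, and (5) is linked to auditory-system development.
    Unknown values fail their criterion. *attrs* needs columns
    ``rank_position``, ``family_member_known_gene``, ``expression_sites``
    (comma/semicolon-separated), ``whole_animal_study``,
    ``auditory_development_link``, indexed by (or with a column of) gene.
    Returns (finalists in input order, per-gene pass/fail audit).
    """
    if "gene" in attrs.columns:
        attrs = attrs.set_index("gene")
    audit_rows = []
    finalists = []
    for gene in candidates:
        if gene not in attrs.index:
            raise ValueError(f"candidate {gene} has no attribute row")
        row = attrs.loc[gene]
        try:
            rank_ok = int(row["rank_position"]) <= rank_cutoff
        except (TypeError, ValueError):
            rank_ok = False
        sites = {
            s.strip().lower()
            for s in str(row.get("expression_sites", "") or "")
            .replace(";", ",")
            .split(",")
            if s.strip()
        }
        checks = {
            "rank_high": rank_ok,
            "family_member_known_gene": _as_bool(row["family_member_known_gene"]) is True,
            "expression_site_match": bool(sites & site_vocabulary),
            "whole_animal_study": _as_bool(row["whole_animal_study"]) is True,
            "auditory_development_link": _as_bool(row["auditory_development_link"]) is True,
        }
        passed = all(checks.values())
        audit_rows.append({"gene": gene, **checks, "finalist": passed})
        if passed:
            finalists.append(gene)
    audit = pd.DataFrame(audit_rows).set_index("gene")
    return finalists, audit


def evaluate(
    scores: pd.Series | dict[str, float],
    positives: set[str],
    ks: list[int] = (100,),
    exclude: set[str] = frozenset(),
) -> dict:
    """AUC (ties count 1/2) and recall@k for a score vector.

    *exclude* genes (typically the seeds, which are labelled, not
    predicted) are removed before evaluation. AUC uses the rank-sum
    formula, equivalent to exhaustive pairwise comparison with ties scored
    one half. Raises ``ValueError`` without both positives and negatives.
    """
    s = pd.Series(scores, dtype=float)
    s = s[~s.index.isin(exclude)]
    pos_mask = s.index.isin(positives)
    n_pos, n_neg = int(pos_mask.sum()), int((~pos_mask).sum())
    if n_pos == 0:
        raise ValueError("no positives to evaluate")
    if n_neg == 0:
        raise ValueError("no negatives to evaluate")
    ranks = rankdata(s.to_numpy())  # average ranks implement the tie-1/2 rule
    auc = (ranks[pos_mask].sum() - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg)
    order = s.loc[sorted(s.index)].sort_values(ascending=False, kind="mergesort")
    metrics = {"auc": float(auc), "n_pos": n_pos, "n_neg": n_neg, "recall_at": {}}
    for k in ks:
        top = set(order.index[:k])
        metrics["recall_at"][int(k)] = len(top & positives) / n_pos
    return metrics
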