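"""Benchmarking protocols: cherry leave-one-out, MAP@k, ortholog P/R/F, RF.

The harness mirrors, at desk scale, the validation protocols used to assess
tree-based homolog search: high-support cherries (mutual sister pairs)
provide leave-one-out test cases with a known expected closest gene;
rankings by branch-length distance are summarised as mean precision at k;
ortholog predictions are scored as precision/recall/F against ground truth;
and re-placed trees are compared to originals by the normalized
Robinson-Foulds distance.
"""

from __future__ import annotations

import json
import statistics
from collections.abc import Iterable, Mapping, Sequence
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from skbio import TreeNode

from .assign import SearchConfig, builtin_search
from .dbbuild import (
    Database,
    FamilyEntry,
    HomologGroup,
    extract_sub_msa,
    induced_subtree,
    node_distances_from,
    select_representatives,
    split_large_tree,
)
from .orthology import label_events, ortholog_set
from .place import PlacedResult, shoot_search
from .treeio import InputError, leaf_names


# ---------------------------------------------------------------------------
# Cherry test cases


@dataclass(frozen=True)
class CherryCase:
    """A leave-one-out test case: a mutual-sister gene pair."""

    family_id: str
    query: str
    expected: str
    support: int


def _tree_cherries(tree: TreeNode) -> list[tuple[str, str, int]]:
    out = []
    for node in tree.non_tips(include_self=True):
        if len(node.children) == 2 and all(c.is_tip() for c in node.children):
            a, b = sorted(c.name for c in node.children)
            support = getattr(node, "support", None)
            out.append((a, b, support if support is not None else -1))
    return out


def find_cherries(
    trees: Mapping[str, TreeNode],
    min_support: int = 95,
    min_median_support: int = 95,
) -> list[CherryCase]:
    """Extract at most one high-support cherry per qualifying tree.

    A tree qualifies if the median of its internal-node supports is at
    least ``min_median_support``; within it, cherries whose joining node
    has support >= ``min_support`` are eligible and the highest-support one
    (ties by lexicographic gene pair) is kept.  The lexicographically
    smaller gene becomes the query, its sister the expected closest gene.
    """
    cases: list[CherryCase] = []
    for fam in sorted(trees):
        tree = trees[fam]
        supports = [
            s for s in (
                getattr(n, "support", None) for n in tree.non_tips(include_self=True)
            )
            if s is not None
        ]
        if not supports or statistics.median(supports) < min_median_support:
            continue
        eligible = [
            (a, b, s) for a, b, s in _tree_cherries(tree) if s >= min_support
        ]
        if not eligible:
            continue
        eligible.sort(key=lambda t: (-t[2], t[0], t[1]))
        a, b, s = eligible[0]
        cases.append(CherryCase(family_id=fam, query=a, expected=b, support=s))
    return cases


# ---------------------------------------------------------------------------
# Leave-one-out


def prune_gene(db: Database, family_id: str, gene: str) -> Database:
    """A copy of ``db`` with one gene removed from its family everywhere:
    sequences, MSA row, tree leaf (parent spliced), and representatives
    (re-selected from the pruned sub-MSAs)."""
    entry = db.families[family_id]
    if gene not in entry.group.sequences:
        raise InputError(f"gene {gene} not in family {family_id}")
    remaining = [g for g in entry.group.sequences if g != gene]
    if len(remaining) < 2:
        raise InputError(f"family {family_id} too small after pruning")
    seqs = {g: s for g, s in entry.group.sequences.items() if g != gene}
    msa = extract_sub_msa(entry.group.msa, remaining)
    tree = induced_subtree(entry.group.tree, remaining)
    group = HomologGroup(family_id, seqs, msa, tree)
    split = split_large_tree(group, db.config)
    reps = {
        st.subtree_id: select_representatives(
            extract_sub_msa(group.msa, st.members),
            db.config,
            family_id=family_id,
            subtree_id=st.subtree_id,
        )
        for st in split.subtrees
    }
    families = dict(db.families)
    families[family_id] = FamilyEntry(group, split, reps)
    return Database(config=db.config, families=families, species_map=db.species_map)


@dataclass
class LooOutcome:
    case: CherryCase
    status: str  # "hit" | "miss" | "skipped"
    predicted: str | None = None
    reason: str | None = None
    result: PlacedResult | None = None


def closest_ranking(placed: PlacedResult | TreeNode, query_id: str | None = None) -> list[str]:
    """All non-query leaves sorted by branch-length distance to the query
    (ties by lexicographic id)."""
    if isinstance(placed, PlacedResult):
        tree, query_id = placed.tree, placed.query_id
    else:
        tree = placed
        if query_id is None:
            raise InputError("query_id required when passing a bare tree")
    start = None
    for tip in tree.tips():
        if tip.name == query_id:
            start = tip
            break
    if start is None:
        raise InputError(f"query leaf {query_id} not in tree")
    dist = node_distances_from(tree, start)
    ranked = sorted(
        (dist[id(t)], t.name) for t in tree.tips() if t.name != query_id
    )
    return [name for _, name in ranked]


def leave_one_out(
    db: Database,
    case: CherryCase,
    method: str = "shoot",
    search_cfg: SearchConfig | None = None,
) -> LooOutcome:
    """Prune the case's query gene from the database, re-search it, and
    score whether the top-ranked gene is the expected closest gene.

    ``method`` is "shoot" (full placement pipeline, ranking by branch
    length in the result tree) or "besthit" (raw e-value search against all
    database sequences — the BLAST-like baseline).
    """
    entry = db.families[case.family_id]
    if entry.group.size - 1 < 3:
        return LooOutcome(case, "skipped", reason="family retains < 3 genes")
    query_seq = entry.group.sequences[case.query]
    pruned = prune_gene(db, case.family_id, case.query)

    if method == "shoot":
        results = shoot_search(
            query_seq, pruned, query_id=case.query, search_cfg=search_cfg
        )
        if not results:
            return LooOutcome(case, "miss", reason="no homologs found")
        ranking = closest_ranking(results[0])
        predicted = ranking[0] if ranking else None
    elif method == "besthit":
        all_seqs = {
            g: s
            for fam in pruned.families.values()
            for g, s in fam.group.sequences.items()
        }
        hits = builtin_search(query_seq, all_seqs, sensitive=True)
        predicted = hits[0].rep_id if hits else None
        results = []
    else:
        raise InputError(f"unknown leave-one-out method {method!r}")

    status = "hit" if predicted == case.expected else "miss"
    return LooOutcome(
        case,
        status,
        predicted=predicted,
        result=results[0] if results else None,
    )


# ---------------------------------------------------------------------------
# Ranking metrics


def precision_at_k_curve(
    predicted: Sequence[str], expected: Sequence[str], k_max: int
) -> np.ndarray:
    """precision@k = |top-k(predicted) & top-k(expected)| / k for k=1..k_max.

    k is capped at the number of available genes.
    """
    if k_max < 1:
        raise InputError("k_max must be >= 1")
    if len(set(predicted)) != len(predicted) or len(set(expected)) != len(expected):
        raise InputError("rankings must be duplicate-free")
    out = np.empty(k_max)
    for k in range(1, k_max + 1):
        kk = min(k, len(predicted), len(expected))
        if kk == 0:
            out[k - 1] = 0.0
            continue
        out[k - 1] = len(set(predicted[:kk]) & set(expected[:kk])) / kk
    return out


def map_at_k(predicted, expected, k_max: int = 50) -> np.ndarray:
    """Mean over cases of precision@k, for k = 1..k_max.

    ``predicted``/``expected`` are either one ranking each (lists of gene
    ids) or parallel lists of rankings, one per test case.
    """
    if predicted and isinstance(predicted[0], str):
        predicted, expected = [predicted], [expected]
    if len(predicted) != len(expected):
        raise InputError("predicted and expected case counts differ")
    curves = [
        precision_at_k_curve(p, e, k_max) for p, e in zip(predicted, expected)
    ]
    return np.mean(curves, axis=0)


# ---------------------------------------------------------------------------
# Ortholog precision/recall/F


@dataclass(frozen=True)
class PrfResult:
    tp: int
    fp: int
    fn: int
    precision: float
    recall: float
    fscore: float


def ortholog_prf(predicted: Iterable[str], truth: Iterable[str]) -> PrfResult:
    """Precision/recall/F of a predicted ortholog set against the truth set.

    Both empty counts as a perfect (1/1/1) prediction.
    """
    predicted, truth = set(predicted), set(truth)
    if not predicted and not truth:
        return PrfResult(0, 0, 0, 1.0, 1.0, 1.0)
    tp = len(predicted & truth)
    fp = len(predicted - truth)
    fn = len(truth - predicted)
    precision = tp / (tp + fp) if (tp + fp) else 0.0
    recall = tp / (tp + fn) if (tp + fn) else 0.0
    fscore = (
        2 * precision * recall / (precision + recall) if (precision + recall) else 0.0
    )
    return PrfResult(tp, fp, fn, precision, recall, fscore)


# ---------------------------------------------------------------------------
# Robinson-Foulds


def _bipartitions(tree: TreeNode, ref_leaf: str) -> set[frozenset[str]]:
    all_leaves = frozenset(leaf_names(tree))
    n = len(all_leaves)
    parts: set[frozenset[str]] = set()
    for node in tree.non_tips(include_self=False):
        side = frozenset(t.name for t in node.tips())
        if len(side) <= 1 or len(side) >= n - 1:
            continue  # trivial bipartition
        if ref_leaf in side:
            side = all_leaves - side
        parts.add(side)
    return parts


def normalized_rf(t1: TreeNode, t2: TreeNode) -> float:
    """Normalized Robinson-Foulds distance between two trees on the same
    leaves, treated as unrooted: |symmetric difference of non-trivial
    bipartitions| / (2(n-3))."""
    l1, l2 = set(leaf_names(t1)), set(leaf_names(t2))
    if l1 != l2:
        raise InputError(
            "leaf sets differ: "
            f"only in first {sorted(l1 - l2)}; only in second {sorted(l2 - l1)}"
        )
    n = len(l1)
    if n < 4:
        raise InputError("normalized RF requires at least 4 leaves")
    ref = min(l1)
    b1 = _bipartitions(t1, ref)
    b2 = _bipartitions(t2, ref)
    return len(b1 ^ b2) / (2 * (n - 3))


# ---------------------------------------------------------------------------
# Split-vs-unsplit placement comparison


def split_vs_unsplit_rf(
    db_split: Database,
    db_unsplit: Database,
    cases: Sequence[CherryCase],
    search_cfg: SearchConfig | None = None,
) -> list[float]:
    """For each case, place the pruned query with both databases and return
    the normalized RF distance between the two full result trees."""
    out: list[float] = []
    for case in cases:
        rfs = []
        for db in (db_split, db_unsplit):
            entry = db.families[case.family_id]
            if case.query not in entry.group.sequences or entry.group.size - 1 < 3:
                rfs = None
                break
            pruned = prune_gene(db, case.family_id, case.query)
            results = shoot_search(
                entry.group.sequences[case.query],
                pruned,
                query_id=case.query,
                search_cfg=search_cfg,
            )
            hit = next(
                (r for r in results if r.family_id == case.family_id), None
            )
            if hit is None:
                rfs = None
                break
            rfs.append(hit.tree)
        if rfs is None:
            continue
        if len(set(leaf_names(rfs[0]))) < 4:
            continue
        out.append(normalized_rf(rfs[0], rfs[1]))
    return out


# ---------------------------------------------------------------------------
# Full benchmark


def run_benchmark(
    db: Database,
    truth,
    k_max: int = 50,
    min_support: int = 95,
    search_cfg: SearchConfig | None = None,
    out_dir=None,
) -> dict:
    """Run the cherry leave-one-out protocol on a database built from
    simulator output with retained truth.

    ``truth`` is a ``simfixtures.SimTruth``.  Reports closest-gene
    accuracy, the MAP@k curve, per-case ortholog precision/recall/F against
    the generator truth, and the normalized RF between each original family
    tree and its re-placed counterpart.
    """
    missing = set(db.families) - set(truth.families)
    if missing:
        raise InputError(f"truth missing families: {sorted(missing)}")

    trees = {fam: entry.group.tree for fam, entry in db.families.items()}
    cases = find_cherries(trees, min_support=min_support, min_median_support=min_support)

    rows = []
    pred_rankings: list[list[str]] = []
    exp_rankings: list[list[str]] = []
    prf_list: list[PrfResult] = []
    rf_list: list[float] = []
    hits = misses = skipped = 0
    for case in cases:
        outcome = leave_one_out(db, case, method="shoot", search_cfg=search_cfg)
        if outcome.status == "skipped":
            skipped += 1
            rows.append((case.family_id, case.query, case.expected, "skipped", ""))
            continue
        if outcome.status == "hit":
            hits += 1
        else:
            misses += 1
        rows.append(
            (case.family_id, case.query, case.expected, outcome.status,
             outcome.predicted or "")
        )
        if outcome.result is None:
            continue
        family_truth = truth.families[case.family_id]
        original_tree = db.families[case.family_id].group.tree

        predicted = closest_ranking(outcome.result)
        expected = closest_ranking(original_tree, case.query)
        pred_rankings.append(predicted)
        exp_rankings.append(expected)

        true_orthologs = family_truth.orthologs_of(case.query)
        query_species = db.species_map[case.query]
        relabeled = label_events(
            outcome.result.tree,
            {**db.species_map, case.query: query_species},
        )
        predicted_orthologs = ortholog_set(relabeled, case.query)
        prf_list.append(ortholog_prf(predicted_orthologs, true_orthologs))

        if len(set(leaf_names(original_tree))) >= 4:
            rf_list.append(normalized_rf(original_tree, outcome.result.tree))

    n_scored = hits + misses
    map_curve = (
        map_at_k(pred_rankings, exp_rankings, k_max)
        if pred_rankings
        else np.zeros(k_max)
    )
    report = {
        "n_families": len(db.families),
        "n_cherry_cases": len(cases),
        "n_scored": n_scored,
        "n_skipped": skipped,
        "closest_gene_accuracy": hits / n_scored if n_scored else float("nan"),
        "map_at_k": [float(x) for x in map_curve],
        "map_at_kmax": float(map_curve[-1]) if len(map_curve) else float("nan"),
        "ortholog_precision": (
            float(np.mean([p.precision for p in prf_list])) if prf_list else float("nan")
        ),
        "ortholog_recall": (
            float(np.mean([p.recall for p in prf_list])) if prf_list else float("nan")
        ),
        "ortholog_fscore": (
            float(np.mean([p.fscore for p in prf_list])) if prf_list else float("nan")
        ),
        "placement_rf_mean": float(np.mean(rf_list)) if rf_list else float("nan"),
        "placement_rf_zero_fraction": (
            float(np.mean([rf == 0.0 for rf in rf_list])) if rf_list else float("nan")
        ),
    }

    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        pd.DataFrame(
            rows, columns=["family", "query", "expected", "status", "predicted"]
        ).to_csv(out / "cases.tsv", sep="\t", index=False)
        pd.DataFrame(
            {"k": np.arange(1, k_max + 1), "map_at_k": map_curve}
        ).to_csv(out / "map_at_k.tsv", sep="\t", index=False)
        (out / "report.json").write_text(json.dumps(report, indent=1))
    return report
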