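"""Phylogenetic placement of a query into pre-computed gene trees.

The query is first aligned to the (sub)tree's pre-computed MSA against a
per-column residue-frequency profile (global affine alignment, BLOSUM62
expected score, gap open 11 / extend 1).  Columns are never altered and
query-only insertion states are discarded, so the reference alignment is
preserved ("keep-length").  The extended alignment is then scored on every
edge of the reference tree: the query is attached mid-edge and the
attachment with the minimum Fitch parsimony cost over the
parsimony-informative columns wins (residues only; gaps and X are treated
as missing).  For split families the placed subtree is rooted on its stored
outgroup, the outgroup is removed, and the subtree is grafted back into the
full family tree using the supertree.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from Bio.Align import substitution_matrices
from skbio import TreeNode

from .assign import SearchConfig, SearchHit, search_with_retry, validate_query
from .dbbuild import Database, SplitFamily
from .orthology import label_events, orthologs_of
from .treeio import GAP, AMINO_ACIDS, InputError, Msa, leaf_names, tree_copy

_NEG = -1.0e30
_GAP_OPEN = 11.0
_GAP_EXTEND = 1.0
_RES_INDEX = {a: i for i, a in enumerate(AMINO_ACIDS)}


@dataclass
class ExtendedMsa:
    """A reference MSA plus one query row aligned to its columns."""

    reference: Msa
    query_id: str
    query_row: str

    def __post_init__(self):
        if len(self.query_row) != self.reference.width:
            raise InputError(
                "query row length does not match reference MSA width"
            )


@dataclass
class PlacedResult:
    """A full gene tree with the query embedded, plus its ortholog table."""

    tree: TreeNode
    query_id: str
    family_id: str
    subtree_id: str
    placement_cost: float
    best_hit: SearchHit | None = None
    sensitive_pass: bool = False
    orthologs: pd.DataFrame | None = None


# ---------------------------------------------------------------------------
# Query-to-profile alignment


def _profile_scores(msa: Msa, query: str) -> np.ndarray:
    """S[i, j]: expected BLOSUM62 score of query residue i against column j."""
    blosum = substitution_matrices.load("BLOSUM62")
    n_res = len(AMINO_ACIDS)
    B = np.zeros((n_res + 1, n_res), dtype=np.float64)  # +1 row for X
    for i, a in enumerate(AMINO_ACIDS):
        for j, b in enumerate(AMINO_ACIDS):
            B[i, j] = blosum[a][b]
        B[n_res, i] = blosum["X"][a]
    width = msa.width
    counts = np.zeros((width, n_res), dtype=np.float64)
    n_rows = len(msa)
    for row in msa.rows.values():
        for j, ch in enumerate(row):
            idx = _RES_INDEX.get(ch)
            if idx is not None:
                counts[j, idx] += 1.0
    freq = counts / n_rows  # gap rows dilute the column profile
    qidx = np.array(
        [_RES_INDEX.get(ch, n_res) for ch in query], dtype=np.intp
    )
    col_scores = freq @ B.T  # (width, n_res+1)
    return col_scores[:, qidx].T  # (len(query), width)


def add_to_msa(query: str, sub_msa: Msa, query_id: str = "QUERY") -> ExtendedMsa:
    """Align a query to a reference MSA's residue-frequency profile.

    Global affine alignment (open 11, extend 1); terminal unmatched
    reference columns are free, so a query covering part of the family
    alignment is not penalised for the flanks.  Reference rows are returned
    byte-identical; query insertions relative to the reference are dropped.
    """
    query = validate_query(query)
    m = len(query)
    n = sub_msa.width
    S = _profile_scores(sub_msa, query)

    M = np.full((m + 1, n + 1), _NEG)
    Ix = np.full((m + 1, n + 1), _NEG)  # consumes query residue, no column
    Iy = np.full((m + 1, n + 1), _NEG)  # consumes column, '-' in query row
    M[0, 0] = 0.0
    Iy[0, 1:] = 0.0  # free leading reference columns
    if m >= 1:
        Ix[1:, 0] = -_GAP_OPEN - _GAP_EXTEND * np.arange(m)

    for i in range(1, m + 1):
        prev_best = np.maximum(np.maximum(M[i - 1], Ix[i - 1]), Iy[i - 1])
        M[i, 1:] = S[i - 1] + prev_best[:-1]
        Ix[i, 1:] = np.maximum(M[i - 1, 1:] - _GAP_OPEN, Ix[i - 1, 1:] - _GAP_EXTEND)
        # Iy along the row is a running max over earlier M entries
        shifted = M[i, :-1] + _GAP_EXTEND * np.arange(n)
        running = np.maximum.accumulate(shifted)
        Iy[i, 1:] = running - _GAP_OPEN - _GAP_EXTEND * np.arange(n)

    # free trailing reference columns: end anywhere on the last row
    ends = np.maximum(M[m], Ix[m])
    ends_free = ends.copy()
    j_end = int(np.argmax(ends_free))
    best_end = ends_free[j_end]
    if Iy[m, n] > best_end:
        j_end, best_end = n, Iy[m, n]
        end_state = 2
    else:
        end_state = 0 if M[m, j_end] >= Ix[m, j_end] else 1

    row = [GAP] * n
    i, j, state = m, j_end, end_state
    for jj in range(j_end, n):
        row[jj] = GAP
    while i > 0 or j > 0:
        if state == 0:  # M
            if i == 0:
                state = 2
                continue
            row[j - 1] = query[i - 1]
            prev = (M[i - 1, j - 1], Ix[i - 1, j - 1], Iy[i - 1, j - 1])
            state = int(np.argmax(prev))
            i, j = i - 1, j - 1
        elif state == 1:  # Ix: query residue dropped
            if M[i - 1, j] - _GAP_OPEN >= Ix[i - 1, j] - _GAP_EXTEND:
                state = 0
            i -= 1
        else:  # Iy: reference column unmatched
            row[j - 1] = GAP
            if i == 0:
                j -= 1
                continue
            if abs(Iy[i, j] - (M[i, j - 1] - _GAP_OPEN)) < 1e-9:
                state = 0
            j -= 1

    return ExtendedMsa(reference=sub_msa, query_id=query_id, query_row="".join(row))


# ---------------------------------------------------------------------------
# Parsimony placement


def _informative_columns(rows: list[str]) -> list[int]:
    """Columns with >= 2 distinct residues each seen >= 2 times (gaps/X ignored)."""
    width = len(rows[0])
    out = []
    for j in range(width):
        counts: dict[str, int] = {}
        for r in rows:
            ch = r[j]
            if ch in _RES_INDEX:
                counts[ch] = counts.get(ch, 0) + 1
        if sum(1 for v in counts.values() if v >= 2) >= 2:
            out.append(j)
    return out


def _column_masks(row: str, cols: list[int]) -> np.ndarray:
    full = (1 << len(AMINO_ACIDS)) - 1
    out = np.empty(len(cols), dtype=np.uint32)
    for k, j in enumerate(cols):
        idx = _RES_INDEX.get(row[j])
        out[k] = (1 << idx) if idx is not None else full
    return out


def _fitch_fold(sets: list[np.ndarray], costs: list[np.ndarray]):
    """Sequential Fitch combination of child state sets (handles polytomies)."""
    cur = sets[0]
    cost = costs[0].copy()
    for s, c in zip(sets[1:], costs[1:]):
        inter = cur & s
        empty = inter == 0
        cur = np.where(empty, cur | s, inter)
        cost = cost + c + empty.astype(np.int32)
    return cur, cost


def p_distance(a: str, b: str) -> float:
    """Fraction of mismatching residue-residue sites (gaps/X skipped)."""
    same = 0
    total = 0
    for x, y in zip(a, b):
        if x in _RES_INDEX and y in _RES_INDEX:
            total += 1
            if x == y:
                same += 1
    return 1.0 - same / total if total else 0.0


def place_in_tree(
    ext: ExtendedMsa,
    tree: TreeNode,
    hint_leaf: str | None = None,
) -> tuple[TreeNode, float]:
    """Attach the query on the minimum-parsimony edge of the reference tree.

    Every edge is scanned: the query joins mid-edge and the resulting tree's
    Fitch cost over parsimony-informative columns is computed (incrementally
    along the path to the root).  Ties go to the edge topologically closest
    to ``hint_leaf`` (normally the best-hit representative), then to the
    lexicographically smallest descendant leaf label, then to the smaller
    clade.  The query's pendant
    branch length is its normalized p-distance to the nearest reference
    leaf; the new node carries no support value.
    """
    work = tree_copy(tree)
    leaves = leaf_names(work)
    missing = set(leaves) - set(ext.reference.ids)
    if missing:
        raise InputError(f"tree leaves missing from MSA: {sorted(missing)}")

    rows = [ext.reference[name] for name in leaves] + [ext.query_row]
    cols = _informative_columns(rows)
    q_mask = _column_masks(ext.query_row, cols)

    # postorder Fitch state sets and cumulative per-column costs
    sets: dict[int, np.ndarray] = {}
    costs: dict[int, np.ndarray] = {}
    zeros = np.zeros(len(cols), dtype=np.int32)
    for node in work.postorder(include_self=True):
        if node.is_tip():
            sets[id(node)] = _column_masks(ext.reference[node.name], cols)
            costs[id(node)] = zeros
        else:
            s, c = _fitch_fold(
                [sets[id(ch)] for ch in node.children],
                [costs[id(ch)] for ch in node.children],
            )
            sets[id(node)], costs[id(node)] = s, c

    # topological distance of every node to the hint leaf, for tie-breaking
    topo = {id(n): 0 for n in work.traverse(include_self=True)}
    if hint_leaf is not None and hint_leaf in leaves:
        start = next(t for t in work.tips() if t.name == hint_leaf)
        topo = {}
        stack = [(start, 0)]
        while stack:
            node, d = stack.pop()
            if id(node) in topo:
                continue
            topo[id(node)] = d
            if node.parent is not None:
                stack.append((node.parent, d + 1))
            stack.extend((ch, d + 1) for ch in node.children)

    min_label: dict[int, str] = {}
    clade_size: dict[int, int] = {}
    for node in work.postorder(include_self=True):
        if node.is_tip():
            min_label[id(node)] = node.name
            clade_size[id(node)] = 1
        else:
            min_label[id(node)] = min(min_label[id(ch)] for ch in node.children)
            clade_size[id(node)] = sum(clade_size[id(ch)] for ch in node.children)

    best: tuple[float, int, str] | None = None
    best_node: TreeNode | None = None
    for node in work.traverse(include_self=False):
        # attach the query on the edge above `node`
        inter = sets[id(node)] & q_mask
        empty = inter == 0
        u_set = np.where(empty, sets[id(node)] | q_mask, inter)
        u_cost = costs[id(node)] + empty.astype(np.int32)
        # recompute ancestors with this child's contribution replaced
        child, c_set, c_cost = node, u_set, u_cost
        anc = node.parent
        while anc is not None:
            ch_sets = [
                c_set if ch is child else sets[id(ch)] for ch in anc.children
            ]
            ch_costs = [
                c_cost if ch is child else costs[id(ch)] for ch in anc.children
            ]
            c_set, c_cost = _fitch_fold(ch_sets, ch_costs)
            child = anc
            anc = anc.parent
        total = float(c_cost.sum())
        key = (total, topo[id(node)], min_label[id(node)], clade_size[id(node)])
        if best is None or key < best:
            best = key
            best_node = node

    if best_node is None:
        raise InputError("reference tree has no edges to place on")

    pendant = min(
        p_distance(ext.query_row, ext.reference[name]) for name in leaves
    )
    parent = best_node.parent
    idx = parent.children.index(best_node)
    half = (best_node.length or 0.0) / 2.0
    junction = TreeNode(length=half)
    junction.support = None
    query_leaf = TreeNode(name=ext.query_id, length=pendant)
    query_leaf.support = None
    best_node.length = half
    parent.children[idx] = junction
    junction.parent = parent
    best_node.parent = junction
    junction.children = [best_node, query_leaf]
    query_leaf.parent = junction
    return work, best[0]


# ---------------------------------------------------------------------------
# Rooting and grafting


def _splice_unary(node: TreeNode) -> None:
    """Remove a degree-2 internal node, summing its two branch lengths."""
    child = node.children[0]
    parent = node.parent
    child.length = (child.length or 0.0) + (node.length or 0.0)
    idx = parent.children.index(node)
    parent.children[idx] = child
    child.parent = parent
    node.parent = None


def _reroot_on_pendant(root: TreeNode, leaf: TreeNode) -> TreeNode:
    """New root on the pendant edge of ``leaf``; supports follow their edges."""
    parent = leaf.parent
    parent.children.remove(leaf)
    leaf.parent = None

    path = []
    node = parent
    while node is not None:
        path.append(node)
        node = node.parent
    lengths = [n.length for n in path]
    supports = [getattr(n, "support", None) for n in path]
    for i in range(len(path) - 1):
        path[i + 1].children.remove(path[i])
    for i in range(len(path) - 1):
        child, par = path[i], path[i + 1]
        child.children.append(par)
        par.parent = child
        par.length = lengths[i]
        par.support = supports[i]
    path[0].length = 0.0
    path[0].support = None

    new_root = TreeNode(length=None)
    new_root.support = None
    new_root.children = [leaf, path[0]]
    leaf.parent = new_root
    path[0].parent = new_root

    old_root = path[-1]
    if len(old_root.children) == 1 and old_root.parent is not None:
        _splice_unary(old_root)
    return new_root


def root_on_outgroup(tree: TreeNode, outgroup_id: str) -> TreeNode:
    """Reroot on the outgroup's pendant edge, then delete the outgroup.

    The degree-2 node left behind by the deletion is suppressed, summing its
    two incident branch lengths.
    """
    work = tree_copy(tree)
    out = None
    for tip in work.tips():
        if tip.name == outgroup_id:
            out = tip
            break
    if out is None:
        raise InputError(f"outgroup {outgroup_id} not present in tree")

    if out.parent is work and len(work.children) == 2:
        rooted = work
    else:
        rooted = _reroot_on_pendant(work, out)
        out = next(t for t in rooted.tips() if t.name == outgroup_id)

    root = out.parent
    root.children.remove(out)
    out.parent = None
    if len(root.children) == 1:
        new_root = root.children[0]
        new_root.parent = None
        if not new_root.is_tip():
            new_root.length = None
            new_root.support = None
        return new_root
    return root


def graft(placed_subtree: TreeNode, split: SplitFamily, subtree_id: str) -> TreeNode:
    """Replace each supertree leaf by its member tree; the queried subtree
    uses ``placed_subtree`` (already rooted and outgroup-free).

    Boundary edges keep the supertree's (contracted) branch lengths.
    """
    if not split.is_split:
        return tree_copy(placed_subtree)
    split.subtree(subtree_id)  # raises on unknown id
    result = tree_copy(split.supertree)
    for tip in list(result.tips()):
        sid = tip.name
        if sid == subtree_id:
            replacement = tree_copy(placed_subtree)
        else:
            st = split.subtree(sid)
            replacement = root_on_outgroup(st.tree, st.outgroup)
        replacement.length = tip.length
        replacement.support = None
        parent = tip.parent
        if parent is None:
            return replacement
        idx = parent.children.index(tip)
        parent.children[idx] = replacement
        replacement.parent = parent
        tip.parent = None
    return result


# ---------------------------------------------------------------------------
# The full search pipeline


def shoot_search(
    query: str,
    db: Database,
    query_id: str = "QUERY",
    search_cfg: SearchConfig | None = None,
    query_species: str | None = None,
) -> list[PlacedResult]:
    """Search, place, root, graft and label one query against a database.

    Returns one :class:`PlacedResult` per candidate (family, subtree), in
    candidate order; an empty list means no homologs were found.
    """
    search_cfg = search_cfg or SearchConfig()
    query = validate_query(query)
    if query_id in db.all_gene_ids():
        query_id = f"query_{query_id}"

    assignment = search_with_retry(query, db, search_cfg)
    results: list[PlacedResult] = []
    for fam, sid in assignment.candidates:
        entry = db.families[fam]
        st = entry.split.subtree(sid)
        ext = add_to_msa(query, st.msa, query_id=query_id)
        hit = assignment.best_hits.get((fam, sid))
        hint = hit.rep_id if hit is not None else None
        placed, cost = place_in_tree(ext, st.tree, hint_leaf=hint)
        if entry.split.is_split:
            placed = root_on_outgroup(placed, st.outgroup)
            full = graft(placed, entry.split, sid)
        else:
            full = placed

        species_map = dict(db.species_map)
        species_map[query_id] = (
            query_species if query_species is not None else f"__query__{query_id}"
        )
        labeled = label_events(full, species_map)
        table = orthologs_of(labeled, query_id)
        results.append(
            PlacedResult(
                tree=full,
                query_id=query_id,
                family_id=fam,
                subtree_id=sid,
                placement_cost=cost,
                best_hit=hit,
                sensitive_pass=assignment.sensitive_pass,
                orthologs=table,
            )
        )
    return results
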