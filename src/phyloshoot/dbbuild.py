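"""Build a searchable phylogenetic database from homolog groups.

A homolog group arrives as protein sequences, their MSA and a rooted gene
tree.  The builder (i) splits trees larger than ``max_subtree_size`` genes
into outgroup-anchored subtrees linked by a supertree, (ii) extracts the
sub-MSA for each subtree, and (iii) selects k = ceil(N/10) representative
sequences per (sub)tree by k-means on a one-hot encoding of the MSA, with a
minimum of min(20, N) representatives.  Representatives form the profile
set a query is searched against before phylogenetic placement.
"""

from __future__ import annotations

import math
import zlib
from collections.abc import Iterable, Mapping, Sequence
from dataclasses import dataclass

import numpy as np
from skbio import TreeNode
from sklearn.cluster import KMeans

from .treeio import (
    GAP,
    AMINO_ACIDS,
    InputError,
    Msa,
    leaf_names,
    validate_gene_tree,
)

_RESIDUES = AMINO_ACIDS + "X"
_RESIDUE_INDEX = {a: i for i, a in enumerate(_RESIDUES)}


@dataclass(frozen=True)
class BuildConfig:
    """Database build parameters.

    ``max_subtree_size`` is the largest number of member genes a placement
    tree may contain (2500 in the deployed tool); ``rep_divisor`` and
    ``rep_floor`` define the representative count rule
    k = max(ceil(N / divisor), min(floor, N)); the k-means seed and restart
    count make representative selection reproducible.
    """

    max_subtree_size: int = 2500
    rep_divisor: int = 10
    rep_floor: int = 20
    seed: int = 17
    kmeans_restarts: int = 10

    def __post_init__(self):
        if self.max_subtree_size < 3:
            raise InputError("max_subtree_size must be >= 3")
        if self.rep_divisor < 1 or self.rep_floor < 1:
            raise InputError("rep_divisor and rep_floor must be >= 1")
        if self.kmeans_restarts < 1:
            raise InputError("kmeans_restarts must be >= 1")

    def to_dict(self) -> dict:
        return {
            "max_subtree_size": self.max_subtree_size,
            "rep_divisor": self.rep_divisor,
            "rep_floor": self.rep_floor,
            "seed": self.seed,
            "kmeans_restarts": self.kmeans_restarts,
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "BuildConfig":
        return cls(**{k: d[k] for k in cls.__dataclass_fields__ if k in d})


@dataclass
class HomologGroup:
    """One gene family: sequences, MSA and rooted gene tree over the same ids."""

    family_id: str
    sequences: dict[str, str]
    msa: Msa
    tree: TreeNode

    def __post_init__(self):
        leaves = set(leaf_names(self.tree))
        if leaves != set(self.msa.ids) or leaves != set(self.sequences):
            raise InputError(
                f"family {self.family_id}: tree leaves, MSA rows and sequences "
                "must cover the same gene ids"
            )
        if len(leaves) < 2:
            raise InputError(f"family {self.family_id}: needs at least 2 genes")
        validate_gene_tree(self.tree)

    @property
    def size(self) -> int:
        return len(self.sequences)


@dataclass
class Subtree:
    """One placement unit: member genes plus (for split families) one outgroup."""

    subtree_id: str
    members: list[str]
    outgroup: str | None
    tree: TreeNode  # leaves = members (+ outgroup when present)
    msa: Msa  # rows = members (+ outgroup)


@dataclass
class SplitFamily:
    family_id: str
    is_split: bool
    subtrees: list[Subtree]
    supertree: TreeNode | None  # leaves are subtree ids; None when unsplit

    def subtree(self, subtree_id: str) -> Subtree:
        for st in self.subtrees:
            if st.subtree_id == subtree_id:
                return st
        raise InputError(
            f"family {self.family_id}: unknown subtree id {subtree_id}"
        )


@dataclass
class FamilyEntry:
    group: HomologGroup
    split: SplitFamily
    representatives: dict[str, list[str]]  # subtree id -> representative gene ids


@dataclass
class Database:
    """A fully built, in-memory database."""

    config: BuildConfig
    families: dict[str, FamilyEntry]
    species_map: dict[str, str]

    def representative_index(self) -> tuple[dict[str, str], dict[str, tuple[str, str]]]:
        """Return (rep id -> sequence, rep id -> (family, subtree))."""
        seqs: dict[str, str] = {}
        where: dict[str, tuple[str, str]] = {}
        for fam in sorted(self.families):
            entry = self.families[fam]
            for sid in sorted(entry.representatives):
                for rid in entry.representatives[sid]:
                    seqs[rid] = entry.group.sequences[rid]
                    where[rid] = (fam, sid)
        return seqs, where

    def all_gene_ids(self) -> set[str]:
        out: set[str] = set()
        for entry in self.families.values():
            out.update(entry.group.sequences)
        return out


# ---------------------------------------------------------------------------
# Tree splitting


def _clade_sizes(tree: TreeNode) -> dict[int, int]:
    sizes: dict[int, int] = {}
    for node in tree.postorder(include_self=True):
        if node.is_tip():
            sizes[id(node)] = 1
        else:
            sizes[id(node)] = sum(sizes[id(c)] for c in node.children)
    return sizes


def _member_blocks(tree: TreeNode, max_size: int) -> list[list[str]]:
    """Greedy root-to-tip partition of the leaf set into blocks of <= max_size.

    Every maximal clade of size <= max_size becomes one block.  A singleton
    leaf hanging directly off a split node is merged into the smallest
    sibling block created at that node when the merged size still fits;
    otherwise it forms its own block.
    """
    sizes = _clade_sizes(tree)
    blocks: list[list[str]] = []

    def walk(node: TreeNode) -> None:
        if sizes[id(node)] <= max_size:
            blocks.append([t.name for t in node.tips()] if not node.is_tip() else [node.name])
            return
        local: list[list[str]] = []
        singletons: list[str] = []
        oversized: list[TreeNode] = []
        for child in node.children:
            n = sizes[id(child)]
            if n > max_size:
                oversized.append(child)
            elif n == 1:
                singletons.append(child.name)
            else:
                local.append([t.name for t in child.tips()])
        for name in singletons:
            if local:
                target = min(local, key=lambda b: (len(b), b[0]))
                if len(target) + 1 <= max_size:
                    target.append(name)
                    continue
            local.append([name])
        blocks.extend(local)
        for child in oversized:
            walk(child)

    walk(tree)
    return blocks


def _contract(tree: TreeNode, assignment: Mapping[str, str]) -> TreeNode:
    """Contract each block of leaves (sharing an assignment id) to one leaf.

    Blocks are clades, or a clade plus a sibling singleton leaf, so each
    block is connected and the contraction is a well-defined tree whose
    leaves are block ids.  Branch lengths of the contracted edges are kept.
    """

    def rec(node: TreeNode) -> TreeNode:
        if node.is_tip():
            leaf = TreeNode(name=assignment[node.name], length=node.length)
            leaf.support = None
            return leaf
        kids = [rec(c) for c in node.children]
        merged: list[TreeNode] = []
        seen: dict[str, TreeNode] = {}
        for kid in kids:
            if kid.is_tip() and kid.name in seen:
                # merged-singleton case: keep the first occurrence
                continue
            if kid.is_tip():
                seen[kid.name] = kid
            merged.append(kid)
        if len(merged) == 1:
            only = merged[0]
            if only.is_tip():
                only.length = node.length
                return only
        if all(k.is_tip() for k in merged) and len({k.name for k in merged}) == 1:
            leaf = TreeNode(name=merged[0].name, length=node.length)
            leaf.support = None
            return leaf
        inner = TreeNode(length=node.length, children=merged)
        inner.support = getattr(node, "support", None)
        return inner

    contracted = rec(tree)
    # suppress any unary internal nodes introduced by the contraction
    changed = True
    while changed:
        changed = False
        for node in list(contracted.traverse(include_self=False)):
            if not node.is_tip() and len(node.children) == 1:
                child = node.children[0]
                child.length = (child.length or 0.0) + (node.length or 0.0)
                parent = node.parent
                idx = parent.children.index(node)
                node.parent = None
                child.parent = parent
                parent.children[idx] = child
                changed = True
    while not contracted.is_tip() and len(contracted.children) == 1:
        contracted = contracted.children[0]
        contracted.parent = None
        contracted.length = None
    return contracted


def node_distances_from(tree: TreeNode, start: TreeNode) -> dict[int, float]:
    """Branch-length distance from ``start`` to every node, via tree edges."""
    dist: dict[int, float] = {id(start): 0.0}
    stack = [start]
    while stack:
        node = stack.pop()
        d = dist[id(node)]
        neighbours: list[tuple[TreeNode, float]] = []
        for child in node.children:
            neighbours.append((child, child.length or 0.0))
        if node.parent is not None:
            neighbours.append((node.parent, node.length or 0.0))
        for other, w in neighbours:
            if id(other) not in dist:
                dist[id(other)] = d + w
                stack.append(other)
    return dist


def select_outgroup(tree: TreeNode, subtree_members: Iterable[str]) -> str:
    """The non-member leaf closest (by branch length) to the member clade root.

    Ties are broken by lexicographically smallest gene id.
    """
    members = set(subtree_members)
    all_leaves = set(leaf_names(tree))
    if not members or not members < all_leaves:
        raise InputError("subtree members must be a proper subset of tree leaves")
    clade_root = tree.lca(sorted(members)) if len(members) > 1 else tree.find(next(iter(members)))
    dist = node_distances_from(tree, clade_root)
    best: tuple[float, str] | None = None
    for tip in tree.tips():
        if tip.name in members:
            continue
        cand = (dist[id(tip)], tip.name)
        if best is None or cand < best:
            best = cand
    if best is None:
        raise InputError("no non-member leaves available as outgroup")
    return best[1]


def induced_subtree(tree: TreeNode, names: Iterable[str]) -> TreeNode:
    """Copy of ``tree`` restricted to ``names``.

    Unary nodes are spliced out, summing branch lengths; supports of the
    surviving nodes are preserved.
    """
    keep = set(names)
    missing = keep - set(leaf_names(tree))
    if missing:
        raise InputError(f"names not in tree: {sorted(missing)}")

    def rec(node: TreeNode) -> TreeNode | None:
        if node.is_tip():
            if node.name not in keep:
                return None
            leaf = TreeNode(name=node.name, length=node.length)
            leaf.support = None
            return leaf
        kids = [k for k in (rec(c) for c in node.children) if k is not None]
        if not kids:
            return None
        if len(kids) == 1:
            only = kids[0]
            only.length = (only.length or 0.0) + (node.length or 0.0)
            return only
        inner = TreeNode(length=node.length, children=kids)
        inner.support = getattr(node, "support", None)
        return inner

    out = rec(tree)
    if out is None:
        raise InputError("induced subtree is empty")
    out.parent = None
    if not out.is_tip():
        out.length = None
    return out


def extract_sub_msa(msa: Msa, ids: Iterable[str]) -> Msa:
    """Restrict an MSA to ``ids`` and drop columns that become all-gap.

    Row order follows the original MSA.
    """
    wanted = set(ids)
    unknown = wanted - set(msa.ids)
    if unknown:
        raise InputError(f"ids not in MSA: {sorted(unknown)}")
    rows = {gid: row for gid, row in msa.items() if gid in wanted}
    arr = np.array([list(r) for r in rows.values()])
    keep = ~(arr == GAP).all(axis=0)
    sub = {gid: "".join(np.array(list(row))[keep]) for gid, row in rows.items()}
    return Msa(sub)


def split_large_tree(group: HomologGroup, cfg: BuildConfig) -> SplitFamily:
    """Partition an oversized family into outgroup-anchored subtrees.

    Families of at most ``cfg.max_subtree_size`` genes pass through unsplit
    (one subtree, no outgroup, no supertree).  Larger families are split by
    greedy root-to-tip traversal into blocks of at most ``max_subtree_size``
    member genes; each subtree gets the branch-length-nearest external gene
    as outgroup, its sub-MSA, and the supertree records how the blocks
    relate, with the contracted edges' branch lengths.
    """
    if group.size <= cfg.max_subtree_size:
        st = Subtree("st000", sorted(group.sequences), None, group.tree, group.msa)
        return SplitFamily(group.family_id, False, [st], None)

    blocks = _member_blocks(group.tree, cfg.max_subtree_size)
    assignment: dict[str, str] = {}
    subtree_ids = [f"st{i:03d}" for i in range(len(blocks))]
    for sid, block in zip(subtree_ids, blocks):
        for name in block:
            assignment[name] = sid
    supertree = _contract(group.tree, assignment)

    subtrees: list[Subtree] = []
    for sid, block in zip(subtree_ids, blocks):
        outgroup = select_outgroup(group.tree, block)
        st_tree = induced_subtree(group.tree, block + [outgroup])
        st_msa = extract_sub_msa(group.msa, block + [outgroup])
        subtrees.append(Subtree(sid, sorted(block), outgroup, st_tree, st_msa))
    return SplitFamily(group.family_id, True, subtrees, supertree)


# ---------------------------------------------------------------------------
# Representative selection


def n_representatives(n_genes: int, cfg: BuildConfig) -> int:
    """Representative count: ceil(N/divisor), at least min(floor, N), at most N."""
    if n_genes < 1:
        raise InputError("gene count must be >= 1")
    k = max(math.ceil(n_genes / cfg.rep_divisor), min(cfg.rep_floor, n_genes))
    return min(n_genes, k)


def one_hot_encode(msa: Msa, ids: Sequence[str] | None = None) -> np.ndarray:
    """Encode MSA rows as one-hot (column x residue) vectors; gaps are zeros."""
    ids = list(ids) if ids is not None else msa.ids
    width = msa.width
    n_res = len(_RESIDUES)
    X = np.zeros((len(ids), width * n_res), dtype=np.float32)
    for i, gid in enumerate(ids):
        row = msa[gid]
        for j, ch in enumerate(row):
            if ch != GAP:
                X[i, j * n_res + _RESIDUE_INDEX[ch]] = 1.0
    return X


def _subtree_seed(cfg: BuildConfig, family_id: str, subtree_id: str) -> int:
    tag = f"{family_id}:{subtree_id}".encode()
    return (cfg.seed + zlib.crc32(tag)) % (2**31)


def select_representatives(
    sub_msa: Msa,
    cfg: BuildConfig,
    *,
    family_id: str = "",
    subtree_id: str = "",
) -> list[str]:
    """Pick k-means representatives from a member-only sub-MSA.

    Rows are one-hot encoded (gap = zero block) and clustered into
    k = ``n_representatives(N)`` groups; each cluster contributes the member
    closest to its centroid (ties by lexicographic id).  If k == N every
    gene is a representative and no clustering runs.
    """
    ids = sub_msa.ids
    n = len(ids)
    k = n_representatives(n, cfg)
    if k == n:
        return sorted(ids)

    X = one_hot_encode(sub_msa)
    km = KMeans(
        n_clusters=k,
        n_init=cfg.kmeans_restarts,
        random_state=_subtree_seed(cfg, family_id, subtree_id),
    )
    labels = km.fit_predict(X)
    centroids = km.cluster_centers_

    chosen: list[str] = []
    chosen_idx: set[int] = set()
    for c in range(k):
        members = np.flatnonzero(labels == c)
        if members.size == 0:
            continue
        d = np.linalg.norm(X[members] - centroids[c], axis=1)
        order = sorted(zip(d, (ids[i] for i in members), members))
        chosen.append(order[0][1])
        chosen_idx.add(int(order[0][2]))
    # empty clusters (rare: sklearn relocates them) are replaced by the
    # farthest-from-its-own-centroid unselected sequence
    while len(chosen) < k:
        best: tuple[float, str, int] | None = None
        for i in range(n):
            if i in chosen_idx:
                continue
            d = float(np.linalg.norm(X[i] - centroids[labels[i]]))
            cand = (-d, ids[i], i)
            if best is None or cand < best:
                best = cand
        chosen.append(best[1])
        chosen_idx.add(best[2])
    return sorted(chosen)


# ---------------------------------------------------------------------------
# Whole-database build


def build(
    groups: Iterable[HomologGroup],
    species_map: Mapping[str, str],
    cfg: BuildConfig | None = None,
) -> Database:
    """Split every family, select representatives, and index the result."""
    cfg = cfg or BuildConfig()
    families: dict[str, FamilyEntry] = {}
    owner: dict[str, str] = {}
    for group in groups:
        if group.family_id in families:
            raise InputError(f"duplicate family id {group.family_id}")
        for gid in group.sequences:
            if gid in owner:
                raise InputError(
                    f"gene id {gid} appears in families {owner[gid]} "
                    f"and {group.family_id}"
                )
            owner[gid] = group.family_id
            if gid not in species_map:
                raise InputError(f"gene {gid} missing from species map")
        split = split_large_tree(group, cfg)
        reps: dict[str, list[str]] = {}
        for st in split.subtrees:
            member_msa = extract_sub_msa(group.msa, st.members)
            reps[st.subtree_id] = select_representatives(
                member_msa, cfg, family_id=group.family_id, subtree_id=st.subtree_id
            )
        families[group.family_id] = FamilyEntry(group, split, reps)
    relevant = {g: s for g, s in species_map.items() if g in owner}
    return Database(config=cfg, families=families, species_map=relevant)


def build_database(
    groups: Iterable[HomologGroup],
    species_map: Mapping[str, str],
    cfg: BuildConfig | None = None,
    out_dir=None,
    overwrite: bool = False,
):
    """Build and, when ``out_dir`` is given, write the database to disk."""
    from .treeio import save_database

    db = build(groups, species_map, cfg)
    if out_dir is not None:
        layout = save_database(db, out_dir, overwrite=overwrite)
        return db, layout
    return db, None
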