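"""Speciation/duplication labelling by species overlap, and ortholog tables.

An internal node of a gene tree is labelled a duplication if and only if
the species sets of (any pair of) its child clades intersect; otherwise it
is a speciation.  Two genes are orthologs when their last common ancestor
is a speciation node, paralogs when it is a duplication.  No species tree
is consulted.
"""

from __future__ import annotations

from collections.abc import Mapping

import pandas as pd
from skbio import TreeNode

from .treeio import InputError, tree_copy

SPECIATION = "speciation"
DUPLICATION = "duplication"


def label_events(tree: TreeNode, species_map: Mapping[str, str]) -> TreeNode:
    """Return a copy of ``tree`` with ``node.event`` set on every internal node.

    Leaves get ``node.species``; each node also carries ``node.species_set``.
    Polytomies are duplications if any pair of child species sets overlaps.
    """
    labeled = tree_copy(tree)
    for node in labeled.postorder(include_self=True):
        if node.is_tip():
            species = species_map.get(node.name)
            if species is None:
                raise InputError(f"gene {node.name} has no species mapping")
            node.species = species
            node.species_set = frozenset([species])
            node.event = None
        else:
            child_sets = [c.species_set for c in node.children]
            union: set[str] = set()
            total = 0
            for s in child_sets:
                union |= s
                total += len(s)
            # any pairwise intersection <=> multiset size exceeds union size
            node.event = DUPLICATION if total > len(union) else SPECIATION
            node.species_set = frozenset(union)
    return labeled


def orthologs_of(labeled: TreeNode, query_id: str) -> pd.DataFrame:
    """Ortholog/paralog table for ``query_id`` against every other leaf.

    The relation of gene g is decided by the event at LCA(query, g).  The
    table is sorted by (relation, species, gene id).
    """
    query = None
    for tip in labeled.tips():
        if tip.name == query_id:
            query = tip
            break
    if query is None:
        raise InputError(f"query leaf {query_id} not present in labeled tree")

    rows: list[tuple[str, str, str, str]] = []
    # walk root-ward from the query: each ancestor a is the LCA of the query
    # with exactly the leaves under a but not under the previous step
    below = query
    node = query.parent
    while node is not None:
        event = node.event
        relation = "ortholog" if event == SPECIATION else "paralog"
        for child in node.children:
            if child is below:
                continue
            for tip in ([child] if child.is_tip() else child.tips()):
                rows.append((tip.name, tip.species, relation, event))
        below = node
        node = node.parent

    table = pd.DataFrame(rows, columns=["gene_id", "species_id", "relation", "lca_event"])
    return table.sort_values(
        ["relation", "species_id", "gene_id"], ignore_index=True
    )


def ortholog_set(labeled: TreeNode, query_id: str) -> set[str]:
    """Just the ortholog gene ids of ``query_id``."""
    table = orthologs_of(labeled, query_id)
    return set(table.loc[table["relation"] == "ortholog", "gene_id"])
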