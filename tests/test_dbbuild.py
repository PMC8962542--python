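"""Tree splitting, outgroup choice, sub-MSAs and representative selection."""

import math

import numpy as np
import pytest

from phyloshoot.dbbuild import (
    BuildConfig,
    HomologGroup,
    _member_blocks,
    build,
    extract_sub_msa,
    induced_subtree,
    n_representatives,
    select_outgroup,
    select_representatives,
    split_large_tree,
)
from phyloshoot.simfixtures import SimConfig, simulate_families
from phyloshoot.treeio import Msa, leaf_names, parse_newick


def bipartitions(tree):
    """Non-trivial splits of an unrooted view of the tree (test-local oracle)."""
    leaves = frozenset(leaf_names(tree))
    ref = min(leaves)
    parts = set()
    for node in tree.non_tips(include_self=False):
        side = frozenset(t.name for t in node.tips())
        if len(side) <= 1 or len(side) >= len(leaves) - 1:
            continue
        if ref in side:
            side = leaves - side
        parts.add(side)
    return parts


def make_group(tree_text, width=30):
    """A homolog group with arbitrary (identical) sequences over a tree."""
    tree = parse_newick(tree_text)
    seqs = {name: "M" * width for name in leaf_names(tree)}
    return HomologGroup("FAM", seqs, Msa(seqs), tree)


def caterpillar(n):
    text = "(L0:1,L1:1)"
    for i in range(2, n):
        text = f"({text}:1,L{i}:1)"
    return text + ";"


class TestRepresentativeCountRule:
    @pytest.mark.parametrize(
        "n,expected",
        [(200, 20), (12, 12), (1000, 100), (1, 1), (20, 20), (21, 20), (201, 21)],
    )
    def test_examples(self, n, expected):
        assert n_representatives(n, BuildConfig()) == expected

    def test_closed_form_over_range(self):
        cfg = BuildConfig()
        for n in range(1, 1001):
            k = n_representatives(n, cfg)
            assert k == min(n, max(math.ceil(n / 10), min(20, n)))
            assert 1 <= k <= n


class TestSplitLargeTree:
    def test_small_family_unsplit(self):
        group = make_group(caterpillar(10))
        split = split_large_tree(group, BuildConfig(max_subtree_size=2500))
        assert not split.is_split
        assert len(split.subtrees) == 1
        assert split.subtrees[0].outgroup is None
        assert split.supertree is None

    def test_caterpillar_partition_and_supertree(self):
        group = make_group(caterpillar(10))
        split = split_large_tree(group, BuildConfig(max_subtree_size=4))
        assert split.is_split
        union = set()
        for st in split.subtrees:
            assert len(st.members) <= 4
            assert union.isdisjoint(st.members)
            union.update(st.members)
        assert union == set(leaf_names(group.tree))
        assert len(list(split.supertree.tips())) == len(split.subtrees)

    def test_each_block_is_clade_or_clade_plus_sibling_singleton(self):
        group = make_group(caterpillar(10))
        split = split_large_tree(group, BuildConfig(max_subtree_size=4))
        for st in split.subtrees:
            members = set(st.members)
            lca = group.tree.lca(sorted(members)) if len(members) > 1 else None
            if lca is None:
                continue  # a singleton block is trivially connected
            under = {t.name for t in lca.tips()}
            if under == members:
                continue  # a clean clade
            # otherwise: a clade plus singleton leaves that hang directly
            # off the spanning node (the merged-singleton case)
            extra = under - members
            for name in extra:
                leaf = next(t for t in lca.tips() if t.name == name)
                assert leaf.parent is lca

    @pytest.mark.parametrize("n,max_size", [(12, 5), (10, 3), (16, 6)])
    def test_supertree_matches_contraction_oracle(self, n, max_size):
        # oracle: a supertree bipartition <=> an original-tree bipartition
        # whose two sides touch disjoint block sets
        group = make_group(caterpillar(n))
        split = split_large_tree(group, BuildConfig(max_subtree_size=max_size))
        assignment = {g: st.subtree_id for st in split.subtrees for g in st.members}
        all_blocks = frozenset(assignment.values())
        ref_block = min(all_blocks)
        expected = set()
        all_genes = set(leaf_names(group.tree))
        for part in bipartitions(group.tree):
            inside = frozenset(assignment[g] for g in part)
            outside = frozenset(assignment[g] for g in all_genes - set(part))
            if inside & outside:
                continue  # the split cuts through a block
            side = outside if ref_block in inside else inside
            if 2 <= len(side) <= len(all_blocks) - 2:
                expected.add(side)
        assert bipartitions(split.supertree) == expected

    @pytest.mark.parametrize("seed,max_size", [(0, 3), (1, 5), (2, 7), (3, 11), (4, 4)])
    def test_partition_and_size_bound_on_random_trees(self, seed, max_size):
        cfg = SimConfig(seed=seed, n_families=1, n_species=8, seq_len=60, dup_rate=1.5)
        families, _, _ = simulate_families(cfg)
        tree = families[0].group.tree
        blocks = _member_blocks(tree, max_size)
        union = []
        for b in blocks:
            assert 1 <= len(b) <= max_size
            union.extend(b)
        assert sorted(union) == sorted(leaf_names(tree))

    def test_balanced_large_tree_member_bound(self):
        # 6000-leaf balanced tree, cap 2500: all blocks within bound, covering
        depth = 13  # 8192 leaves
        text = "L"
        for _ in range(depth):
            text = f"({text},{text})"
        # make labels unique
        counter = [0]

        def relabel(s):
            out = []
            for ch in s:
                if ch == "L":
                    out.append(f"L{counter[0]}")
                    counter[0] += 1
                else:
                    out.append(ch)
            return "".join(out)

        tree = parse_newick(relabel(text) + ";")
        blocks = _member_blocks(tree, 2500)
        sizes = [len(b) for b in blocks]
        assert max(sizes) <= 2500
        assert sum(sizes) == 8192


class TestSelectOutgroup:
    def test_nearest_by_branch_length(self):
        tree = parse_newick("((a:1,b:1):1,(c:1,d:5):1);")
        assert select_outgroup(tree, {"a", "b"}) == "c"

    def test_only_candidate(self):
        tree = parse_newick("((a:1,b:1):1,c:1);")
        assert select_outgroup(tree, {"a", "b"}) == "c"

    def test_lexicographic_tie_break(self):
        tree = parse_newick("((a:1,b:1):1,(d:1,c:1):1);")
        assert select_outgroup(tree, {"a", "b"}) == "c"

    def test_all_members_rejected(self):
        tree = parse_newick("((a:1,b:1):1,c:1);")
        with pytest.raises(Exception):
            select_outgroup(tree, {"a", "b", "c"})


class TestExtractSubMsa:
    def test_restriction_without_gap_columns(self):
        msa = Msa({"a": "M-K", "b": "MAK", "c": "MA-"})
        sub = extract_sub_msa(msa, {"a", "b"})
        assert sub.rows == {"a": "M-K", "b": "MAK"}

    def test_all_gap_column_dropped(self):
        msa = Msa({"a": "M-K", "b": "M-K", "c": "MAK"})
        sub = extract_sub_msa(msa, {"a", "b"})
        assert sub.rows == {"a": "MK", "b": "MK"}

    def test_identity_when_all_rows(self):
        msa = Msa({"a": "M-K", "b": "MAK"})
        assert extract_sub_msa(msa, {"a", "b"}) == msa

    def test_unknown_id_rejected(self):
        msa = Msa({"a": "MK"})
        with pytest.raises(Exception, match="zz"):
            extract_sub_msa(msa, {"a", "zz"})


class TestSelectRepresentatives:
    def test_all_genes_when_k_equals_n(self):
        msa = Msa({f"g{i:02d}": "MKVW" for i in range(12)})
        reps = select_representatives(msa, BuildConfig())
        assert reps == sorted(msa.ids)

    def test_two_clusters_yield_in_cluster_representatives(self):
        rng = np.random.default_rng(0)
        rows = {}
        for i in range(100):  # cluster A: alanine-rich
            row = list("A" * 40)
            row[int(rng.integers(40))] = "C"
            rows[f"a{i:03d}"] = "".join(row)
        for i in range(100):  # cluster B: tryptophan-rich
            row = list("W" * 40)
            row[int(rng.integers(40))] = "Y"
            rows[f"b{i:03d}"] = "".join(row)
        msa = Msa(rows)
        reps = select_representatives(msa, BuildConfig(seed=1))
        assert len(reps) == 20
        assert len(set(reps)) == 20
        for rid in reps:
            # a representative of a cluster must be a member of that cluster
            assert rows[rid].count("A") > 30 or rows[rid].count("W") > 30

    def test_fixed_seed_determinism(self):
        rng = np.random.default_rng(3)
        rows = {
            f"g{i:03d}": "".join(
                rng.choice(list("ACDEFGHIKLMNPQRSTVWY"), size=25)
            )
            for i in range(250)
        }
        msa = Msa(rows)
        r1 = select_representatives(msa, BuildConfig(seed=9))
        r2 = select_representatives(msa, BuildConfig(seed=9))
        assert r1 == r2
        assert len(r1) == n_representatives(250, BuildConfig())


class TestBuild:
    def test_profile_counts_for_small_families(self):
        groups = []
        smap = {}
        for fam, n in [("A", 10), ("B", 15), ("C", 30)]:
            cfg = SimConfig(seed=ord(fam), n_families=1, n_species=5,
                            seq_len=60, dup_rate=2.0)
            while True:
                fams, m, _ = simulate_families(cfg)
                if fams[0].group.size >= n:
                    break
                cfg = SimConfig(seed=cfg.seed + 100, n_families=1, n_species=5,
                                seq_len=60, dup_rate=2.0)
            group = fams[0].group
            keep = sorted(group.sequences)[:n]
            tree = induced_subtree(group.tree, keep)
            for tip in tree.tips():  # make ids unique across the test families
                tip.name = f"{fam}_{tip.name}"
            seqs = {f"{fam}_{g}": group.sequences[g] for g in keep}
            msa = extract_sub_msa(group.msa, keep)
            msa = Msa({f"{fam}_{g}": row for g, row in msa.items()})
            groups.append(HomologGroup(fam, seqs, msa, tree))
            smap.update({f"{fam}_{g}": m[g] for g in keep})
        db = build(groups, smap, BuildConfig())
        counts = {
            fam: sum(len(r) for r in e.representatives.values())
            for fam, e in db.families.items()
        }
        assert counts == {"A": 10, "B": 15, "C": 20}

    def test_duplicate_gene_id_across_families_rejected(self):
        g1 = make_group("((x:1,y:1):1,z:1);")
        g2 = HomologGroup(
            "FAM2",
            {"x": "M" * 30, "w": "M" * 30},
            Msa({"x": "M" * 30, "w": "M" * 30}),
            parse_newick("(x:1,w:1);"),
        )
        smap = {k: "s1" for k in ["x", "y", "z", "w"]}
        with pytest.raises(Exception, match="FAM"):
            build([g1, g2], smap)

    def test_missing_species_mapping_rejected(self):
        g1 = make_group("((x:1,y:1):1,z:1);")
        with pytest.raises(Exception, match="species"):
            build([g1], {"x": "s1", "y": "s1"})
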