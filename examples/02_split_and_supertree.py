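"""Tree splitting and supertree grafting on an oversized family.

Placement cost grows with tree size, so families above a size limit are
partitioned into subtrees (each anchored by a nearby outgroup gene) linked
by a supertree.  A query is placed within one small subtree only, rooted
on the outgroup, and grafted back — the caller still receives the full
family tree.  Here the limit is lowered to 10 genes to force the path.
"""

from phyloshoot import BuildConfig, SimConfig, build, shoot_search, simulate_families
from phyloshoot.treeio import leaf_names, write_newick

families, species_map, _ = simulate_families(
    SimConfig(seed=5, n_families=2, n_species=10, seq_len=200, dup_rate=1.2)
)
db = build(
    [f.group for f in families], species_map,
    BuildConfig(seed=5, max_subtree_size=10),
)

for fam, entry in db.families.items():
    mark = "SPLIT" if entry.split.is_split else "unsplit"
    sizes = [len(st.members) for st in entry.split.subtrees]
    print(f"{fam}: {entry.group.size} genes -> {mark}, subtree sizes {sizes}")
    if entry.split.is_split:
        print(f"  supertree: {write_newick(entry.split.supertree)}")
        for st in entry.split.subtrees:
            print(f"  {st.subtree_id}: outgroup = {st.outgroup}")

fam = next(f for f, e in db.families.items() if e.split.is_split)
query_seq = next(iter(db.families[fam].group.sequences.values()))
res = shoot_search(query_seq, db, query_id="Q")[0]
n_family = db.families[fam].group.size
print(f"\nquery placed via subtree {res.subtree_id}; grafted result has "
      f"{len(leaf_names(res.tree))} leaves "
      f"(= {n_family} family genes + the query)")
print("The subtree is placed in, the outgroup dropped, and the supertree "
      "restores the between-subtree topology.")
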