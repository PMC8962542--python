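"""Build a database from simulated gene families and place a query.

The simulator stands in for an upstream orthology workflow: it emits, for
each family, the protein sequences, their alignment and a rooted gene
tree.  The builder turns those into a searchable database; the search
aligns a query against the representative profiles, places it on the best
family's pre-computed tree, and labels orthologs by species overlap.
"""

from phyloshoot import BuildConfig, SimConfig, build, shoot_search, simulate_families
from phyloshoot.evalharness import closest_ranking
from phyloshoot.treeio import write_newick

families, species_map, _ = simulate_families(
    SimConfig(seed=4, n_families=8, n_species=8, seq_len=200)
)
db = build([f.group for f in families], species_map, BuildConfig(seed=4))
print(f"database: {len(db.families)} families, "
      f"{sum(f.group.size for f in families)} genes")

# take one database gene's sequence as the "novel" query
donor_family = families[0].group
query_gene, query_seq = next(iter(donor_family.sequences.items()))
results = shoot_search(query_seq, db, query_id="my_query")

res = results[0]
print(f"\nquery assigned to family {res.family_id} "
      f"(best-hit e-value {res.best_hit.evalue:.2e})")
print(f"placement parsimony cost: {res.placement_cost:.0f}")
print(f"result tree: {write_newick(res.tree)[:120]}...")
print(f"nearest database gene: {closest_ranking(res)[0]} "
      f"(the donor was {query_gene})")
print("\northolog table (species overlap):")
print(res.orthologs.to_string(index=False))
print("\nEach row is a database gene; 'ortholog' means its last common "
      "ancestor with the query is a speciation node, 'paralog' a duplication.")
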