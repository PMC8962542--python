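"""Run the cherry leave-one-out benchmark on a simulated database.

High-support cherries (mutual sister pairs) give test cases with a known
correct answer: prune one member, search for it, and check that its sister
comes back as the nearest gene.  The same runs also score MAP@k of the
distance ranking, ortholog precision/recall/F against the generator truth,
and the Robinson-Foulds distance between original and re-placed trees.
"""

from phyloshoot import BuildConfig, SimConfig, build, run_benchmark, simulate_families
from phyloshoot.simfixtures import SimTruth

families, species_map, _ = simulate_families(
    SimConfig(seed=2, n_families=12, n_species=10, seq_len=300)
)
db = build([f.group for f in families], species_map, BuildConfig(seed=2))
truth = SimTruth(families={f.group.family_id: f.truth for f in families})

report = run_benchmark(db, truth, k_max=10)

print(f"families: {report['n_families']}, cherry cases: {report['n_cherry_cases']}")
print(f"closest-gene accuracy: {report['closest_gene_accuracy']:.2%} "
      "(fraction of pruned genes whose sister is recovered as nearest)")
print(f"MAP@10: {report['map_at_kmax']:.2%} "
      "(agreement of predicted vs true closest-homolog rankings)")
print(f"ortholog P/R/F: {report['ortholog_precision']:.2f} / "
      f"{report['ortholog_recall']:.2f} / {report['ortholog_fscore']:.2f}")
print(f"mean re-placement RF: {report['placement_rf_mean']:.4f} "
      f"({report['placement_rf_zero_fraction']:.0%} of cases identical to "
      "the original tree)")
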