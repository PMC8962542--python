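"""Shared fixtures: simulated families and databases built from them.

Everything is generated programmatically with fixed seeds, so the suite
needs no data files and is reproducible bit-for-bit.
"""

from __future__ import annotations

import pytest

from phyloshoot.dbbuild import BuildConfig, build
from phyloshoot.simfixtures import SimConfig, SimTruth, simulate_families


@pytest.fixture(scope="session")
def small_sim():
    """Six small noiseless families on eight species."""
    cfg = SimConfig(seed=0, n_families=6, n_species=8, seq_len=120)
    families, species_map, species_tree = simulate_families(cfg)
    return families, species_map, species_tree


@pytest.fixture(scope="session")
def small_db(small_sim):
    families, species_map, _ = small_sim
    return build([f.group for f in families], species_map, BuildConfig(seed=0))


@pytest.fixture(scope="session")
def small_truth(small_sim):
    families, _, _ = small_sim
    return SimTruth(families={f.group.family_id: f.truth for f in families})


@pytest.fixture(scope="session")
def dup_sim():
    """Duplication-rich families (larger trees, still loss-free)."""
    cfg = SimConfig(seed=5, n_families=4, n_species=10, seq_len=120, dup_rate=1.2)
    families, species_map, species_tree = simulate_families(cfg)
    return families, species_map, species_tree


@pytest.fixture(scope="session")
def dup_db_split(dup_sim):
    """The duplication-rich families forced through the splitting path."""
    families, species_map, _ = dup_sim
    return build(
        [f.group for f in families], species_map,
        BuildConfig(seed=5, max_subtree_size=10),
    )


@pytest.fixture(scope="session")
def dup_db_unsplit(dup_sim):
    families, species_map, _ = dup_sim
    return build([f.group for f in families], species_map, BuildConfig(seed=5))
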