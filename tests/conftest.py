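"""Shared fixtures: hand-built toy tables and seeded synthetic studies."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from spongecore import (CountTable, RunConfig, SampleMetadata, TaxonomyTable,
                        generate, run_all)
from spongecore.synthetic import SimulationParams, SpeciesSpec, SWPoolSpec


@pytest.fixture
def toy_table() -> CountTable:
    """3 sponge species × 3 replicates + 3 water samples, 8 taxa.

    Presence patterns are chosen so core membership, species-specificity and
    seawater sharing are all enumerable by hand.
    """
    taxa = [f"t{i}" for i in range(1, 9)]
    rows = {
        # species A: t1,t2 in all three replicates; t3 in 2/3; t4 once
        "A1": [10, 5, 3, 2, 0, 0, 0, 10],
        "A2": [8, 6, 2, 0, 0, 0, 0, 12],
        "A3": [12, 4, 0, 0, 0, 0, 0, 9],
        # species B: t2,t5 in all; t6 in all → shared with C
        "B1": [0, 7, 0, 0, 9, 4, 0, 5],
        "B2": [0, 6, 0, 0, 8, 3, 0, 4],
        "B3": [0, 5, 0, 0, 10, 5, 0, 6],
        # species C: t6,t7 in all
        "C1": [0, 0, 0, 0, 0, 6, 11, 2],
        "C2": [0, 0, 0, 0, 0, 7, 9, 3],
        "C3": [0, 0, 0, 0, 0, 5, 10, 4],
        # water: t8 everywhere; t1 in 2/3 water samples
        "W1": [3, 0, 0, 0, 0, 0, 0, 30],
        "W2": [2, 0, 0, 0, 0, 0, 0, 28],
        "W3": [0, 0, 0, 0, 0, 0, 0, 33],
    }
    return CountTable(pd.DataFrame.from_dict(rows, orient="index", columns=taxa))


@pytest.fixture
def toy_meta() -> SampleMetadata:
    rows = []
    for s in ["A1", "A2", "A3", "B1", "B2", "B3", "C1", "C2", "C3"]:
        rows.append({"sample_id": s, "group": f"sponge {s[0]}",
                     "habitat_class": "HMA" if s[0] == "A" else "LMA",
                     "location": "site1", "replicate": int(s[1])})
    for s in ["W1", "W2", "W3"]:
        rows.append({"sample_id": s, "group": "seawater", "habitat_class": "SW",
                     "location": "site1", "replicate": int(s[1])})
    return SampleMetadata(pd.DataFrame(rows).set_index("sample_id"))


@pytest.fixture
def toy_taxonomy(toy_table) -> TaxonomyTable:
    lineages = {
        "t1": ("Proteobacteria", "Alphaproteobacteria"),
        "t2": ("Proteobacteria", "Gammaproteobacteria"),
        "t3": ("Proteobacteria", "Betaproteobacteria"),
        "t4": ("Chloroflexi", "Anaerolineae"),
        "t5": ("Chloroflexi", "Anaerolineae"),
        "t6": ("Cyanobacteria", "Cyanobacteriia"),
        "t7": (None, None),
        "t8": ("Bacteroidetes", "Bacteroidia"),
    }
    df = pd.DataFrame(
        {"domain": "Bacteria",
         "phylum": [lineages[t][0] for t in toy_table.taxon_ids],
         "class": [lineages[t][1] for t in toy_table.taxon_ids]},
        index=pd.Index(toy_table.taxon_ids, name="taxon_id"))
    return TaxonomyTable(df)


def small_params(seed: int = 0, transient: float = 0.1, depth: int = 20_000,
                 **overrides) -> SimulationParams:
    """A fast four-species simulation for unit/property tests."""
    pool = SWPoolSpec(n_abundant=6, n_mid=20, n_rare_cosmo=6,
                      n_shared_hma=20, n_shared_lma=60, n_tail=50,
                      rare_cosmo_abundance=(4e-5, 6e-5))
    species = [
        SpeciesSpec("host alpha", 3, True, 28, 4, 12, rare_sw_core_share=0.3,
                    abundant_sw_core_share=0.2, specific_share=0.1),
        SpeciesSpec("host beta", 3, True, 26, 3, 11, rare_sw_core_share=0.2,
                    abundant_sw_core_share=0.4, specific_share=0.05),
        SpeciesSpec("host gamma", 2, False, 20, 0, 8,
                    abundant_sw_core_share=0.3),
        SpeciesSpec("host delta", 4, False, 25, 5, 8,
                    abundant_sw_core_share=0.25, specific_share=0.08),
    ]
    kwargs = dict(species=species, sw_pool=pool, n_sw_samples=9, depth=depth,
                  transient_fraction=transient, min_core_weight=1e-3, seed=seed)
    kwargs.update(overrides)
    return SimulationParams(**kwargs)


@pytest.fixture(scope="session")
def small_sim():
    params = small_params(seed=3)
    return params, generate(params)


@pytest.fixture(scope="session")
def study_sim():
    """Default 19-species study simulation (seed 0) — the acceptance dataset."""
    params = SimulationParams.default_study(seed=0)
    return params, generate(params)


@pytest.fixture(scope="session")
def study_run(study_sim):
    """Full pipeline run on the default simulation (199 permutations)."""
    params, (table, meta, taxonomy, truth) = study_sim
    config = RunConfig(n_permutations=199, seed=1)
    return run_all(table, meta, taxonomy=taxonomy, config=config)
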