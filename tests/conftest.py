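import numpy as np
import pandas as pd
import pytest

from targetscreen import (BiodomainMap, GeneSetCollection, ProteinMatrix,
                          RunConfig, SimulationConfig)
from targetscreen.simulate import simulate_all


@pytest.fixture()
def tiny_collection():
    coll = GeneSetCollection()
    coll.add("S1", "first", ["g1", "g2", "g3"])
    coll.add("S2", "second", ["g2", "g4"])
    return coll


@pytest.fixture()
def tiny_bdmap():
    return BiodomainMap({"S1": ("Immune Response",),
                         "S2": ("Immune Response", "Apoptosis")})


@pytest.fixture()
def tiny_matrix():
    values = pd.DataFrame(
        {"s1": [1.0, 2.0, np.nan], "s2": [4.0, np.nan, 6.0]},
        index=["p1", "p2", "p3"],
    )
    samples = pd.DataFrame(
        {"target": ["ctrl", "T01"], "cell_line": ["scramble", "scramble"],
         "replicate": ["1", "1"]},
        index=pd.Index(["s1", "s2"], name="sample"),
    )
    return ProteinMatrix(values, samples)


def small_sim_config(**overrides) -> SimulationConfig:
    """A scaled-down synthetic study for fast unit tests."""
    params = dict(
        n_targets=6, n_dual_evidence=2, n_assay_only=1,
        n_proteins=400, n_terms=24, term_size_range=(8, 15),
        genes_per_domain=50,
        assay_design={"alamarBlue": (3, 3), "MitoTracker": (3, 3),
                      "phagocytosis": (3, 3), "NFkB": (3, 3)},
        replicates_per_group=4,
        n_low_quality_samples=1,
        seed=0,
    )
    params.update(overrides)
    return SimulationConfig(**params)


@pytest.fixture(scope="session")
def small_data():
    return simulate_all(small_sim_config())


@pytest.fixture()
def small_run_config():
    return RunConfig(n_permutations=199, qc_min_proteins=300,
                     min_set_size=5, seed=0)
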