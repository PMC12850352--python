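import numpy as np
import pandas as pd
import pytest

from pepsite.core import ProteinDatabase, ProteinRecord
from pepsite.io import GroupDesign
from pepsite.simulate import (
    SimulationConfig,
    inject_missingness,
    simulate_degradome,
    simulate_proteome,
)


@pytest.fixture
def toy_protein():
    return ProteinRecord("PROT", "MKLVRAGEST")


@pytest.fixture
def toy_db(toy_protein):
    return ProteinDatabase([toy_protein, ProteinRecord("OTHER", "WWWWYYYYHHHH")])


@pytest.fixture
def two_group_design():
    mapping = {f"Ctr_{i}": "Ctr" for i in range(1, 6)}
    mapping.update({f"Case_{i}": "Case" for i in range(1, 6)})
    return GroupDesign(mapping, ["Ctr", "Case"])


@pytest.fixture(scope="session")
def small_sim():
    """A fast scaled-down degradome: 8 proteins, 2 hotspots, 8/group."""
    cfg = SimulationConfig(
        seed=7, n_proteins=8, protein_length=240, hotspots_per_protein=2,
        group_sizes=(8, 8),
    )
    db = simulate_proteome(cfg)
    matrix, truth, design = simulate_degradome(db, cfg)
    observed = inject_missingness(matrix, cfg)
    return cfg, db, matrix, observed, truth, design


def random_matrix(rng, n_features=20, samples=None, missing=0.1):
    samples = samples or [f"S{i}" for i in range(6)]
    values = np.exp(rng.normal(10, 1, size=(n_features, len(samples))))
    mask = rng.random(values.shape) < missing
    values[mask] = np.nan
    return pd.DataFrame(values, index=[f"PEP{i}" for i in range(n_features)],
                        columns=samples)
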