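import numpy as np
import pytest

import dissectmap as dm


@pytest.fixture(scope="session")
def toy_model():
    """Small genome for mapper/oracle comparisons: ~100 kb over 4 scaffolds."""
    cfg = dm.SimulationConfig(
        seed=3, n_scaffolds=4, scaffold_length_range=(20_000, 30_000),
        n_reads=1000, repeat_family_count=2, repeat_copy_number=6,
    )
    return dm.build_genome(cfg), cfg


@pytest.fixture(scope="session")
def toy_reads(toy_model):
    model, cfg = toy_model
    reads, truth = dm.simulate_reads(model, cfg)
    return reads, truth


@pytest.fixture(scope="session")
def default_sim():
    """The study-condition simulation: 60 scaffolds of 50-300 kb, 200k reads,
    5% contamination, no hybrids; mapped with v=2, m=1."""
    cfg = dm.SimulationConfig(seed=1)
    model = dm.build_genome(cfg)
    reads, truth = dm.simulate_reads(model, cfg)
    table = dm.map_reads(reads, model)
    return cfg, model, reads, truth, table


def make_uniform_hits(scaffold, length_bp, density_per_kb, seed=0):
    """Synthetic hit table at a given mean density (Poisson positions)."""
    rng = np.random.default_rng(seed)
    n = rng.poisson(density_per_kb * length_bp / 1000.0)
    pos = np.sort(rng.integers(0, length_bp, n))
    import pandas as pd
    return pd.DataFrame({
        "read_id": [f"r{i}" for i in range(n)],
        "scaffold": scaffold,
        "pos0": pos,
        "strand": "+",
        "mismatches": 0,
    })
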