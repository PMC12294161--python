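import numpy as np
import pandas as pd
import pytest

from dmfkit.coverage import build_matrix, filter_complete
from dmfkit.simulate import SimulationConfig, simulate_dataset


@pytest.fixture(scope="session")
def sim():
    """Small seeded cohort shared across test modules."""
    return simulate_dataset(SimulationConfig(seed=1, n_fragments=300))


@pytest.fixture(scope="session")
def matrix(sim):
    return build_matrix(sim.calls_by_sample, sim.catalog, sim.sheet)


@pytest.fixture(scope="session")
def complete(matrix):
    return filter_complete(matrix)


@pytest.fixture()
def rng():
    return np.random.default_rng(42)


def random_genome_dict(rng, n_chrom=2, length=3000):
    """Unstructured random sequence (CCGG sites arise by chance)."""
    return {
        f"chr{i + 1}": "".join("ACGT"[b] for b in rng.integers(0, 4, size=length))
        for i in range(n_chrom)
    }


@pytest.fixture()
def random_genome(rng):
    from dmfkit.digest import Genome

    return Genome(random_genome_dict(rng))
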