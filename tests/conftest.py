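import numpy as np
import pytest

from rose.io_formats import GenomeSequence, ReadStartProfile
from rose.synthetic_data import SimulationConfig, generate_genome, simulate_read_starts


@pytest.fixture(scope="session")
def small_fixture():
    """A compact planted-promoter dataset shared by read-only tests."""
    config = SimulationConfig(n_genes=40, seed=7)
    genome, genes, truth = generate_genome(config)
    profiles = simulate_read_starts(truth, config, genome.length)
    return {
        "config": config,
        "genome": genome,
        "genes": genes,
        "truth": truth,
        "profiles": profiles,
    }


def random_profile(rng: np.random.Generator, length: int = 2000) -> ReadStartProfile:
    """A noisy profile with a few strong stacks, for oracle comparisons."""
    counts_fw: dict[int, int] = {}
    counts_rv: dict[int, int] = {}
    for counts in (counts_fw, counts_rv):
        n_noise = int(rng.integers(20, 80))
        for pos in rng.integers(1, length + 1, size=n_noise):
            counts[int(pos)] = counts.get(int(pos), 0) + int(rng.integers(1, 6))
        n_stacks = int(rng.integers(1, 8))
        for pos in rng.integers(1, length + 1, size=n_stacks):
            counts[int(pos)] = counts.get(int(pos), 0) + int(rng.integers(5, 200))
    return ReadStartProfile("s", "r1", "c1", counts_fw, counts_rv)
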