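import numpy as np
import pytest

from barcodeid import simulate as sim


@pytest.fixture(scope="session")
def coi_dataset():
    """Fixed-length protein-coding-like benchmark library (10 sp x 20 at 650 bp)."""
    return sim.simulate_dataset(sim.coi_like_config(seed=0))


@pytest.fixture(scope="session")
def small_dataset():
    """A small, strongly separated library for fast pipeline tests."""
    cfg = sim.SimulationConfig(
        n_species=5,
        records_per_species=6,
        seq_length=200,
        between_divergence=0.2,
        within_divergence=0.002,
        seed=11,
    )
    return sim.simulate_dataset(cfg)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def random_sequence(rng, length):
    return "".join(np.array(list("ACGT"))[rng.integers(0, 4, size=length)])
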