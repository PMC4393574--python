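import numpy as np
import pytest

from gshuffle.catalogue import Locus, LocusCatalogue, load_mutation_catalogue
from gshuffle.simulate import SimulationConfig


@pytest.fixture(scope="session")
def mutation_records():
    return load_mutation_catalogue()


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def make_catalogue(n_loci=5, chromosome=1, spacing_cm=20.0, effects=None, dominance=0.5):
    """A small test catalogue of loci on one chromosome."""
    effects = effects if effects is not None else [0.0] * n_loci
    return LocusCatalogue(
        [
            Locus(
                f"L{i}", chromosome, i * spacing_cm, "A", "G",
                effect_size=effects[i], dominance=dominance,
            )
            for i in range(n_loci)
        ]
    )


@pytest.fixture
def neutral_catalogue():
    return make_catalogue(n_loci=5)


@pytest.fixture
def neutral_config():
    return SimulationConfig(
        population_size=400,
        uv_mutation_rate=1.0,
        founder_boost=0,
        selection_fraction=1.0,
        fitness_noise_sd=0.0,
        selfing_probability=0.0,
        rounds=2,
        seed=0,
    )
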