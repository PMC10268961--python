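import numpy as np
import pytest
from hypothesis import settings

from isevs.chem_io import DescriptorTable
from isevs.synthetic import generate_planted_fixture

settings.register_profile("ci", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def small_fixture():
    """60 actives + 600 decoys, 10 descriptors, one planted box, no noise."""
    return generate_planted_fixture(60, 600, n_descriptors=10, n_planted=1, seed=1234)


@pytest.fixture()
def tiny_table():
    """6 molecules × 6 descriptors with a clean active box on d0–d4."""
    rng = np.random.default_rng(7)
    names = [f"d{i}" for i in range(6)]
    # actives m0-m2 near 10, decoys m3-m5 near 50 on every descriptor
    values = np.vstack(
        [
            rng.uniform(8, 12, size=(3, 6)),
            rng.uniform(40, 60, size=(3, 6)),
        ]
    )
    ids = [f"m{i}" for i in range(6)]
    return DescriptorTable(ids, names, values), np.array([1, 1, 1, 0, 0, 0])
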