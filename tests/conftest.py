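import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import antnet as an

settings.register_profile(
    "default",
    derandomize=True,
    deadline=None,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def table1():
    """The packaged 31 x 9 field incidence matrix."""
    return an.fixture_table1()


@pytest.fixture(scope="session")
def table1_binary(table1):
    return an.binarize(table1)


@pytest.fixture()
def small_matrix():
    return an.InteractionMatrix(
        ant_labels=("a1", "a2", "a3"),
        plant_labels=("p1", "p2"),
        counts=np.array([[2, 0], [5, 1], [0, 3]]),
        n_individuals_per_plant=10,
    )


def random_binary(rng, max_rows=8, max_cols=8):
    """A random binary matrix of random shape (>=2 on each side)."""
    r = rng.integers(2, max_rows + 1)
    c = rng.integers(2, max_cols + 1)
    return rng.integers(0, 2, size=(r, c))
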