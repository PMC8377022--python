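import numpy as np
import pytest

from icuenterotype.abundance import aggregate_to_rank, to_relative
from icuenterotype.synthetic import generate_cohort, worked_example_fixture


@pytest.fixture(scope="session")
def cohort():
    """One default synthetic cohort (131 samples), shared across tests."""
    return generate_cohort(seed=20210217)


@pytest.fixture(scope="session")
def genus_table(cohort):
    table, _, _ = cohort
    return aggregate_to_rank(to_relative(table), "genus")


@pytest.fixture(scope="session")
def worked_example():
    return worked_example_fixture()


@pytest.fixture()
def rng():
    return np.random.default_rng(42)


def random_distance_matrix(rng, n):
    """Random metric-ish distance matrix: Euclidean distances of random
    points, so the triangle inequality holds."""
    from scipy.spatial.distance import pdist, squareform

    pts = rng.normal(size=(n, 3))
    return squareform(pdist(pts))
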