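import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

from aflpzone.aflp_io import AFLPDataset, PopulationHierarchy

settings.register_profile("ci", deadline=None, derandomize=True, max_examples=50)
settings.load_profile("ci")


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_dataset():
    """4 individuals x 5 loci with one missing cell."""
    pheno = np.array(
        [
            [1, 0, 1, 1, 0],
            [0, 0, 1, 1, 0],
            [1, 1, 0, 0, 1],
            [0, 1, 0, -1, 1],
        ],
        dtype=np.int8,
    )
    return AFLPDataset(["a1", "a2", "b1", "b2"], [f"L{i}" for i in range(5)], pheno)


@pytest.fixture
def small_hierarchy():
    rows = [
        ("a1", "siteA", "popA", "race1"),
        ("a2", "siteA", "popA", "race1"),
        ("b1", "siteB", "popB", "race2"),
        ("b2", "siteB", "popB", "race2"),
    ]
    return PopulationHierarchy(
        pd.DataFrame(rows, columns=["individual", "site", "population", "race"])
    )


def two_pop_hierarchy(dataset):
    """Hierarchy in which the 'popN_xxx' ID prefix names site/pop/race."""
    rows = [
        (i, i.split("_")[0], i.split("_")[0], i.split("_")[0]) for i in dataset.individual_ids
    ]
    return PopulationHierarchy(
        pd.DataFrame(rows, columns=["individual", "site", "population", "race"])
    )
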