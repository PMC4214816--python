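import numpy as np
import pandas as pd
import pytest

from betascale.io import CommunityMatrix, Hierarchy
from betascale.simulate import SimConfig, simulate_dataset


@pytest.fixture(scope="session")
def study_data():
    """Study-like synthetic dataset: 2 regions x 2 areas x 5 sites x 5 points."""
    return simulate_dataset(SimConfig(seed=7))


@pytest.fixture()
def toy_hierarchy():
    frame = pd.DataFrame(
        {
            "site_id": ["s1", "s1", "s2", "s2", "s3", "s3", "s4", "s4"],
            "area_id": ["a1", "a1", "a1", "a1", "a2", "a2", "a2", "a2"],
            "region_id": ["r1", "r1", "r1", "r1", "r2", "r2", "r2", "r2"],
        },
        index=pd.Index([f"p{i}" for i in range(1, 9)], name="point_id"),
    )
    return Hierarchy(frame)


@pytest.fixture()
def toy_community(toy_hierarchy):
    rng = np.random.default_rng(3)
    data = pd.DataFrame(
        rng.poisson(2.0, size=(8, 4)).astype(float),
        index=toy_hierarchy.point_ids,
        columns=["spA", "spB", "spC", "spD"],
    )
    data.iloc[0, 0] = 5.0  # make sure no all-zero column
    return CommunityMatrix(data)
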