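import numpy as np
import pytest

from hexstream.core_math import salmon_params, trout_params
from hexstream.environment import generate_synthetic_environment
from hexstream.habitat import Cell, Reach, generate_synthetic_reach


@pytest.fixture(scope="session")
def species():
    return {"trout": trout_params(), "salmon": salmon_params()}


@pytest.fixture(scope="session")
def trout():
    return trout_params()


@pytest.fixture(scope="session")
def salmon():
    return salmon_params()


@pytest.fixture(scope="session")
def small_reach():
    return generate_synthetic_reach(8, 6, seed=11)


@pytest.fixture(scope="session")
def one_year_env():
    return generate_synthetic_environment(1, seed=5)


def make_pair_reach(shelter=(0.0, 0.5), depth=40.0, velocity=30.0, params=None):
    """Two adjacent cells, identical except for velocity-shelter fraction."""
    flows = np.array([0.5, 30.0])
    cells = []
    for i, frac in enumerate(shelter):
        cells.append(Cell(
            cellID=i, centroid=(1.5 * i, 0.0),
            corners=[(1.5 * i + np.cos(k * np.pi / 3),
                      np.sin(k * np.pi / 3)) for k in range(6)],
            area=2.598076, cellFracShelter=frac, cellFracHidingCover=0.2,
            cellDistToHide=100.0, cellFracSpawn=0.0,
            reachEnd="U" if i == 0 else "D", neighbors=[1 - i],
            lookup_flows=flows,
            lookup_depth=np.array([depth, depth]),
            lookup_velocity=np.array([velocity, velocity])))
    return Reach(cells, params)
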