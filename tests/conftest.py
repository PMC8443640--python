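import numpy as np
import pytest

from demoscope import EpochSchedule, IslandModel, PanmicticModel, Scenario


@pytest.fixture(scope="session")
def island_const():
    """Single-epoch island model used across tests: n=5, M=0.5."""
    return IslandModel(5, EpochSchedule.constant(M=0.5))


@pytest.fixture(scope="session")
def island_multi():
    """Four-connectivity-change island model (five epochs)."""
    sched = EpochSchedule(
        (0.0, 0.06, 0.5, 1.6, 2.6),
        (0.2, 0.5, 4.6, 10.0, 1.0),
        (1.0,) * 5,
    )
    return IslandModel(29, sched)


@pytest.fixture(scope="session")
def panmictic_step():
    """Panmictic size-change model: size 1 before t=2, then 5."""
    return PanmicticModel(EpochSchedule((0.0, 2.0), (0.0, 0.0), (1.0, 5.0)))


@pytest.fixture(scope="session")
def single_deme():
    return Scenario(deme_sizes=(1000.0,), samples=(0,))


@pytest.fixture(scope="session")
def grid_log():
    return np.geomspace(1e-3, 1e2, 200)
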