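import dataclasses

import numpy as np
import pytest

from ferrotherm.grid import RadialGrid
from ferrotherm.scenario import Numerics, preset_scenario


@pytest.fixture(scope="session")
def default_sphere():
    return preset_scenario("paper_default_sphere")


@pytest.fixture(scope="session")
def default_cube():
    return preset_scenario("paper_default_cube")


@pytest.fixture()
def small_grid():
    return RadialGrid.make(2e-4, 20e-3, 60e-3, 60)


def fast_numerics(**overrides) -> Numerics:
    """Coarse, short-protocol numerics for cheap end-to-end runs."""
    base = dict(cell_count=100, transport_dt=5.0, thermal_dt=1.0,
                coupling_dt=20.0, heating_duration=300.0, snapshot_interval=100.0)
    base.update(overrides)
    return Numerics(**base)


def fast_scenario(shape="sphere", **numerics_overrides):
    s = preset_scenario(f"paper_default_{shape}")
    s = s.replace(numerics=fast_numerics(**numerics_overrides))
    s.infusion = dataclasses.replace(s.infusion, infusion_duration=200.0)
    return s


@pytest.fixture()
def rng():
    return np.random.default_rng(20240817)
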