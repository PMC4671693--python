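import numpy as np
import pytest

from colonyabc.colony_model import ColonyState, LatticeConfig, ModelParams


@pytest.fixture(scope="session")
def small_cfg() -> LatticeConfig:
    """A small lattice for fast audit-mode simulations."""
    return LatticeConfig(
        width_sites=41,
        spacing_um=18.0,
        step_h=0.04,
        initial_count=60,
        initial_radius_sites=8,
        observation_times_h=(0.4,),
    )


@pytest.fixture(scope="session")
def validation_params() -> ModelParams:
    return ModelParams(motility_prob=0.1, adhesion=0.2, proliferation_prob=0.0012)


def place_agents(width: int, coords) -> ColonyState:
    """Hand-placed occupancy grid helper for summary tests."""
    occ = np.zeros((width, width), dtype=np.uint8)
    for r, c in coords:
        occ[r, c] = 1
    return ColonyState(occ)
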