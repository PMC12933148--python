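"""Shared desk-scale ocean fixtures.

Two synthetic oceans are built once per session: a ~90-box one for
cheap unit tests and oracle comparisons, and a ~200-box one for
symmetry and parameter-recovery experiments.
"""

import numpy as np
import pytest

from oceancp.element_cycles import CycleParameters, solve_equilibrium
from oceancp.grid_transport import SyntheticGridSpec, build_synthetic_transport
from oceancp.residence_time import RestoringSink
from oceancp.synthetic_ocean import make_forcing


class Ocean:
    """Bundle of grid, transport, forcing, truth parameters, equilibrium."""

    def __init__(self, spec: SyntheticGridSpec, seed: int):
        self.grid, self.A = build_synthetic_transport(spec, seed=seed)
        self.forcing = make_forcing(self.grid, seed=seed)
        self.params = CycleParameters()
        self.state = solve_equilibrium(self.params, self.A, self.forcing, self.grid)
        self.sink = RestoringSink.for_grid(self.grid)
        self.seed = seed


@pytest.fixture(scope="session")
def ocean90() -> Ocean:
    return Ocean(SyntheticGridSpec(n_lat=5, n_lon=3, n_layers=6), seed=1)


@pytest.fixture(scope="session")
def ocean200() -> Ocean:
    return Ocean(SyntheticGridSpec(n_lat=7, n_lon=4, n_layers=7), seed=5)


@pytest.fixture(scope="session")
def t_grid_short() -> np.ndarray:
    return np.concatenate([[0.0], np.geomspace(0.01, 200.0, 12)])
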