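import numpy as np
import pytest

from odontomorph.dataio import ClosedOutline
from odontomorph.simulate import (
    CrownModelParams,
    OutlineModelParams,
    default_mouse_crown,
    simulate_crown_mesh,
    simulate_outline,
)


@pytest.fixture
def unit_circle_outline() -> ClosedOutline:
    t = 2 * np.pi * np.arange(256) / 256
    return ClosedOutline(np.column_stack([np.cos(t), np.sin(t)]))


@pytest.fixture
def unit_square_outline() -> ClosedOutline:
    return ClosedOutline(np.array([[0.0, 0.0], [1.0, 0.0], [1.0, 1.0], [0.0, 1.0]]))


@pytest.fixture
def cusp_outline() -> ClosedOutline:
    """A deterministic star-shaped crown outline with cusps and mild noise."""
    return simulate_outline(OutlineModelParams(seed=7), n_points=64)


@pytest.fixture(scope="session")
def crown_params() -> CrownModelParams:
    base = default_mouse_crown()
    return CrownModelParams(a=base.a, b=base.b, h=base.h, cusps=base.cusps,
                            cusp_shift=base.cusp_shift, resolution=32)


@pytest.fixture(scope="session")
def crown_pair(crown_params):
    """(WT mesh, WT landmarks, mutant mesh, mutant landmarks) at test resolution."""
    wt, wt_lms = simulate_crown_mesh(crown_params, "WT")
    mut, mut_lms = simulate_crown_mesh(crown_params, "mutant")
    return wt, wt_lms, mut, mut_lms
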