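import numpy as np
import pytest

from eprbind.lineshape import FieldGrid
from eprbind.synthetic import NoiseSpec, generate_epr_titration, get_preset


@pytest.fixture(scope="session")
def tempone_preset():
    return get_preset("TEMPONE_CB7")


@pytest.fixture(scope="session")
def btbk_preset():
    return get_preset("BTBK_CB8")


@pytest.fixture(scope="session")
def small_grid():
    """Coarse grid for fast fitting tests."""
    return FieldGrid(center_field=3480.0, span=80.0, n_points=512)


@pytest.fixture(scope="session")
def small_tempone_series(tempone_preset, small_grid):
    """Noiseless 9-point TEMPONE titration on a coarse grid."""
    schedule = np.array([0.0, 0.1, 0.25, 0.5, 1.0, 2.0, 4.0, 7.0, 10.0]) * 1e-3
    return generate_epr_titration(
        tempone_preset, schedule=schedule, noise=NoiseSpec(), grid=small_grid
    )


@pytest.fixture(scope="session")
def tempone_templates(tempone_preset):
    """Structural templates (satellite sets) for the TEMPONE fit."""
    return {"free": tempone_preset.free, "bound": tempone_preset.bound}
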