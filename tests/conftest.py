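import numpy as np
import pytest

from zonarisk import (
    GridTransform,
    RasterGrid,
    SyntheticScenario,
    generate_predictor_stack,
    generate_true_suitability,
    sample_presences,
)
from zonarisk.pipeline import run_synthetic_study


@pytest.fixture(scope="session")
def small_scenario() -> SyntheticScenario:
    """A 30x30, 6-predictor landscape that keeps fit-based tests fast."""
    return SyntheticScenario(
        grid_shape=(30, 30),
        cell_size=0.05,
        n_predictors=6,
        collinear_pairs=((0, 4, 0.9), (1, 5, 0.8)),
        linear_coefficients=(4.0, -3.0, 2.5, 2.0, 0.0, 0.0),
        quadratic_coefficients=(-2.0, 0.0, -1.0, 0.0, 0.0, 0.0),
        intercept=-5.0,
        presence_n=60,
        seed=42,
    )


@pytest.fixture(scope="session")
def small_stack(small_scenario):
    return generate_predictor_stack(small_scenario)


@pytest.fixture(scope="session")
def small_truth(small_scenario, small_stack):
    return generate_true_suitability(
        small_stack,
        small_scenario.linear_coefficients,
        small_scenario.quadratic_coefficients,
        intercept=small_scenario.intercept,
    )


@pytest.fixture(scope="session")
def small_presences(small_scenario, small_truth):
    return sample_presences(small_truth, small_scenario.presence_n, seed=small_scenario.seed + 1)


@pytest.fixture(scope="session")
def default_study():
    """One full run on the default strong-signal landscape (documented seed 0)."""
    return run_synthetic_study(seed=0)


@pytest.fixture()
def flat_grid():
    """A 5x4 all-valid grid for raster arithmetic tests."""
    t = GridTransform(origin_lon=0.0, origin_lat=2.0, cell_size=0.5, nrows=5, ncols=4)

    def make(values, units=""):
        return RasterGrid(values=np.asarray(values, dtype=float), transform=t,
                          mask=np.zeros((5, 4), dtype=bool), units=units)

    make.transform = t
    return make
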