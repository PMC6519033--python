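import numpy as np
import pandas as pd
import pytest

from ldjump.experiments import simulate_grid_table, train_model
from ldjump.regression import fit_bias_correction, fit_gam
from ldjump.simulate import ScenarioGrid


@pytest.fixture(scope="session")
def neutral_model():
    """Full-design neutral model (999 training + 999 calibration scenarios)."""
    return train_model(theta=0.01, seed=20250)


@pytest.fixture(scope="session")
def demog_model(neutral_model):
    """Demography-trained model; Box-Cox exponent carried over from the
    neutral model, Tajima's D added to the predictors."""
    return train_model(
        theta=0.01,
        demography_tag="bottleneck_growth",
        seed=20251,
        lmbda=neutral_model.lmbda,
    )


@pytest.fixture(scope="session")
def small_model():
    """A cheap neutral model on a reduced grid, for unit-level tests."""
    grid = ScenarioGrid(
        sample_sizes=(10,),
        lengths_bp=(1000,),
        rho_values=tuple(np.linspace(0.002, 0.1, 30)),
        theta=0.01,
        replicates=3,
        seed=7,
    )
    table = simulate_grid_table(grid)
    model = fit_gam(table, training_meta={"demography_tag": "neutral"})
    calib = simulate_grid_table(
        ScenarioGrid(
            sample_sizes=(10,),
            lengths_bp=(1000,),
            rho_values=tuple(np.linspace(0.002, 0.1, 30)),
            theta=0.01,
            replicates=3,
            seed=8,
        )
    )
    return fit_bias_correction(model, calib)
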