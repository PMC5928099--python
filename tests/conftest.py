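import numpy as np
import pytest

from omzflux import CellSimParams, IncubationSimParams, IsotopeContext


@pytest.fixture
def ctx() -> IsotopeContext:
    """A simple labelling context with round numbers for hand arithmetic."""
    return IsotopeContext(r_dic=0.05, incubation_days=1.0, r_background=0.011)


@pytest.fixture
def exact_cells_params() -> CellSimParams:
    """Deterministic cells: no size spread, no rate spread, no counting noise."""
    return CellSimParams(
        n_cells=25,
        true_rate_mean=0.19,
        true_rate_cv=0.0,
        size_cv=0.0,
        counting_noise=False,
        seed=7,
    )


@pytest.fixture
def noisefree_pairing_params() -> IncubationSimParams:
    return IncubationSimParams(
        true_denitrification=10.0,
        true_anammox=0.0,
        labeled_fraction=0.5,
        noise_sd=0.0,
        seed=3,
    )


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(2024)
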