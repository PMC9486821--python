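import numpy as np
import pandas as pd
import pytest

from occomm import (
    CommunityHyper,
    MCMCConfig,
    ModelSpec,
    default_design,
    fit,
    simulate_survey,
    simulate_truth,
)


@pytest.fixture(scope="session")
def small_truth():
    return simulate_truth(CommunityHyper(), n_species=10, seed=11)


@pytest.fixture(scope="session")
def small_design():
    return default_design(n_stations=50, n_occasions=8, seed=11)


@pytest.fixture(scope="session")
def small_survey(small_truth, small_design):
    return simulate_survey(small_truth, small_design, seed=11)


@pytest.fixture(scope="session")
def small_spec(small_design):
    st = small_design.stations
    return ModelSpec(
        landuse=st["landuse"].to_numpy(),
        fmu=st["fmu"].to_numpy(),
        road=st["road"].to_numpy(),
        covariates=st[list(small_design.covariate_names)],
    )


@pytest.fixture(scope="session")
def small_fit(small_spec, small_survey):
    cfg = MCMCConfig(chains=2, iterations=500, burn_in=250, thin=5, seed=11)
    return fit(small_spec, small_survey.detections, small_survey.effort, cfg)


def toy_draws(values_by_var, coords=None):
    """Build a minimal posterior Dataset from literal per-variable arrays
    shaped (chain, draw, ...)."""
    import xarray as xr

    data = {}
    for name, (dims, vals) in values_by_var.items():
        data[name] = (dims, np.asarray(vals, dtype=float))
    return xr.Dataset(data, coords=coords or {})
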