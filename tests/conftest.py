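import numpy as np
import pandas as pd
import pytest

from stellatesim.parameters import (
    base_parameter_vector,
    load_parameter_space,
    load_validation_bounds,
)
from stellatesim.simulator import build_model, settle


@pytest.fixture(scope="session")
def space():
    return load_parameter_space()


@pytest.fixture(scope="session")
def bounds():
    return load_validation_bounds()


@pytest.fixture(scope="session")
def base_params():
    return base_parameter_vector()


@pytest.fixture(scope="session")
def base_model(base_params):
    return build_model(base_params)


@pytest.fixture(scope="session")
def base_settled(base_model):
    """(trace, state) of the base model after the 6-s zero-current settle."""
    return settle(base_model)


@pytest.fixture(scope="session")
def passive_params(base_params):
    """Base passive properties with every active conductance removed."""
    p = base_params.copy()
    for g in ("g_naf", "g_kdr", "g_hcn", "g_nap", "g_ka",
              "g_hva", "g_lva", "g_km", "g_sk"):
        p[g] = 0.0
    return p


@pytest.fixture(scope="session")
def passive_model(passive_params):
    return build_model(passive_params)


@pytest.fixture(scope="session")
def base_measurements(base_model, base_settled):
    """Full measurement battery of the base model at dt = 25 us."""
    from stellatesim.measurements import measure_all

    return measure_all(base_model, settled=base_settled)


@pytest.fixture(scope="session")
def scaled_population():
    """Scaled-down stochastic search: 5,000 sampled models at dt = 25 us.

    Shared by the search-yield and knockout-screen checks; this is the long
    pole of the suite (a few minutes).
    """
    from stellatesim.search import run_search

    return run_search(5000, seed=20)


@pytest.fixture(scope="session")
def extended_population(scaled_population):
    """The same seed-20 search extended to 10,000 models (resume reuses the
    5,000 already evaluated), to collect enough valid models for the
    knockout screen."""
    from stellatesim.search import run_search

    return run_search(10000, seed=20, resume=scaled_population)
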