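import dataclasses

import pytest

import rehabcea as r
from rehabcea.synth import TrialParams, apply_missingness, generate_trial


@pytest.fixture(scope="session")
def costing_inputs():
    """Shipped catalogue, salary table and course specs."""
    return r.load_default_costing()


@pytest.fixture(scope="session")
def catalogue(costing_inputs):
    return costing_inputs[0]


@pytest.fixture(scope="session")
def salaries(costing_inputs):
    return costing_inputs[1]


@pytest.fixture(scope="session")
def course_specs(costing_inputs):
    return costing_inputs[2]


@pytest.fixture(scope="session")
def default_params():
    return TrialParams.default()


def scaled_params(params: TrialParams, n_per_arm: int) -> TrialParams:
    return dataclasses.replace(
        params,
        lc=dataclasses.replace(params.lc, n=n_per_arm),
        standard=dataclasses.replace(params.standard, n=n_per_arm),
    )


@pytest.fixture(scope="session")
def small_trial(default_params):
    """Complete (no missingness) 120-per-arm synthetic trial."""
    return generate_trial(scaled_params(default_params, 120), seed=7)


@pytest.fixture(scope="session")
def small_masked_trial(small_trial, default_params):
    return apply_missingness(small_trial, mechanism="MAR", params=default_params, seed=8)
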