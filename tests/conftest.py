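import dataclasses

import pytest

from bphce.lifetable import constant_life_table
from bphce.parameters import base_case_parameters


@pytest.fixture(scope="session")
def base_params():
    return base_case_parameters()


@pytest.fixture(scope="session")
def immortal_params(base_params):
    """Base case with background mortality switched off, so matrix
    entries equal the raw disease transition probabilities."""
    lt = constant_life_table(base_params.settings.cohort_start_age, 0.0)
    return dataclasses.replace(base_params, life_table=lt)


def with_horizon(params, years):
    return dataclasses.replace(
        params, settings=dataclasses.replace(params.settings, horizon_years=years))
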