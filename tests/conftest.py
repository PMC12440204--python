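import numpy as np
import pytest

import spsgame as sg


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def case1_params():
    return sg.case_parameters("case1")


@pytest.fixture(scope="session")
def case2_params():
    return sg.case_parameters("case2")


@pytest.fixture(scope="session")
def case3_params():
    return sg.case_parameters("case3")


@pytest.fixture(scope="session")
def small_case1_summary():
    """A small but full-featured experiment shared across analysis tests."""
    config = sg.make_case_config("case1", n_runs=30, rounds=200, base_seed=900)
    return sg.run_experiment(config, keep_records=True)
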