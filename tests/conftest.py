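import numpy as np
import pytest

import cryptdyn as cd


@pytest.fixture(scope="session")
def globals_calibrated():
    return cd.default_global_params()


@pytest.fixture(scope="session")
def gene_specs():
    return cd.default_gene_specs()


@pytest.fixture(scope="session")
def lynch_config():
    return cd.preset("lynch-mlh1")


@pytest.fixture(scope="session")
def lynch_system(lynch_config):
    return cd.build_system_matrix(lynch_config)


@pytest.fixture(scope="session")
def lynch_trajectory(lynch_config, lynch_system):
    x0 = cd.initial_state(lynch_config, lynch_system.index)
    return cd.solve(lynch_system, x0, cd.default_age_grid())


@pytest.fixture(scope="session")
def lynch_b0_trajectory():
    cfg = cd.preset("lynch-mlh1", b_zero=True)
    return cd.simulate(cfg)


@pytest.fixture(scope="session")
def ages_grid():
    return np.arange(0.0, 71.0)
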