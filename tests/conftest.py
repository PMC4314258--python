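import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import dendrofit as df

settings.register_profile(
    "ci", derandomize=True, deadline=None, suppress_health_check=[HealthCheck.too_slow]
)
settings.load_profile("ci")

# a 19-cm beech gaining ~0.46 cm over the season, weekly sampling
TREE_TRUTH = df.LG5Params(L=19.0, K=19.46, doy_ip=170.0, r=0.06, theta=1.5)

# reference best-model (Nelder-Mead) parameters for an example beech tree-year
REFERENCE_BEST = df.LG5Params(L=54.402, K=55.270, doy_ip=187.0, r=0.044, theta=3.679)


@pytest.fixture(scope="session")
def tree_truth():
    return TREE_TRUTH


@pytest.fixture(scope="session")
def reference_params():
    return REFERENCE_BEST


@pytest.fixture(scope="session")
def noiseless_series():
    return df.simulate_tree(df.SimSpec(truth=TREE_TRUTH, noise_sd=0.0, seed=1))


@pytest.fixture(scope="session")
def noisy_series():
    return df.simulate_tree(df.SimSpec(truth=TREE_TRUTH, noise_sd=0.003, seed=2))


@pytest.fixture(scope="session")
def noiseless_fit(noiseless_series):
    s = noiseless_series
    return df.fit_cascade(s.doy, s.dbh, df.CascadeConfig(seed=0))


@pytest.fixture(scope="session")
def noisy_fit(noisy_series):
    s = noisy_series
    return df.fit_cascade(s.doy, s.dbh, df.CascadeConfig(seed=0))
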