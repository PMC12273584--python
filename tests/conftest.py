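import numpy as np
import pytest
from hypothesis import settings

from liggrad import fcs, reaction_diffusion as rd

settings.register_profile("default", derandomize=True, deadline=None)
settings.load_profile("default")


@pytest.fixture(scope="session")
def default_kinetics():
    return rd.KineticParams()


@pytest.fixture(scope="session")
def coarse_grid():
    """Fast grid for unit tests; acceptance tests use the default grid."""
    return rd.build_grid(10.0, 100.0, 200)


@pytest.fixture(scope="session")
def truth_acf():
    return fcs.AcfParams(N=1.0, T=0.15, tau_triplet=5e-6, tau_D=1e-4, kappa=5.0)


@pytest.fixture(scope="session")
def noiseless_curve(truth_acf):
    from liggrad.synthetic import default_lag_grid

    lags = default_lag_grid()
    return fcs.AutocorrelationCurve(lags=lags, values=fcs.acf_model(lags, truth_acf))
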