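import numpy as np
import pytest

from seizurepath import adf, model


@pytest.fixture(scope="session")
def mats400():
    return model.build_matrices(dt=1.0 / 400.0)


@pytest.fixture(scope="session")
def sigmoid():
    return model.SigmoidParams()


def make_belief(rng, state_scale: float, param_frac: float = 0.2):
    """Random full-covariance belief around the reference operating point."""
    theta0 = model.reference_params().as_vector()
    mu = np.zeros(model.N_XI)
    mu[:model.N_X] = rng.normal(0.0, 0.004, model.N_X)
    mu[model.N_X:] = theta0 * (1.0 + rng.normal(0.0, 0.2, 5))
    sd = np.concatenate([np.full(model.N_X, state_scale),
                         param_frac * np.abs(theta0)])
    M = rng.normal(0.0, 1.0, (model.N_XI, 2 * model.N_XI))
    R = M @ M.T / (2 * model.N_XI)
    d = np.sqrt(np.diag(R))
    corr = R / np.outer(d, d)
    P = corr * np.outer(sd, sd)
    return adf.GaussianBelief(mean=mu, cov=0.5 * (P + P.T))
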