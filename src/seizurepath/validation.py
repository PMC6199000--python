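"""Sampling-based oracles for validating the semi-analytic moment propagation.

These routines propagate Gaussian beliefs through one step of the neural-mass
map by brute-force sampling, entirely bypassing the closed-form moment
machinery in :mod:`seizurepath._kernels` — they share only the model
definition (matrices and the sigmoid itself).  Scrambled-Sobol quasi-Monte-
Carlo sampling keeps the actual integration error well below the iid
Monte-Carlo standard error for the same sample count, so comparisons at the
iid 3-SE level are conservative.
"""

from __future__ import annotations

import numpy as np

from .adf import GaussianBelief
from .model import N_SYNAPSES, N_X, N_XI, SigmoidParams, SystemMatrices, \
    erf_sigmoid, erf_sigmoid_slope

__all__ = ["sample_gaussian_qmc", "mc_propagate_belief", "mc_sigmoid_moments"]


def sample_gaussian_qmc(mean: np.ndarray, cov: np.ndarray, n: int,
                        seed: int) -> np.ndarray:
    """Draw ``n`` samples from N(mean, cov) with scrambled Sobol points."""
    from scipy.stats import qmc
    mean = np.asarray(mean, dtype=float)
    dim = mean.size
    m = int(np.ceil(np.log2(max(n, 2))))
    eng = qmc.MultivariateNormalQMC(
        mean=np.zeros(dim), cov=np.asarray(cov, dtype=float),
        engine=qmc.Sobol(d=dim, scramble=True, rng=seed))
    return mean + eng.random(2 ** m)[:n]


def mc_propagate_belief(belief: GaussianBelief, mats: SystemMatrices,
                        Q: np.ndarray, sp: SigmoidParams = SigmoidParams(),
                        n: int = 10 ** 6, seed: int = 0):
    """Sample-based mean/cov of A xi + B g(xi) + w under the belief.

    Returns (mean, cov, se_mean, se_cov): the sampling estimates plus iid
    Monte-Carlo standard errors for every component (Gaussian fourth-moment
    formula for the covariance entries).
    """
    X = sample_gaussian_qmc(belief.mean, belief.cov, n, seed)
    G = np.zeros_like(X)
    for s in range(N_SYNAPSES):
        zrow = 2 * s + 1
        vpre = X @ mats.C[zrow]
        G[:, zrow] = X[:, N_X + 1 + s] * erf_sigmoid(vpre, sp)
    Y = X @ mats.A.T + G @ mats.B.T
    mean = Y.mean(axis=0)
    cov = np.cov(Y.T) + Q
    se_mean = np.sqrt(np.diag(cov).clip(0) / n)
    d = np.diag(cov) - np.diag(Q)
    cov_noq = cov - Q
    se_cov = np.sqrt((np.outer(d, d) + cov_noq ** 2).clip(0) / n)
    return mean, cov, se_mean, se_cov


def mc_sigmoid_moments(m: float, s2: float, sp: SigmoidParams = SigmoidParams(),
                       n: int = 10 ** 7, seed: int = 0):
    """Sample-based E[phi(v)] and E[phi'(v)] for v ~ N(m, s2).

    Returns (mean_phi, mean_slope, se_phi, se_slope) with iid standard errors.
    """
    v = sample_gaussian_qmc(np.array([m]), np.array([[max(s2, 0.0)]]),
                            n, seed)[:, 0]
    ph = erf_sigmoid(v, sp)
    sl = erf_sigmoid_slope(v, sp)
    return (float(ph.mean()), float(sl.mean()),
            float(ph.std(ddof=1) / np.sqrt(n)), float(sl.std(ddof=1) / np.sqrt(n)))
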