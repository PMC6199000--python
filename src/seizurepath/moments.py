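"""Gaussian expectations of the erf firing-rate sigmoid and its derivatives.

These are the semi-analytic building blocks of the assumed-density filter: the
erf sigmoid is the CDF of a normal with mean ``v0`` and variance
``varsigma^2/2``, so its expectation under a Gaussian belief is again an erf,
and expectations of its derivatives follow by differentiating under the
integral.  Products of sigmoids over a bivariate Gaussian reduce to the
bivariate normal CDF (see :func:`seizurepath._kernels.pair_phi_moments`).
"""

from __future__ import annotations

import numpy as np

from . import _kernels
from .model import SigmoidParams

__all__ = ["gaussian_sigmoid_mean", "gaussian_sigmoid_slope_mean", "bvn_cdf"]


def _check_s2(s2) -> np.ndarray:
    s2 = np.asarray(s2, dtype=float)
    if np.any(s2 < 0):
        raise ValueError("variance s2 must be non-negative")
    return s2


def gaussian_sigmoid_mean(m, s2, sp: SigmoidParams = SigmoidParams()):
    """E[phi(v)] for v ~ N(m, s2).

    Equals ``(1 + erf((m - v0) / sqrt(varsigma^2 + 2 s2))) / 2``; reduces to
    phi(m) at s2 = 0 and shrinks toward 1/2 as s2 grows.
    """
    from scipy.special import erf
    m = np.asarray(m, dtype=float)
    s2 = _check_s2(s2)
    out = 0.5 * (1.0 + erf((m - sp.v0) / np.sqrt(sp.varsigma ** 2 + 2.0 * s2)))
    return out if out.ndim else float(out)


def gaussian_sigmoid_slope_mean(m, s2, sp: SigmoidParams = SigmoidParams()):
    """E[phi'(v)] for v ~ N(m, s2), in 1/volts.

    Equals ``exp(-(m - v0)^2 / (varsigma^2 + 2 s2)) / sqrt(pi (varsigma^2 + 2 s2))``;
    reduces to phi'(m) at s2 = 0 and flattens to 0 for large s2.
    """
    m = np.asarray(m, dtype=float)
    s2 = _check_s2(s2)
    d = sp.varsigma ** 2 + 2.0 * s2
    out = np.exp(-((m - sp.v0) ** 2) / d) / np.sqrt(np.pi * d)
    return out if out.ndim else float(out)


def bvn_cdf(h: float, k: float, rho: float) -> float:
    """Standard bivariate normal CDF P(X <= h, Y <= k), correlation ``rho``."""
    return float(_kernels.bvn_cdf(float(h), float(k), float(rho)))
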