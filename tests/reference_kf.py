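"""Independent textbook Kalman filter used as an oracle in tests.

Deliberately implemented from the standard equations with plain numpy —
no code shared with seizurepath.adf beyond the system matrices it is given.
"""

import numpy as np


def textbook_kalman(y, F, H, Q, R, mu0, P0):
    """Standard linear Kalman filter; returns per-sample means and covariances.

    F is the full state-transition matrix, H the (1, n) observation row.
    Covariance update uses the plain (I - K H) P form.
    """
    n_dim = mu0.size
    H = H.reshape(1, n_dim)
    mu = mu0.copy()
    P = P0.copy()
    means = np.zeros((len(y), n_dim))
    covs = np.zeros((len(y), n_dim, n_dim))
    I = np.eye(n_dim)
    for t, yt in enumerate(y):
        mu = F @ mu
        P = F @ P @ F.T + Q
        S = H @ P @ H.T + R
        K = (P @ H.T) / S
        mu = mu + (K * (yt - H @ mu)).ravel()
        P = (I - K @ H) @ P
        means[t] = mu
        covs[t] = P
    return means, covs
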