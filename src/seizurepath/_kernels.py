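"""Numba kernels: Gaussian sigmoid moments, moment propagation, filter loops.

Everything here operates on plain float64 arrays with the fixed state layout of
:mod:`seizurepath.model` (8 synaptic states followed by 5 parameters).  The
public, documented API lives in :mod:`seizurepath.moments` and
:mod:`seizurepath.adf`; those call straight into these kernels so there is a
single implementation of every formula.

The nonlinear vector of the augmented model is g(xi) with entries
``g[2s+1] = theta_s * phi(c_s . xi)`` at the z-rows (theta_s the gain of
synapse s, c_s the pre-synaptic-potential row of C).  Propagating a Gaussian
belief through one step ``xi' = A xi + B g(xi) + w`` needs

* E[theta phi(v)] and Cov(xi, theta phi(v))   -> Stein's identity plus the
  closed-form Gaussian expectations of phi, phi', phi'';
* Cov(theta_s phi(v_s), theta_r phi(v_r))     -> iterated Stein identities,
  reducing to E[phi phi], E[phi' phi], E[phi' phi'] and E[phi'' phi] under a
  bivariate Gaussian.  With the erf sigmoid phi(v) = P(X <= v),
  X ~ N(v0, varsigma^2/2), these are all elementary given the bivariate
  normal CDF, for which we use the Genz/Drezner–Wesolowsky quadrature.

All expressions are exact (no linearization, no sigma points); the only
numerical component is the 20-point Gauss–Legendre rule inside the bivariate
CDF, accurate to ~1e-15.
"""

import math

import numpy as np
from numba import njit

N_SYN = 4
N_X = 8
N_XI = 13
SQ2PI = math.sqrt(2.0 * math.pi)

# 20-point Gauss-Legendre nodes/weights on (0, 1) pairs (10 symmetric pairs).
_GL_X = np.array([
    0.9931285991850949, 0.9639719272779138, 0.9122344282513259,
    0.8391169718222188, 0.7463319064601508, 0.6360536807265150,
    0.5108670019508271, 0.3737060887154195, 0.2277858511416451,
    0.07652652113349734])
_GL_W = np.array([
    0.01761400713915212, 0.04060142980038694, 0.06267204833410906,
    0.08327674157670475, 0.10193011981724044, 0.11819453196151841,
    0.13168863844917664, 0.14209610931838205, 0.14917298647260374,
    0.15275338713072585])


@njit(cache=True)
def ndtr(x):
    return 0.5 * math.erfc(-x / math.sqrt(2.0))


@njit(cache=True)
def bvn_cdf(h, k, rho):
    """Standard bivariate normal P(X <= h, Y <= k) with correlation rho.

    Genz (2004) formulation of the Drezner–Wesolowsky algorithm with a
    20-point Gauss–Legendre rule and the |rho| >= 0.925 tail transformation.
    """
    if rho > 0.99999999:
        return ndtr(min(h, k))
    if rho < -0.99999999:
        return max(0.0, ndtr(h) - ndtr(-k))
    tp = 2.0 * math.pi
    hs = -h   # switch to the survival-form arguments used by the algorithm
    ks = -k
    bvn = 0.0
    if abs(rho) < 0.925:
        hk = hs * ks
        hss = (hs * hs + ks * ks) / 2.0
        asr = math.asin(rho)
        for i in range(10):
            for sgn in (-1.0, 1.0):
                sn = math.sin(asr * (sgn * _GL_X[i] + 1.0) / 2.0)
                bvn += _GL_W[i] * math.exp((sn * hk - hss) / (1.0 - sn * sn))
        return bvn * asr / (2.0 * tp) + ndtr(-hs) * ndtr(-ks)
    if rho < 0.0:
        ks = -ks
    hk = hs * ks
    ass = (1.0 - rho) * (1.0 + rho)
    a = math.sqrt(ass)
    bs = (hs - ks) ** 2
    c = (4.0 - hk) / 8.0
    d = (12.0 - hk) / 16.0
    asr = -(bs / ass + hk) / 2.0
    if asr > -100.0:
        bvn = a * math.exp(asr) * (1.0 - c * (bs - ass) * (1.0 - d * bs / 5.0) / 3.0
                                   + c * d * ass * ass / 5.0)
    if -hk < 100.0:
        b = math.sqrt(bs)
        bvn -= (math.exp(-hk / 2.0) * math.sqrt(tp) * ndtr(-b / a) * b
                * (1.0 - c * bs * (1.0 - d * bs / 5.0) / 3.0))
    a = a / 2.0
    for i in range(10):
        for sgn in (-1.0, 1.0):
            xs = (a * (sgn * _GL_X[i] + 1.0)) ** 2
            rs = math.sqrt(1.0 - xs)
            asr = -(bs / xs + hk) / 2.0
            if asr > -100.0:
                sp = 1.0 + c * xs * (1.0 + d * xs)
                ep = math.exp(-hk * (1.0 - rs) / (2.0 * (1.0 + rs))) / rs
                bvn += a * _GL_W[i] * math.exp(asr) * (ep - sp)
    bvn = -bvn / tp
    if rho > 0.0:
        return bvn + ndtr(-max(hs, ks))
    bvn = -bvn
    if ks > hs:
        bvn += ndtr(ks) - ndtr(hs)
    return bvn


@njit(cache=True)
def phi_scalar(v, v0, vs):
    """phi(v) = (erf((v - v0)/vs) + 1)/2."""
    return 0.5 * (math.erf((v - v0) / vs) + 1.0)


@njit(cache=True)
def phi_mean(m, s2, v0, vs):
    """E[phi(v)] for v ~ N(m, s2): (1 + erf((m - v0)/sqrt(vs^2 + 2 s2)))/2."""
    return 0.5 * (1.0 + math.erf((m - v0) / math.sqrt(vs * vs + 2.0 * s2)))


@njit(cache=True)
def phi_slope_mean(m, s2, v0, vs):
    """E[phi'(v)] = exp(-(m - v0)^2/(vs^2 + 2 s2)) / sqrt(pi (vs^2 + 2 s2))."""
    d = vs * vs + 2.0 * s2
    return math.exp(-(m - v0) ** 2 / d) / math.sqrt(math.pi * d)


@njit(cache=True)
def phi_curv_mean(m, s2, v0, vs):
    """E[phi''(v)] = -2 (m - v0)/(vs^2 + 2 s2) * E[phi'(v)]."""
    d = vs * vs + 2.0 * s2
    return -2.0 * (m - v0) / d * phi_slope_mean(m, s2, v0, vs)


@njit(cache=True)
def pair_phi_moments(m1, s1sq, m2, s2sq, c12, v0, vs):
    """Bivariate-Gaussian expectations of products of phi and its derivatives.

    For (v1, v2) jointly Gaussian with means m, variances s^2, covariance c12,
    returns (E[phi1 phi2], E[phi1' phi2], E[phi1 phi2'], E[phi1' phi2'],
    E[phi1'' phi2], E[phi1 phi2'']).  Derivative expectations are the
    mean-derivatives of the bivariate CDF, all elementary.

    Degenerate pairs (v1 == v2) are the c12 = s1sq = s2sq case and remain
    strictly inside |rho| < 1 because the sigmoid's own width vs^2/2 adds to
    both marginal scales.
    """
    t1 = vs * vs / 2.0 + s1sq
    t2 = vs * vs / 2.0 + s2sq
    sd1 = math.sqrt(t1)
    sd2 = math.sqrt(t2)
    h = (m1 - v0) / sd1
    k = (m2 - v0) / sd2
    rho = c12 / (sd1 * sd2)
    if rho > 0.999999999:
        rho = 0.999999999
    elif rho < -0.999999999:
        rho = -0.999999999
    rr = math.sqrt(1.0 - rho * rho)
    e_pp = bvn_cdf(h, k, rho)                           # E[phi1 phi2]
    nh = math.exp(-0.5 * h * h) / SQ2PI
    nk = math.exp(-0.5 * k * k) / SQ2PI
    cnd_kh = ndtr((k - rho * h) / rr)
    cnd_hk = ndtr((h - rho * k) / rr)
    e_d1 = nh * cnd_kh / sd1                            # E[phi1' phi2]
    e_d2 = nk * cnd_hk / sd2                            # E[phi1 phi2']
    pdf2 = math.exp(-0.5 * (h * h - 2.0 * rho * h * k + k * k) / (rr * rr)) \
        / (2.0 * math.pi * rr)
    e_d1d2 = pdf2 / (sd1 * sd2)                         # E[phi1' phi2']
    n2 = math.exp(-0.5 * ((k - rho * h) / rr) ** 2) / SQ2PI
    e_c1 = (-h * nh * cnd_kh - rho * nh * n2 / rr) / t1  # E[phi1'' phi2]
    n3 = math.exp(-0.5 * ((h - rho * k) / rr) ** 2) / SQ2PI
    e_c2 = (-k * nk * cnd_hk - rho * nk * n3 / rr) / t2  # E[phi1 phi2'']
    return e_pp, e_d1, e_d2, e_d1d2, e_c1, e_c2


@njit(cache=True)
def predict_kernel(mu, P, A, B, C, Q, v0, vs, linear):
    """Exact mean/cov of A xi + B g(xi) + w under xi ~ N(mu, P).

    ``linear != 0`` replaces the sigmoid coupling by identity coupling
    g[2s+1] = c_s . xi (no parameter product), making the model linear; the
    propagation then reduces exactly to the Kalman prediction with
    A_eff = A + B C.
    """
    mean = np.zeros(N_XI)
    Eg = np.zeros(N_XI)
    S = np.zeros((N_XI, N_XI))       # Cov(xi, g)
    G = np.zeros((N_XI, N_XI))       # Cov(g, g)

    if linear:
        for s in range(N_SYN):
            r = 2 * s + 1
            m = 0.0
            for j in range(N_XI):
                m += C[r, j] * mu[j]
            Eg[r] = m
            for j in range(N_XI):
                acc = 0.0
                for l in range(N_XI):
                    acc += P[j, l] * C[r, l]
                S[j, r] = acc
        for s in range(N_SYN):
            for t in range(N_SYN):
                rs = 2 * s + 1
                rt = 2 * t + 1
                acc = 0.0
                for j in range(N_XI):
                    acc += C[rs, j] * S[j, rt]
                G[rs, rt] = acc
    else:
        m_v = np.zeros(N_SYN)
        s2_v = np.zeros(N_SYN)
        b_v = np.zeros((N_SYN, N_XI))    # Cov(xi, v_s)
        a_th = np.zeros((N_SYN, N_XI))   # Cov(xi, theta_s)
        mu_th = np.zeros(N_SYN)
        ef = np.zeros(N_SYN)
        Phi = np.zeros(N_SYN)
        Psi = np.zeros(N_SYN)
        for s in range(N_SYN):
            r = 2 * s + 1
            th = N_X + 1 + s
            mu_th[s] = mu[th]
            m = 0.0
            for j in range(N_XI):
                m += C[r, j] * mu[j]
            m_v[s] = m
            for j in range(N_XI):
                acc = 0.0
                for l in range(N_XI):
                    acc += P[j, l] * C[r, l]
                b_v[s, j] = acc
                a_th[s, j] = P[j, th]
            s2 = 0.0
            for j in range(N_XI):
                s2 += C[r, j] * b_v[s, j]
            if s2 < 0.0:
                s2 = 0.0
            s2_v[s] = s2
            Phi[s] = phi_mean(m_v[s], s2, v0, vs)
            Psi[s] = phi_slope_mean(m_v[s], s2, v0, vs)
        for s in range(N_SYN):
            r = 2 * s + 1
            gam = 0.0                                  # Cov(theta_s, v_s)
            for j in range(N_XI):
                gam += C[r, j] * a_th[s, j]
            ef[s] = mu_th[s] * Phi[s] + gam * Psi[s]
            Eg[r] = ef[s]
            e_thp = mu_th[s] * Psi[s] + gam * phi_curv_mean(m_v[s], s2_v[s], v0, vs)
            for j in range(N_XI):
                S[j, r] = a_th[s, j] * Phi[s] + b_v[s, j] * e_thp
        for s in range(N_SYN):
            rs = 2 * s + 1
            cs_as = 0.0                                # Cov(theta_s, v_s)
            for j in range(N_XI):
                cs_as += C[rs, j] * a_th[s, j]
            for t in range(s, N_SYN):
                rt = 2 * t + 1
                c_sr = 0.0                             # Cov(v_s, v_t)
                for j in range(N_XI):
                    c_sr += C[rs, j] * b_v[t, j]
                ct_vs = 0.0                            # Cov(theta_t, v_s)
                cs_vt = 0.0                            # Cov(theta_s, v_t)
                ct_vt = 0.0                            # Cov(theta_t, v_t)
                for j in range(N_XI):
                    ct_vs += C[rs, j] * a_th[t, j]
                    cs_vt += C[rt, j] * a_th[s, j]
                    ct_vt += C[rt, j] * a_th[t, j]
                cthth = P[N_X + 1 + s, N_X + 1 + t]
                e_pp, e_d1, e_d2, e_d1d2, e_c1, e_c2 = pair_phi_moments(
                    m_v[s], s2_v[s], m_v[t], s2_v[t], c_sr, v0, vs)
                # E[theta_s theta_t phi_s phi_t] by iterated Stein identities
                e4 = (mu_th[s] * mu_th[t] * e_pp
                      + mu_th[s] * (ct_vs * e_d1 + ct_vt * e_d2)
                      + mu_th[t] * (cs_as * e_d1 + cs_vt * e_d2)
                      + cthth * e_pp
                      + cs_as * ct_vs * e_c1
                      + cs_as * ct_vt * e_d1d2
                      + cs_vt * ct_vs * e_d1d2
                      + cs_vt * ct_vt * e_c2)
                cov_f = e4 - ef[s] * ef[t]
                G[rs, rt] = cov_f
                G[rt, rs] = cov_f

    # mean = A mu + B Eg
    for j in range(N_XI):
        acc = 0.0
        for l in range(N_XI):
            acc += A[j, l] * mu[l] + B[j, l] * Eg[l]
        mean[j] = acc
    # cov = A P A' + A S B' + B S' A' + B G B' + Q
    AP = A @ P
    cov = AP @ A.T
    ASB = (A @ S) @ B.T
    cov += ASB + ASB.T + (B @ G) @ B.T + Q
    for j in range(N_XI):
        for l in range(j + 1, N_XI):
            m = 0.5 * (cov[j, l] + cov[l, j])
            cov[j, l] = m
            cov[l, j] = m
    return mean, cov


@njit(cache=True)
def update_kernel(mu, P, H, y, R):
    """Scalar-observation Kalman update, Joseph-stabilized.

    Returns (mu_post, P_post, K, innovation, innovation_variance).
    """
    PH = np.zeros(N_XI)
    for j in range(N_XI):
        acc = 0.0
        for l in range(N_XI):
            acc += P[j, l] * H[l]
        PH[j] = acc
    s_inn = R
    for j in range(N_XI):
        s_inn += H[j] * PH[j]
    innov = y
    for j in range(N_XI):
        innov -= H[j] * mu[j]
    K = PH / s_inn
    mu_post = mu + K * innov
    # Joseph form: (I - K H) P (I - K H)' + K R K'
    IKH = -np.outer(K, H)
    for j in range(N_XI):
        IKH[j, j] += 1.0
    P_post = IKH @ P @ IKH.T + R * np.outer(K, K)
    for j in range(N_XI):
        for l in range(j + 1, N_XI):
            m = 0.5 * (P_post[j, l] + P_post[l, j])
            P_post[j, l] = m
            P_post[l, j] = m
    return mu_post, P_post, K, innov, s_inn


@njit(cache=True)
def filter_loop(y, A, B, C, H, Q, R, mu0, P0, v0, vs, linear):
    """Run the assumed-density filter over a full observation stream.

    Returns (means, variances, innovations, gains, yhat, n_valid) where
    ``n_valid`` is the number of samples before the first instability
    (non-finite estimate, non-positive innovation variance, or a covariance
    whose diagonal stays negative after one jitter repair).  Outputs beyond
    ``n_valid`` are zero-filled.
    """
    n = y.shape[0]
    means = np.zeros((n, N_XI))
    variances = np.zeros((n, N_XI))
    innovations = np.zeros(n)
    gains = np.zeros((n, N_XI))
    yhat = np.zeros(n)
    mu = mu0.copy()
    P = P0.copy()
    n_valid = n
    for t in range(n):
        if not math.isfinite(y[t]):
            n_valid = t
            break
        mu_p, P_p = predict_kernel(mu, P, A, B, C, Q, v0, vs, linear)
        ok = True
        for j in range(N_XI):
            if not math.isfinite(mu_p[j]):
                ok = False
        # one jitter repair allowed on a negative diagonal
        mind = P_p[0, 0]
        tr = 0.0
        for j in range(N_XI):
            if P_p[j, j] < mind:
                mind = P_p[j, j]
            tr += P_p[j, j]
            if not math.isfinite(P_p[j, j]):
                ok = False
        if ok and mind < 0.0:
            jit = 1e-12 * tr / N_XI
            if jit <= 0.0:
                ok = False
            else:
                for j in range(N_XI):
                    P_p[j, j] += jit
                for j in range(N_XI):
                    if P_p[j, j] < 0.0:
                        ok = False
        if not ok:
            n_valid = t
            break
        mu_u, P_u, K, innov, s_inn = update_kernel(mu_p, P_p, H, y[t], R)
        if s_inn <= 0.0 or not math.isfinite(innov):
            n_valid = t
            break
        mu = mu_u
        P = P_u
        means[t] = mu
        for j in range(N_XI):
            variances[t, j] = P[j, j]
        innovations[t] = innov
        gains[t] = K
        hy = 0.0
        for j in range(N_XI):
            hy += H[j] * mu[j]
        yhat[t] = hy
    return means, variances, innovations, gains, yhat, n_valid


@njit(cache=True)
def simulate_loop(A, B, C, theta_traj, z_noise, x0, v0, vs):
    """Euler-integrate the model with a prescribed parameter trajectory.

    theta_traj is (T, 5); z_noise (T, 4) is added to the z-states after each
    step.  Returns the (T, N_XI) state trajectory (theta block echoing the
    prescribed values) and the noise-free observation H xi.
    """
    n = theta_traj.shape[0]
    states = np.zeros((n, N_XI))
    y = np.zeros(n)
    xi = np.zeros(N_XI)
    for j in range(N_X):
        xi[j] = x0[j]
    for t in range(n):
        for j in range(5):
            xi[N_X + j] = theta_traj[t, j]
        nxt = np.zeros(N_XI)
        for j in range(N_XI):
            acc = 0.0
            for l in range(N_XI):
                acc += A[j, l] * xi[l]
            nxt[j] = acc
        for s in range(N_SYN):
            r = 2 * s + 1
            vpre = 0.0
            for l in range(N_XI):
                vpre += C[r, l] * xi[l]
            g = xi[N_X + 1 + s] * phi_scalar(vpre, v0, vs)
            nxt[r] += B[r, r] * g + z_noise[t, s]
        for j in range(N_X):
            xi[j] = nxt[j]
        for j in range(5):
            xi[N_X + j] = theta_traj[t, j]
        states[t] = xi
        y[t] = xi[0] - xi[2] + xi[N_X]
    return states, y
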