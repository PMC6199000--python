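"""Assumed-density (Kalman) filter for joint state and connectivity estimation.

The augmented state xi = [x; theta] couples the 8 synaptic states with the 5
connectivity parameters (external input and four gains), the latter given
random-walk dynamics.  Each sample is processed in two stages:

* prediction — the Gaussian belief is pushed through the nonlinear neural-mass
  step ``xi' = A xi + B g(xi) + w`` using exact closed-form moments
  (:mod:`seizurepath._kernels`), keeping the posterior in the Gaussian family;
* update — a standard linear Kalman correction against the observed ECoG
  sample (the observation map H is linear), implemented in Joseph form for
  numerical robustness.

Because the moment propagation is exact, the filter reduces to a textbook
Kalman filter whenever the coupling is linear, and matches Monte-Carlo moment
propagation to sampling accuracy in the nonlinear case.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import _kernels
from .model import (N_THETA, N_X, N_XI, THETA_LABELS, ConnectivityParams,
                    SigmoidParams, SimulationOutput, SystemMatrices,
                    build_matrices, reference_params, simulate)

__all__ = [
    "GaussianBelief", "NoiseSpec", "FilterConfig", "FilterDiagnostics",
    "TrajectoryEstimate", "predict", "update", "initialize", "run_filter",
    "run_filter_array", "reconstruct_forward",
]


@dataclass
class GaussianBelief:
    """Gaussian belief over the augmented state: mean (13,) and covariance P."""

    mean: np.ndarray
    cov: np.ndarray

    def __post_init__(self) -> None:
        self.mean = np.asarray(self.mean, dtype=float)
        self.cov = np.asarray(self.cov, dtype=float)
        if self.mean.shape != (N_XI,) or self.cov.shape != (N_XI, N_XI):
            raise ValueError(f"belief must have dimension {N_XI}")
        asym = np.max(np.abs(self.cov - self.cov.T))
        scale = max(np.max(np.abs(self.cov)), 1.0)
        if asym > 1e-10 * scale:
            raise ValueError("covariance is not symmetric")

    @property
    def theta_mean(self) -> np.ndarray:
        return self.mean[N_X:]

    @property
    def theta_sd(self) -> np.ndarray:
        return np.sqrt(np.clip(np.diag(self.cov)[N_X:], 0.0, None))


@dataclass
class NoiseSpec:
    """Process-noise covariance Q (13 x 13) and observation variance R."""

    Q: np.ndarray
    R: float

    def __post_init__(self) -> None:
        self.Q = np.asarray(self.Q, dtype=float)
        if self.Q.shape != (N_XI, N_XI):
            raise ValueError(f"Q must be {N_XI} x {N_XI}")
        if not self.R > 0:
            raise ValueError("R must be > 0")


@dataclass
class FilterConfig:
    """Tunables of the estimator.

    Defaults follow a slow-parameters / fast-states split: per-step process
    noise is ``(sigma_obs * q_state_scale)^2`` on each z-state and
    ``(sigma_obs * q_param_scale)^2`` on each parameter, with sigma_obs the
    observation-noise SD (from ``r_override`` or the baseline residual).  Any
    entry can be overridden, e.g. with the generator's true noise levels when
    filtering synthetic data (a matched filter).
    """

    theta0: np.ndarray = field(
        default_factory=lambda: reference_params().as_vector())
    p0_state: float = 1e-6          # initial variance per synaptic state
    p0_param_frac: float = 0.2      # initial parameter SD as fraction of theta0
    q_state_scale: float = 1e-2     # z-state process SD relative to sigma_obs
    q_param_scale: float = 1e-4     # parameter process SD relative to sigma_obs
    q_state_sd: float | None = None     # absolute overrides (V/s, V per step)
    q_param_sd: float | np.ndarray | None = None   # scalar or per-parameter (5,)
    r_override: float | None = None
    r_highpass_hz: float | None = 100.0  # baseline high-pass for the R proxy
    sigmoid: SigmoidParams = field(default_factory=SigmoidParams)
    linear: bool = False            # identity coupling (testing/diagnostics)


@dataclass
class FilterDiagnostics:
    """Per-sample innovations and gains, stability flags, per-run MSE."""

    innovation: np.ndarray          # y - H xi_prior, volts
    gain: np.ndarray                # (T, 13) Kalman gain
    stability_flag: np.ndarray      # True where the sample produced a valid update
    mse: float                      # mean (y - H xi_post)^2 over valid samples


@dataclass
class TrajectoryEstimate:
    """Filter output for one seizure x channel.

    ``means``/``variances`` hold the posterior mean and marginal variance of
    every augmented-state entry per sample.  ``valid`` is False if the filter
    became unstable anywhere in the run; downstream analyses drop such
    trajectories.  ``n_valid`` marks the first unstable sample.
    """

    time: np.ndarray                # seconds relative to seizure onset
    means: np.ndarray               # (T, 13)
    variances: np.ndarray           # (T, 13)
    diagnostics: FilterDiagnostics
    valid: bool
    n_valid: int
    fs: float
    channel: int | str | None = None
    seizure_id: str | None = None

    @property
    def theta(self) -> np.ndarray:
        """(T, 5) posterior means of [u, alpha_ep, alpha_ip, alpha_pe, alpha_pi]."""
        return self.means[:, N_X:]

    def to_frame(self):
        import pandas as pd
        data = {"time_s": self.time}
        names = []
        for lbl in ("ep", "ip", "pe", "pi"):
            names += [f"v_{lbl}", f"z_{lbl}"]
        names += list(THETA_LABELS)
        for j, nm in enumerate(names):
            data[f"mean_{nm}"] = self.means[:, j]
        for j, nm in enumerate(names):
            data[f"var_{nm}"] = self.variances[:, j]
        df = pd.DataFrame(data)
        df.insert(1, "channel", self.channel)
        return df


def predict(belief: GaussianBelief, mats: SystemMatrices, Q: np.ndarray,
            sp: SigmoidParams = SigmoidParams(),
            linear: bool = False) -> GaussianBelief:
    """A-priori belief: exact Gaussian moments of A xi + B g(xi) + w."""
    Q = np.asarray(Q, dtype=float)
    mean, cov = _kernels.predict_kernel(
        belief.mean, belief.cov, mats.A, mats.B, mats.C, Q,
        sp.v0, sp.varsigma, 1 if linear else 0)
    if not np.all(np.isfinite(cov)):
        raise FloatingPointError("prediction produced a non-finite covariance")
    d = np.diag(cov)
    if np.any(d < 0):
        jitter = 1e-12 * np.trace(cov) / N_XI
        cov = cov + jitter * np.eye(N_XI)
        if np.any(np.diag(cov) < 0):
            raise FloatingPointError("covariance repair failed")
    return GaussianBelief(mean=mean, cov=cov)


def update(prior: GaussianBelief, y: float, H: np.ndarray, R: float):
    """Linear Kalman update against one observation.

    Returns the posterior belief and a diagnostics tuple
    (gain, innovation, innovation_variance).
    """
    if not R > 0:
        raise ValueError("R must be > 0")
    mu, P, K, innov, s_inn = _kernels.update_kernel(
        prior.mean, prior.cov, np.asarray(H, dtype=float), float(y), float(R))
    if s_inn <= 0:
        raise FloatingPointError("non-positive innovation variance")
    return GaussianBelief(mean=mu, cov=P), (K, innov, s_inn)


def initialize(baseline: np.ndarray, fs: float,
               config: FilterConfig = FilterConfig()):
    """Initial belief and noise spec from a pre-ictal baseline segment.

    The state block starts at zero mean with small variance; the parameter
    block starts at the configured nominal values.  R is estimated as the
    variance of the baseline after a high-pass (observation-noise proxy;
    override with ``config.r_override``), and Q is diagonal with separate
    state/parameter scales tied to sigma_obs unless absolute SDs are given.
    """
    baseline = np.asarray(baseline, dtype=float).ravel()
    if baseline.size == 0:
        raise ValueError("baseline segment is empty")
    if np.ptp(baseline) == 0:
        raise ValueError("baseline segment is constant; cannot estimate R")
    if config.r_override is not None:
        R = float(config.r_override)
    else:
        resid = baseline - baseline.mean()
        if config.r_highpass_hz is not None and config.r_highpass_hz < fs / 2:
            from scipy.signal import butter, sosfiltfilt
            sos = butter(2, config.r_highpass_hz, btype="highpass",
                         fs=fs, output="sos")
            resid = sosfiltfilt(sos, resid)
        R = float(np.var(resid))
    sigma_obs = np.sqrt(R)
    q_state = (config.q_state_sd if config.q_state_sd is not None
               else sigma_obs * config.q_state_scale)
    q_param = (config.q_param_sd if config.q_param_sd is not None
               else sigma_obs * config.q_param_scale)
    qdiag = np.zeros(N_XI)
    qdiag[1:N_X:2] = q_state ** 2         # z-states only
    qdiag[N_X:] = np.broadcast_to(np.asarray(q_param, dtype=float) ** 2, (N_THETA,))
    Q = np.diag(qdiag)

    theta0 = np.asarray(config.theta0, dtype=float)
    mean = np.zeros(N_XI)
    mean[N_X:] = theta0
    pdiag = np.full(N_XI, config.p0_state)
    pdiag[N_X:] = (config.p0_param_frac * np.maximum(np.abs(theta0), 1e-3)) ** 2
    return GaussianBelief(mean=mean, cov=np.diag(pdiag)), NoiseSpec(Q=Q, R=R)


def run_filter_array(y: np.ndarray, fs: float, belief0: GaussianBelief,
                     noise: NoiseSpec, config: FilterConfig = FilterConfig(),
                     t0: float = 0.0, channel=None,
                     seizure_id=None) -> TrajectoryEstimate:
    """Filter a raw observation stream (one channel), one belief per sample."""
    y = np.asarray(y, dtype=float).ravel()
    if y.size == 0:
        raise ValueError("empty observation stream")
    mats = build_matrices(sp=config.sigmoid, dt=1.0 / fs)
    means, variances, innov, gains, yhat, n_valid = _kernels.filter_loop(
        y, mats.A, mats.B, mats.C, mats.H, noise.Q, float(noise.R),
        belief0.mean, belief0.cov, config.sigmoid.v0, config.sigmoid.varsigma,
        1 if config.linear else 0)
    n = y.size
    valid = bool(n_valid == n)
    flags = np.zeros(n, dtype=bool)
    flags[:n_valid] = True
    mse = float(np.mean((y[:n_valid] - yhat[:n_valid]) ** 2)) if n_valid else np.nan
    diag = FilterDiagnostics(innovation=innov, gain=gains,
                             stability_flag=flags, mse=mse)
    time = t0 + np.arange(n) / fs
    return TrajectoryEstimate(time=time, means=means, variances=variances,
                              diagnostics=diag, valid=valid, n_valid=int(n_valid),
                              fs=fs, channel=channel, seizure_id=seizure_id)


def run_filter(seg, channel: int, config: FilterConfig = FilterConfig(),
               baseline_window: tuple[float, float] = (-120.0, -60.0)
               ) -> TrajectoryEstimate:
    """Filter one channel of an extracted seizure segment.

    The belief and noise spec are initialized from the segment's own pre-ictal
    baseline window (seconds relative to onset); time in the returned estimate
    is relative to seizure onset.
    """
    y = np.asarray(seg.data[channel], dtype=float)
    fs = seg.fs
    rel = seg.t0_rel_onset + np.arange(y.size) / fs
    bmask = (rel >= baseline_window[0]) & (rel < baseline_window[1])
    if not np.any(bmask):
        bmask = rel < 0
    belief0, noise = initialize(y[bmask], fs, config)
    sid = getattr(seg.seizure, "seizure_id", None) if seg.seizure else None
    return run_filter_array(y, fs, belief0, noise, config,
                            t0=seg.t0_rel_onset, channel=channel,
                            seizure_id=sid)


def reconstruct_forward(estimate: TrajectoryEstimate,
                        sp: SigmoidParams = SigmoidParams()) -> SimulationOutput:
    """Deterministic forward simulation driven by the estimated theta(t).

    No process or observation noise: the reconstruction shows what the
    identified model, on its own, does with the inferred parameter pathway.
    """
    if not estimate.valid:
        raise ValueError("cannot reconstruct from an invalid estimate")
    theta = estimate.theta
    return simulate(theta, sp=sp, fs=estimate.fs,
                    process_noise_sd=0.0, obs_noise_sd=0.0, seed=None)
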