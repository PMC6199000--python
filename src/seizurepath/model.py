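"""Jansen–Rit neural mass model: types, firing-rate sigmoid, state-space form.

The model lumps a cortical column into three populations — pyramidal cells (p),
excitatory interneurons (e) and inhibitory interneurons (i) — coupled through
four synapses.  Each synapse converts the pre-synaptic population's firing rate
into a post-synaptic membrane potential through a second-order kernel with time
constant ``tau`` and a lumped connectivity gain ``alpha`` (volts; the gain
absorbs synaptic efficacy, connection count and maximum firing rate).  The
recorded ECoG channel is modelled as the pyramidal membrane potential

    v_p(t) = v_ep(t) - v_ip(t) + u(t)

where ``u`` is a lumped non-local input and subscripts are pre->post.

State layout (dimension ``N_XI = 13``)::

    xi = [v_ep, z_ep, v_ip, z_ip, v_pe, z_pe, v_pi, z_pi,
          u, alpha_ep, alpha_ip, alpha_pe, alpha_pi]

with ``v`` the post-synaptic potential of each synapse and ``z`` its time
derivative.  The five trailing entries are the estimated parameters theta,
which follow identity (random-walk) dynamics in the augmented model.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.special import erf

__all__ = [
    "N_SYNAPSES", "N_X", "N_THETA", "N_XI", "THETA_LABELS", "SYNAPSE_LABELS",
    "SigmoidParams", "SynapseSpec", "ConnectivityParams", "SystemMatrices",
    "SimulationOutput", "erf_sigmoid", "erf_sigmoid_slope", "build_synapse_set",
    "pyramidal_potential", "build_matrices", "simulate", "reference_params",
]

N_SYNAPSES = 4
N_X = 2 * N_SYNAPSES
N_THETA = 5
N_XI = N_X + N_THETA

#: Synapse ordering (pre -> post).  Fixed; everything else indexes off it.
SYNAPSE_LABELS = ("ep", "ip", "pe", "pi")
#: Flattened parameter vector ordering.
THETA_LABELS = ("u", "alpha_ep", "alpha_ip", "alpha_pe", "alpha_pi")

#: Row index of each synapse's z-state (the rows where the nonlinearity acts).
Z_ROWS = tuple(2 * s + 1 for s in range(N_SYNAPSES))
#: Column index of each synapse's gain within xi (u sits at N_X).
THETA_ROWS = tuple(N_X + 1 + s for s in range(N_SYNAPSES))
U_ROW = N_X


@dataclass(frozen=True)
class SigmoidParams:
    """Firing-rate sigmoid: threshold ``v0`` and slope scale ``varsigma`` (V)."""

    v0: float = 6.0e-3
    varsigma: float = 3.0e-3

    def __post_init__(self) -> None:
        if not self.varsigma > 0:
            raise ValueError("varsigma must be > 0")


@dataclass(frozen=True)
class SynapseSpec:
    """One synapse: pre/post population labels, time constant (s) and sign."""

    pre: str
    post: str
    tau: float
    sign: int

    def __post_init__(self) -> None:
        if self.pre not in "pei" or self.post not in "pei":
            raise ValueError("populations must be one of 'p', 'e', 'i'")
        if self.pre == self.post:
            raise ValueError("self-synapses are not part of the model")
        if not self.tau > 0:
            raise ValueError("tau must be > 0")
        if (self.sign == -1) != (self.pre == "i"):
            raise ValueError("sign is -1 iff the pre-synaptic population is inhibitory")


def build_synapse_set() -> list[SynapseSpec]:
    """The four synapses of the model, in canonical order.

    Excitatory and pyramidal kernels use tau = 10 ms; the inhibitory kernel is
    slower at tau = 20 ms.  Only the inhibitory-pre synapse carries sign -1
    (gains alpha stay non-negative by convention; the minus sign lives in the
    observation/potential assembly).
    """
    return [
        SynapseSpec("e", "p", 0.010, +1),
        SynapseSpec("i", "p", 0.020, -1),
        SynapseSpec("p", "e", 0.010, +1),
        SynapseSpec("p", "i", 0.010, +1),
    ]


TAUS = np.array([s.tau for s in build_synapse_set()])


@dataclass(frozen=True)
class ConnectivityParams:
    """External input ``u`` plus the four lumped gains, all in volts.

    ``alpha`` maps synapse label ("ep", "ip", "pe", "pi"; pre->post) to gain.
    """

    u: float
    alpha: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if set(self.alpha) != set(SYNAPSE_LABELS):
            raise ValueError(f"alpha must have exactly the keys {SYNAPSE_LABELS}")

    def as_vector(self) -> np.ndarray:
        """Flatten to theta = [u, alpha_ep, alpha_ip, alpha_pe, alpha_pi]."""
        return np.array([self.u] + [self.alpha[k] for k in SYNAPSE_LABELS])

    @classmethod
    def from_vector(cls, theta: np.ndarray) -> "ConnectivityParams":
        theta = np.asarray(theta, dtype=float)
        if theta.shape != (N_THETA,):
            raise ValueError(f"theta must have shape ({N_THETA},)")
        return cls(u=float(theta[0]),
                   alpha=dict(zip(SYNAPSE_LABELS, (float(a) for a in theta[1:]))))

    def scaled(self, factor: float) -> "ConnectivityParams":
        return ConnectivityParams.from_vector(self.as_vector() * factor)


def reference_params(u: float = 9.0e-3) -> ConnectivityParams:
    """Reference oscillatory parameter set.

    Gains follow the classic Jansen–Rit constants mapped into this lumped
    formulation (gain x connectivity-multiplier x max firing rate): with
    A = 3.25 mV, B = 22 mV, C1 = 135, C2 = 0.8 C1, C3 = C4 = 0.25 C1 and
    2 e0 = 5 s^-1 the four gains are alpha_mn = (A|B) * C_k * 2 e0.  At
    u around 9–12 mV the deterministic model sits on an alpha-band
    (about 10 Hz) limit cycle; well below that it rests at a fixed point.
    """
    A, B = 3.25e-3, 22e-3
    C1 = 135.0
    C2, C3, C4 = 0.8 * C1, 0.25 * C1, 0.25 * C1
    e0x2 = 5.0
    return ConnectivityParams(u=u, alpha={
        "ep": A * C2 * e0x2,   # 1.755 V
        "ip": B * C4 * e0x2,   # 3.7125 V
        "pe": A * C1 * e0x2,   # 2.19375 V
        "pi": A * C3 * e0x2,   # 0.5484375 V
    })


def erf_sigmoid(v, sp: SigmoidParams = SigmoidParams()):
    """Normalized firing rate phi(v) = (erf((v - v0)/varsigma) + 1) / 2."""
    v = np.asarray(v, dtype=float)
    out = 0.5 * (erf((v - sp.v0) / sp.varsigma) + 1.0)
    return out if out.ndim else float(out)


def erf_sigmoid_slope(v, sp: SigmoidParams = SigmoidParams()):
    """phi'(v) = exp(-((v - v0)/varsigma)^2) / (varsigma sqrt(pi))."""
    v = np.asarray(v, dtype=float)
    out = np.exp(-(((v - sp.v0) / sp.varsigma) ** 2)) / (sp.varsigma * np.sqrt(np.pi))
    return out if out.ndim else float(out)


def pyramidal_potential(state: np.ndarray, u: float) -> float:
    """v_p = v_ep - v_ip + u, from a state vector of length >= N_X."""
    state = np.asarray(state, dtype=float)
    return float(state[0] - state[2] + u)


@dataclass(frozen=True)
class SystemMatrices:
    """Discrete-time matrices of the augmented model xi' = A xi + B g(C xi) + w.

    ``A`` carries the Euler-discretized linear synaptic dynamics plus identity
    dynamics on the theta block.  ``B`` routes the nonlinear vector ``g``
    (per-synapse products alpha_s * phi(v_pre)) into the z-rows with gain
    dt/tau_s.  Active rows of ``C`` (the z-rows) assemble each synapse's
    pre-synaptic membrane potential; for a pyramidal pre-population that row is
    the combination v_ep - v_ip + u.  ``H`` reads the observation v_p.
    """

    A: np.ndarray
    B: np.ndarray
    C: np.ndarray
    H: np.ndarray
    dt: float


def build_matrices(cp: ConnectivityParams | None = None,
                   sp: SigmoidParams = SigmoidParams(),
                   dt: float = 1.0 / 400.0) -> SystemMatrices:
    """Build the discrete-time system matrices for time step ``dt``.

    One application of (A, B, C) reproduces an explicit Euler step of the
    synapse ODEs  dv = z dt,  dz = dt (alpha/tau phi_pre - 2 z / tau - v/tau^2).
    The gains themselves live in the state vector (augmented model), so the
    matrices do not depend on ``cp``; it is accepted for interface symmetry.
    """
    if not dt > 0:
        raise ValueError("dt must be > 0")
    A = np.eye(N_XI)
    B = np.zeros((N_XI, N_XI))
    C = np.zeros((N_XI, N_XI))
    for s in range(N_SYNAPSES):
        tau = TAUS[s]
        A[2 * s, 2 * s + 1] = dt
        A[2 * s + 1, 2 * s] = -dt / tau ** 2
        A[2 * s + 1, 2 * s + 1] = 1.0 - 2.0 * dt / tau
        B[2 * s + 1, 2 * s + 1] = dt / tau
    # Pre-synaptic membrane potentials (rows aligned with the z-rows):
    C[Z_ROWS[0], 4] = 1.0          # e->p reads v_e = v_pe
    C[Z_ROWS[1], 6] = 1.0          # i->p reads v_i = v_pi
    for r in (Z_ROWS[2], Z_ROWS[3]):   # p->e, p->i read v_p = v_ep - v_ip + u
        C[r, 0] = 1.0
        C[r, 2] = -1.0
        C[r, U_ROW] = 1.0
    H = np.zeros(N_XI)
    H[0], H[2], H[U_ROW] = 1.0, -1.0, 1.0
    return SystemMatrices(A=A, B=B, C=C, H=H, dt=dt)


@dataclass
class SimulationOutput:
    """Forward simulation result; all arrays share the sample count."""

    time: np.ndarray            # seconds
    states: np.ndarray          # (T, N_XI) full augmented state (noise-free obs = H xi)
    observation: np.ndarray     # (T,) volts, including observation noise if any
    params_used: np.ndarray     # (T, N_THETA)
    fs: float
    seed: int | None = None

    def observation_clean(self) -> np.ndarray:
        """H xi per sample (observation before measurement noise)."""
        return self.states[:, 0] - self.states[:, 2] + self.states[:, U_ROW]


def _theta_trajectory(param_traj, n_samples: int) -> np.ndarray:
    if isinstance(param_traj, ConnectivityParams):
        theta = np.tile(param_traj.as_vector(), (n_samples, 1))
    else:
        theta = np.asarray(param_traj, dtype=float)
        if theta.ndim == 1:
            theta = np.tile(theta, (n_samples, 1))
        if theta.shape != (n_samples, N_THETA):
            raise ValueError(
                f"parameter trajectory must be constant or ({n_samples}, {N_THETA})")
    return theta


def simulate(param_traj,
             sp: SigmoidParams = SigmoidParams(),
             fs: float = 400.0,
             duration: float | None = None,
             process_noise_sd: float = 0.0,
             obs_noise_sd: float = 0.0,
             seed: int | None = None,
             x0: np.ndarray | None = None) -> SimulationOutput:
    """Integrate the model at step 1/fs with a prescribed parameter trajectory.

    ``param_traj`` is a :class:`ConnectivityParams` (held constant), a length-5
    vector, or a (T, 5) array.  Process noise (sd in V/s, per step) enters the
    z-states only — the v-states are exact integrals of z; observation noise
    (sd in V) is added to y = v_p.  Zero noise gives a deterministic run.
    """
    if not fs > 0:
        raise ValueError("fs must be > 0")
    if duration is None:
        theta = np.asarray(param_traj, dtype=float)
        if isinstance(param_traj, ConnectivityParams) or theta.ndim != 2:
            raise ValueError("duration is required unless param_traj is (T, 5)")
        n = theta.shape[0]
    else:
        n = int(round(duration * fs))
    theta = _theta_trajectory(param_traj, n)
    if not np.all(np.isfinite(theta)):
        raise ValueError("non-finite parameters")
    mats = build_matrices(sp=sp, dt=1.0 / fs)
    rng = np.random.default_rng(seed)
    z_noise = (rng.normal(0.0, process_noise_sd, (n, N_SYNAPSES))
               if process_noise_sd > 0 else np.zeros((n, N_SYNAPSES)))
    obs_noise = (rng.normal(0.0, obs_noise_sd, n)
                 if obs_noise_sd > 0 else np.zeros(n))
    x_init = np.zeros(N_X) if x0 is None else np.asarray(x0, dtype=float)

    from ._kernels import simulate_loop
    states, y = simulate_loop(mats.A, mats.B, mats.C, theta, z_noise,
                              x_init, sp.v0, sp.varsigma)
    y = y + obs_noise
    return SimulationOutput(time=np.arange(n) / fs, states=states, observation=y,
                            params_used=theta, fs=fs, seed=seed)
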