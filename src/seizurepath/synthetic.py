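"""Ground-truth seizure catalogs and model-based ECoG for validation studies.

The generator emulates the statistical structure of a chronically implanted
focal-epilepsy patient: a catalog of seizures with unimodal or bimodal
log-duration distribution, per-seizure connectivity trajectories following one
of three onset motifs (decrease, increase, decrease-then-increase of the
in-going pyramidal connections), and multichannel ECoG produced by the neural
mass model driven along those trajectories plus process and observation noise.

Two study-design constraints are built in:

* long and short seizures share an identical onset epoch — they diverge only
  in a terminal epoch whose amplitude can be linked to duration (the
  ``link`` effect), so pre-onset statistics are duration-independent by
  construction;
* only a configurable subset of channels is affected (focal seizures);
  unaffected channels run baseline dynamics throughout.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np

from .adf import FilterDiagnostics, TrajectoryEstimate
from .model import (N_THETA, N_XI, THETA_LABELS, ConnectivityParams,
                    SigmoidParams, reference_params, simulate)
from .preprocessing import EcogRecording, SeizureRecord, write_annotations, \
    write_recording
from .stats import DurationCatalog

__all__ = [
    "MotifSpec", "CatalogSpec", "GroundTruthBundle", "SeizureSim",
    "make_motif_trajectory", "sample_durations", "generate_bundle",
    "direct_parameter_estimates", "write_bundle",
]

MOTIFS = ("decrease", "increase", "decrease_then_increase")


@dataclass(frozen=True)
class MotifSpec:
    """Shape of the ictal parameter excursion.

    ``amplitude`` is the depth of the primary excursion in percent of
    baseline; ``overshoot`` (decrease_then_increase only) is the height of
    the terminal above-baseline epoch, defaulting to ``amplitude``.  Ramps
    are half-cosine, so trajectories are piecewise-smooth, start and end at
    baseline, and the plateau hits the stated amplitude exactly.
    """

    motif: str = "decrease_then_increase"
    affected: tuple[str, ...] = ("u", "alpha_ep", "alpha_ip")
    amplitude: float = 30.0            # percent of baseline
    onset_ramp_s: float = 2.0
    offset_ramp_s: float = 2.0
    offset_epoch_s: float = 8.0        # terminal epoch (decrease_then_increase)
    overshoot: float | None = None     # percent; None -> amplitude

    def __post_init__(self) -> None:
        if self.motif not in MOTIFS:
            raise ValueError(f"motif must be one of {MOTIFS}")
        if self.amplitude < 0 or self.onset_ramp_s <= 0 or self.offset_ramp_s <= 0:
            raise ValueError("amplitude and ramp times must be positive")
        bad = set(self.affected) - set(THETA_LABELS)
        if bad:
            raise ValueError(f"unknown parameters {bad}")


def _cos_interp(t: np.ndarray, nodes: list[tuple[float, float]]) -> np.ndarray:
    """Piecewise half-cosine interpolation through (time, value) nodes."""
    out = np.zeros_like(t)
    for (t0, y0), (t1, y1) in zip(nodes[:-1], nodes[1:]):
        m = (t >= t0) & (t < t1)
        if t1 > t0:
            frac = 0.5 * (1.0 - np.cos(np.pi * (t[m] - t0) / (t1 - t0)))
            out[m] = y0 + (y1 - y0) * frac
    out[t >= nodes[-1][0]] = nodes[-1][1]
    return out


def motif_shape(spec: MotifSpec, duration: float, fs: float,
                overshoot: float | None = None) -> np.ndarray:
    """Dimensionless motif shape over [0, duration): 0 at both ends.

    decrease dips to -1, increase rises to +1; decrease_then_increase dips to
    -1 and ends with an epoch at +overshoot/amplitude before returning to
    baseline at offset.
    """
    r_on, r_off = spec.onset_ramp_s, spec.offset_ramp_s
    need = r_on + r_off + (spec.offset_epoch_s if
                           spec.motif == "decrease_then_increase" else 0.0)
    if duration <= need:
        raise ValueError(f"duration {duration:.2f}s too short for ramps "
                         f"(needs > {need:.2f}s)")
    n = int(round(duration * fs))
    t = np.arange(n) / fs
    if spec.motif == "decrease":
        nodes = [(0.0, 0.0), (r_on, -1.0), (duration - r_off, -1.0),
                 (duration, 0.0)]
    elif spec.motif == "increase":
        nodes = [(0.0, 0.0), (r_on, 1.0), (duration - r_off, 1.0),
                 (duration, 0.0)]
    else:
        ov = spec.overshoot if spec.overshoot is not None else spec.amplitude
        if overshoot is not None:
            ov = overshoot
        q = ov / max(spec.amplitude, 1e-12)
        t_rise = duration - spec.offset_epoch_s
        nodes = [(0.0, 0.0), (r_on, -1.0), (t_rise, -1.0),
                 (t_rise + spec.offset_epoch_s / 2.0, q),
                 (duration - r_off, q), (duration, 0.0)]
    shape = _cos_interp(t, nodes)
    shape[-1] = 0.0 if n else 0.0
    return shape


def make_motif_trajectory(spec: MotifSpec, duration: float, fs: float,
                          baseline: ConnectivityParams,
                          overshoot: float | None = None) -> np.ndarray:
    """(T, 5) parameter trajectory over the seizure interval.

    Affected parameters follow ``baseline * (1 + amplitude/100 * shape(t))``;
    unaffected parameters stay at baseline.  ``overshoot`` overrides the
    spec's terminal-epoch height (percent of baseline) for one seizure — the
    hook used to link offset behaviour to duration.
    """
    base = baseline.as_vector()
    shape = motif_shape(spec, duration, fs, overshoot=overshoot)
    traj = np.tile(base, (shape.size, 1))
    for lbl in spec.affected:
        j = THETA_LABELS.index(lbl)
        traj[:, j] = base[j] * (1.0 + spec.amplitude / 100.0 * shape)
    return traj


@dataclass(frozen=True)
class CatalogSpec:
    """Study conditions for one synthetic patient.

    Durations are a one- or two-component lognormal; the defaults give a
    clearly bimodal catalog with short seizures near 30 s and long seizures
    near 90 s (log-SD 0.3).  ``channels_affected`` lists the focal channels;
    the rest run baseline dynamics.
    """

    patient_id: str = "synthetic"
    n_seizures: int = 100
    duration_log_means: tuple[float, ...] = (np.log(30.0), np.log(90.0))
    duration_log_sds: tuple[float, ...] = (0.3, 0.3)
    mixture_weight: float = 0.5         # probability of the first component
    n_channels: int = 1
    channels_affected: tuple[int, ...] = (0,)
    baseline_u: float = 9.0e-3
    process_noise_sd: float = 1.0e-3    # V/s per step, z-states
    obs_noise_sd: float = 1.0e-4        # V
    fs: float = 400.0
    pre_onset_s: float = 300.0
    post_offset_s: float = 60.0
    min_duration_s: float = 15.0    # truncation floor so motif ramps always fit
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.duration_log_means) != len(self.duration_log_sds):
            raise ValueError("log_means and log_sds must have equal length")
        if len(self.duration_log_means) == 2 and not 0 < self.mixture_weight < 1:
            raise ValueError("mixture_weight must lie in (0, 1)")
        if any(c >= self.n_channels or c < 0 for c in self.channels_affected):
            raise ValueError("channels_affected out of range")

    def baseline(self) -> ConnectivityParams:
        return reference_params(u=self.baseline_u)


def sample_durations(spec: CatalogSpec,
                     rng: np.random.Generator | None = None
                     ) -> tuple[DurationCatalog, np.ndarray]:
    """Draw seizure durations (s) from the lognormal (mixture) model.

    Returns the catalog and the component index per seizure (0 = first/short
    component).  Seeded by ``spec.seed`` unless an explicit generator is
    passed.
    """
    rng = np.random.default_rng(spec.seed) if rng is None else rng
    k = len(spec.duration_log_means)
    if k == 1:
        comp = np.zeros(spec.n_seizures, dtype=int)
    else:
        comp = (rng.random(spec.n_seizures) >= spec.mixture_weight).astype(int)
    mus = np.asarray(spec.duration_log_means)[comp]
    sds = np.asarray(spec.duration_log_sds)[comp]
    durations = np.exp(rng.normal(mus, sds))
    # truncation floor: redraw rare too-short durations so motifs always fit
    for _ in range(100):
        short = durations < spec.min_duration_s
        if not np.any(short):
            break
        durations[short] = np.exp(rng.normal(mus[short], sds[short]))
    durations = np.maximum(durations, spec.min_duration_s)
    return DurationCatalog(patient_id=spec.patient_id, durations=durations), comp


@dataclass
class SeizureSim:
    """One simulated seizure: recording, annotation and ground truth."""

    seizure_id: str
    recording: EcogRecording
    seizure: SeizureRecord
    theta_true: np.ndarray      # (T, 5) over the full recorded span
    component: int              # duration-mixture component (0 = short)
    overshoot_used: float | None = None


@dataclass
class GroundTruthBundle:
    """Everything a downstream pipeline needs, with the generating spec."""

    seizures: list[SeizureSim]
    catalog: DurationCatalog
    components: np.ndarray
    cat_spec: CatalogSpec
    motif_long: MotifSpec
    motif_short: MotifSpec
    link: float
    seed: int


def generate_bundle(cat_spec: CatalogSpec,
                    motif_long: MotifSpec | None = None,
                    motif_short: MotifSpec | None = None,
                    link: float = 0.0) -> GroundTruthBundle:
    """Generate a full synthetic patient.

    Long and short seizures (mixture components 1 and 0) may use different
    motifs, but their onset epochs are identical by construction; the
    divergence is confined to the terminal epoch.  ``link`` sets the
    offset-effect size: the terminal overshoot of the linked excitatory gain
    (alpha_ep) is ``overshoot + link * z`` percent of baseline, with z the
    z-scored log duration, so a positive link makes longer seizures end with
    stronger excitatory input.  ``link = 0`` leaves terminal behaviour
    duration-independent.
    """
    motif_long = motif_long or MotifSpec()
    motif_short = motif_short or motif_long
    if motif_long.onset_ramp_s != motif_short.onset_ramp_s or \
            motif_long.amplitude != motif_short.amplitude or \
            motif_long.affected != motif_short.affected:
        raise ValueError("long and short motifs must share their onset epoch "
                         "(same amplitude, ramp and affected parameters)")
    catalog, comp = sample_durations(cat_spec)
    logd = catalog.log_durations
    z = (logd - logd.mean()) / (logd.std() if logd.std() > 0 else 1.0)
    baseline = cat_spec.baseline()
    base_vec = baseline.as_vector()
    fs = cat_spec.fs
    n_pre = int(round(cat_spec.pre_onset_s * fs))
    n_post = int(round(cat_spec.post_offset_s * fs))
    seizures = []
    for i, d in enumerate(catalog.durations):
        motif = motif_long if comp[i] == 1 else motif_short
        overshoot = None
        if motif.motif == "decrease_then_increase":
            base_ov = motif.overshoot if motif.overshoot is not None \
                else motif.amplitude
            overshoot = base_ov + link * z[i]
        ictal = make_motif_trajectory(motif, float(d), fs, baseline,
                                      overshoot=overshoot)
        theta = np.vstack([np.tile(base_vec, (n_pre, 1)), ictal,
                           np.tile(base_vec, (n_post, 1))])
        data = np.empty((cat_spec.n_channels, theta.shape[0]))
        for ch in range(cat_spec.n_channels):
            tr = theta if ch in cat_spec.channels_affected \
                else np.tile(base_vec, (theta.shape[0], 1))
            sim = simulate(tr, fs=fs,
                           process_noise_sd=cat_spec.process_noise_sd,
                           obs_noise_sd=cat_spec.obs_noise_sd,
                           seed=np.random.default_rng(
                               [cat_spec.seed, 7919, i, ch]).integers(2 ** 31))
            data[ch] = sim.observation
        sid = f"{cat_spec.patient_id}_sz{i:04d}"
        rec = EcogRecording(data=data, fs=fs, patient_id=cat_spec.patient_id)
        sz = SeizureRecord(patient_id=cat_spec.patient_id, seizure_id=sid,
                           onset=cat_spec.pre_onset_s,
                           offset=cat_spec.pre_onset_s + ictal.shape[0] / fs)
        seizures.append(SeizureSim(seizure_id=sid, recording=rec, seizure=sz,
                                   theta_true=theta, component=int(comp[i]),
                                   overshoot_used=overshoot))
    return GroundTruthBundle(seizures=seizures, catalog=catalog,
                             components=comp, cat_spec=cat_spec,
                             motif_long=motif_long, motif_short=motif_short,
                             link=link, seed=cat_spec.seed)


def direct_parameter_estimates(cat_spec: CatalogSpec,
                               motif_long: MotifSpec | None = None,
                               motif_short: MotifSpec | None = None,
                               link: float = 0.0,
                               est_noise_pct: float = 2.0,
                               est_noise_ar: float = 0.99,
                               fs_est: float = 50.0):
    """Trajectory-level surrogate estimates: ground truth + estimation noise.

    Skips ECoG synthesis and filtering entirely: each seizure's true
    parameter trajectory is resampled at ``fs_est`` and corrupted with slow
    AR(1) noise of SD ``est_noise_pct`` percent of baseline, emulating the
    smooth wander of filtered estimates.  Intended for statistical
    calibration studies (e.g. null replicates of the correlation pipeline)
    where running the full filter for every replicate is unnecessary.

    Returns (estimates, durations): seizure_id -> [TrajectoryEstimate],
    seizure_id -> seconds.
    """
    motif_long = motif_long or MotifSpec()
    motif_short = motif_short or motif_long
    rng = np.random.default_rng([cat_spec.seed, 104729])
    catalog, comp = sample_durations(
        cat_spec, rng=np.random.default_rng(cat_spec.seed))
    logd = catalog.log_durations
    z = (logd - logd.mean()) / (logd.std() if logd.std() > 0 else 1.0)
    baseline = cat_spec.baseline()
    base_vec = baseline.as_vector()
    n_pre = int(round(cat_spec.pre_onset_s * fs_est))
    n_post = int(round(cat_spec.post_offset_s * fs_est))
    estimates: dict[str, list[TrajectoryEstimate]] = {}
    durations: dict[str, float] = {}
    for i, d in enumerate(catalog.durations):
        motif = motif_long if comp[i] == 1 else motif_short
        overshoot = None
        if motif.motif == "decrease_then_increase":
            base_ov = motif.overshoot if motif.overshoot is not None \
                else motif.amplitude
            overshoot = base_ov + link * z[i]
        ictal = make_motif_trajectory(motif, float(d), fs_est, baseline,
                                      overshoot=overshoot)
        theta = np.vstack([np.tile(base_vec, (n_pre, 1)), ictal,
                           np.tile(base_vec, (n_post, 1))])
        n = theta.shape[0]
        noise = np.empty((n, N_THETA))
        eps = rng.normal(0.0, 1.0, (n, N_THETA))
        noise[0] = eps[0]
        a = est_noise_ar
        scale = np.sqrt(1.0 - a * a)
        for t in range(1, n):
            noise[t] = a * noise[t - 1] + scale * eps[t]
        theta_est = theta + noise * (est_noise_pct / 100.0) * np.abs(base_vec)
        means = np.zeros((n, N_XI))
        means[:, N_XI - N_THETA:] = theta_est
        sid = f"{cat_spec.patient_id}_sz{i:04d}"
        est = TrajectoryEstimate(
            time=-cat_spec.pre_onset_s + np.arange(n) / fs_est,
            means=means, variances=np.zeros((n, N_XI)),
            diagnostics=FilterDiagnostics(
                innovation=np.zeros(n), gain=np.zeros((n, N_XI)),
                stability_flag=np.ones(n, dtype=bool), mse=0.0),
            valid=True, n_valid=n, fs=fs_est, channel=0, seizure_id=sid)
        estimates[sid] = [est]
        durations[sid] = float(d)
    return estimates, durations


def write_bundle(bundle: GroundTruthBundle, outdir) -> None:
    """Write recordings (CSV + sidecar), annotations, truth and a manifest."""
    import pandas as pd
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    for sim in bundle.seizures:
        write_recording(sim.recording, outdir / f"{sim.seizure_id}.csv")
        truth = pd.DataFrame(sim.theta_true, columns=list(THETA_LABELS))
        truth.insert(0, "time_s", np.arange(sim.theta_true.shape[0])
                     / sim.recording.fs)
        truth.to_csv(outdir / f"{sim.seizure_id}_truth.csv", index=False)
    write_annotations([s.seizure for s in bundle.seizures],
                      outdir / "annotations.csv")
    manifest = {
        "seed": bundle.seed, "link": bundle.link,
        "cat_spec": {k: (list(v) if isinstance(v, tuple) else v)
                     for k, v in asdict(bundle.cat_spec).items()},
        "motif_long": asdict(bundle.motif_long),
        "motif_short": asdict(bundle.motif_short),
        "components": bundle.components.tolist(),
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=1))
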