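"""Run orchestration: synth -> preprocess -> estimate -> analyze.

Each stage is a plain function taking a :class:`RunConfig`; the console
script (:mod:`seizurepath.cli`) and the numbered analysis drivers are thin
wrappers over these.  Every stage writes tidy CSV outputs plus entries in a
run manifest (config hash, file hashes, wall-clock, per-seizure validity
ledger), and all randomness derives from the single config seed through a
fixed per-stage offset (synth: seed, analyze clustering: seed + 1) so stages
can be rerun independently yet reproducibly.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import adf, stats, synthetic
from .model import THETA_LABELS
from .preprocessing import (EcogSegment, SegmentRejection, bandpass_notch,
                            compute_energy, extract_segment, read_annotations,
                            read_recording)

__all__ = ["RunConfig", "load_config", "cmd_synth", "cmd_preprocess",
           "cmd_estimate", "cmd_analyze", "run_all"]


@dataclass
class PreprocessConfig:
    bandpass: bool = True
    low_hz: float = 1.0
    high_hz: float = 180.0
    notch_hz: float = 50.0
    dropout_min_run_s: float = 0.25


@dataclass
class EstimatorConfig:
    """Filter settings; q_param_sd_frac scales the per-parameter random walk
    as a fraction of the nominal parameter magnitudes."""

    q_state_sd: float | None = None
    q_param_sd_frac: float = 2e-3
    r_override: float | None = None
    p0_param_frac: float = 0.2
    use_truth_noise: bool = True     # matched filter: take Q/R from the generator


@dataclass
class AnalysisConfig:
    baseline_window: tuple[float, float] = (-120.0, -60.0)
    t_start: float = -30.0
    dt: float = 0.25
    bonferroni_patients: int = 1
    cluster_n_ref: int = 100
    min_seizures: int = 20      # patient-inclusion rule for clustering


@dataclass
class RunConfig:
    out_dir: str = "runs/demo"
    seed: int = 0
    link: float = 0.0
    catalog: dict = field(default_factory=dict)
    motif_long: dict = field(default_factory=dict)
    motif_short: dict | None = None
    preprocess: PreprocessConfig = field(default_factory=PreprocessConfig)
    estimator: EstimatorConfig = field(default_factory=EstimatorConfig)
    analysis: AnalysisConfig = field(default_factory=AnalysisConfig)


def _build(cls, d: dict, where: str):
    names = {f.name for f in dataclasses.fields(cls)}
    unknown = set(d) - names
    if unknown:
        raise ValueError(f"unknown config key(s) in {where}: {sorted(unknown)}")
    return cls(**d)


def load_config(path) -> RunConfig:
    """Load a YAML config, rejecting unknown keys at every level."""
    import yaml
    raw = yaml.safe_load(Path(path).read_text()) or {}
    return config_from_dict(raw)


def config_from_dict(raw: dict) -> RunConfig:
    raw = dict(raw)
    sub = {}
    for key, cls in (("preprocess", PreprocessConfig),
                     ("estimator", EstimatorConfig),
                     ("analysis", AnalysisConfig)):
        if key in raw:
            val = raw.pop(key)
            sub[key] = _build(cls, dict(val), key) if isinstance(val, dict) else val
    if "analysis" in sub and isinstance(sub["analysis"].baseline_window, list):
        sub["analysis"].baseline_window = tuple(sub["analysis"].baseline_window)
    cfg = _build(RunConfig, raw | sub, "run config")
    # validate nested synth specs eagerly so bad keys fail here, not mid-run
    _catalog_spec(cfg)
    _motifs(cfg)
    return cfg


def _catalog_spec(cfg: RunConfig) -> synthetic.CatalogSpec:
    d = dict(cfg.catalog)
    for key in ("duration_log_means", "duration_log_sds", "channels_affected"):
        if key in d and isinstance(d[key], list):
            d[key] = tuple(d[key])
    d.setdefault("seed", cfg.seed)
    return _build(synthetic.CatalogSpec, d, "catalog")


def _motifs(cfg: RunConfig):
    ml = dict(cfg.motif_long)
    if "affected" in ml and isinstance(ml["affected"], list):
        ml["affected"] = tuple(ml["affected"])
    long_ = _build(synthetic.MotifSpec, ml, "motif_long")
    if cfg.motif_short is None:
        return long_, long_
    ms = dict(cfg.motif_short)
    if "affected" in ms and isinstance(ms["affected"], list):
        ms["affected"] = tuple(ms["affected"])
    return long_, _build(synthetic.MotifSpec, ms, "motif_short")


def _config_hash(cfg: RunConfig) -> str:
    def enc(o):
        if dataclasses.is_dataclass(o):
            return dataclasses.asdict(o)
        if isinstance(o, tuple):
            return list(o)
        return str(o)
    blob = json.dumps(dataclasses.asdict(cfg), default=enc, sort_keys=True)
    return hashlib.sha256(blob.encode()).hexdigest()[:16]


def _file_hash(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()[:16]


class Manifest:
    """Accumulating run manifest, persisted as JSON after every stage."""

    def __init__(self, cfg: RunConfig):
        self.path = Path(cfg.out_dir) / "manifest.json"
        if self.path.exists():
            self.data = json.loads(self.path.read_text())
        else:
            self.data = {"config_hash": _config_hash(cfg), "stages": {}}
        self.data["config_hash"] = _config_hash(cfg)

    def record(self, stage: str, outputs: list[Path], extra: dict | None = None,
               wall_s: float = 0.0) -> None:
        self.data["stages"][stage] = {
            "wall_s": round(wall_s, 3),
            "outputs": {p.name: _file_hash(p) for p in outputs},
            **(extra or {})}
        self.path.parent.mkdir(parents=True, exist_ok=True)
        self.path.write_text(json.dumps(self.data, indent=1, sort_keys=True))


def cmd_synth(cfg: RunConfig) -> Path:
    """Generate the synthetic patient and write the bundle to <out>/synth."""
    t0 = time.time()
    cat_spec = _catalog_spec(cfg)
    motif_long, motif_short = _motifs(cfg)
    bundle = synthetic.generate_bundle(cat_spec, motif_long, motif_short,
                                       link=cfg.link)
    outdir = Path(cfg.out_dir) / "synth"
    synthetic.write_bundle(bundle, outdir)
    outputs = sorted(outdir.glob("*.csv")) + [outdir / "manifest.json"]
    Manifest(cfg).record("synth", outputs,
                         {"n_seizures": len(bundle.seizures)}, time.time() - t0)
    return outdir


def _iter_segments(cfg: RunConfig):
    cat_spec = _catalog_spec(cfg)
    synth_dir = Path(cfg.out_dir) / "synth"
    if not synth_dir.exists():
        raise FileNotFoundError(f"no synth outputs under {synth_dir}")
    seizures = read_annotations(synth_dir / "annotations.csv")
    for sz in seizures:
        rec = read_recording(synth_dir / f"{sz.seizure_id}.csv")
        try:
            seg = extract_segment(rec, sz, pre_s=cat_spec.pre_onset_s,
                                  post_s=cat_spec.post_offset_s,
                                  dropout_min_run_s=cfg.preprocess.dropout_min_run_s)
        except SegmentRejection as e:
            yield sz, None, e.reason
            continue
        yield sz, seg, None


def cmd_preprocess(cfg: RunConfig) -> Path:
    """Extract segments, filter if configured, and write window energies."""
    t0 = time.time()
    pc = cfg.preprocess
    rows = []
    ledger = []
    for sz, seg, reason in _iter_segments(cfg):
        if seg is None:
            ledger.append({"seizure_id": sz.seizure_id,
                           "status": f"excluded:{reason}"})
            continue
        if pc.bandpass:
            seg = bandpass_notch(seg, low=pc.low_hz, high=pc.high_hz,
                                 notch=pc.notch_hz)
        es = compute_energy(seg)
        df = es.to_frame(seg.seizure and None)
        df.insert(0, "seizure_id", sz.seizure_id)
        rows.append(df)
        ledger.append({"seizure_id": sz.seizure_id, "status": "processed"})
    outdir = Path(cfg.out_dir) / "preprocess"
    outdir.mkdir(parents=True, exist_ok=True)
    energy_path = outdir / "energy.csv"
    pd.concat(rows, ignore_index=True).to_csv(energy_path, index=False) \
        if rows else pd.DataFrame().to_csv(energy_path, index=False)
    ledger_path = outdir / "segments.csv"
    pd.DataFrame(ledger).to_csv(ledger_path, index=False)
    Manifest(cfg).record("preprocess", [energy_path, ledger_path],
                         {"n_processed": sum(l["status"] == "processed"
                                             for l in ledger)},
                         time.time() - t0)
    return outdir


def _filter_config(cfg: RunConfig) -> adf.FilterConfig:
    cat_spec = _catalog_spec(cfg)
    ec = cfg.estimator
    theta0 = cat_spec.baseline().as_vector()
    q_state = ec.q_state_sd
    r_override = ec.r_override
    if ec.use_truth_noise:
        q_state = cat_spec.process_noise_sd if q_state is None else q_state
        r_override = cat_spec.obs_noise_sd ** 2 if r_override is None \
            else r_override
    return adf.FilterConfig(theta0=theta0,
                            p0_param_frac=ec.p0_param_frac,
                            q_state_sd=q_state,
                            q_param_sd=np.abs(theta0) * ec.q_param_sd_frac,
                            r_override=r_override)


def cmd_estimate(cfg: RunConfig, resume: bool = False) -> Path:
    """Filter every seizure x channel; write estimates and a validity ledger."""
    t0 = time.time()
    fc = _filter_config(cfg)
    bw = cfg.analysis.baseline_window
    outdir = Path(cfg.out_dir) / "estimates"
    outdir.mkdir(parents=True, exist_ok=True)
    ledger = []
    outputs = []
    for sz, seg, reason in _iter_segments(cfg):
        if seg is None:
            ledger.append({"seizure_id": sz.seizure_id, "channel": "",
                           "status": f"excluded:{reason}", "mse": np.nan,
                           "valid_fraction": 0.0})
            continue
        for ch in range(seg.data.shape[0]):
            path = outdir / f"{sz.seizure_id}_ch{ch}.csv"
            if resume and path.exists():
                ledger.append({"seizure_id": sz.seizure_id, "channel": ch,
                               "status": "skipped:resume", "mse": np.nan,
                               "valid_fraction": np.nan})
                outputs.append(path)
                continue
            est = adf.run_filter(seg, ch, fc, baseline_window=bw)
            est.to_frame().to_csv(path, index=False)
            outputs.append(path)
            ledger.append({
                "seizure_id": sz.seizure_id, "channel": ch,
                "status": "processed" if est.valid
                else "excluded:instability",
                "mse": est.diagnostics.mse,
                "valid_fraction": est.n_valid / max(est.means.shape[0], 1)})
    ledger_path = outdir / "ledger.csv"
    pd.DataFrame(ledger).to_csv(ledger_path, index=False)
    n_proc = sum(l["status"] == "processed" for l in ledger)
    n_exc = sum(str(l["status"]).startswith("excluded") for l in ledger)
    Manifest(cfg).record("estimate", outputs + [ledger_path],
                         {"n_processed": n_proc, "n_excluded": n_exc,
                          "exclusion_fraction": n_exc / max(n_proc + n_exc, 1)},
                         time.time() - t0)
    return outdir


def _load_estimates(cfg: RunConfig):
    """Reload per-seizure estimate CSVs into TrajectoryEstimate objects."""
    outdir = Path(cfg.out_dir) / "estimates"
    ledger = pd.read_csv(outdir / "ledger.csv")
    synth_dir = Path(cfg.out_dir) / "synth"
    seizures = {s.seizure_id: s
                for s in read_annotations(synth_dir / "annotations.csv")}
    ests: dict[str, list[adf.TrajectoryEstimate]] = {}
    durations: dict[str, float] = {}
    for row in ledger.itertuples():
        if row.status not in ("processed", "skipped:resume"):
            continue
        sid = str(row.seizure_id)
        ch = int(row.channel)
        df = pd.read_csv(outdir / f"{sid}_ch{ch}.csv")
        mean_cols = [c for c in df.columns if c.startswith("mean_")]
        var_cols = [c for c in df.columns if c.startswith("var_")]
        n = len(df)
        est = adf.TrajectoryEstimate(
            time=df["time_s"].to_numpy(),
            means=df[mean_cols].to_numpy(),
            variances=df[var_cols].to_numpy(),
            diagnostics=adf.FilterDiagnostics(
                innovation=np.zeros(n), gain=np.zeros((n, 13)),
                stability_flag=np.ones(n, dtype=bool),
                mse=float(row.mse) if np.isfinite(row.mse) else np.nan),
            valid=True, n_valid=n, fs=_catalog_spec(cfg).fs,
            channel=ch, seizure_id=sid)
        ests.setdefault(sid, []).append(est)
        durations[sid] = seizures[sid].duration
    return ests, durations


def cmd_analyze(cfg: RunConfig) -> Path:
    """Clusters, trajectory summaries, long/short contrast and correlations."""
    t0 = time.time()
    ac = cfg.analysis
    ests, durations = _load_estimates(cfg)
    if not ests:
        raise FileNotFoundError("no processed estimates to analyze")
    outdir = Path(cfg.out_dir) / "analysis"
    outdir.mkdir(parents=True, exist_ok=True)
    outputs = []

    sids = sorted(ests)
    cat = stats.DurationCatalog(
        patient_id=_catalog_spec(cfg).patient_id,
        durations=np.array([durations[s] for s in sids]))
    cres = stats.cluster_durations(cat, seed=cfg.seed + 1,
                                   n_ref=ac.cluster_n_ref,
                                   min_seizures=ac.min_seizures)
    cluster_path = outdir / "clusters.csv"
    pd.DataFrame({
        "seizure_id": sids, "duration_s": cat.durations,
        "cluster": cres.assignments}).to_csv(cluster_path, index=False)
    summary = {"optimal_k_kmeans": cres.optimal_k,
               "optimal_k_gmm": cres.optimal_k_gmm,
               "method_agreement": cres.method_agreement,
               "long_short_boundary_s": cres.long_short_boundary,
               "gap_values": {str(k): v for k, v in cres.gap_values.items()}}
    outputs.append(cluster_path)

    norms = []
    for sid in sids:
        for est in ests[sid]:
            norms.append(stats.baseline_normalize(est, durations[sid],
                                                  ac.baseline_window))
    summ = stats.summarize_trajectories(norms, t_start=ac.t_start, dt=ac.dt)
    traj_path = outdir / "trajectory_summary.csv"
    summ.to_frame().to_csv(traj_path, index=False)
    outputs.append(traj_path)
    summ_off = stats.summarize_trajectories(
        norms, align="offset", t_start=-min(durations.values()), dt=ac.dt)
    traj_off_path = outdir / "trajectory_summary_offset_aligned.csv"
    summ_off.to_frame().to_csv(traj_off_path, index=False)
    outputs.append(traj_off_path)

    if cres.optimal_k == 2:
        df_ls, overall = stats.compare_long_short(
            [n for sid in sids for n in
             [x for x in norms if x.seizure_id == sid]],
            cres, t_start=ac.t_start, dt=ac.dt) \
            if len(norms) == len(sids) else (None, None)
        if df_ls is not None:
            ls_path = outdir / "long_short_contrast.csv"
            df_ls.to_csv(ls_path, index=False)
            outputs.append(ls_path)

    m = stats.bonferroni_divisor(ac.bonferroni_patients)
    corr_rows = []
    for window in ("onset", "offset"):
        res = stats.correlate_duration(ests, durations, window,
                                       bonferroni_m=m)
        t = res.table.copy()
        t.insert(0, "window", window)
        corr_rows.append(t)
    corr_path = outdir / "duration_correlations.csv"
    pd.concat(corr_rows, ignore_index=True).to_csv(corr_path, index=False)
    outputs.append(corr_path)

    summary_path = outdir / "summary.json"
    summary_path.write_text(json.dumps(summary, indent=1))
    outputs.append(summary_path)
    Manifest(cfg).record("analyze", outputs, {}, time.time() - t0)
    return outdir


def run_all(cfg: RunConfig, resume: bool = False) -> Path:
    cmd_synth(cfg)
    cmd_preprocess(cfg)
    cmd_estimate(cfg, resume=resume)
    return cmd_analyze(cfg)
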