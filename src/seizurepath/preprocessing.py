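"""ECoG I/O, seizure segment extraction, filtering and sliding-window energy.

Recordings are channels x samples in volts (or device units with a configured
gain).  Seizure annotations give onset/offset on the recording clock; analysis
segments span five minutes before onset to one minute after offset.  Filtering
is the standard clinical chain: zero-phase second-order Butterworth bandpass
1–180 Hz plus a zero-phase second-order notch around the mains frequency.
Signal energy is the sum of squared samples over 1-s windows with 50% overlap.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.signal import butter, filtfilt

__all__ = [
    "EcogRecording", "SeizureRecord", "EcogSegment", "EnergySeries",
    "SegmentRejection", "read_recording", "write_recording", "read_annotations",
    "write_annotations", "annotate_lead_times", "extract_segment",
    "bandpass_notch", "compute_energy",
]

PRE_ONSET_S = 300.0      # segment context before onset
POST_OFFSET_S = 60.0     # segment context after offset


class SegmentRejection(Exception):
    """A seizure segment could not be used; ``reason`` says why."""

    def __init__(self, reason: str, detail: str = ""):
        self.reason = reason
        super().__init__(f"{reason}: {detail}" if detail else reason)


@dataclass
class EcogRecording:
    """Multichannel recording: ``data`` is channels x samples, volts."""

    data: np.ndarray
    fs: float
    channel_labels: list[str] = field(default_factory=list)
    patient_id: str = ""

    def __post_init__(self) -> None:
        self.data = np.atleast_2d(np.asarray(self.data, dtype=float))
        if not self.fs > 0:
            raise ValueError("fs must be > 0")
        if not self.channel_labels:
            self.channel_labels = [f"ch{i}" for i in range(self.data.shape[0])]
        if len(self.channel_labels) != self.data.shape[0]:
            raise ValueError("channel_labels length must match channel count")

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def duration(self) -> float:
        return self.data.shape[1] / self.fs


@dataclass(frozen=True)
class SeizureRecord:
    """One annotated seizure on the recording clock (seconds)."""

    patient_id: str
    seizure_id: str
    onset: float
    offset: float
    lead_time_ok: bool = True

    def __post_init__(self) -> None:
        if not self.offset > self.onset:
            raise ValueError("offset must be after onset")

    @property
    def duration(self) -> float:
        return self.offset - self.onset


@dataclass
class EcogSegment:
    """Extracted per-seizure data with pre/post context."""

    data: np.ndarray            # channels x samples
    fs: float
    t0_rel_onset: float         # segment start relative to seizure onset (s)
    seizure: SeizureRecord | None = None

    def __post_init__(self) -> None:
        self.data = np.atleast_2d(np.asarray(self.data, dtype=float))

    @property
    def time_rel_onset(self) -> np.ndarray:
        return self.t0_rel_onset + np.arange(self.data.shape[1]) / self.fs


@dataclass
class EnergySeries:
    """Sliding-window signal energy (sum of squared samples per window)."""

    window_centers: np.ndarray      # seconds relative to onset
    energy: np.ndarray              # channels x windows
    channel_average: np.ndarray     # windows

    def to_frame(self, channel_labels=None) -> pd.DataFrame:
        labels = channel_labels or [f"ch{i}" for i in range(self.energy.shape[0])]
        rows = []
        for i, lbl in enumerate(labels):
            rows.append(pd.DataFrame({"window_center_s": self.window_centers,
                                      "channel": lbl, "energy": self.energy[i]}))
        rows.append(pd.DataFrame({"window_center_s": self.window_centers,
                                  "channel": "average",
                                  "energy": self.channel_average}))
        return pd.concat(rows, ignore_index=True)


def write_recording(rec: EcogRecording, path) -> None:
    """Write a recording as CSV (one column per channel) + JSON sidecar."""
    path = Path(path)
    pd.DataFrame(rec.data.T, columns=rec.channel_labels).to_csv(path, index=False)
    sidecar = {"fs": rec.fs, "patient_id": rec.patient_id,
               "channel_labels": rec.channel_labels, "units": "V"}
    path.with_suffix(path.suffix + ".json").write_text(json.dumps(sidecar))


def read_recording(path, format: str = "csv", gain: float = 1.0) -> EcogRecording:
    """Read a recording from CSV + JSON sidecar, or from EDF.

    ``gain`` converts device units to volts for formats that do not declare
    physical units.  EDF support uses :mod:`mne` when available.
    """
    path = Path(path)
    if format == "csv":
        sidecar_path = path.with_suffix(path.suffix + ".json")
        if not sidecar_path.exists():
            raise FileNotFoundError(f"missing sidecar {sidecar_path}")
        sidecar = json.loads(sidecar_path.read_text())
        df = pd.read_csv(path)
        labels = sidecar.get("channel_labels", list(df.columns))
        if list(df.columns) != labels:
            raise ValueError("sidecar channel labels disagree with CSV columns")
        return EcogRecording(data=df.to_numpy().T * gain, fs=float(sidecar["fs"]),
                             channel_labels=labels,
                             patient_id=sidecar.get("patient_id", ""))
    if format == "edf":
        import mne
        raw = mne.io.read_raw_edf(path, preload=True, verbose="error")
        return EcogRecording(data=raw.get_data() * gain, fs=float(raw.info["sfreq"]),
                             channel_labels=list(raw.ch_names))
    raise ValueError(f"unknown format {format!r}")


def write_annotations(seizures, path) -> None:
    pd.DataFrame([{"patient_id": s.patient_id, "seizure_id": s.seizure_id,
                   "onset_s": s.onset, "offset_s": s.offset,
                   "lead_time_ok": s.lead_time_ok} for s in seizures]
                 ).to_csv(path, index=False)


def read_annotations(path) -> list[SeizureRecord]:
    df = pd.read_csv(path)
    return [SeizureRecord(patient_id=str(r.patient_id), seizure_id=str(r.seizure_id),
                          onset=float(r.onset_s), offset=float(r.offset_s),
                          lead_time_ok=bool(getattr(r, "lead_time_ok", True)))
            for r in df.itertuples()]


def annotate_lead_times(seizures, min_lead_s: float = 3600.0) -> list[SeizureRecord]:
    """Flag seizures with at least ``min_lead_s`` seizure-free lead time.

    Seizures are taken to be on a common recording clock per patient; the
    first seizure of a patient is assumed to have sufficient lead time.
    """
    out = []
    by_patient: dict[str, list[SeizureRecord]] = {}
    for s in seizures:
        by_patient.setdefault(s.patient_id, []).append(s)
    for plist in by_patient.values():
        plist = sorted(plist, key=lambda s: s.onset)
        prev_offset = None
        for s in plist:
            ok = prev_offset is None or (s.onset - prev_offset) >= min_lead_s
            out.append(replace(s, lead_time_ok=ok))
            prev_offset = s.offset
    return out


def _find_dropout(data: np.ndarray, fs: float, min_run_s: float) -> bool:
    """True if any channel holds an exactly-constant value for >= min_run_s."""
    min_run = max(int(round(min_run_s * fs)), 2)
    for ch in data:
        same = np.diff(ch) == 0.0
        if same.size >= min_run - 1:
            # longest run of consecutive True
            run = 0
            longest = 0
            for v in same:
                run = run + 1 if v else 0
                if run > longest:
                    longest = run
            if longest + 1 >= min_run:
                return True
    return False


def extract_segment(rec: EcogRecording, sz: SeizureRecord,
                    pre_s: float = PRE_ONSET_S, post_s: float = POST_OFFSET_S,
                    dropout_min_run_s: float = 0.25) -> EcogSegment:
    """Cut the analysis segment [onset - pre_s, offset + post_s].

    Raises :class:`SegmentRejection` (with a reason) when the recording does
    not cover the span or when a telemetry dropout — an exactly-constant run
    of at least ``dropout_min_run_s`` on any channel — is present.
    """
    start = sz.onset - pre_s
    stop = sz.offset + post_s
    if start < 0 or stop > rec.duration + 0.5 / rec.fs:
        raise SegmentRejection("coverage",
                               f"recording does not span [{start:.1f}, {stop:.1f}] s")
    i0 = int(round(start * rec.fs))
    i1 = int(round(stop * rec.fs))
    data = rec.data[:, i0:i1]
    if _find_dropout(data, rec.fs, dropout_min_run_s):
        raise SegmentRejection("dropout", "exactly-constant run on some channel")
    return EcogSegment(data=data.copy(), fs=rec.fs, t0_rel_onset=-pre_s, seizure=sz)


def bandpass_notch(seg: EcogSegment, low: float = 1.0, high: float = 180.0,
                   notch: float = 50.0, notch_halfwidth: float = 2.0) -> EcogSegment:
    """Zero-phase second-order Butterworth bandpass, then bandstop at mains.

    Both stages run forward–backward (zero phase) with reflect padding of
    three filter lengths; output length equals input length.
    """
    fs = seg.fs
    if high >= fs / 2:
        raise ValueError("bandpass upper edge must be below Nyquist")
    b_bp, a_bp = butter(2, [low, high], btype="bandpass", fs=fs)
    b_bs, a_bs = butter(2, [notch - notch_halfwidth, notch + notch_halfwidth],
                        btype="bandstop", fs=fs)
    out = np.empty_like(seg.data)
    for i, ch in enumerate(seg.data):
        x = filtfilt(b_bp, a_bp, ch, padtype="even",
                     padlen=3 * max(len(a_bp), len(b_bp)))
        out[i] = filtfilt(b_bs, a_bs, x, padtype="even",
                          padlen=3 * max(len(a_bs), len(b_bs)))
    return EcogSegment(data=out, fs=fs, t0_rel_onset=seg.t0_rel_onset,
                       seizure=seg.seizure)


def compute_energy(seg: EcogSegment, window_s: float = 1.0,
                   overlap: float = 0.5) -> EnergySeries:
    """Sum-of-squares energy per sliding window, per channel and averaged.

    Windows that would overhang the segment end are dropped, so window
    centers align exactly across seizures cut with the same context.
    """
    n_win = int(round(window_s * seg.fs))
    hop = int(round(n_win * (1.0 - overlap)))
    n = seg.data.shape[1]
    if n < n_win:
        raise ValueError("segment shorter than one window")
    starts = np.arange(0, n - n_win + 1, hop)
    energy = np.empty((seg.data.shape[0], starts.size))
    for w, s0 in enumerate(starts):
        energy[:, w] = np.sum(seg.data[:, s0:s0 + n_win] ** 2, axis=1)
    centers = seg.t0_rel_onset + (starts + n_win / 2.0) / seg.fs
    return EnergySeries(window_centers=centers, energy=energy,
                        channel_average=energy.mean(axis=0))
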