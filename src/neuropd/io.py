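"""Readers and writers for the pipeline's on-disk formats.

Everything is plain text: concentration-response and cohort tables as CSV,
time-activity curves as CSV with a JSON scan-metadata sidecar, EEG as wide
CSV (one column per channel) with a JSON header.  EDF reading is supported
when mne is installed; synthetic data is written as CSV.  Generators'
ground truth travels in a ``*.truth.json`` sidecar so downstream checks can
recover it.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
import pandas as pd

from .eeg_spectra import EEGRecording
from .pet_kinetics import FrameSchedule, ScanMeta, TimeActivityCurve

__all__ = [
    "write_conc_response", "read_conc_response",
    "write_cohort", "read_cohort",
    "write_tacs", "read_tacs",
    "write_scan_meta", "read_scan_meta",
    "write_eeg_csv", "read_eeg_csv", "read_eeg_edf",
    "write_truth_sidecar",
]


def _jsonify(obj):
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {f.name: _jsonify(getattr(obj, f.name))
                for f in dataclasses.fields(obj)}
    if isinstance(obj, dict):
        return {str(k): _jsonify(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonify(v) for v in obj]
    return obj


def write_truth_sidecar(truth, path):
    """Dump a generator's ground truth next to the data it produced."""
    Path(path).write_text(json.dumps(_jsonify(truth), indent=2))


def write_conc_response(df: pd.DataFrame, path):
    df.to_csv(path, index=False, columns=["conc_nM", "response", "replicate"])


def read_conc_response(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = {"conc_nM", "response"} - set(df.columns)
    if missing:
        raise ValueError(f"concentration-response CSV lacks columns {missing}")
    return df


_COHORT_COLS = ["animal_id", "treatment", "dose_mg_kg", "region",
                "signal_fmol_mg", "plasma_ng_ml"]


def write_cohort(df: pd.DataFrame, path):
    df.to_csv(path, index=False, columns=_COHORT_COLS)


def read_cohort(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = set(_COHORT_COLS[:5]) - set(df.columns)
    if missing:
        raise ValueError(f"cohort CSV lacks columns {missing}")
    return df


def write_tacs(tacs, path):
    """Write a collection of TACs (shared schedule) as tidy CSV."""
    rows = []
    for tac in tacs:
        for s, d, a in zip(tac.schedule.start_s, tac.schedule.dur_s,
                           tac.activity_kbq_ml):
            rows.append((s, d, tac.region, tac.scan_id, a))
    pd.DataFrame(rows, columns=["frame_start_s", "frame_dur_s", "region",
                                "scan_id", "activity_kbq_ml"]).to_csv(
        path, index=False)


def read_tacs(path):
    """Read TAC CSV back into {scan_id: {region: TimeActivityCurve}}."""
    df = pd.read_csv(path)
    out = {}
    for (scan, region), grp in df.groupby(["scan_id", "region"], sort=True):
        grp = grp.sort_values("frame_start_s")
        sched = FrameSchedule(grp["frame_start_s"].to_numpy(),
                              grp["frame_dur_s"].to_numpy())
        out.setdefault(scan, {})[region] = TimeActivityCurve(
            schedule=sched, activity_kbq_ml=grp["activity_kbq_ml"].to_numpy(),
            region=region, scan_id=scan)
    return out


def write_scan_meta(meta: ScanMeta, path):
    Path(path).write_text(json.dumps(_jsonify(meta), indent=2))


def read_scan_meta(path) -> ScanMeta:
    d = json.loads(Path(path).read_text())
    return ScanMeta(**d)


def write_eeg_csv(rec: EEGRecording, path):
    """Wide CSV (time column + one column per channel) with a JSON header."""
    path = Path(path)
    t = np.arange(rec.n_samples) / rec.fs
    df = pd.DataFrame(rec.data.T, columns=list(rec.channels))
    df.insert(0, "time_s", t)
    df.to_csv(path, index=False, float_format="%.8e")
    header = {"fs": rec.fs, "subject": rec.subject,
              "condition": rec.condition, "rec_index": rec.rec_index,
              "reference": rec.reference}
    path.with_suffix(".json").write_text(json.dumps(header, indent=2))


def read_eeg_csv(path) -> EEGRecording:
    path = Path(path)
    df = pd.read_csv(path)
    if "time_s" not in df.columns:
        raise ValueError("EEG CSV must contain a time_s column")
    t = df.pop("time_s").to_numpy()
    fs = 1.0 / np.median(np.diff(t))
    kwargs = {}
    sidecar = path.with_suffix(".json")
    if sidecar.exists():
        hdr = json.loads(sidecar.read_text())
        fs = hdr.get("fs", fs)
        kwargs = {k: hdr[k] for k in ("subject", "condition", "rec_index",
                                      "reference") if k in hdr}
    return EEGRecording(data=df.to_numpy().T, fs=float(fs),
                        channels=tuple(df.columns), **kwargs)


def read_eeg_edf(path, subject="", condition="baseline") -> EEGRecording:
    """Read an EDF recording via mne (optional dependency)."""
    try:
        import mne
    except ImportError as exc:  # pragma: no cover
        raise ImportError("reading EDF requires the 'mne' package "
                          "(pip install neuropd[edf])") from exc
    raw = mne.io.read_raw_edf(path, preload=True, verbose="error")
    return EEGRecording(data=raw.get_data(), fs=float(raw.info["sfreq"]),
                        channels=tuple(raw.ch_names), subject=subject,
                        condition=condition)
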