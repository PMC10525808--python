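"""Reading and writing of recordings, tables and results.

Signal files are comma-delimited text with a header row
``time_s,ER_L,ER_R,ML_L,ML_R`` and values in volts; each recording has a
JSON sidecar (same stem, ``.json``) with metadata and, for synthetic
recordings, the planted ground-truth annotations.  Floating-point output
is serialized at fixed precision so identical configs reproduce files
byte for byte.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import DataError
from .preprocess import Roi
from .simulate import CHANNELS, EmgRecording, PlantedBurst

FLOAT_FORMAT = "%.10g"
#: Signals round-trip exactly: 17 significant digits uniquely identify a double.
SIGNAL_FLOAT_FORMAT = "%.17g"


def _sidecar_path(path: Path) -> Path:
    return path.with_suffix(".json")


def write_recording(recording: EmgRecording, path: str | Path) -> Path:
    """Write a recording as CSV + JSON sidecar; returns the CSV path."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    n = recording.n_samples
    data = {"time_s": np.arange(n) / recording.fs}
    for channel in recording.channels:
        data[channel] = recording.samples[channel]
    pd.DataFrame(data).to_csv(path, index=False,
                              float_format=SIGNAL_FLOAT_FORMAT)

    meta: dict = {
        "subject_id": recording.subject_id,
        "condition": recording.condition,
        "fs": recording.fs,
        "channels": list(recording.channels),
    }
    if recording.truth is not None:
        meta["truth"] = {
            ch: [{"start": b.start, "stop": b.stop,
                  "center_freq": round(b.center_freq, 6),
                  "rms": float(f"{b.rms:.10g}")}
                 for b in bursts]
            for ch, bursts in recording.truth.items()}
    with open(_sidecar_path(path), "w") as fh:
        json.dump(meta, fh, indent=1, sort_keys=True)
    return path


def read_recording(path: str | Path) -> EmgRecording:
    """Read a recording written by :func:`write_recording`.

    Malformed files (missing channels, non-numeric cells, ragged rows)
    raise :class:`DataError` naming the offending line where possible.
    """
    path = Path(path)
    try:
        frame = pd.read_csv(path, float_precision="round_trip")
    except (pd.errors.ParserError, pd.errors.EmptyDataError) as exc:
        raise DataError(f"{path}: {exc}") from exc
    missing = [c for c in ("time_s", *CHANNELS) if c not in frame.columns]
    if missing:
        raise DataError(f"{path}: missing columns {missing} (line 1)")
    for column in CHANNELS:
        values = pd.to_numeric(frame[column], errors="coerce")
        bad = values.index[values.isna() & frame[column].notna()]
        if len(bad):
            raise DataError(
                f"{path}: non-numeric value in column {column} "
                f"(line {bad[0] + 2})")
        if values.isna().any():
            raise DataError(f"{path}: missing value in column {column}")

    sidecar = _sidecar_path(path)
    meta: dict = {}
    if sidecar.exists():
        with open(sidecar) as fh:
            meta = json.load(fh)
    t = frame["time_s"].to_numpy(dtype=float)
    fs = float(meta.get("fs") or (1.0 / np.median(np.diff(t))))
    truth = None
    if "truth" in meta:
        truth = {ch: [PlantedBurst(b["start"], b["stop"], b["center_freq"],
                                   b["rms"]) for b in bursts]
                 for ch, bursts in meta["truth"].items()}
    return EmgRecording(
        subject_id=str(meta.get("subject_id", path.stem)),
        condition=str(meta.get("condition", "")),
        fs=fs,
        samples={c: frame[c].to_numpy(dtype=float) for c in CHANNELS},
        truth=truth)


def recording_filename(recording: EmgRecording) -> str:
    label = recording.condition.replace("-", "")
    return f"{recording.subject_id}_{label}.csv"


def write_table(frame: pd.DataFrame, path: str | Path) -> Path:
    """Write a results table as CSV at fixed float precision."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    frame.to_csv(path, index=False, float_format=FLOAT_FORMAT)
    return path


def rois_frame(rois_by_channel: dict[str, list[Roi]]) -> pd.DataFrame:
    rows = [{"channel": r.channel, "lift_index": r.lift_index,
             "start_sample": r.start, "stop_sample": r.stop}
            for channel in sorted(rois_by_channel)
            for r in rois_by_channel[channel]]
    return pd.DataFrame(rows,
                        columns=["channel", "lift_index", "start_sample",
                                 "stop_sample"])


def write_json(obj: dict, path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=1, sort_keys=True, default=_json_default)
    return path


def _json_default(value):
    if isinstance(value, (np.integer,)):
        return int(value)
    if isinstance(value, (np.floating,)):
        return float(value)
    if isinstance(value, np.ndarray):
        return value.tolist()
    raise TypeError(f"not JSON-serializable: {type(value)}")
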