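"""Readers/writers: IMU session CSV + sidecar JSON, checkpoints, manifests."""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd

from .synthetic import InjuryEvent, LabeledImuStream, ScenarioSegment


def write_imu_csv(stream: LabeledImuStream, path) -> None:
    """Delimited session file: ``time_s,<channel...>`` plus a sidecar JSON
    (``<path>.json``) holding segments, events and dropout intervals."""
    path = Path(path)
    df = pd.DataFrame(stream.values, columns=stream.channels)
    df.insert(0, "time_s", stream.times)
    df.to_csv(path, index=False, float_format="%.9g")
    sidecar = {
        "sample_rate": stream.sample_rate,
        "subject_id": stream.subject_id,
        "segments": [{"scenario": s.scenario, "start_s": s.start_s,
                      "end_s": s.end_s} for s in stream.segments],
        "events": [{"time_s": e.time_s, "itype": e.itype, "side": e.side}
                   for e in stream.events],
        "dropout": [{"channel": c, "start_s": a, "end_s": b}
                    for c, a, b in stream.dropout],
    }
    Path(str(path) + ".json").write_text(json.dumps(sidecar, indent=1))


def read_imu_csv(path) -> LabeledImuStream:
    path = Path(path)
    header = pd.read_csv(path, nrows=0).columns.tolist()
    if not header or header[0] != "time_s":
        raise ValueError(f"{path}: missing 'time_s' header column")
    df = pd.read_csv(path)
    t = df["time_s"].to_numpy()
    bad = np.nonzero(np.diff(t) <= 0)[0]
    if bad.size:
        raise ValueError(
            f"{path}: non-monotone timestamps at data line {bad[0] + 3}")
    channels = [c for c in df.columns if c != "time_s"]
    sidecar_path = Path(str(path) + ".json")
    meta = json.loads(sidecar_path.read_text()) if sidecar_path.exists() else {}
    sample_rate = meta.get("sample_rate",
                           1.0 / np.median(np.diff(t)) if len(t) > 1 else 200.0)
    stream = LabeledImuStream(
        sample_rate=float(sample_rate), channels=channels,
        values=df[channels].to_numpy(),
        segments=[ScenarioSegment(s["scenario"], s["start_s"], s["end_s"])
                  for s in meta.get("segments", [])],
        events=[InjuryEvent(e["time_s"], e["itype"], e["side"])
                for e in meta.get("events", [])],
        dropout=[(d["channel"], d["start_s"], d["end_s"])
                 for d in meta.get("dropout", [])],
        subject_id=int(meta.get("subject_id", 0)))
    for ch, a, b in stream.dropout:
        j = stream.channel_index(ch)
        i0, i1 = int(round(a * stream.sample_rate)), int(round(b * stream.sample_rate))
        stream.mask[i0:i1, j] = False
    return stream


def config_hash(config: dict) -> str:
    return hashlib.sha256(
        json.dumps(config, sort_keys=True, default=str).encode()).hexdigest()[:16]


def file_checksum(path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()[:16]


def save_json(obj, path) -> None:
    Path(path).write_text(json.dumps(obj, indent=1, default=_json_default))


def _json_default(o):
    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        return float(o)
    if isinstance(o, np.ndarray):
        return o.tolist()
    raise TypeError(f"not JSON serializable: {type(o)}")
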