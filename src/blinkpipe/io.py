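"""File formats: landmark streams (CSV / JSON-lines), traces, protocols.

The landmark CSV dialect has one row per frame::

    frame,timestamp_ms,bbox_x,bbox_y,bbox_w,bbox_h,x0,y0,...,x76,y76

The JSON-lines dialect has one object per frame with keys ``timestamp_ms``,
``bbox`` (4 numbers) and ``points`` (77 [x, y] pairs). Reading validates the
77-landmark shape and strict timestamp monotonicity and reports offending
line numbers.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Union

import numpy as np
import pandas as pd

from .protocol import SessionProtocol, session_from_json, session_to_json
from .signal import EyelidTrace, LandmarkStream, N_LANDMARKS

__all__ = [
    "write_landmark_stream",
    "read_landmark_stream",
    "write_trace",
    "read_trace",
    "write_protocol",
    "read_protocol",
]

PathLike = Union[str, Path]

_HEADER = ["frame", "timestamp_ms", "bbox_x", "bbox_y", "bbox_w", "bbox_h"] + [
    f"{axis}{k}" for k in range(N_LANDMARKS) for axis in ("x", "y")
]


def write_landmark_stream(stream: LandmarkStream, path: PathLike) -> None:
    n = stream.n_frames
    flat = stream.points.reshape(n, 2 * N_LANDMARKS)
    df = pd.DataFrame(
        np.column_stack(
            [np.arange(n), stream.timestamps_ms, stream.bbox, flat]
        ),
        columns=_HEADER,
    )
    df["frame"] = df["frame"].astype(int)
    df.to_csv(path, index=False)


def _read_jsonl(path: Path) -> LandmarkStream:
    ts, pts, boxes = [], [], []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            try:
                rec = json.loads(line)
            except json.JSONDecodeError as exc:
                raise ValueError(f"{path}:{lineno}: malformed JSON ({exc})")
            p = np.asarray(rec["points"], dtype=float)
            if p.shape != (N_LANDMARKS, 2):
                raise ValueError(
                    f"{path}:{lineno}: expected {N_LANDMARKS} (x, y) landmark "
                    f"pairs, got shape {p.shape}"
                )
            ts.append(float(rec["timestamp_ms"]))
            pts.append(p)
            boxes.append(np.asarray(rec["bbox"], dtype=float))
    if not ts:
        raise ValueError(f"{path}: empty landmark stream")
    return _validated_stream(path, np.asarray(ts), np.asarray(pts), np.asarray(boxes))


def _validated_stream(path, ts, pts, boxes) -> LandmarkStream:
    bad = np.where(np.diff(ts) <= 0)[0]
    if bad.size:
        raise ValueError(
            f"{path}: timestamps must be strictly increasing; first violation "
            f"at data row {bad[0] + 2} (t={ts[bad[0] + 1]} after t={ts[bad[0]]})"
        )
    return LandmarkStream(ts, pts, boxes)


def read_landmark_stream(path: PathLike) -> LandmarkStream:
    """Read the CSV or JSON-lines landmark dialect, with validation."""
    path = Path(path)
    with open(path) as fh:
        head = fh.read(1)
    if not head:
        raise ValueError(f"{path}: empty landmark stream")
    if head in "{[":
        return _read_jsonl(path)
    df = pd.read_csv(path)
    if len(df.columns) != len(_HEADER):
        n_pairs = (len(df.columns) - 6) // 2
        raise ValueError(
            f"{path}: expected {len(_HEADER)} columns "
            f"({N_LANDMARKS} landmark pairs), found {len(df.columns)} "
            f"({n_pairs} pairs)"
        )
    if df.empty:
        raise ValueError(f"{path}: empty landmark stream")
    ts = df["timestamp_ms"].to_numpy(dtype=float)
    boxes = df[["bbox_x", "bbox_y", "bbox_w", "bbox_h"]].to_numpy(dtype=float)
    pts = df[_HEADER[6:]].to_numpy(dtype=float).reshape(len(df), N_LANDMARKS, 2)
    return _validated_stream(path, ts, pts, boxes)


def write_trace(trace: EyelidTrace, path: PathLike) -> None:
    pd.DataFrame(
        {"t_ms": trace.t_ms, "closure": trace.closure, "stage": trace.stage}
    ).to_csv(path, index=False)


def read_trace(path: PathLike) -> EyelidTrace:
    df = pd.read_csv(path)
    stage = str(df["stage"].iloc[0]) if len(df) else "raw"
    t = df["t_ms"].to_numpy(dtype=float)
    d = np.diff(t)
    fs = 1000.0 / float(np.median(d)) if d.size else 60.0
    return EyelidTrace(t, df["closure"].to_numpy(dtype=float), fs, stage)


def write_protocol(protocol: SessionProtocol, path: PathLike) -> None:
    Path(path).write_text(session_to_json(protocol))


def read_protocol(path: PathLike) -> SessionProtocol:
    return session_from_json(Path(path).read_text())
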