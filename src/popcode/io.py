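"""Plain-text session serialization.

A session directory holds:

* ``raster.tsv``   — neurons as rows, frames as columns, entries {0,1}
* ``traces.tsv``   — same layout, floating-point dF/F (optional)
* ``annotation.tsv`` — one row per frame: frame_index, epoch_id, context_id,
  behavior_label, arm_label (empty when not applicable)
* ``truth.json``   — planted per-neuron gains (optional)
* ``meta.json``    — frame rate and shape

Round trips are lossless for raster, annotation and truth.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .core import CalciumTraces, EventRaster, SessionAnnotation
from .synthgen import GroundTruth, SyntheticSession

__all__ = ["write_session", "read_session", "read_raster", "read_annotation", "ParseError"]

_ANNOT_COLS = ["frame_index", "epoch_id", "context_id", "behavior_label", "arm_label"]


class ParseError(ValueError):
    """A session file failed validation; message names file, line and field."""


def write_session(session: SyntheticSession, path: str | Path) -> Path:
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    np.savetxt(path / "raster.tsv", session.raster.values, fmt="%d", delimiter="\t")
    if session.traces is not None:
        np.savetxt(path / "traces.tsv", session.traces.values, fmt="%.6g", delimiter="\t")
    ann = session.annotation.frame.copy()
    ann.insert(0, "frame_index", np.arange(len(ann)))
    ann.to_csv(path / "annotation.tsv", sep="\t", index=False)
    if session.truth is not None:
        truth = session.truth
        payload = {
            "remap": bool(truth.remap),
            "social_gain": {k: v.tolist() for k, v in truth.social_gain.items()},
            "context_gain": {k: v.tolist() for k, v in truth.context_gain.items()},
            "arm_gain": {k: v.tolist() for k, v in truth.arm_gain.items()},
            "drift": truth.drift.tolist(),
        }
        (path / "truth.json").write_text(json.dumps(payload))
    meta = {
        "frame_rate": session.raster.frame_rate,
        "n_neurons": session.raster.n_neurons,
        "n_frames": session.raster.n_frames,
    }
    (path / "meta.json").write_text(json.dumps(meta))
    return path


def read_raster(path: str | Path, frame_rate: float = 20.0) -> EventRaster:
    path = Path(path)
    arr = _read_matrix(path)
    bad = ~np.isin(arr, (0.0, 1.0))
    if bad.any():
        r, c = np.argwhere(bad)[0]
        raise ParseError(
            f"{path}: non-binary raster entry {arr[r, c]!r} at line {r + 1}, column {c + 1}"
        )
    return EventRaster(arr.astype(np.uint8), frame_rate)


def _read_matrix(path: Path) -> np.ndarray:
    try:
        arr = np.loadtxt(path, delimiter="\t", ndmin=2)
    except ValueError as e:
        raise ParseError(f"{path}: could not parse matrix: {e}") from e
    return arr


def read_annotation(path: str | Path) -> SessionAnnotation:
    path = Path(path)
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    missing = [c for c in _ANNOT_COLS if c not in df.columns]
    if missing:
        raise ParseError(f"{path}: missing columns {missing}")
    try:
        idx = df["frame_index"].astype(int).to_numpy()
    except ValueError as e:
        raise ParseError(f"{path}: non-integer frame_index: {e}") from e
    if not np.array_equal(idx, np.arange(len(df))):
        raise ParseError(f"{path}: frame_index must run 0..n_frames-1 without gaps")
    return SessionAnnotation(df.drop(columns=["frame_index"]))


def read_session(path: str | Path) -> SyntheticSession:
    path = Path(path)
    meta = json.loads((path / "meta.json").read_text()) if (path / "meta.json").exists() else {}
    frame_rate = float(meta.get("frame_rate", 20.0))
    raster = read_raster(path / "raster.tsv", frame_rate)
    annotation = read_annotation(path / "annotation.tsv")
    if annotation.n_frames != raster.n_frames:
        raise ParseError(
            f"{path}: annotation has {annotation.n_frames} frames "
            f"but raster has {raster.n_frames}"
        )
    traces = None
    if (path / "traces.tsv").exists():
        vals = _read_matrix(path / "traces.tsv")
        if vals.shape != raster.values.shape:
            raise ParseError(f"{path}: traces shape {vals.shape} != raster shape")
        traces = CalciumTraces(vals, frame_rate)
    truth = None
    if (path / "truth.json").exists():
        payload = json.loads((path / "truth.json").read_text())
        truth = GroundTruth(
            social_gain={k: np.array(v) for k, v in payload["social_gain"].items()},
            context_gain={k: np.array(v) for k, v in payload["context_gain"].items()},
            arm_gain={k: np.array(v) for k, v in payload["arm_gain"].items()},
            remap=bool(payload["remap"]),
            drift=np.array(payload["drift"]),
        )
    if traces is None:
        traces = CalciumTraces(raster.values.astype(float), frame_rate)
    return SyntheticSession(
        traces=traces, raster=raster, annotation=annotation, truth=truth
    )
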