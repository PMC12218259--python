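"""Core data containers shared across the analysis pipeline.

The central objects are a binary event raster (neurons x frames), optional
dF/F traces with the same shape, and a frame-aligned annotation table that
carries epoch, context, behavior and maze-arm labels.  All analyses address
frames through boolean masks built from the annotation; frames are 0-based
and intervals are half-open ``[start, end)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "CalciumTraces",
    "EventRaster",
    "SessionAnnotation",
    "NONSOCIAL_DEFINITIONS",
]

#: Recognised definitions of "nonsocial" frames.  ``all`` pools every frame
#: in which the animal is not interacting, regardless of whether a
#: conspecific is present; the alternates restrict to alone-only or
#: present-but-not-interacting frames.
NONSOCIAL_DEFINITIONS = ("all", "alone", "present")


def _as_2d_float(values) -> np.ndarray:
    arr = np.asarray(values, dtype=float)
    if arr.ndim != 2:
        raise ValueError(f"expected a neurons x frames matrix, got shape {arr.shape}")
    return arr


@dataclass
class CalciumTraces:
    """Per-neuron dF/F traces sampled at a fixed frame rate."""

    values: np.ndarray
    frame_rate: float = 20.0

    def __post_init__(self) -> None:
        self.values = _as_2d_float(self.values)
        if self.frame_rate <= 0:
            raise ValueError("frame_rate must be positive")

    @property
    def n_neurons(self) -> int:
        return self.values.shape[0]

    @property
    def n_frames(self) -> int:
        return self.values.shape[1]


@dataclass
class EventRaster:
    """Binary neurons x frames matrix of detected calcium events."""

    values: np.ndarray
    frame_rate: float = 20.0

    def __post_init__(self) -> None:
        arr = np.asarray(self.values)
        if arr.ndim != 2:
            raise ValueError(f"expected a neurons x frames matrix, got shape {arr.shape}")
        uniq = np.unique(arr)
        if not np.isin(uniq, (0, 1)).all():
            bad = uniq[~np.isin(uniq, (0, 1))]
            raise ValueError(f"raster entries must be 0/1; found {bad[:5]}")
        self.values = arr.astype(np.uint8)
        if self.frame_rate <= 0:
            raise ValueError("frame_rate must be positive")

    @property
    def n_neurons(self) -> int:
        return self.values.shape[0]

    @property
    def n_frames(self) -> int:
        return self.values.shape[1]


_ANNOTATION_COLUMNS = ("epoch_id", "context_id", "behavior_label", "arm_label")


class SessionAnnotation:
    """Frame-aligned epoch / context / behavior / arm labels.

    Wraps a DataFrame with one row per frame and columns ``epoch_id``,
    ``context_id``, ``behavior_label`` and ``arm_label`` (empty string when
    not applicable).  Every downstream analysis obtains its frame masks from
    this object.
    """

    def __init__(self, frame: pd.DataFrame):
        missing = [c for c in _ANNOTATION_COLUMNS if c not in frame.columns]
        if missing:
            raise ValueError(f"annotation missing columns: {missing}")
        df = frame.loc[:, list(_ANNOTATION_COLUMNS)].reset_index(drop=True)
        for c in _ANNOTATION_COLUMNS:
            df[c] = df[c].fillna("").astype(str)
        if df["epoch_id"].eq("").any():
            raise ValueError("every frame must carry an epoch_id")
        # epochs must be contiguous blocks
        codes = df["epoch_id"].to_numpy()
        change = np.flatnonzero(codes[1:] != codes[:-1]) + 1
        blocks = [codes[0]] + [codes[i] for i in change]
        if len(blocks) != len(set(blocks)):
            raise ValueError("epoch_id blocks must be contiguous (an epoch id recurs)")
        self.frame = df

    @property
    def n_frames(self) -> int:
        return len(self.frame)

    @property
    def epoch_ids(self) -> list[str]:
        return list(dict.fromkeys(self.frame["epoch_id"]))

    @property
    def context_ids(self) -> list[str]:
        return list(dict.fromkeys(c for c in self.frame["context_id"] if c))

    def context_of(self, epoch_id: str) -> str:
        sel = self.frame.loc[self.frame["epoch_id"] == epoch_id, "context_id"]
        if sel.empty:
            raise KeyError(f"unknown epoch {epoch_id!r}")
        return sel.iloc[0]

    # ------------------------------------------------------------------ masks
    def epoch_mask(self, epochs: str | Iterable[str]) -> np.ndarray:
        if isinstance(epochs, str):
            epochs = [epochs]
        epochs = list(epochs)
        unknown = set(epochs) - set(self.epoch_ids)
        if unknown:
            raise KeyError(f"unknown epochs: {sorted(unknown)}")
        return self.frame["epoch_id"].isin(epochs).to_numpy()

    def context_mask(self, contexts: str | Iterable[str]) -> np.ndarray:
        if isinstance(contexts, str):
            contexts = [contexts]
        return self.frame["context_id"].isin(list(contexts)).to_numpy()

    def behavior_mask(self, behavior: str, epochs: Iterable[str] | None = None) -> np.ndarray:
        m = (self.frame["behavior_label"] == behavior).to_numpy()
        if epochs is not None:
            m &= self.epoch_mask(epochs)
        return m

    def social_mask(self, epochs: Iterable[str] | None = None) -> np.ndarray:
        return self.behavior_mask("social", epochs)

    def nonsocial_mask(
        self, epochs: Iterable[str] | None = None, definition: str = "all"
    ) -> np.ndarray:
        """Frames without active interaction.

        ``definition`` selects between the pooled definition (every
        non-interaction frame), alone-only, or conspecific-present-but-not-
        interacting frames.
        """
        if definition not in NONSOCIAL_DEFINITIONS:
            raise ValueError(f"definition must be one of {NONSOCIAL_DEFINITIONS}")
        beh = self.frame["behavior_label"].to_numpy()
        if definition == "all":
            m = beh != "social"
        elif definition == "alone":
            m = beh == "alone"
        else:
            m = beh == "present"
        if epochs is not None:
            m &= self.epoch_mask(epochs)
        return m

    def arm_mask(self, arms: str | Iterable[str], epochs: Iterable[str] | None = None) -> np.ndarray:
        if isinstance(arms, str):
            arms = [arms]
        m = self.frame["arm_label"].isin(list(arms)).to_numpy()
        if epochs is not None:
            m &= self.epoch_mask(epochs)
        return m

    def arm_labels(self, epochs: Iterable[str] | None = None) -> list[str]:
        sub = self.frame if epochs is None else self.frame[self.epoch_mask(epochs)]
        return sorted(a for a in sub["arm_label"].unique() if a)

    # ------------------------------------------------------------- validation
    def check_length(self, n_frames: int, what: str = "raster") -> None:
        if self.n_frames != n_frames:
            raise ValueError(
                f"annotation has {self.n_frames} frames but {what} has {n_frames}"
            )

    def __eq__(self, other) -> bool:  # pragma: no cover - convenience
        return isinstance(other, SessionAnnotation) and self.frame.equals(other.frame)


def require_nonempty(mask: np.ndarray, name: str) -> np.ndarray:
    """Validate that a condition mask selects at least one frame."""
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise ValueError(f"condition {name!r} selects no frames")
    return mask
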