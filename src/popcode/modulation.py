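"""Per-neuron modulation indices from circular-shift permutation nulls.

For each neuron, the activity row restricted to an analysis scope (one
epoch, the epoch pair AB or CD, or a maze plus its adjacent home-cage
blocks) is circularly shifted by offsets drawn uniformly from
``{0, ..., T-1}``; the condition statistic (mean activity inside a frame
mask, or the difference in mean activity between two masks) is recomputed
at every shift.  The modulation index is the percentile of the observed
statistic within this null distribution, on a 0-100 scale with a mid-rank
tie convention:

    index = 100 * (#{null < observed} + 0.5 * #{null == observed}) / n_shuffles

Indices > 90 flag neurons more active in the condition than expected by
chance, indices < 10 less active.  Because rows are binary, every per-shift
statistic is an exact ratio of integer counts; the all-shift count profile
is computed by circular cross-correlation (FFT, rounded back to integers),
so the sampled null and the exhaustive-enumeration null agree bit-exactly.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .core import EventRaster, SessionAnnotation
from .synthgen import MAZE_ARMS

__all__ = [
    "NullDistribution",
    "ModulationVector",
    "circular_shift_stats",
    "circular_null",
    "modulation_index",
    "behavior_modulation",
    "context_modulation",
    "maze_modulation",
    "arm_modulation",
]

DEFAULT_N_SHUFFLES = 10_000


@dataclass
class NullDistribution:
    """Per-neuron null statistic values under circular shifts."""

    values: np.ndarray  # (n_neurons, n_shuffles)
    statistic: str  # "mean-in-mask" | "mean-difference"
    n_shuffles: int
    exhaustive: bool = False


@dataclass
class ModulationVector:
    """Per-neuron percentile indices for one scope/contrast."""

    index: np.ndarray  # (n_neurons,), NaN where excluded
    excluded: np.ndarray  # (n_neurons,) bool
    scope: tuple[str, ...]
    contrast: str

    @property
    def n_neurons(self) -> int:
        return len(self.index)

    def valid(self) -> np.ndarray:
        return ~self.excluded

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "neuron_id": np.arange(self.n_neurons),
                "scope": "+".join(self.scope),
                "contrast": self.contrast,
                "index": self.index,
                "excluded": self.excluded,
            }
        )


def _mask_count_profile(rows: np.ndarray, mask: np.ndarray) -> np.ndarray:
    """Event counts inside ``mask`` for every circular shift.

    ``profile[i, s]`` is the number of events neuron ``i`` has inside the
    mask after shifting its row right by ``s``.  Computed as a circular
    cross-correlation; inputs are 0/1 so results are rounded back to exact
    integers.
    """
    T = rows.shape[1]
    rf = np.fft.rfft(rows, axis=1)
    mf = np.fft.rfft(mask.astype(float))
    prof = np.fft.irfft(np.conj(rf) * mf[None, :], n=T, axis=1)
    return np.rint(prof).astype(np.int64)


def circular_shift_stats(
    rows: np.ndarray,
    mask_a: np.ndarray,
    mask_b: np.ndarray | None = None,
) -> np.ndarray:
    """The statistic at every possible shift offset (n_neurons x T).

    Mean activity inside ``mask_a``, or the difference of means between
    ``mask_a`` and ``mask_b``.
    """
    na = int(mask_a.sum())
    if na == 0:
        raise ValueError("mask_a selects no frames")
    stats = _mask_count_profile(rows, mask_a) / na
    if mask_b is not None:
        nb = int(mask_b.sum())
        if nb == 0:
            raise ValueError("mask_b selects no frames")
        stats = stats - _mask_count_profile(rows, mask_b) / nb
    return stats


def circular_null(
    rows: np.ndarray,
    mask: np.ndarray,
    statistic: str = "mean-in-mask",
    n_shuffles: int = DEFAULT_N_SHUFFLES,
    seed: int | np.random.Generator | None = None,
    mask_b: np.ndarray | None = None,
    exhaustive: bool = False,
) -> NullDistribution:
    """Null distribution of the statistic under uniform circular shifts.

    ``rows`` must already be restricted to the scope's concatenated frames;
    ``mask`` (and ``mask_b`` for the mean-difference statistic) index into
    those columns.  Offsets are sampled with replacement (offset 0 allowed);
    with ``exhaustive`` every offset ``0..T-1`` is used exactly once.
    """
    rows = np.atleast_2d(np.asarray(rows))
    T = rows.shape[1]
    if T < 2:
        raise ValueError("scope length must be at least 2 frames")
    if statistic not in ("mean-in-mask", "mean-difference"):
        raise ValueError(f"unknown statistic {statistic!r}")
    if statistic == "mean-difference" and mask_b is None:
        raise ValueError("mean-difference requires mask_b")
    stats_all = circular_shift_stats(
        rows, np.asarray(mask, bool), None if statistic == "mean-in-mask" else mask_b
    )
    if exhaustive:
        return NullDistribution(stats_all, statistic, T, exhaustive=True)
    rng = np.random.default_rng(seed)
    # per-neuron deterministic substreams
    offsets = np.vstack(
        [g.integers(0, T, size=n_shuffles) for g in rng.spawn(rows.shape[0])]
    )
    values = np.take_along_axis(stats_all, offsets, axis=1)
    return NullDistribution(values, statistic, n_shuffles)


def modulation_index(observed: np.ndarray | float, null: NullDistribution) -> np.ndarray:
    """Mid-rank percentile of the observed statistic in its null (0-100).

    NaN observed values propagate to NaN indices (excluded neurons).
    """
    obs = np.atleast_1d(np.asarray(observed, dtype=float))
    vals = null.values
    if vals.shape[0] != obs.shape[0]:
        raise ValueError("observed and null have different neuron counts")
    below = (vals < obs[:, None]).sum(axis=1)
    ties = (vals == obs[:, None]).sum(axis=1)
    idx = 100.0 * (below + 0.5 * ties) / vals.shape[1]
    idx[~np.isfinite(obs)] = np.nan
    return idx


def _indices_from_masks(
    raster: EventRaster,
    scope_mask: np.ndarray,
    mask_a: np.ndarray,
    mask_b: np.ndarray | None,
    statistic: str,
    n_shuffles: int,
    seed,
    scope: tuple[str, ...],
    contrast: str,
    exhaustive: bool = False,
) -> ModulationVector:
    scope_idx = np.flatnonzero(scope_mask)
    if scope_idx.size < 2:
        raise ValueError(f"scope {scope} spans fewer than 2 frames")
    rows = raster.values[:, scope_idx].astype(np.int64)
    a = np.asarray(mask_a, bool)[scope_idx]
    b = np.asarray(mask_b, bool)[scope_idx] if mask_b is not None else None
    if not a.any():
        raise ValueError(f"contrast {contrast!r}: first mask empty within scope {scope}")
    if b is not None and not b.any():
        raise ValueError(f"contrast {contrast!r}: second mask empty within scope {scope}")
    # remove neurons with no activity in either set of frames (for the
    # mean-in-mask statistic: no activity anywhere in the scope)
    active_mask = np.ones(rows.shape[1], bool) if b is None else (a | b)
    excluded = rows[:, active_mask].sum(axis=1) == 0
    na = int(a.sum())
    obs = rows[:, a].sum(axis=1) / na
    if b is not None:
        obs = obs - rows[:, b].sum(axis=1) / int(b.sum())
    null = circular_null(
        rows, a, statistic, n_shuffles, seed, mask_b=b, exhaustive=exhaustive
    )
    idx = modulation_index(obs, null)
    idx[excluded] = np.nan
    return ModulationVector(idx, excluded, scope, contrast)


def behavior_modulation(
    raster: EventRaster,
    annotation: SessionAnnotation,
    scope: Sequence[str],
    behavior: str = "social",
    statistic: str = "mean-in-mask",
    n_shuffles: int = DEFAULT_N_SHUFFLES,
    seed: int | np.random.Generator | None = None,
    nonsocial_definition: str = "all",
    exhaustive: bool = False,
) -> ModulationVector:
    """Behavioral (social / nonsocial) modulation index over an epoch set.

    ``statistic='mean-in-mask'`` gives the epoch-specific index (activity
    during the behavior's frames vs chance within the scope);
    ``'mean-difference'`` contrasts the behavior's frames against the
    complementary nonsocial frames.  Epochs are concatenated and a single
    circular shift is applied across the concatenation.
    """
    scope = tuple(scope)
    scope_mask = annotation.epoch_mask(scope)
    if behavior == "social":
        mask_a = annotation.social_mask(scope)
        mask_b_full = annotation.nonsocial_mask(scope, nonsocial_definition)
    elif behavior in ("nonsocial", "alone", "present"):
        definition = "all" if behavior == "nonsocial" else behavior
        mask_a = annotation.nonsocial_mask(scope, definition)
        mask_b_full = annotation.social_mask(scope)
    else:
        mask_a = annotation.behavior_mask(behavior, scope)
        mask_b_full = scope_mask & ~mask_a
    if not mask_a.any():
        raise ValueError(f"behavior {behavior!r} absent in scope {scope}")
    mask_b = mask_b_full if statistic == "mean-difference" else None
    return _indices_from_masks(
        raster, scope_mask, mask_a, mask_b, statistic, n_shuffles, seed,
        scope, f"{behavior}" + ("-minus-rest" if mask_b is not None else "-vs-null"),
        exhaustive,
    )


def context_modulation(
    raster: EventRaster,
    annotation: SessionAnnotation,
    context_split: tuple[Sequence[str], Sequence[str]],
    n_shuffles: int = DEFAULT_N_SHUFFLES,
    seed: int | np.random.Generator | None = None,
    exhaustive: bool = False,
) -> ModulationVector:
    """Context modulation: mean activity in epoch set A minus set B,
    against shifts over the concatenated A+B scope (all frames, social and
    nonsocial alike)."""
    eps_a, eps_b = (tuple(e) for e in context_split)
    mask_a = annotation.epoch_mask(eps_a)
    mask_b = annotation.epoch_mask(eps_b)
    if not mask_a.any() or not mask_b.any():
        raise ValueError("both context epoch sets must contain frames")
    scope_mask = mask_a | mask_b
    return _indices_from_masks(
        raster, scope_mask, mask_a, mask_b, "mean-difference", n_shuffles, seed,
        eps_a + eps_b, f"{'+'.join(eps_a)}-minus-{'+'.join(eps_b)}", exhaustive,
    )


def _adjacent_hc_epochs(annotation: SessionAnnotation, maze_epoch: str) -> list[str]:
    ids = annotation.epoch_ids
    k = ids.index(maze_epoch)
    adj = []
    if k > 0 and ids[k - 1].startswith("HC"):
        adj.append(ids[k - 1])
    if k + 1 < len(ids) and ids[k + 1].startswith("HC"):
        adj.append(ids[k + 1])
    if not adj:
        raise ValueError(f"maze epoch {maze_epoch!r} has no adjacent home-cage epochs")
    return adj


def maze_modulation(
    raster: EventRaster,
    annotation: SessionAnnotation,
    maze_epoch: str,
    hc_epochs: Sequence[str] | None = None,
    n_shuffles: int = DEFAULT_N_SHUFFLES,
    seed: int | np.random.Generator | None = None,
    exhaustive: bool = False,
) -> ModulationVector:
    """Maze-vs-home-cage context index: mean activity within the maze as a
    percentile of shifts across all frames from the maze and the adjacent
    home-cage epochs."""
    if hc_epochs is None:
        hc_epochs = _adjacent_hc_epochs(annotation, maze_epoch)
    scope = tuple(hc_epochs[:1]) + (maze_epoch,) + tuple(hc_epochs[1:])
    scope_mask = annotation.epoch_mask(scope)
    mask_a = annotation.epoch_mask(maze_epoch)
    return _indices_from_masks(
        raster, scope_mask, mask_a, None, "mean-in-mask", n_shuffles, seed,
        scope, f"{maze_epoch}-vs-HC", exhaustive,
    )


def arm_modulation(
    raster: EventRaster,
    annotation: SessionAnnotation,
    maze_epoch: str,
    arms: str | Sequence[str],
    n_shuffles: int = DEFAULT_N_SHUFFLES,
    seed: int | np.random.Generator | None = None,
    exhaustive: bool = False,
) -> ModulationVector:
    """Arm-specific index: mean activity in the given arm(s) as a percentile
    of shifts across all frames of that maze (e.g. open arms vs the whole
    elevated zero maze)."""
    if isinstance(arms, str):
        arms = [arms]
    scope_mask = annotation.epoch_mask(maze_epoch)
    available = annotation.arm_labels([maze_epoch])
    missing = [a for a in arms if a not in available]
    if missing:
        raise ValueError(
            f"arm(s) {missing} never visited in {maze_epoch}; available: {available}"
        )
    mask_a = annotation.arm_mask(arms, [maze_epoch])
    return _indices_from_masks(
        raster, scope_mask, mask_a, None, "mean-in-mask", n_shuffles, seed,
        (maze_epoch,), f"{'+'.join(arms)}-vs-{maze_epoch}", exhaustive,
    )
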