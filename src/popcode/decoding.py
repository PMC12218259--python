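"""Balanced linear decoding of behavior/context from event rasters.

Single frames are the samples and neurons the features.  Each iteration
downsamples the majority class to the minority-class count, fits a linear
max-margin classifier (hinge loss, C = 1), and scores accuracy, precision,
recall and F1 on held-out frames (or on a disjoint test scope for transfer
decoding).  Chance level is established with degree-preserving surrogate
rasters in which event neuron-identities are swapped so that both per-frame
and per-neuron event counts are unchanged.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.exceptions import ConvergenceWarning
from sklearn.svm import LinearSVC

from .core import EventRaster, require_nonempty
from .modulation import ModulationVector

__all__ = [
    "DecodeTask",
    "DecodingResult",
    "surrogate_shuffle",
    "train_eval",
    "transfer_eval",
    "metrics",
    "weight_modulation_correlation",
]


@dataclass
class DecodeTask:
    """One decoding problem: which frames are positive/negative, how many
    balanced iterations, and the hold-out fraction."""

    positive_mask: np.ndarray
    negative_mask: np.ndarray
    n_iterations: int = 500
    holdout: float = 0.25
    seed: int | np.random.Generator | None = None
    C: float = 1.0

    def __post_init__(self):
        self.positive_mask = np.asarray(self.positive_mask, bool)
        self.negative_mask = np.asarray(self.negative_mask, bool)
        if (self.positive_mask & self.negative_mask).any():
            raise ValueError("positive and negative masks overlap")
        if not 0 < self.holdout < 1:
            raise ValueError("holdout must lie in (0, 1)")


@dataclass
class DecodingResult:
    """Iteration-averaged classification metrics for one train/test pair."""

    train_scope: str
    test_scope: str
    accuracy_mean: float
    accuracy_sd: float
    precision: float
    recall: float
    f1: float
    n_iterations: int
    beta_mean: np.ndarray | None = None  # mean fitted weight per neuron
    surrogate: bool = False

    def to_row(self) -> dict:
        return {
            "train_scope": self.train_scope,
            "test_scope": self.test_scope,
            "accuracy_mean": self.accuracy_mean,
            "accuracy_sd": self.accuracy_sd,
            "precision": self.precision,
            "recall": self.recall,
            "f1": self.f1,
            "n_iterations": self.n_iterations,
            "surrogate": self.surrogate,
        }


# --------------------------------------------------------------------------
# degree-preserving surrogate
# --------------------------------------------------------------------------

def surrogate_shuffle(
    raster: EventRaster,
    seed: int | np.random.Generator | None = None,
    swaps_per_event: int = 10,
) -> EventRaster:
    """Shuffle event neuron-identities preserving both margins exactly.

    Randomizes the binary matrix by 2x2 checkerboard swaps: two events
    (r1, c1), (r2, c2) with r1 != r2, c1 != c2 and empty opposite corners
    are traded for (r1, c2), (r2, c1).  Each swap preserves every row and
    column sum.  The number of attempted swaps is ``swaps_per_event`` times
    the event count; degenerate matrices come back unchanged.
    """
    rng = np.random.default_rng(seed)
    M = raster.values.copy()
    n_rows, n_cols = M.shape
    events = [int(r) * n_cols + int(c) for r, c in zip(*np.nonzero(M))]
    n_events = len(events)
    if n_events < 2:
        return EventRaster(M, raster.frame_rate)
    occupied = set(events)
    n_attempts = swaps_per_event * n_events
    pair_idx = rng.integers(0, n_events, size=(n_attempts, 2))
    for i, j in pair_idx:
        if i == j:
            continue
        e1, e2 = events[i], events[j]
        r1, c1 = divmod(e1, n_cols)
        r2, c2 = divmod(e2, n_cols)
        if r1 == r2 or c1 == c2:
            continue
        f1 = r1 * n_cols + c2
        f2 = r2 * n_cols + c1
        if f1 in occupied or f2 in occupied:
            continue
        occupied.discard(e1)
        occupied.discard(e2)
        occupied.add(f1)
        occupied.add(f2)
        events[i], events[j] = f1, f2
    out = np.zeros_like(M)
    flat = np.fromiter(occupied, dtype=np.int64, count=len(occupied))
    out.flat[flat] = 1
    return EventRaster(out, raster.frame_rate)


# --------------------------------------------------------------------------
# metrics
# --------------------------------------------------------------------------

def metrics(tp: int, fp: int, fn: int, tn: int = 0) -> dict[str, float]:
    """Precision, recall and F1 from confusion counts.

    Undefined ratios (zero denominators) are returned as NaN with an
    explicit flag rather than silently coerced to 0.
    """
    if min(tp, fp, fn, tn) < 0:
        raise ValueError("confusion counts must be non-negative")
    precision = tp / (tp + fp) if (tp + fp) > 0 else np.nan
    recall = tp / (tp + fn) if (tp + fn) > 0 else np.nan
    if np.isfinite(precision) and np.isfinite(recall) and (precision + recall) > 0:
        f1 = 2 * precision * recall / (precision + recall)
    else:
        f1 = np.nan
    return {
        "precision": precision,
        "recall": recall,
        "f1": f1,
        "precision_defined": bool(np.isfinite(precision)),
        "recall_defined": bool(np.isfinite(recall)),
        "f1_defined": bool(np.isfinite(f1)),
    }


def _fit_linear(X: np.ndarray, y: np.ndarray, C: float) -> LinearSVC:
    clf = LinearSVC(C=C, loss="hinge", max_iter=5000, tol=1e-3, random_state=0)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ConvergenceWarning)
        clf.fit(X, y)
    return clf


def _balanced_sample(
    pos_idx: np.ndarray, neg_idx: np.ndarray, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    n = min(len(pos_idx), len(neg_idx))
    p = rng.choice(pos_idx, size=n, replace=False)
    q = rng.choice(neg_idx, size=n, replace=False)
    return p, q


def train_eval(raster: EventRaster, task: DecodeTask, scope_name: str = "all") -> DecodingResult:
    """Train/test with hold-out on one scope, balancing classes per iteration.

    Each iteration: downsample the majority class to the minority count,
    split the balanced set into train and hold-out fractions, fit the
    linear classifier, and score the held-out frames.
    """
    X = raster.values.T.astype(np.float64)
    pos_idx = np.flatnonzero(task.positive_mask)
    neg_idx = np.flatnonzero(task.negative_mask)
    _check_classes(pos_idx, neg_idx)
    rng = np.random.default_rng(task.seed)
    accs, tps, fps, fns, tns, betas = [], 0, 0, 0, 0, []
    for _ in range(task.n_iterations):
        p, q = _balanced_sample(pos_idx, neg_idx, rng)
        n = len(p)
        n_test = max(int(round(task.holdout * n)), 1)
        perm_p, perm_q = rng.permutation(n), rng.permutation(n)
        test_p, train_p = p[perm_p[:n_test]], p[perm_p[n_test:]]
        test_q, train_q = q[perm_q[:n_test]], q[perm_q[n_test:]]
        Xtr = X[np.concatenate([train_p, train_q])]
        ytr = np.r_[np.ones(len(train_p)), np.zeros(len(train_q))]
        clf = _fit_linear(Xtr, ytr, task.C)
        Xte = X[np.concatenate([test_p, test_q])]
        yte = np.r_[np.ones(n_test), np.zeros(n_test)]
        pred = clf.predict(Xte)
        accs.append((pred == yte).mean())
        tps += int(((pred == 1) & (yte == 1)).sum())
        fps += int(((pred == 1) & (yte == 0)).sum())
        fns += int(((pred == 0) & (yte == 1)).sum())
        tns += int(((pred == 0) & (yte == 0)).sum())
        betas.append(clf.coef_.ravel())
    m = metrics(tps, fps, fns, tns)
    return DecodingResult(
        train_scope=scope_name,
        test_scope=scope_name,
        accuracy_mean=float(np.mean(accs)),
        accuracy_sd=float(np.std(accs)),
        precision=m["precision"],
        recall=m["recall"],
        f1=m["f1"],
        n_iterations=task.n_iterations,
        beta_mean=np.mean(betas, axis=0),
    )


def _check_classes(pos_idx: np.ndarray, neg_idx: np.ndarray) -> None:
    if len(pos_idx) == 0 or len(neg_idx) == 0:
        raise ValueError("a class has zero frames")
    if min(len(pos_idx), len(neg_idx)) < 10:
        warnings.warn("fewer than 10 frames in a class", RuntimeWarning)


def transfer_eval(
    raster: EventRaster,
    train_task: DecodeTask,
    test_masks: Sequence[tuple[str, np.ndarray, np.ndarray]],
    train_name: str = "train",
    balance_test: bool = True,
) -> list[DecodingResult]:
    """Train on one scope, test on disjoint scopes.

    ``test_masks`` is a sequence of ``(name, positive_mask, negative_mask)``.
    Training uses all frames of the training scope with per-iteration
    balancing; testing draws equal random subsamples per class each
    iteration (making 50% the exact chance level) unless ``balance_test``
    is off.
    """
    X = raster.values.T.astype(np.float64)
    pos_idx = np.flatnonzero(train_task.positive_mask)
    neg_idx = np.flatnonzero(train_task.negative_mask)
    _check_classes(pos_idx, neg_idx)
    train_frames = train_task.positive_mask | train_task.negative_mask
    for name, pm, nm in test_masks:
        if ((pm | nm) & train_frames).any():
            raise ValueError(f"test scope {name!r} overlaps the training frames")
    rng = np.random.default_rng(train_task.seed)
    acc: dict[str, list[float]] = {name: [] for name, _, _ in test_masks}
    counts = {name: [0, 0, 0, 0] for name, _, _ in test_masks}
    betas = []
    for _ in range(train_task.n_iterations):
        p, q = _balanced_sample(pos_idx, neg_idx, rng)
        Xtr = X[np.concatenate([p, q])]
        ytr = np.r_[np.ones(len(p)), np.zeros(len(q))]
        clf = _fit_linear(Xtr, ytr, train_task.C)
        betas.append(clf.coef_.ravel())
        for name, pm, nm in test_masks:
            tp_idx = np.flatnonzero(pm)
            tn_idx = np.flatnonzero(nm)
            if balance_test:
                tp_idx, tn_idx = _balanced_sample(tp_idx, tn_idx, rng)
            Xte = X[np.concatenate([tp_idx, tn_idx])]
            yte = np.r_[np.ones(len(tp_idx)), np.zeros(len(tn_idx))]
            pred = clf.predict(Xte)
            acc[name].append((pred == yte).mean())
            c = counts[name]
            c[0] += int(((pred == 1) & (yte == 1)).sum())
            c[1] += int(((pred == 1) & (yte == 0)).sum())
            c[2] += int(((pred == 0) & (yte == 1)).sum())
            c[3] += int(((pred == 0) & (yte == 0)).sum())
    beta_mean = np.mean(betas, axis=0)
    results = []
    for name, _, _ in test_masks:
        tp, fp, fn, tn = counts[name]
        m = metrics(tp, fp, fn, tn)
        results.append(
            DecodingResult(
                train_scope=train_name,
                test_scope=name,
                accuracy_mean=float(np.mean(acc[name])),
                accuracy_sd=float(np.std(acc[name])),
                precision=m["precision"],
                recall=m["recall"],
                f1=m["f1"],
                n_iterations=train_task.n_iterations,
                beta_mean=beta_mean,
            )
        )
    return results


def weight_modulation_correlation(
    result: DecodingResult, modvec: ModulationVector
) -> tuple[float, float]:
    """Pearson r (and p) between mean classifier weights and modulation
    indices over the shared non-excluded neuron set."""
    if result.beta_mean is None:
        raise ValueError("decoding result carries no weight vector")
    beta = np.asarray(result.beta_mean)
    idx = modvec.index
    if len(beta) != len(idx):
        raise ValueError("weight vector and modulation vector differ in length")
    keep = np.isfinite(idx)
    if keep.sum() < 3:
        raise ValueError("fewer than 3 shared neurons")
    r, p = stats.pearsonr(beta[keep], idx[keep])
    return float(r), float(p)
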