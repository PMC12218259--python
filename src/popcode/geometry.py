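"""Orthogonality and overlap structure of modulation vectors.

Two ensembles (e.g. the social ensemble and the context ensemble) are
compared by the similarity of their modulation-index vectors: cosine
similarity after zero-centering each index (subtracting 50, the null
midpoint of a percentile), or the Pearson correlation (mean-centering).
Significance comes from an entry-permutation null: the neuron assigned to
each index value of one vector is randomly re-assigned.  Overlap between
strongly modulated groups (>90th / <10th percentile) is tabulated in 3x3
tables and compared across days with per-cell 2x2 chi-square tests.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .modulation import ModulationVector

__all__ = [
    "VectorSimilarityReport",
    "OverlapTable",
    "vector_similarity",
    "similarity_report_matrix",
    "overlap_table",
    "compare_overlap",
]

CENTER = 50.0  # null expectation of a percentile index
POSITIVE_CUT = 90.0  # strictly greater => positively modulated
NEGATIVE_CUT = 10.0  # strictly less => negatively modulated


@dataclass
class VectorSimilarityReport:
    pair: tuple[str, str]
    metric: str  # "cosine" (zero-centered) | "pearson"
    observed: float
    null_mean: float
    null_sd: float
    percentile: float  # mid-rank percentile of observed in the null
    n_permutations: int
    n_neurons: int

    @property
    def outside_null_band(self) -> bool:
        """Observed outside the central 95% of the permutation null."""
        return self.percentile > 97.5 or self.percentile < 2.5


def _paired_values(v1: ModulationVector, v2: ModulationVector) -> tuple[np.ndarray, np.ndarray]:
    if v1.n_neurons != v2.n_neurons:
        raise ValueError("modulation vectors differ in neuron count")
    keep = np.isfinite(v1.index) & np.isfinite(v2.index)
    if keep.sum() < 3:
        raise ValueError("fewer than 3 shared non-excluded neurons")
    return v1.index[keep], v2.index[keep]


def _similarity(a: np.ndarray, b: np.ndarray, metric: str) -> float:
    if metric == "cosine":
        x, y = a - CENTER, b - CENTER
    elif metric == "pearson":
        x, y = a - a.mean(), b - b.mean()
    else:
        raise ValueError(f"unknown metric {metric!r}")
    nx, ny = np.linalg.norm(x), np.linalg.norm(y)
    if nx == 0 or ny == 0:
        return np.nan  # all-constant vector: similarity undefined
    return float(np.dot(x, y) / (nx * ny))


def vector_similarity(
    v1: ModulationVector,
    v2: ModulationVector,
    metric: str = "cosine",
    n_permutations: int = 10_000,
    seed: int | np.random.Generator | None = None,
    names: tuple[str, str] = ("v1", "v2"),
) -> VectorSimilarityReport:
    """Similarity between two modulation vectors with a permutation null.

    The null re-assigns the neuron associated with each index value of the
    second vector; the report carries the observed value, the null mean and
    sd, and the mid-rank percentile of the observed value in the null.
    """
    a, b = _paired_values(v1, v2)
    observed = _similarity(a, b, metric)
    rng = np.random.default_rng(seed)
    null = np.empty(n_permutations)
    for k in range(n_permutations):
        null[k] = _similarity(a, rng.permutation(b), metric)
    below = (null < observed).sum()
    ties = (null == observed).sum()
    pct = 100.0 * (below + 0.5 * ties) / n_permutations
    return VectorSimilarityReport(
        pair=names,
        metric=metric,
        observed=observed,
        null_mean=float(null.mean()),
        null_sd=float(null.std()),
        percentile=float(pct),
        n_permutations=n_permutations,
        n_neurons=len(a),
    )


def similarity_report_matrix(
    vectors: Sequence[ModulationVector],
    names: Sequence[str] | None = None,
    metric: str = "cosine",
    n_permutations: int = 1000,
    seed: int | np.random.Generator | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame, dict[tuple[str, str], VectorSimilarityReport]]:
    """All-pairs similarity with real and shuffled matrices.

    Returns (real, shuffled, reports): the observed pairwise similarity
    matrix, the matching permutation-null-mean matrix (self-pairs included:
    permutation destroys self-similarity, so shuffled diagonals sit near 0),
    and the per-pair reports keyed by name.  Neuron sets are aligned
    pairwise (intersection of non-excluded neurons).
    """
    if names is None:
        names = [f"v{i}" for i in range(len(vectors))]
    k = len(vectors)
    rng = np.random.default_rng(seed)
    real = np.full((k, k), np.nan)
    shuf = np.full((k, k), np.nan)
    reports: dict[tuple[str, str], VectorSimilarityReport] = {}
    for i in range(k):
        for j in range(i, k):
            rep = vector_similarity(
                vectors[i], vectors[j], metric, n_permutations, rng,
                names=(names[i], names[j]),
            )
            real[i, j] = real[j, i] = rep.observed
            shuf[i, j] = shuf[j, i] = rep.null_mean
            reports[(names[i], names[j])] = rep
    real_df = pd.DataFrame(real, index=list(names), columns=list(names))
    shuf_df = pd.DataFrame(shuf, index=list(names), columns=list(names))
    return real_df, shuf_df, reports


@dataclass
class OverlapTable:
    """3x3 counts of neurons by modulation class on two vectors.

    Classes: positive (> 90), middle (10-90 inclusive), negative (< 10);
    rows index the first vector, columns the second.
    """

    counts: np.ndarray  # (3, 3) ints, rows/cols = (positive, middle, negative)
    n: int
    labels: tuple[str, ...] = ("positive", "middle", "negative")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=self.labels, columns=self.labels)

    def proportion(self, row: str, col: str) -> float:
        i, j = self.labels.index(row), self.labels.index(col)
        return self.counts[i, j] / self.n


def _classify(idx: np.ndarray) -> np.ndarray:
    cls = np.ones(len(idx), dtype=int)  # middle
    cls[idx > POSITIVE_CUT] = 0
    cls[idx < NEGATIVE_CUT] = 2
    return cls


def overlap_table(v1: ModulationVector, v2: ModulationVector) -> OverlapTable:
    """Cross-tabulate strongly modulated groups on two index vectors."""
    a, b = _paired_values(v1, v2)
    ca, cb = _classify(a), _classify(b)
    counts = np.zeros((3, 3), dtype=int)
    for i, j in zip(ca, cb):
        counts[i, j] += 1
    return OverlapTable(counts, len(a))


def compare_overlap(
    table_a: OverlapTable,
    table_b: OverlapTable,
    cell: tuple[str, str],
    continuity_correction: bool = False,
) -> dict[str, float]:
    """Per-cell 2x2 chi-square comparison of two overlap tables.

    Tests whether the fraction of neurons in the chosen cell differs
    between the two tables (in-cell vs not, table A vs table B).
    """
    if table_a.n <= 0 or table_b.n <= 0:
        raise ValueError("overlap tables must have positive n")
    i, j = (table_a.labels.index(cell[0]), table_a.labels.index(cell[1]))
    a_in = int(table_a.counts[i, j])
    b_in = int(table_b.counts[i, j])
    cont = np.array(
        [[a_in, table_a.n - a_in], [b_in, table_b.n - b_in]], dtype=float
    )
    if (cont.sum(axis=0) == 0).any():
        # both tables empty (or full) in this cell: no difference to test
        return {
            "chi2": 0.0,
            "pvalue": 1.0,
            "dof": 1,
            "prop_a": a_in / table_a.n,
            "prop_b": b_in / table_b.n,
        }
    expected = stats.contingency.expected_freq(cont)
    if (expected < 1).any():
        import warnings

        warnings.warn("expected count below 1 in chi-square comparison", RuntimeWarning)
    chi2, p, dof, _ = stats.chi2_contingency(cont, correction=continuity_correction)
    return {
        "chi2": float(chi2),
        "pvalue": float(p),
        "dof": int(dof),
        "prop_a": a_in / table_a.n,
        "prop_b": b_in / table_b.n,
    }
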