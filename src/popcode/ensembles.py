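"""Population activity vectors, activity summaries and similarity matrices.

A population vector is the per-neuron mean activity over a condition's
frames: in raster mode the fraction of frames active, in trace mode the mean
z-scored dF/F.  Similarity between conditions is the Pearson correlation
between their population vectors; neurons with >7.5% of frames active in a
condition are classed "highly active", neurons with no events "inactive".
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .core import EventRaster, CalciumTraces, SessionAnnotation, require_nonempty

__all__ = [
    "PopulationVector",
    "SimilarityMatrix",
    "HIGHLY_ACTIVE_THRESHOLD",
    "population_vector",
    "activity_summary",
    "similarity_matrix",
    "within_between_summary",
    "filter_active_both",
]

#: Strict lower bound on fraction-of-frames-active for the "highly active"
#: class (a neuron at exactly the threshold is not highly active).
HIGHLY_ACTIVE_THRESHOLD = 0.075


@dataclass
class PopulationVector:
    condition: str
    values: np.ndarray  # (n_neurons,)
    n_frames: int
    mode: str = "raster"  # or "trace"

    def __len__(self) -> int:
        return len(self.values)


@dataclass
class SimilarityMatrix:
    conditions: list[str]
    values: np.ndarray  # pairwise Pearson r

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.conditions, columns=self.conditions)

    def pair(self, a: str, b: str) -> float:
        i, j = self.conditions.index(a), self.conditions.index(b)
        return float(self.values[i, j])


def population_vector(
    data: EventRaster | CalciumTraces,
    mask: np.ndarray,
    condition: str = "",
) -> PopulationVector:
    """Per-neuron mean activity over the masked frames."""
    mask = require_nonempty(mask, condition or "mask")
    values = data.values[:, mask].mean(axis=1)
    mode = "raster" if isinstance(data, EventRaster) else "trace"
    return PopulationVector(condition, values, int(mask.sum()), mode)


def activity_summary(
    raster: EventRaster,
    masks: Mapping[str, np.ndarray],
) -> pd.DataFrame:
    """Activity-distribution summary per condition.

    For each named condition mask: per-neuron activity fractions summarised
    into counts of highly active (> 7.5% of frames) and inactive neurons,
    plus the two-sample KS statistic between each condition's activity
    distribution and the first condition's.
    """
    if not masks:
        raise ValueError("no condition masks supplied")
    names = list(masks)
    fracs = {
        name: population_vector(raster, masks[name], name).values for name in names
    }
    ref = fracs[names[0]]
    rows = []
    for name in names:
        f = fracs[name]
        ks = stats.ks_2samp(f, ref)
        rows.append(
            {
                "condition": name,
                "n_frames": int(np.asarray(masks[name], bool).sum()),
                "mean_activity": f.mean(),
                "n_highly_active": int((f > HIGHLY_ACTIVE_THRESHOLD).sum()),
                "n_inactive": int((f == 0).sum()),
                "ks_vs_first": float(ks.statistic),
                "ks_pvalue_vs_first": float(ks.pvalue),
            }
        )
    return pd.DataFrame(rows)


def similarity_matrix(
    vectors: Sequence[PopulationVector], drop_zero_variance: bool = False
) -> SimilarityMatrix:
    """Pairwise Pearson correlation between population vectors.

    All neurons contribute by default (pooled-vector convention); with
    ``drop_zero_variance`` neurons constant across a pair are excluded from
    that pair (sensitivity check).
    """
    if len(vectors) < 2:
        raise ValueError("need at least two population vectors")
    lengths = {len(v) for v in vectors}
    if len(lengths) != 1:
        raise ValueError(f"vectors have unequal lengths: {sorted(lengths)}")
    mat = np.vstack([v.values for v in vectors])
    n_const = int(np.sum(mat.std(axis=1) == 0))
    if len(vectors) - n_const < 2:
        raise ValueError("fewer than two non-constant vectors")
    k = len(vectors)
    out = np.eye(k)
    for i in range(k):
        for j in range(i + 1, k):
            a, b = mat[i], mat[j]
            if drop_zero_variance:
                sel = a != b  # drop neurons constant across this pair
                if sel.sum() < 2:
                    sel = np.ones(len(a), bool)
            else:
                sel = np.ones(len(a), bool)
            with np.errstate(invalid="ignore"):
                r = np.corrcoef(a[sel], b[sel])[0, 1]
            out[i, j] = out[j, i] = r
    return SimilarityMatrix([v.condition for v in vectors], out)


def within_between_summary(
    similarity: SimilarityMatrix,
    context_map: Mapping[str, str],
) -> pd.DataFrame:
    """Mean similarity within vs between contexts, per vector-type pair.

    Conditions are keyed "<epoch>:<type>" (e.g. ``A:social``); ``context_map``
    assigns each epoch to a context.  Returns one row per (type_a, type_b,
    within|between) with the mean r over the qualifying epoch pairs; a
    within-context mean over a context with fewer than two epochs is NaN.
    """
    parsed = []
    for cond in similarity.conditions:
        epoch, _, vtype = cond.partition(":")
        if epoch not in context_map:
            raise KeyError(f"epoch {epoch!r} missing from context_map")
        parsed.append((epoch, vtype or "activity"))
    types = sorted({t for _, t in parsed})
    rows = []
    for ta in types:
        for tb in types:
            if tb < ta:
                continue
            within, between = [], []
            for i, (ea, tia) in enumerate(parsed):
                for j, (eb, tjb) in enumerate(parsed):
                    if j <= i or {tia, tjb} != ({ta, tb} if ta != tb else {ta}):
                        continue
                    if ea == eb:
                        continue  # same-epoch cross-type pairs are excluded
                    r = similarity.values[i, j]
                    (within if context_map[ea] == context_map[eb] else between).append(r)
            rows.append(
                {
                    "type_a": ta,
                    "type_b": tb,
                    "within_context": float(np.mean(within)) if within else np.nan,
                    "between_context": float(np.mean(between)) if between else np.nan,
                    "n_within_pairs": len(within),
                    "n_between_pairs": len(between),
                }
            )
    return pd.DataFrame(rows)


def filter_active_both(
    raster: EventRaster, annotation: SessionAnnotation,
    contexts: Iterable[str] | None = None,
) -> np.ndarray:
    """Indices of neurons with at least one event in every context."""
    ctxs = list(contexts) if contexts is not None else annotation.context_ids
    if len(ctxs) < 2:
        raise ValueError("need at least two contexts")
    keep = np.ones(raster.n_neurons, dtype=bool)
    for c in ctxs:
        m = annotation.context_mask(c)
        keep &= raster.values[:, m].any(axis=1)
    return np.flatnonzero(keep)
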