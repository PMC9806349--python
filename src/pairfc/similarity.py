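"""Pairwise FC-series similarity between subjects.

For two subjects p and q, each ROI pair contributes the cosine of its two
weighted FC series; summing (or averaging) those P cosines gives the
subject-to-subject similarity.  Because the cosine is computed element-wise
over the K windows, it is invariant to any re-ordering applied jointly to
both series — window phases between subjects are matched by construction.

Also provides the cohort-level analyses: average query-vs-support similarity
matrices re-folded to N x N, and discriminative ROI-pair ranking by the
NC-query vs patient-query mean-similarity gap on a shared support set.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "PairSimilarityVector",
    "SubjectSimilarity",
    "pairwise_cosine",
    "subject_similarity",
    "average_similarity_matrix",
    "rank_discriminative_pairs",
]


@dataclass
class PairSimilarityVector:
    """Per-ROI-pair cosine similarities between two subjects (length P)."""

    values: np.ndarray
    pair_index: list[tuple[int, int]]


@dataclass
class SubjectSimilarity:
    value: float
    aggregation: str  # "sum" or "mean"


def _check_layout(a, b) -> None:
    if a.series.shape != b.series.shape:
        raise ValueError(
            f"layout mismatch: {a.series.shape} vs {b.series.shape}"
        )
    if list(a.pair_index) != list(b.pair_index):
        raise ValueError("pair orderings differ between the two inputs")


def _row_cosines(x: np.ndarray, y: np.ndarray, warn: bool = True) -> np.ndarray:
    nx = np.linalg.norm(x, axis=1)
    ny = np.linalg.norm(y, axis=1)
    zero = (nx == 0.0) | (ny == 0.0)
    if warn and zero.any():
        warnings.warn(
            f"{int(zero.sum())} zero-norm FC series; their cosine is set to 0",
            RuntimeWarning,
            stacklevel=3,
        )
    denom = np.where(zero, 1.0, nx * ny)
    cos = (x * y).sum(axis=1) / denom
    cos[zero] = 0.0
    return np.clip(cos, -1.0, 1.0)


def pairwise_cosine(a, b) -> PairSimilarityVector:
    """Cosine similarity of each ROI pair's FC series between two subjects.

    Zero-norm series make the cosine undefined; those entries are set to 0
    with a warning (neutral, consistent with the zero-variance FC convention).
    """
    _check_layout(a, b)
    return PairSimilarityVector(
        values=_row_cosines(a.series, b.series),
        pair_index=list(a.pair_index),
    )


def subject_similarity(
    psv: PairSimilarityVector, aggregation: str = "mean"
) -> SubjectSimilarity:
    """Aggregate the P per-pair cosines into one subject-level similarity.

    ``"sum"`` is the raw summed similarity; ``"mean"`` (default) divides by P
    so the value stays in [-1, 1] regardless of the number of ROI pairs.
    """
    if aggregation == "sum":
        value = float(psv.values.sum())
    elif aggregation == "mean":
        value = float(psv.values.mean())
    else:
        raise ValueError(f"unknown aggregation {aggregation!r}")
    return SubjectSimilarity(value=value, aggregation=aggregation)


def _mean_cosine_vector(queries: Sequence, supports: Sequence) -> np.ndarray:
    """Mean per-pair cosine over all (query, support) combinations."""
    total = np.zeros(queries[0].series.shape[0])
    for q in queries:
        for s in supports:
            _check_layout(q, s)
            total += _row_cosines(q.series, s.series, warn=False)
    return total / (len(queries) * len(supports))


def average_similarity_matrix(queries: Sequence, supports: Sequence) -> np.ndarray:
    """Mean per-pair cosine over all query/support combinations, re-folded
    into a symmetric N x N matrix with unit diagonal (self-FC is undefined
    in the pair set; the diagonal value is cosmetic)."""
    if not queries or not supports:
        raise ValueError("query and support lists must be non-empty")
    mean_vec = _mean_cosine_vector(queries, supports)
    pair_index = queries[0].pair_index
    n = int(round((1 + np.sqrt(1 + 8 * len(pair_index))) / 2))
    out = np.eye(n)
    for p, (i, j) in enumerate(pair_index):
        out[i, j] = mean_vec[p]
        out[j, i] = mean_vec[p]
    return out


def rank_discriminative_pairs(
    nc_queries: Sequence,
    patient_queries: Sequence,
    nc_supports: Sequence,
    patient_supports: Sequence,
    top_k: int = 10,
    roi_labels: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Rank ROI pairs by how differently NC and patient queries relate to a
    shared support set.

    For each support class, the per-pair mean similarity of NC queries and of
    patient queries is computed; a pair's score is the absolute NC-patient
    difference averaged over the two support classes (signed per-class
    differences are reported alongside).  Returns the ``top_k`` pairs by
    score, descending, ties broken by pair order.
    """
    for name, group in (
        ("nc_queries", nc_queries),
        ("patient_queries", patient_queries),
        ("nc_supports", nc_supports),
        ("patient_supports", patient_supports),
    ):
        if not group:
            raise ValueError(f"{name} is empty")
    diff_on_nc = _mean_cosine_vector(nc_queries, nc_supports) - _mean_cosine_vector(
        patient_queries, nc_supports
    )
    diff_on_patient = _mean_cosine_vector(
        nc_queries, patient_supports
    ) - _mean_cosine_vector(patient_queries, patient_supports)
    score = (np.abs(diff_on_nc) + np.abs(diff_on_patient)) / 2.0

    pair_index = nc_queries[0].pair_index
    if roi_labels is None:
        roi_labels = getattr(nc_queries[0], "roi_labels", None)
    if roi_labels is None:
        roi_labels = [str(i) for i in range(max(j for _, j in pair_index) + 1)]

    # stable mergesort on -score keeps pair_index order among ties
    order = np.argsort(-score, kind="stable")[:top_k]
    rows = [
        {
            "roi_i": roi_labels[pair_index[p][0]],
            "roi_j": roi_labels[pair_index[p][1]],
            "pair": pair_index[p],
            "score": score[p],
            "diff_nc_support": diff_on_nc[p],
            "diff_patient_support": diff_on_patient[p],
        }
        for p in order
    ]
    return pd.DataFrame(rows)
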