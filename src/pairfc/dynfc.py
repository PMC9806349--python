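"""Dynamic functional connectivity networks from ROI BOLD time series.

A scan is an ``N x M`` matrix of BOLD measurements (N ROIs, M time points).
A sliding window of length ``w`` advanced by step ``s`` yields
``K = floor((M - w) / s) + 1`` overlapping sub-segments; the Pearson
correlation matrix of each sub-segment is one short-term functional
connectivity network (FCN), and the stack of all K of them is the dynamic
FCN.  Because each slice is symmetric with unit diagonal, only the
``P = N(N-1)/2`` lower off-diagonal entries carry information; the dynamic
FCN is therefore flattened to a ``P x K`` matrix of per-ROI-pair FC series
for everything downstream.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "RoiTimeSeries",
    "SlidingWindowConfig",
    "DynamicFCN",
    "FCSeriesMatrix",
    "InvalidWindowError",
    "enumerate_windows",
    "short_term_fc",
    "build_dynamic_fcn",
    "vectorize_lower_triangle",
    "reconstruct_slice",
    "mean_fc_features",
    "lower_triangle_pairs",
]

NC_LABEL = "NC"
PATIENT_LABEL = "patient"


class InvalidWindowError(ValueError):
    """Sliding-window configuration incompatible with the scan length."""


@dataclass
class RoiTimeSeries:
    """One scan: N ROI mean BOLD series over M time points.

    ``label`` is ``"NC"``, ``"patient"`` or ``None`` (unknown).
    """

    values: np.ndarray
    roi_labels: list[str]
    subject_id: str = ""
    label: str | None = None
    scan_id: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("values must be a 2-D (N x M) matrix")
        n, m = self.values.shape
        if n < 2 or m < 2:
            raise ValueError(f"need at least 2 ROIs and 2 time points, got {n}x{m}")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("BOLD matrix contains non-finite entries")
        self.roi_labels = [str(r) for r in self.roi_labels]
        if len(self.roi_labels) != n:
            raise ValueError(
                f"{len(self.roi_labels)} ROI labels for {n} ROIs"
            )
        if len(set(self.roi_labels)) != n:
            raise ValueError("ROI labels must be unique")
        if self.label is not None and self.label not in (NC_LABEL, PATIENT_LABEL):
            raise ValueError(f"unknown class label {self.label!r}")

    @property
    def n_rois(self) -> int:
        return self.values.shape[0]

    @property
    def n_timepoints(self) -> int:
        return self.values.shape[1]


@dataclass(frozen=True)
class SlidingWindowConfig:
    """Sliding-window parameters in time points (window length w, step s)."""

    window_length: int = 30
    step: int = 2

    def __post_init__(self) -> None:
        if self.window_length < 2:
            raise InvalidWindowError("window_length must be >= 2")
        if self.step < 1:
            raise InvalidWindowError("step must be >= 1")

    def n_windows(self, n_timepoints: int) -> int:
        if self.window_length > n_timepoints:
            raise InvalidWindowError(
                f"window_length {self.window_length} exceeds scan length {n_timepoints}"
            )
        return (n_timepoints - self.window_length) // self.step + 1


@dataclass
class DynamicFCN:
    """K stacked N x N short-term correlation matrices."""

    tensor: np.ndarray  # (K, N, N)
    window_starts: list[int]

    def __post_init__(self) -> None:
        self.tensor = np.asarray(self.tensor, dtype=float)
        if self.tensor.ndim != 3 or self.tensor.shape[1] != self.tensor.shape[2]:
            raise ValueError("tensor must be K x N x N")
        if len(self.window_starts) != self.tensor.shape[0]:
            raise ValueError("window_starts length must equal K")

    @property
    def n_windows(self) -> int:
        return self.tensor.shape[0]

    @property
    def n_rois(self) -> int:
        return self.tensor.shape[1]


def lower_triangle_pairs(n_rois: int) -> list[tuple[int, int]]:
    """Ordered ROI pairs: lower triangle scanned by rows, stored as (i, j), i < j."""
    rows, cols = np.tril_indices(n_rois, k=-1)
    return [(int(c), int(r)) for r, c in zip(rows, cols)]


@dataclass
class FCSeriesMatrix:
    """P x K matrix of per-ROI-pair FC series (P = N(N-1)/2 lower-triangle pairs)."""

    series: np.ndarray  # (P, K)
    pair_index: list[tuple[int, int]] = field(repr=False)
    roi_labels: list[str] | None = None

    def __post_init__(self) -> None:
        self.series = np.asarray(self.series, dtype=float)
        if self.series.ndim != 2:
            raise ValueError("series must be a 2-D (P x K) matrix")
        if len(self.pair_index) != self.series.shape[0]:
            raise ValueError("pair_index length must equal number of rows P")

    @property
    def n_pairs(self) -> int:
        return self.series.shape[0]

    @property
    def n_windows(self) -> int:
        return self.series.shape[1]

    @property
    def n_rois(self) -> int:
        # P = N(N-1)/2  =>  N = (1 + sqrt(1 + 8P)) / 2
        p = self.n_pairs
        n = int(round((1 + np.sqrt(1 + 8 * p)) / 2))
        if n * (n - 1) // 2 != p:
            raise ValueError(f"row count {p} is not a triangular number")
        return n


def enumerate_windows(n_timepoints: int, cfg: SlidingWindowConfig) -> list[int]:
    """0-based start offsets of all half-open windows [o, o+w) that fit in M.

    Trailing time points not covered by a full window are dropped.
    """
    k = cfg.n_windows(n_timepoints)  # raises InvalidWindowError if w > M
    return [o * cfg.step for o in range(k)]


def short_term_fc(x: RoiTimeSeries, offset: int, window_length: int) -> np.ndarray:
    """Pearson correlation matrix of the windowed sub-series [offset, offset+w).

    Zero-variance sub-series make the coefficient undefined; those entries are
    set to 0 (neutral) with a warning, keeping the unit diagonal.
    """
    if offset < 0 or offset + window_length > x.n_timepoints:
        raise InvalidWindowError(
            f"window [{offset}, {offset + window_length}) outside scan of length {x.n_timepoints}"
        )
    window = x.values[:, offset : offset + window_length]
    return _pearson_matrix(window)


def _pearson_matrix(window: np.ndarray) -> np.ndarray:
    centered = window - window.mean(axis=1, keepdims=True)
    norms = np.linalg.norm(centered, axis=1)
    degenerate = norms == 0.0
    if degenerate.any():
        warnings.warn(
            f"{int(degenerate.sum())} zero-variance ROI sub-series; "
            "their correlations are set to 0",
            RuntimeWarning,
            stacklevel=3,
        )
    safe = np.where(degenerate, 1.0, norms)
    unit = centered / safe[:, None]
    corr = unit @ unit.T
    corr[degenerate, :] = 0.0
    corr[:, degenerate] = 0.0
    np.clip(corr, -1.0, 1.0, out=corr)
    corr = (corr + corr.T) / 2.0
    np.fill_diagonal(corr, 1.0)
    return corr


def build_dynamic_fcn(x: RoiTimeSeries, cfg: SlidingWindowConfig) -> DynamicFCN:
    """Stack short-term FC matrices over all sliding windows, in time order."""
    starts = enumerate_windows(x.n_timepoints, cfg)
    tensor = np.stack(
        [short_term_fc(x, o, cfg.window_length) for o in starts], axis=0
    )
    return DynamicFCN(tensor=tensor, window_starts=starts)


def vectorize_lower_triangle(
    d: DynamicFCN, roi_labels: list[str] | None = None
) -> FCSeriesMatrix:
    """Flatten the dynamic FCN to its P x K lower-triangle FC-series matrix."""
    n = d.n_rois
    rows, cols = np.tril_indices(n, k=-1)
    series = d.tensor[:, rows, cols].T  # (P, K)
    return FCSeriesMatrix(
        series=np.ascontiguousarray(series),
        pair_index=lower_triangle_pairs(n),
        roi_labels=roi_labels,
    )


def reconstruct_slice(fcm: FCSeriesMatrix, k: int) -> np.ndarray:
    """Rebuild the symmetric N x N matrix of window k (diagonal restored to 1)."""
    n = fcm.n_rois
    out = np.eye(n)
    rows, cols = np.tril_indices(n, k=-1)
    out[rows, cols] = fcm.series[:, k]
    out[cols, rows] = fcm.series[:, k]
    return out


def mean_fc_features(fcm: FCSeriesMatrix) -> np.ndarray:
    """Per-pair time-averaged FC: the length-P feature vector used by
    conventional baseline classifiers (mean of each FC series over K)."""
    return fcm.series.mean(axis=1)
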