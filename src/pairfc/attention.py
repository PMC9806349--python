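"""Self-attention weighting of the FC-series matrix.

Tokens are the P ROI-pair FC series (rows of the P x K matrix); the feature
dimension is the K windows.  With projections

    Query = D W_Q^T,  Key = D W_K^T,  Value = D W_V^T,

the weighted matrix is ``softmax(Query Key^T / sqrt(d_k)) Value``, each query
row distributing weight over all P key rows.  ``W_V`` is K x K so the output
has exactly the input's P x K shape.

No autodiff framework is used: :func:`attention_backward` implements the
exact reverse-mode gradient of the layer, validated against central finite
differences in the test suite.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "AttentionParams",
    "WeightedFCSeries",
    "init_params",
    "attend",
    "attention_forward",
    "attention_backward",
]


@dataclass
class AttentionParams:
    """Learnable projections W_Q, W_K (d_k x K) and W_V (K x K)."""

    w_query: np.ndarray
    w_key: np.ndarray
    w_value: np.ndarray

    def __post_init__(self) -> None:
        self.w_query = np.asarray(self.w_query, dtype=float)
        self.w_key = np.asarray(self.w_key, dtype=float)
        self.w_value = np.asarray(self.w_value, dtype=float)
        if self.w_query.ndim != 2 or self.w_key.ndim != 2 or self.w_value.ndim != 2:
            raise ValueError("all parameter matrices must be 2-D")
        if self.w_query.shape != self.w_key.shape:
            raise ValueError("W_Q and W_K must share the d_k x K shape")
        k = self.w_query.shape[1]
        if self.w_value.shape != (k, k):
            raise ValueError(
                f"W_V must be K x K = {k}x{k}, got {self.w_value.shape}"
            )
        if self.w_query.shape[0] < 1:
            raise ValueError("d_k must be >= 1")
        for name, w in self.items():
            if not np.all(np.isfinite(w)):
                raise ValueError(f"{name} contains non-finite entries")

    @property
    def d_k(self) -> int:
        return self.w_query.shape[0]

    @property
    def n_windows(self) -> int:
        return self.w_query.shape[1]

    def items(self):
        return (
            ("w_query", self.w_query),
            ("w_key", self.w_key),
            ("w_value", self.w_value),
        )

    def copy(self) -> "AttentionParams":
        return AttentionParams(
            self.w_query.copy(), self.w_key.copy(), self.w_value.copy()
        )


@dataclass
class WeightedFCSeries:
    """Attention-weighted P x K FC-series matrix (same layout as the input)."""

    series: np.ndarray
    pair_index: list[tuple[int, int]]
    roi_labels: list[str] | None = None

    @property
    def n_pairs(self) -> int:
        return self.series.shape[0]

    @property
    def n_windows(self) -> int:
        return self.series.shape[1]


def init_params(
    n_windows: int,
    d_k: int | None = None,
    seed: int = 0,
    identity_gain: float = 3.0,
    noise_scale: float = 0.05,
) -> AttentionParams:
    """Seeded initialization of the attention projections.

    The projections are anchored at (scaled) identity maps with small
    zero-mean noise of scale ``noise_scale / sqrt(K)``.  At ``identity_gain``
    around 3 the initial attention of each FC series concentrates on its own
    token for FC-scale inputs, so the untrained network behaves like the
    plain unweighted per-pair comparison and training refines it from there.
    ``identity_gain=0`` gives the fully random zero-mean alternative, under
    which attention starts uniform over tokens.
    """
    if n_windows < 1:
        raise ValueError("n_windows must be >= 1")
    if d_k is None:
        d_k = n_windows
    if d_k < 1:
        raise ValueError("d_k must be >= 1")
    rng = np.random.default_rng(seed)
    sd = noise_scale / np.sqrt(n_windows)
    eye_qk = identity_gain * np.eye(d_k, n_windows)
    w_q = eye_qk + rng.normal(0.0, sd, size=(d_k, n_windows))
    w_k = eye_qk + rng.normal(0.0, sd, size=(d_k, n_windows))
    w_v = (1.0 if identity_gain else 0.0) * np.eye(n_windows) + rng.normal(
        0.0, sd, size=(n_windows, n_windows)
    )
    return AttentionParams(w_q, w_k, w_v)


def _softmax_rows(scores: np.ndarray) -> np.ndarray:
    shifted = scores - scores.max(axis=1, keepdims=True)
    e = np.exp(shifted)
    return e / e.sum(axis=1, keepdims=True)


def attention_forward(series: np.ndarray, params: AttentionParams) -> dict:
    """Run the layer and keep every intermediate needed for the backward pass."""
    series = np.asarray(series, dtype=float)
    if series.ndim != 2:
        raise ValueError("series must be P x K")
    if series.shape[1] != params.n_windows:
        raise ValueError(
            f"series has K={series.shape[1]} windows but parameters expect "
            f"K={params.n_windows}"
        )
    query = series @ params.w_query.T        # (P, d_k)
    key = series @ params.w_key.T            # (P, d_k)
    value = series @ params.w_value.T        # (P, K)
    scale = 1.0 / np.sqrt(params.d_k)
    weights = _softmax_rows(query @ key.T * scale)  # (P, P)
    output = weights @ value                 # (P, K)
    return {
        "input": series,
        "query": query,
        "key": key,
        "value": value,
        "weights": weights,
        "scale": scale,
        "output": output,
    }


def attend(fcm, params: AttentionParams) -> WeightedFCSeries:
    """Apply self-attention to an FC-series matrix; output matches its shape."""
    cache = attention_forward(fcm.series, params)
    return WeightedFCSeries(
        series=cache["output"],
        pair_index=list(fcm.pair_index),
        roi_labels=getattr(fcm, "roi_labels", None),
    )


def attention_backward(
    cache: dict, grad_output: np.ndarray
) -> dict[str, np.ndarray]:
    """Gradients of a scalar loss w.r.t. W_Q, W_K, W_V given dL/d(output).

    Reverse-mode through ``softmax(Q K^T / sqrt(d_k)) V`` with the shared
    input matrix held fixed (the input is data, not a parameter).
    """
    a = cache["input"]
    weights = cache["weights"]
    scale = cache["scale"]
    grad_value = weights.T @ grad_output                     # (P, K)
    grad_weights = grad_output @ cache["value"].T            # (P, P)
    # softmax backward, row-wise: dZ = S * (dS - rowsum(dS * S))
    inner = (grad_weights * weights).sum(axis=1, keepdims=True)
    grad_scores = weights * (grad_weights - inner)
    grad_query = grad_scores @ cache["key"] * scale          # (P, d_k)
    grad_key = grad_scores.T @ cache["query"] * scale        # (P, d_k)
    return {
        "w_query": grad_query.T @ a,
        "w_key": grad_key.T @ a,
        "w_value": grad_value.T @ a,
    }
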