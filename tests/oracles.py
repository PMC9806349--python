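"""Independent brute-force reference implementations used only by tests.

Everything here is written as straight-line/looped textbook code, sharing no
helpers with the package, so that agreement between the two routes is
meaningful.
"""

from __future__ import annotations

import math

import numpy as np


def pearson_textbook(x, y) -> float:
    """Pearson correlation from the definition, scalar loops only."""
    n = len(x)
    mx = sum(x) / n
    my = sum(y) / n
    num = sum((x[i] - mx) * (y[i] - my) for i in range(n))
    dx = math.sqrt(sum((x[i] - mx) ** 2 for i in range(n)))
    dy = math.sqrt(sum((y[i] - my) ** 2 for i in range(n)))
    if dx == 0.0 or dy == 0.0:
        return 0.0
    return num / (dx * dy)


def windows_exhaustive(m: int, w: int, s: int) -> list[int]:
    """All window offsets o = 0, s, 2s, ... with o + w <= m, by direct scan."""
    offsets = []
    o = 0
    while o + w <= m:
        offsets.append(o)
        o += s
    return offsets


def dynamic_fcn_bruteforce(values: np.ndarray, w: int, s: int) -> np.ndarray:
    """Per-window correlation tensor via explicit loops over windows and pairs."""
    n, m = values.shape
    offsets = windows_exhaustive(m, w, s)
    tensor = np.zeros((len(offsets), n, n))
    for k, o in enumerate(offsets):
        for i in range(n):
            tensor[k, i, i] = 1.0
            for j in range(i):
                r = pearson_textbook(values[i, o : o + w], values[j, o : o + w])
                tensor[k, i, j] = r
                tensor[k, j, i] = r
    return tensor


def attention_bruteforce(series: np.ndarray, w_q, w_k, w_v) -> np.ndarray:
    """Score-by-score self-attention with explicit loops over tokens."""
    p, k_dim = series.shape
    d_k = w_q.shape[0]
    query = np.array([[sum(w_q[d][k] * series[t][k] for k in range(k_dim)) for d in range(d_k)] for t in range(p)])
    key = np.array([[sum(w_k[d][k] * series[t][k] for k in range(k_dim)) for d in range(d_k)] for t in range(p)])
    value = np.array([[sum(w_v[c][k] * series[t][k] for k in range(k_dim)) for c in range(k_dim)] for t in range(p)])
    out = np.zeros((p, k_dim))
    for t in range(p):
        scores = [
            sum(query[t][d] * key[u][d] for d in range(d_k)) / math.sqrt(d_k)
            for u in range(p)
        ]
        mx = max(scores)
        exps = [math.exp(sc - mx) for sc in scores]
        z = sum(exps)
        weights = [e / z for e in exps]
        for c in range(k_dim):
            out[t][c] = sum(weights[u] * value[u][c] for u in range(p))
    return out


def cosine_rows_bruteforce(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Row-wise cosine similarity by the summation formula."""
    out = np.zeros(a.shape[0])
    for t in range(a.shape[0]):
        num = sum(a[t][k] * b[t][k] for k in range(a.shape[1]))
        da = math.sqrt(sum(v * v for v in a[t]))
        db = math.sqrt(sum(v * v for v in b[t]))
        out[t] = 0.0 if da == 0.0 or db == 0.0 else num / (da * db)
    return out


def siamese_pair_bruteforce(
    series_a: np.ndarray,
    series_b: np.ndarray,
    w_q,
    w_k,
    w_v,
    y: int,
    margin: float,
    aggregation: str,
) -> tuple[float, float]:
    """Straight-line recomputation of one Siamese pair: shared-parameter
    attention on both branches, per-row cosine, aggregation, contrastive loss."""
    out_a = attention_bruteforce(series_a, w_q, w_k, w_v)
    out_b = attention_bruteforce(series_b, w_q, w_k, w_v)
    cos = cosine_rows_bruteforce(out_a, out_b)
    s = float(np.mean(cos)) if aggregation == "mean" else float(np.sum(cos))
    loss = (1 - y) * s**2 + y * max(margin - s, 0.0) ** 2
    return s, loss


def metrics_by_hand(tp: int, tn: int, fp: int, fn: int) -> dict:
    def div(a, b):
        return a / b if b else float("nan")

    return {
        "ACC": div(tp + tn, tp + tn + fp + fn),
        "SPE": div(tn, tn + fp),
        "PPV": div(tp, tp + fp),
        "NPV": div(tn, tn + fn),
    }
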