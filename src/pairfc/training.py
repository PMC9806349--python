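"""Siamese training of the attention parameters under a contrastive objective.

Both members of a scan pair pass through the *same* attention parameters
(weight sharing is structural: there is exactly one parameter set), then the
per-pair cosine similarities are aggregated into one subject similarity s and
scored by the contrastive loss

    L = (1 - y) s^2 + y * max(margin - s, 0)^2

with y = 1 for a same-category pair and y = 0 otherwise, so training pulls
same-class similarities above the margin and pushes different-class
similarities toward zero.

Gradients are computed by an explicit reverse-mode pass through
cosine-aggregation and the attention layer (see :mod:`pairfc.attention`);
parameters are updated with Adam on the mean pair loss, one step per epoch,
with pairs re-sampled every epoch from a seeded stream.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .attention import AttentionParams, attention_backward, attention_forward
from .cohort import LabeledScan, class_counts

__all__ = [
    "LossConfig",
    "TrainConfig",
    "TrainState",
    "SubjectPair",
    "TrainingError",
    "contrastive_loss",
    "sample_pairs",
    "forward_pair",
    "train",
]


class TrainingError(RuntimeError):
    """Raised when optimization produces non-finite losses or gradients."""


@dataclass(frozen=True)
class LossConfig:
    margin: float = 1.0
    aggregation: str = "mean"  # "mean" keeps s in [-1, 1]; "sum" is the raw variant

    def __post_init__(self) -> None:
        if self.margin <= 0:
            raise ValueError("margin must be positive")
        if self.aggregation not in ("mean", "sum"):
            raise ValueError(f"unknown aggregation {self.aggregation!r}")


@dataclass(frozen=True)
class TrainConfig:
    learning_rate: float = 1e-4
    epochs: int = 50
    pairs_per_epoch: int = 256
    balance: float = 0.5  # target fraction of same-class pairs
    seed: int = 0
    # validation-selection protocol (used when a validation cohort is given)
    val_episodes: int = 20
    val_n_shot: int = 3
    val_seed: int = 0

    def __post_init__(self) -> None:
        if self.learning_rate < 0 or self.epochs < 1 or self.pairs_per_epoch < 1:
            raise ValueError("invalid optimizer settings")
        if not 0.0 < self.balance < 1.0:
            raise ValueError("balance must lie in (0, 1)")


@dataclass
class SubjectPair:
    first: LabeledScan
    second: LabeledScan

    @property
    def y(self) -> int:
        """1 if the two scans share a category, else 0."""
        return int(self.first.label == self.second.label)


@dataclass
class TrainState:
    params: AttentionParams
    loss_config: LossConfig = field(default_factory=LossConfig)
    train_config: TrainConfig = field(default_factory=TrainConfig)
    loss_history: list[float] = field(default_factory=list)
    val_history: list[float] = field(default_factory=list)
    best_epoch: int | None = None  # epoch whose params were selected (0-based)


def contrastive_loss(s: float, y: int, cfg: LossConfig) -> float:
    hinge = max(cfg.margin - s, 0.0)
    return float((1 - y) * s * s + y * hinge * hinge)


def _contrastive_loss_grad(s: float, y: int, cfg: LossConfig) -> float:
    """dL/ds; subgradient 0 at the hinge point s == margin."""
    return float(2.0 * (1 - y) * s - 2.0 * y * max(cfg.margin - s, 0.0))


def sample_pairs(
    cohort: Sequence[LabeledScan],
    n_pairs: int,
    balance: float = 0.5,
    seed: int = 0,
) -> list[SubjectPair]:
    """Seeded sample of scan pairs with ``round(n_pairs * balance)`` same-class
    pairs; a scan is never paired with itself."""
    by_label: dict[str, list[LabeledScan]] = {}
    for scan in cohort:
        by_label.setdefault(scan.label, []).append(scan)
    labels = sorted(by_label)
    if len(labels) < 2:
        raise ValueError("need scans from both classes to form pairs")
    for label in labels:
        if len(by_label[label]) < 2:
            raise ValueError(f"class {label!r} has fewer than 2 scans")
    rng = np.random.default_rng(seed)
    n_same = int(round(n_pairs * balance))
    pairs: list[SubjectPair] = []
    for _ in range(n_same):
        label = labels[rng.integers(len(labels))]
        a, b = rng.choice(len(by_label[label]), size=2, replace=False)
        pairs.append(SubjectPair(by_label[label][a], by_label[label][b]))
    for _ in range(n_pairs - n_same):
        la, lb = rng.choice(len(labels), size=2, replace=False)
        a = by_label[labels[la]][rng.integers(len(by_label[labels[la]]))]
        b = by_label[labels[lb]][rng.integers(len(by_label[labels[lb]]))]
        pairs.append(SubjectPair(a, b))
    return pairs


def _cosine_similarity_with_grads(
    out_a: np.ndarray, out_b: np.ndarray, aggregation: str
):
    """Subject similarity s from two weighted P x K outputs, plus ds/d(out)."""
    na = np.linalg.norm(out_a, axis=1)
    nb = np.linalg.norm(out_b, axis=1)
    zero = (na == 0.0) | (nb == 0.0)
    denom = np.where(zero, 1.0, na * nb)
    cos = (out_a * out_b).sum(axis=1) / denom
    cos[zero] = 0.0
    p = out_a.shape[0]
    weight = 1.0 / p if aggregation == "mean" else 1.0
    s = float(cos.sum() * weight)
    # d cos_p / d a_p = b_p/(|a||b|) - cos_p a_p/|a|^2 ; zero-norm rows get 0
    na2 = np.where(zero, 1.0, na * na)
    nb2 = np.where(zero, 1.0, nb * nb)
    grad_a = weight * (out_b / denom[:, None] - (cos / na2)[:, None] * out_a)
    grad_b = weight * (out_a / denom[:, None] - (cos / nb2)[:, None] * out_b)
    grad_a[zero] = 0.0
    grad_b[zero] = 0.0
    return s, grad_a, grad_b


def forward_pair(
    pair: SubjectPair, params: AttentionParams, cfg: LossConfig
) -> tuple[float, float]:
    """Similarity and loss of one pair through the shared-parameter branches."""
    s, loss, _ = _pair_loss_and_grads(pair, params, cfg, want_grads=False)
    return s, loss


def _pair_loss_and_grads(
    pair: SubjectPair,
    params: AttentionParams,
    cfg: LossConfig,
    want_grads: bool = True,
    caches: dict[int, dict] | None = None,
):
    def cache_for(scan: LabeledScan) -> dict:
        if caches is not None:
            key = id(scan)
            if key not in caches:
                caches[key] = attention_forward(scan.fcm.series, params)
            return caches[key]
        return attention_forward(scan.fcm.series, params)

    cache_a = cache_for(pair.first)
    cache_b = cache_for(pair.second)
    s, grad_out_a, grad_out_b = _cosine_similarity_with_grads(
        cache_a["output"], cache_b["output"], cfg.aggregation
    )
    y = pair.y
    loss = contrastive_loss(s, y, cfg)
    if not want_grads:
        return s, loss, None
    dl_ds = _contrastive_loss_grad(s, y, cfg)
    grads_a = attention_backward(cache_a, dl_ds * grad_out_a)
    grads_b = attention_backward(cache_b, dl_ds * grad_out_b)
    grads = {name: grads_a[name] + grads_b[name] for name in grads_a}
    return s, loss, grads


def _val_accuracy(
    val_cohort: Sequence[LabeledScan],
    params: AttentionParams,
    loss_cfg: LossConfig,
    train_cfg: TrainConfig,
) -> float:
    from .fewshot import evaluate  # local import: fewshot sits above training

    counts = class_counts(val_cohort)
    n_shot = min(train_cfg.val_n_shot, min(counts.values()) - 1)
    result = evaluate(
        val_cohort,
        params,
        n_shot=n_shot,
        n_query=1,
        n_episodes=train_cfg.val_episodes,
        seed=train_cfg.val_seed,
        aggregation=loss_cfg.aggregation,
    )
    return result.pooled.acc


def train(
    cohort: Sequence[LabeledScan],
    params: AttentionParams,
    loss_cfg: LossConfig | None = None,
    train_cfg: TrainConfig | None = None,
    val_cohort: Sequence[LabeledScan] | None = None,
) -> TrainState:
    """Optimize the attention parameters on sampled scan pairs.

    One Adam step per epoch on the mean pair loss; the forward pass of each
    scan is computed once per epoch and shared across all pairs touching it.
    If ``val_cohort`` is given, a small fixed few-shot probe is run on it
    after every epoch and the returned parameters are those of the epoch
    with the highest validation accuracy (earliest on ties, initial
    parameters included as the pre-training baseline) — early stopping in
    selection form, guarding against over-training collapse of the
    similarity structure.  Fully reproducible from ``train_cfg`` seeds.
    """
    loss_cfg = loss_cfg or LossConfig()
    train_cfg = train_cfg or TrainConfig()
    counts = class_counts(cohort)
    if len(counts) < 2 or min(counts.values()) < 2:
        raise ValueError(
            f"training needs >=2 scans in each of 2 classes, got {counts}"
        )
    params = params.copy()
    adam_m = {name: np.zeros_like(w) for name, w in params.items()}
    adam_v = {name: np.zeros_like(w) for name, w in params.items()}
    beta1, beta2, eps = 0.9, 0.999, 1e-8
    loss_history: list[float] = []
    val_history: list[float] = []
    best_params = params
    best_val = -np.inf
    best_epoch: int | None = None
    if val_cohort is not None:
        best_val = _val_accuracy(val_cohort, params, loss_cfg, train_cfg)
        best_epoch = -1  # pre-training baseline
    pair_seed = np.random.default_rng(train_cfg.seed)
    for epoch in range(train_cfg.epochs):
        pairs = sample_pairs(
            cohort,
            train_cfg.pairs_per_epoch,
            train_cfg.balance,
            seed=int(pair_seed.integers(2**31)),
        )
        caches: dict[int, dict] = {}
        total_loss = 0.0
        grad_sum = {name: np.zeros_like(w) for name, w in params.items()}
        for pair in pairs:
            _, loss, grads = _pair_loss_and_grads(
                pair, params, loss_cfg, caches=caches
            )
            total_loss += loss
            for name in grad_sum:
                grad_sum[name] += grads[name]
        mean_loss = total_loss / len(pairs)
        if not np.isfinite(mean_loss):
            raise TrainingError(
                f"non-finite mean loss {mean_loss} at epoch {epoch}"
            )
        loss_history.append(mean_loss)
        t = epoch + 1
        updated = {}
        for name, w in params.items():
            g = grad_sum[name] / len(pairs)
            if not np.all(np.isfinite(g)):
                raise TrainingError(f"non-finite gradient for {name} at epoch {epoch}")
            adam_m[name] = beta1 * adam_m[name] + (1 - beta1) * g
            adam_v[name] = beta2 * adam_v[name] + (1 - beta2) * g * g
            m_hat = adam_m[name] / (1 - beta1**t)
            v_hat = adam_v[name] / (1 - beta2**t)
            updated[name] = w - train_cfg.learning_rate * m_hat / (
                np.sqrt(v_hat) + eps
            )
        params = AttentionParams(
            updated["w_query"], updated["w_key"], updated["w_value"]
        )
        if val_cohort is not None:
            val_acc = _val_accuracy(val_cohort, params, loss_cfg, train_cfg)
            val_history.append(val_acc)
            if val_acc > best_val:
                best_val = val_acc
                best_params = params
                best_epoch = epoch
    return TrainState(
        params=params if val_cohort is None else best_params,
        loss_config=loss_cfg,
        train_config=train_cfg,
        loss_history=loss_history,
        val_history=val_history,
        best_epoch=best_epoch,
    )
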