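"""Episodic 2-way K-shot evaluation.

The cohort is split subject-level (all scans of one subject stay in one
part) into train/validation/test.  Evaluation then draws episodes from the
test split: each episode holds ``n_shot`` support scans per class and a
disjoint query set; a query is assigned the class whose support scans it is
most similar to on average.  Confusion counts are pooled over episodes and
summarized as ACC, SPE, PPV and NPV, with the patient class treated as
positive (TP = correctly detected patients).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .attention import AttentionParams, attend
from .cohort import LabeledScan
from .dynfc import NC_LABEL, PATIENT_LABEL
from .similarity import pairwise_cosine, subject_similarity

__all__ = [
    "Episode",
    "ConfusionCounts",
    "MetricsReport",
    "EvaluationResult",
    "split_cohort",
    "build_episodes",
    "classify_query",
    "compute_metrics",
    "evaluate",
]


@dataclass
class Episode:
    support: list[LabeledScan]
    query: list[LabeledScan]

    def __post_init__(self) -> None:
        support_ids = {id(s) for s in self.support}
        if any(id(q) in support_ids for q in self.query):
            raise ValueError("a scan appears in both support and query")
        per_class = {}
        for s in self.support:
            per_class[s.label] = per_class.get(s.label, 0) + 1
        if len(per_class) != 2 or len(set(per_class.values())) != 1:
            raise ValueError(
                f"support must hold both classes with equal counts, got {per_class}"
            )


@dataclass
class ConfusionCounts:
    tp: int = 0
    tn: int = 0
    fp: int = 0
    fn: int = 0

    def __add__(self, other: "ConfusionCounts") -> "ConfusionCounts":
        return ConfusionCounts(
            self.tp + other.tp,
            self.tn + other.tn,
            self.fp + other.fp,
            self.fn + other.fn,
        )

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn


@dataclass
class MetricsReport:
    """ACC, SPE, PPV, NPV; an undefined ratio (0/0) is reported as NaN."""

    acc: float
    spe: float
    ppv: float
    npv: float
    counts: ConfusionCounts

    def as_dict(self) -> dict:
        return {
            "ACC": self.acc,
            "SPE": self.spe,
            "PPV": self.ppv,
            "NPV": self.npv,
            "TP": self.counts.tp,
            "TN": self.counts.tn,
            "FP": self.counts.fp,
            "FN": self.counts.fn,
        }


@dataclass
class EvaluationResult:
    pooled: MetricsReport
    episode_acc_mean: float
    episode_acc_sd: float
    n_episodes: int
    per_episode_counts: list[ConfusionCounts] = field(repr=False, default_factory=list)


def _group_by_subject(cohort: Sequence[LabeledScan]) -> dict[str, list[LabeledScan]]:
    groups: dict[str, list[LabeledScan]] = {}
    for scan in cohort:
        groups.setdefault(scan.subject_id, []).append(scan)
    for subject, scans in groups.items():
        if len({s.label for s in scans}) != 1:
            raise ValueError(f"subject {subject!r} carries inconsistent labels")
    return groups


def _largest_remainder(n: int, fractions: Sequence[float]) -> list[int]:
    raw = [n * f for f in fractions]
    base = [math.floor(r) for r in raw]
    short = n - sum(base)
    remainders = sorted(
        range(len(fractions)), key=lambda i: raw[i] - base[i], reverse=True
    )
    for i in remainders[:short]:
        base[i] += 1
    return base


def split_cohort(
    cohort: Sequence[LabeledScan],
    fractions: tuple[float, float, float] = (0.6, 0.2, 0.2),
    seed: int = 0,
) -> tuple[list[LabeledScan], list[LabeledScan], list[LabeledScan]]:
    """Stratified subject-level train/validation/test split.

    Subjects (not scans) are apportioned to parts per class by largest-
    remainder rounding, so no subject's scans leak across parts.
    """
    if len(fractions) != 3 or any(f <= 0 for f in fractions) or not math.isclose(
        sum(fractions), 1.0, abs_tol=1e-9
    ):
        raise ValueError("fractions must be three positives summing to 1")
    groups = _group_by_subject(cohort)
    by_label: dict[str, list[str]] = {}
    for subject, scans in groups.items():
        by_label.setdefault(scans[0].label, []).append(subject)
    rng = np.random.default_rng(seed)
    parts: tuple[list[LabeledScan], ...] = ([], [], [])
    for label in sorted(by_label):
        subjects = sorted(by_label[label])
        rng.shuffle(subjects)
        counts = _largest_remainder(len(subjects), fractions)
        if min(counts) == 0:
            raise ValueError(
                f"class {label!r} has too few subjects ({len(subjects)}) "
                "to populate all three parts"
            )
        cursor = 0
        for part, count in zip(parts, counts):
            for subject in subjects[cursor : cursor + count]:
                part.extend(groups[subject])
            cursor += count
    return parts


def build_episodes(
    cohort: Sequence[LabeledScan],
    n_shot: int = 5,
    n_query: int = 5,
    n_episodes: int = 100,
    seed: int = 0,
) -> list[Episode]:
    """Draw reproducible 2-way episodes: ``n_shot`` supports per class and up
    to ``n_query`` disjoint queries per class, sampled without replacement
    within each episode."""
    by_label: dict[str, list[LabeledScan]] = {}
    for scan in cohort:
        by_label.setdefault(scan.label, []).append(scan)
    if len(by_label) != 2:
        raise ValueError(f"2-way episodes need exactly 2 classes, got {sorted(by_label)}")
    for label, scans in by_label.items():
        if len(scans) < n_shot + 1:
            raise ValueError(
                f"class {label!r} has {len(scans)} scans; needs >= {n_shot + 1} "
                "for support plus at least one query"
            )
    rng = np.random.default_rng(seed)
    episodes = []
    for _ in range(n_episodes):
        support: list[LabeledScan] = []
        query: list[LabeledScan] = []
        for label in sorted(by_label):
            scans = by_label[label]
            take = min(n_shot + n_query, len(scans))
            picked = rng.choice(len(scans), size=take, replace=False)
            support.extend(scans[i] for i in picked[:n_shot])
            query.extend(scans[i] for i in picked[n_shot:])
        episodes.append(Episode(support=support, query=query))
    return episodes


def _weighted(scan: LabeledScan, params: AttentionParams, cache: dict | None):
    if cache is None:
        return attend(scan.fcm, params)
    key = id(scan)
    if key not in cache:
        cache[key] = attend(scan.fcm, params)
    return cache[key]


def classify_query(
    query: LabeledScan,
    episode: Episode,
    params: AttentionParams,
    aggregation: str = "mean",
    rule: str = "class_mean",
    _cache: dict | None = None,
) -> str:
    """Predict a query's class from its similarity to the episode's supports.

    ``class_mean`` (default) compares the mean similarity to each class's
    supports; ``nearest`` takes the class of the single most similar support.
    Exact ties go to NC.
    """
    wq = _weighted(query, params, _cache)
    per_class: dict[str, list[float]] = {}
    for support in episode.support:
        ws = _weighted(support, params, _cache)
        sim = subject_similarity(pairwise_cosine(wq, ws), aggregation).value
        per_class.setdefault(support.label, []).append(sim)
    if rule == "class_mean":
        scores = {label: float(np.mean(v)) for label, v in per_class.items()}
    elif rule == "nearest":
        scores = {label: float(np.max(v)) for label, v in per_class.items()}
    else:
        raise ValueError(f"unknown decision rule {rule!r}")
    best = max(scores.values())
    winners = sorted(label for label, v in scores.items() if v == best)
    return NC_LABEL if NC_LABEL in winners else winners[0]


def _ratio(num: int, den: int) -> float:
    return num / den if den > 0 else float("nan")


def compute_metrics(counts: ConfusionCounts) -> MetricsReport:
    """ACC/SPE/PPV/NPV from confusion counts; 0/0 ratios come back NaN."""
    if counts.total < 1:
        raise ValueError("confusion counts are all zero")
    return MetricsReport(
        acc=_ratio(counts.tp + counts.tn, counts.total),
        spe=_ratio(counts.tn, counts.tn + counts.fp),
        ppv=_ratio(counts.tp, counts.tp + counts.fp),
        npv=_ratio(counts.tn, counts.tn + counts.fn),
        counts=counts,
    )


def evaluate(
    cohort: Sequence[LabeledScan],
    params: AttentionParams,
    n_shot: int = 5,
    n_query: int = 5,
    n_episodes: int = 100,
    seed: int = 0,
    aggregation: str = "mean",
    rule: str = "class_mean",
) -> EvaluationResult:
    """Run the episodic protocol and pool confusion counts over episodes.

    Patient is the positive class.  Reports pooled (micro-averaged) metrics
    plus the mean and sd of per-episode accuracy (macro view).
    """
    episodes = build_episodes(cohort, n_shot, n_query, n_episodes, seed)
    cache: dict = {}  # weighted series per scan, shared across episodes
    pooled = ConfusionCounts()
    per_episode: list[ConfusionCounts] = []
    episode_accs = []
    for episode in episodes:
        counts = ConfusionCounts()
        for query in episode.query:
            predicted = classify_query(
                query, episode, params, aggregation, rule, _cache=cache
            )
            actual_pos = query.label == PATIENT_LABEL
            predicted_pos = predicted == PATIENT_LABEL
            if actual_pos and predicted_pos:
                counts.tp += 1
            elif actual_pos:
                counts.fn += 1
            elif predicted_pos:
                counts.fp += 1
            else:
                counts.tn += 1
        pooled = pooled + counts
        per_episode.append(counts)
        episode_accs.append((counts.tp + counts.tn) / counts.total)
    return EvaluationResult(
        pooled=compute_metrics(pooled),
        episode_acc_mean=float(np.mean(episode_accs)),
        episode_acc_sd=float(np.std(episode_accs, ddof=1)) if len(episode_accs) > 1 else 0.0,
        n_episodes=len(episodes),
        per_episode_counts=per_episode,
    )
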