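"""Labeled-scan containers shared by the training and evaluation stages."""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

from .dynfc import (
    FCSeriesMatrix,
    RoiTimeSeries,
    SlidingWindowConfig,
    build_dynamic_fcn,
    vectorize_lower_triangle,
)

__all__ = ["LabeledScan", "prepare_cohort", "class_counts"]


@dataclass
class LabeledScan:
    """One scan's flattened FC-series matrix together with its identity."""

    subject_id: str
    scan_id: str
    label: str
    fcm: FCSeriesMatrix


def prepare_cohort(
    scans: Sequence[RoiTimeSeries], cfg: SlidingWindowConfig
) -> list[LabeledScan]:
    """Build and vectorize the dynamic FCN of every scan in a labeled cohort."""
    out = []
    for x in scans:
        if x.label is None:
            raise ValueError(f"scan {x.subject_id}/{x.scan_id} has no class label")
        fcm = vectorize_lower_triangle(build_dynamic_fcn(x, cfg), x.roi_labels)
        out.append(
            LabeledScan(
                subject_id=x.subject_id,
                scan_id=x.scan_id or x.subject_id,
                label=x.label,
                fcm=fcm,
            )
        )
    return out


def class_counts(cohort: Sequence[LabeledScan]) -> dict[str, int]:
    counts: dict[str, int] = {}
    for scan in cohort:
        counts[scan.label] = counts.get(scan.label, 0) + 1
    return counts
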