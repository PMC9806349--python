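import numpy as np
import pytest

from pairfc.cohort import LabeledScan, prepare_cohort
from pairfc.dynfc import FCSeriesMatrix, SlidingWindowConfig, lower_triangle_pairs
from pairfc.synthdata import CohortSpec, generate_cohort


@pytest.fixture
def rng():
    return np.random.default_rng(20260921)


@pytest.fixture
def small_window():
    return SlidingWindowConfig(window_length=8, step=4)


def make_fcm(rng, n_rois=4, n_windows=6, scale=1.0) -> FCSeriesMatrix:
    p = n_rois * (n_rois - 1) // 2
    return FCSeriesMatrix(
        series=rng.uniform(-scale, scale, size=(p, n_windows)),
        pair_index=lower_triangle_pairs(n_rois),
        roi_labels=[f"R{i}" for i in range(n_rois)],
    )


def make_scan(rng, label, subject_id, n_rois=4, n_windows=6) -> LabeledScan:
    return LabeledScan(
        subject_id=subject_id,
        scan_id=f"{subject_id}_s1",
        label=label,
        fcm=make_fcm(rng, n_rois, n_windows),
    )


@pytest.fixture
def toy_labeled_cohort(rng):
    """8 NC + 8 patient random-series scans (no planted structure)."""
    return [make_scan(rng, "NC", f"NC_{i}") for i in range(8)] + [
        make_scan(rng, "patient", f"PT_{i}") for i in range(8)
    ]


@pytest.fixture(scope="session")
def small_strong_cohort():
    """Small strong-effect synthetic cohort, FC-vectorized, for training tests."""
    spec = CohortSpec(n_rois=10, n_timepoints=80, n_subjects_per_group=8,
                      altered_pairs=((0, 1), (2, 3)), seed=5)
    scans, gt = generate_cohort(spec)
    cohort = prepare_cohort(scans, SlidingWindowConfig(window_length=20, step=4))
    return cohort, gt
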