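"""Synthetic two-group BOLD cohorts with planted dynamic-FC group differences.

The generator emulates the kind of resting-state cohort the pipeline is
designed for: N ROI band-limited signals per scan, where a designated subset
of ROI pairs carries group-dependent coupling.  Signals are built from
independent band-pass-filtered Gaussian sources mixed with a latent-factor
model:

    x_i(t) = sqrt(c) g(t) + sum_pairs +-sqrt(|e_ij(t)|) h_ij(t)
             + sqrt(1 - c - sum |e_ij(t)|) eps_i(t)

with one global factor g (background coupling ``c`` between every ROI pair),
one shared factor h per altered pair, and private noise eps_i, all
unit-variance.  The instantaneous correlation is then ``c`` everywhere
except at altered pairs, where the patient group gets ``c + effect`` (NC
stays at ``c``).  With the dynamic option on (default), the patient-side
extra coupling oscillates slowly around ``effect`` with a random per-scan
phase, so FC *series* — not only their means — differ between groups.
White measurement noise of standard deviation ``noise_sd`` attenuates every
correlation by ``1 / (1 + noise_sd^2)``; the returned ground-truth record
carries the resulting closed-form expected correlations.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import signal

from .dynfc import NC_LABEL, PATIENT_LABEL, RoiTimeSeries

__all__ = ["CohortSpec", "generate_cohort", "write_cohort", "default_altered_pairs"]


def default_altered_pairs(n_pairs: int = 5) -> list[tuple[int, int]]:
    """Disjoint ROI pairs (0,1), (2,3), ... so coupling budgets never stack."""
    return [(2 * i, 2 * i + 1) for i in range(n_pairs)]


@dataclass(frozen=True)
class CohortSpec:
    """Study conditions for one synthetic cohort.

    ``effect_size`` is the group difference in latent coupling at altered
    pairs (patient = base + sign * effect, NC = base); ``band`` is the
    Butterworth pass band as fractions of Nyquist (defaults mirror a
    0.015-0.15 Hz BOLD band at a 3 s repetition time).

    The default conditions put the two groups at oppositely signed altered-
    pair coupling (NC +0.35, patient -0.25): each group's FC series then
    align within class while anticorrelating across classes, which is the
    regime a cosine-similarity comparison is sensitive to.  A same-sign
    magnitude difference (``effect_sign=+1``) is the harder alternative, in
    which the weak-coupling class is noise-dominated at the altered pairs.
    """

    n_rois: int = 20
    n_timepoints: int = 137
    n_subjects_per_group: int = 40
    scans_per_subject: int = 1
    altered_pairs: tuple[tuple[int, int], ...] = field(
        default_factory=lambda: tuple(default_altered_pairs(5))
    )
    effect_size: float = 0.6
    effect_sign: int = -1
    base_coupling: float = 0.35
    noise_sd: float = 0.1
    band: tuple[float, float] = (0.09, 0.9)
    dynamic: bool = True
    dyn_amplitude: float = 0.07
    dyn_period: float = 45.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_rois < 2 or self.n_timepoints < 8:
            raise ValueError("need n_rois >= 2 and n_timepoints >= 8")
        if self.n_subjects_per_group < 1 or self.scans_per_subject < 1:
            raise ValueError("subject and scan counts must be >= 1")
        if not 0.0 <= self.effect_size <= 1.0:
            raise ValueError("effect_size must lie in [0, 1]")
        if self.effect_sign not in (-1, 1):
            raise ValueError("effect_sign must be +1 or -1")
        if not 0.0 <= self.base_coupling < 1.0:
            raise ValueError("base_coupling must lie in [0, 1)")
        if self.effect_size + abs(self.base_coupling) > 1.0:
            raise ValueError("effect_size + |base_coupling| must be <= 1")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be positive")
        if not 0.0 < self.band[0] < self.band[1] < 1.0:
            raise ValueError("band must satisfy 0 < low < high < 1 (Nyquist fractions)")
        if not 0.0 <= self.dyn_amplitude < 1.0:
            raise ValueError("dyn_amplitude must lie in [0, 1)")
        multiplicity: dict[int, float] = {}
        for i, j in self.altered_pairs:
            if not 0 <= i < j < self.n_rois:
                raise ValueError(f"invalid altered pair ({i}, {j})")
            for r in (i, j):
                multiplicity[r] = multiplicity.get(r, 0) + 1
        peak = self.effect_size * (1.0 + (self.dyn_amplitude if self.dynamic else 0.0))
        worst = self.base_coupling + max(multiplicity.values(), default=0) * peak
        if worst > 1.0 + 1e-12:
            raise ValueError(
                f"coupling budget exceeded: base + peak altered coupling = {worst:.3f} > 1"
            )

    @property
    def expected_attenuation(self) -> float:
        return 1.0 / (1.0 + self.noise_sd**2)


def _band_limited_sources(
    rng: np.random.Generator, n_sources: int, n_timepoints: int, band: tuple[float, float]
) -> np.ndarray:
    """Unit-variance band-pass-filtered Gaussian sources, one per row."""
    white = rng.standard_normal((n_sources, n_timepoints))
    b, a = signal.butter(2, band, btype="band")
    filtered = signal.filtfilt(b, a, white, axis=1)
    sd = filtered.std(axis=1, keepdims=True)
    sd[sd == 0.0] = 1.0
    return (filtered - filtered.mean(axis=1, keepdims=True)) / sd


def _scan_signals(
    spec: CohortSpec, rng: np.random.Generator, is_patient: bool
) -> np.ndarray:
    n, m = spec.n_rois, spec.n_timepoints
    n_altered = len(spec.altered_pairs)
    sources = _band_limited_sources(rng, 1 + n_altered + n, m, spec.band)
    shared = sources[0]
    pair_factors = sources[1 : 1 + n_altered]
    private = sources[1 + n_altered :]

    t = np.arange(m)
    extra = np.zeros((n_altered, m))
    if is_patient and n_altered:
        if spec.dynamic:
            phases = rng.uniform(0.0, 2 * np.pi, size=n_altered)
            modulation = 1.0 + spec.dyn_amplitude * np.sin(
                2 * np.pi * t[None, :] / spec.dyn_period + phases[:, None]
            )
        else:
            modulation = np.ones((n_altered, m))
        extra = spec.effect_sign * spec.effect_size * modulation

    c = spec.base_coupling
    x = np.sqrt(c) * np.tile(shared, (n, 1))
    load = np.sqrt(np.abs(extra))
    budget = np.full((n, m), 1.0 - c)
    for p, (i, j) in enumerate(spec.altered_pairs):
        x[i] += load[p] * pair_factors[p]
        # a negative extra coupling flips the loading sign on one member
        x[j] += np.where(extra[p] < 0, -1.0, 1.0) * load[p] * pair_factors[p]
        budget[i] -= np.abs(extra[p])
        budget[j] -= np.abs(extra[p])
    np.clip(budget, 0.0, None, out=budget)
    x += np.sqrt(budget) * private
    x += spec.noise_sd * rng.standard_normal((n, m))
    return x


def generate_cohort(spec: CohortSpec) -> tuple[list[RoiTimeSeries], dict]:
    """Generate the labeled scans of a two-group cohort plus a ground-truth
    record (altered pairs, expected group correlations, seed) sufficient to
    score recovery experiments without re-deriving the signal model."""
    roi_labels = [f"ROI_{i:03d}" for i in range(spec.n_rois)]
    entropy = np.random.SeedSequence(spec.seed)
    total_scans = 2 * spec.n_subjects_per_group * spec.scans_per_subject
    children = entropy.spawn(total_scans)
    scans: list[RoiTimeSeries] = []
    idx = 0
    for label, prefix in ((NC_LABEL, "NC"), (PATIENT_LABEL, "PT")):
        for subj in range(spec.n_subjects_per_group):
            subject_id = f"{prefix}_{subj + 1:03d}"
            for rep in range(spec.scans_per_subject):
                rng = np.random.default_rng(children[idx])
                idx += 1
                values = _scan_signals(spec, rng, is_patient=label == PATIENT_LABEL)
                scans.append(
                    RoiTimeSeries(
                        values=values,
                        roi_labels=roi_labels,
                        subject_id=subject_id,
                        label=label,
                        scan_id=f"{subject_id}_scan{rep + 1}",
                    )
                )
    att = spec.expected_attenuation
    ground_truth = {
        "altered_pairs": [list(p) for p in spec.altered_pairs],
        "base_coupling": spec.base_coupling,
        "effect_size": spec.effect_size,
        "effect_sign": spec.effect_sign,
        "expected_corr_background": spec.base_coupling * att,
        "expected_corr_altered_nc": spec.base_coupling * att,
        "expected_corr_altered_patient": (
            spec.base_coupling + spec.effect_sign * spec.effect_size
        )
        * att,
        "dynamic": spec.dynamic,
        "seed": spec.seed,
    }
    return scans, ground_truth


def write_cohort(
    cohort: Sequence[RoiTimeSeries],
    directory: str | Path,
    ground_truth: dict | None = None,
) -> Path:
    """Write one TSV per scan plus a manifest (and optional ground-truth
    JSON) in the format the cohort reader consumes; returns the manifest path."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    rows = []
    for scan in cohort:
        filename = f"{scan.scan_id or scan.subject_id}.tsv"
        frame = pd.DataFrame(
            scan.values,
            index=pd.Index(scan.roi_labels, name="roi"),
            columns=[f"t{k}" for k in range(scan.n_timepoints)],
        )
        frame.to_csv(directory / filename, sep="\t", float_format="%.10g")
        rows.append(
            {
                "subject_id": scan.subject_id,
                "scan_id": scan.scan_id,
                "path": filename,
                "label": scan.label,
            }
        )
    manifest_path = directory / "manifest.tsv"
    pd.DataFrame(rows).to_csv(manifest_path, sep="\t", index=False)
    if ground_truth is not None:
        (directory / "ground_truth.json").write_text(
            json.dumps(ground_truth, indent=2)
        )
    return manifest_path
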