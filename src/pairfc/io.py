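"""Readers and writers for scans, manifests, FC containers and checkpoints.

Scan files are plain TSV/CSV: rows are ROIs, the first column the ROI label,
remaining columns time points (optional header).  A manifest binds scan
files to subjects and class labels.  Array containers (dynamic FCNs,
FC-series matrices, attention checkpoints) are ``.npz`` files with a JSON
sidecar carrying shapes, window parameters and pair order.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .attention import AttentionParams
from .dynfc import (
    NC_LABEL,
    PATIENT_LABEL,
    DynamicFCN,
    FCSeriesMatrix,
    RoiTimeSeries,
    SlidingWindowConfig,
)

__all__ = [
    "CohortReadError",
    "read_scan",
    "read_cohort",
    "save_fcn",
    "load_fcn",
    "save_fc_series",
    "load_fc_series",
    "save_checkpoint",
    "load_checkpoint",
]

_LABEL_ALIASES = {
    "nc": NC_LABEL,
    "patient": PATIENT_LABEL,
    "emci": PATIENT_LABEL,
    "mci": PATIENT_LABEL,
}


class CohortReadError(ValueError):
    """A scan or manifest could not be parsed; the message names the file."""


def _sep_for(path: Path) -> str:
    return "," if path.suffix.lower() == ".csv" else "\t"


def read_scan(
    path: str | Path,
    subject_id: str = "",
    label: str | None = None,
    scan_id: str = "",
) -> RoiTimeSeries:
    """Read one ROI x time scan table (first column = ROI label)."""
    path = Path(path)
    if not path.exists():
        raise CohortReadError(f"scan file not found: {path}")
    try:
        frame = pd.read_csv(path, sep=_sep_for(path), index_col=0)
    except Exception as exc:  # noqa: BLE001 - surface parser context
        raise CohortReadError(f"cannot parse {path}: {exc}") from exc
    if frame.empty:
        raise CohortReadError(f"{path}: empty scan table")
    values = frame.to_numpy()
    if not np.issubdtype(values.dtype, np.number):
        for r, row in enumerate(frame.itertuples(index=False)):
            for c, cell in enumerate(row):
                try:
                    float(cell)
                except (TypeError, ValueError):
                    raise CohortReadError(
                        f"{path}: non-numeric value {cell!r} at row "
                        f"{frame.index[r]!r}, column {frame.columns[c]!r}"
                    ) from None
        values = values.astype(float)
    if not np.all(np.isfinite(values.astype(float))):
        raise CohortReadError(f"{path}: scan contains non-finite values")
    try:
        return RoiTimeSeries(
            values=values.astype(float),
            roi_labels=[str(r) for r in frame.index],
            subject_id=subject_id,
            label=label,
            scan_id=scan_id,
        )
    except ValueError as exc:
        raise CohortReadError(f"{path}: {exc}") from exc


def read_cohort(manifest_path: str | Path) -> list[RoiTimeSeries]:
    """Read a manifest (subject_id, path, label[, scan_id]) and all its scans.

    Paths are resolved relative to the manifest's directory.  The cohort is
    validated for recognized labels and a consistent ROI count.
    """
    manifest_path = Path(manifest_path)
    if not manifest_path.exists():
        raise CohortReadError(f"manifest not found: {manifest_path}")
    manifest = pd.read_csv(manifest_path, sep=_sep_for(manifest_path))
    required = {"subject_id", "path", "label"}
    missing = required - set(manifest.columns)
    if missing:
        raise CohortReadError(
            f"{manifest_path}: manifest lacks columns {sorted(missing)}"
        )
    scans = []
    for row in manifest.itertuples(index=False):
        raw_label = str(row.label).strip().lower()
        if raw_label not in _LABEL_ALIASES:
            raise CohortReadError(
                f"{manifest_path}: unknown label {row.label!r} for subject "
                f"{row.subject_id!r} (expected NC or patient/eMCI)"
            )
        scan_path = manifest_path.parent / str(row.path)
        scans.append(
            read_scan(
                scan_path,
                subject_id=str(row.subject_id),
                label=_LABEL_ALIASES[raw_label],
                scan_id=str(getattr(row, "scan_id", "") or ""),
            )
        )
    n_rois = {scan.n_rois for scan in scans}
    if len(n_rois) > 1:
        raise CohortReadError(
            f"{manifest_path}: inconsistent ROI counts across scans: {sorted(n_rois)}"
        )
    return scans


def _write_sidecar(path: Path, meta: dict) -> None:
    path.with_suffix(path.suffix + ".json").write_text(json.dumps(meta, indent=2))


def _read_sidecar(path: Path) -> dict:
    return json.loads(path.with_suffix(path.suffix + ".json").read_text())


def save_fcn(d: DynamicFCN, path: str | Path, cfg: SlidingWindowConfig | None = None) -> None:
    path = Path(path)
    np.savez(path, tensor=d.tensor, window_starts=np.asarray(d.window_starts))
    meta = {"K": d.n_windows, "N": d.n_rois}
    if cfg is not None:
        meta.update({"w": cfg.window_length, "s": cfg.step})
    _write_sidecar(path, meta)


def load_fcn(path: str | Path) -> DynamicFCN:
    with np.load(Path(path)) as data:
        return DynamicFCN(
            tensor=data["tensor"], window_starts=[int(o) for o in data["window_starts"]]
        )


def save_fc_series(fcm: FCSeriesMatrix, path: str | Path) -> None:
    path = Path(path)
    np.savez(path, series=fcm.series, pair_index=np.asarray(fcm.pair_index))
    _write_sidecar(
        path,
        {
            "P": fcm.n_pairs,
            "K": fcm.n_windows,
            "pair_order": "lower-triangle row-major, stored (i, j) with i < j",
            "roi_labels": fcm.roi_labels,
        },
    )


def load_fc_series(path: str | Path) -> FCSeriesMatrix:
    path = Path(path)
    meta = _read_sidecar(path)
    with np.load(path) as data:
        return FCSeriesMatrix(
            series=data["series"],
            pair_index=[tuple(int(v) for v in p) for p in data["pair_index"]],
            roi_labels=meta.get("roi_labels"),
        )


def save_checkpoint(
    params: AttentionParams, path: str | Path, metadata: dict | None = None
) -> None:
    path = Path(path)
    np.savez(path, w_query=params.w_query, w_key=params.w_key, w_value=params.w_value)
    meta = {"d_k": params.d_k, "K": params.n_windows}
    if metadata:
        meta.update(metadata)
    _write_sidecar(path, meta)


def load_checkpoint(path: str | Path) -> tuple[AttentionParams, dict]:
    path = Path(path)
    with np.load(path) as data:
        params = AttentionParams(data["w_query"], data["w_key"], data["w_value"])
    return params, _read_sidecar(path)
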