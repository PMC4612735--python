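"""Dice Similarity Coefficient and volumetry between binary masks.

The agreement between a manual mask M and a semi-automatic mask S is

    DSC = 2 V(M ∩ S) / (V(M) + V(S))

with V(·) the physical volume, computed by counting voxels and multiplying
by the physical voxel size.  Per-case records and min/max/mean/σ summaries
mirror the usual reporting layout (volume in mm³, voxel count, DSC in %).
"""

from __future__ import annotations

import csv
import json
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np

from .errors import InvalidParameterError
from .volume import SegmentationMask

__all__ = [
    "EvaluationRecord",
    "dice",
    "mask_volume",
    "evaluate_masks",
    "summarize",
    "write_records_csv",
    "write_records_json",
]


@dataclass
class EvaluationRecord:
    """One case of manual-vs-automatic comparison."""

    case_id: str
    volume_manual_mm3: float
    volume_auto_mm3: float
    voxels_manual: int
    voxels_auto: int
    dsc_percent: float


def dice(m: SegmentationMask, s: SegmentationMask) -> float:
    """Dice Similarity Coefficient in [0, 1] between two aligned masks.

    Two empty masks agree perfectly (defined limit 1.0).
    """
    m.check_compatible(s)
    inter = int(np.logical_and(m.grid, s.grid).sum())
    total = m.voxel_count + s.voxel_count
    if total == 0:
        return 1.0
    # uniform voxel volume cancels between numerator and denominator
    return 2.0 * inter / total


def mask_volume(mask: SegmentationMask) -> float:
    """Physical volume in mm³: voxel count × voxel size."""
    return mask.volume_mm3


def evaluate_masks(
    manual: SegmentationMask, auto: SegmentationMask, case_id: str = ""
) -> EvaluationRecord:
    """Build the per-case record comparing a manual and an automatic mask."""
    return EvaluationRecord(
        case_id=case_id,
        volume_manual_mm3=mask_volume(manual),
        volume_auto_mm3=mask_volume(auto),
        voxels_manual=manual.voxel_count,
        voxels_auto=auto.voxel_count,
        dsc_percent=100.0 * dice(manual, auto),
    )


def summarize(records: list[EvaluationRecord]) -> dict:
    """Min/max/mean/σ summary of volumes and DSC over a list of records.

    Standard deviations use the sample (n−1) formula; for a single record
    σ is reported as 0.0 with ``"sigma_defined": False``.
    """
    if not records:
        raise InvalidParameterError("summarize needs at least one record")
    n = len(records)

    def stats(values):
        arr = np.asarray(values, dtype=float)
        sigma = float(arr.std(ddof=1)) if n > 1 else 0.0
        return {
            "min": float(arr.min()),
            "max": float(arr.max()),
            "mean": float(arr.mean()),
            "sigma": sigma,
        }

    return {
        "n": n,
        "sigma_defined": n > 1,
        "volume_manual_mm3": stats([r.volume_manual_mm3 for r in records]),
        "volume_auto_mm3": stats([r.volume_auto_mm3 for r in records]),
        "voxels_manual": stats([r.voxels_manual for r in records]),
        "voxels_auto": stats([r.voxels_auto for r in records]),
        "dsc_percent": stats([r.dsc_percent for r in records]),
    }


_CSV_COLUMNS = [
    "case_id",
    "volume_manual_mm3",
    "volume_auto_mm3",
    "voxels_manual",
    "voxels_auto",
    "dsc_percent",
]


def write_records_csv(records: list[EvaluationRecord], path) -> None:
    """CSV report: volume of AZ (mm³), number of voxels, DSC (%) per case."""
    with open(path, "w", newline="") as fh:
        writer = csv.DictWriter(fh, fieldnames=_CSV_COLUMNS)
        writer.writeheader()
        for rec in records:
            writer.writerow(asdict(rec))


def write_records_json(records: list[EvaluationRecord], path) -> None:
    """Per-case records plus summary as JSON."""
    payload = {
        "records": [asdict(r) for r in records],
        "summary": summarize(records) if records else None,
    }
    Path(path).write_text(json.dumps(payload, indent=2))
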