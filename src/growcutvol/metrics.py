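"""Volumetry and agreement metrics for tumor segmentations.

Covers everything needed for a manual-vs-automatic volumetry study:

* the Dice Similarity Coefficient DSC = 2|A∩B| / (|A| + |B|) between two
  binary segmentations A and B;
* physical volumes (voxel count × voxel volume in mm³);
* classical geometric volume approximations used in clinical practice
  (spherical 1/6·π·d³, ellipsoid 1/6·π·a·b·c, mean-radius sphere
  4/3·π·r̄³, caliper a·b²/2);
* the Macdonald bidimensional size measure (largest cross-sectional
  diameter × largest perpendicular diameter) and its ≥50 %-reduction
  response rule;
* per-case records and min/max/mean/sample-std study summaries, reported in
  the field's conventional units (per-case volumes in mm³, summary volumes
  in cm³, DSC in percent).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform

from .core import FOREGROUND, LabelMap, validate_geometry

__all__ = [
    "CaseRecord",
    "SummaryStats",
    "StudySummary",
    "GeometricMeasures",
    "dice",
    "label_volume",
    "summarize",
    "geometric_volume",
    "macdonald_area",
    "macdonald_response",
    "compare_pair",
    "study_report",
]


@dataclass(frozen=True)
class CaseRecord:
    """One study case: manual vs automatic volumes, voxel counts, DSC (%)."""

    case_id: str
    volume_manual_mm3: float
    volume_auto_mm3: float
    voxels_manual: int
    voxels_auto: int
    dsc_percent: float

    def __post_init__(self):
        if not 0.0 <= self.dsc_percent <= 100.0:
            raise ValueError("dsc_percent must lie in [0, 100]")


@dataclass(frozen=True)
class SummaryStats:
    """min / max / mean / sample standard deviation of one study column.

    ``std`` is the n−1 (sample) form; it is None where a column is
    conventionally reported without spread (voxel counts) or n < 2.
    """

    min: float
    max: float
    mean: float
    std: float | None


@dataclass(frozen=True)
class StudySummary:
    """Study-level summary: volumes in cm³, voxel counts, DSC in percent."""

    volume_manual_cm3: SummaryStats
    volume_auto_cm3: SummaryStats
    voxels_manual: SummaryStats
    voxels_auto: SummaryStats
    dsc_percent: SummaryStats


@dataclass(frozen=True)
class GeometricMeasures:
    """Caliper-style diameters (mm) feeding the geometric volume models.

    d — diameter of the maximum cross-sectional area; a, b, c — diameters
    along three axes (for the caliper model a is the largest diameter and b
    the one perpendicular to it); r — mean of the three radii.
    """

    d: float | None = None
    a: float | None = None
    b: float | None = None
    c: float | None = None
    r: float | None = None

    def __post_init__(self):
        for name in ("d", "a", "b", "c", "r"):
            v = getattr(self, name)
            if v is not None and v < 0:
                raise ValueError(f"measure {name} must be >= 0")

    @classmethod
    def from_radii(cls, rx: float, ry: float, rz: float) -> "GeometricMeasures":
        """Mean-radius measures from per-plane radii."""
        return cls(r=(rx + ry + rz) / 3.0)


def dice(a: LabelMap, b: LabelMap) -> float:
    """Dice Similarity Coefficient between two binary label maps, in [0, 1].

    DSC = 2|A∩B| / (|A| + |B|) with A, B the foreground masks
    (``labels == 1``). Two empty masks are defined as perfectly agreeing
    (DSC = 1).
    """
    validate_geometry(a, b, strict=True)
    ma, mb = a.foreground_mask, b.foreground_mask
    na, nb = int(ma.sum()), int(mb.sum())
    if na + nb == 0:
        return 1.0
    return 2.0 * int(np.count_nonzero(ma & mb)) / (na + nb)


def label_volume(m: LabelMap, label: int = FOREGROUND) -> tuple[int, float]:
    """Voxel count and physical volume (mm³) of one label.

    Volume = count × voxel volume (product of spacings).
    """
    if label != 0 and label not in m.label_meaning:
        raise ValueError(f"label {label} not present in label_meaning")
    voxels = int(np.count_nonzero(m.labels == label))
    return voxels, voxels * m.geometry.voxel_volume_mm3


def summarize(values) -> SummaryStats:
    """min / max / mean / sample std (n−1 denominator) of a list of values.

    The sample form of the standard deviation is used throughout the
    package. At least one value is required; with a single value the std is
    undefined and reported as None.
    """
    arr = np.asarray(list(values), dtype=float)
    if arr.size == 0:
        raise ValueError("cannot summarize an empty list")
    std = float(np.std(arr, ddof=1)) if arr.size >= 2 else None
    return SummaryStats(
        min=float(arr.min()), max=float(arr.max()), mean=float(arr.mean()), std=std
    )


_GEOMETRIC_REQUIRES = {
    "spherical": ("d",),
    "ellipsoid": ("a", "b", "c"),
    "mean_radius": ("r",),
    "caliper": ("a", "b"),
}


def geometric_volume(g: GeometricMeasures, model: str) -> float:
    """Volume approximation (mm³) from caliper diameters.

    ``spherical``: π·d³/6 — single diameter, sphere assumption.
    ``ellipsoid``: π·a·b·c/6 — three orthogonal diameters.
    ``mean_radius``: 4/3·π·r̄³ with r̄ the mean of the three radii.
    ``caliper``: a·b²/2 with a the largest diameter and b the perpendicular
    one (the transplant-caliper convention).
    """
    if model not in _GEOMETRIC_REQUIRES:
        raise ValueError(f"unknown model {model!r}")
    for name in _GEOMETRIC_REQUIRES[model]:
        if getattr(g, name) is None:
            raise ValueError(f"model {model!r} requires measure {name!r}")
    if model == "spherical":
        return math.pi * g.d**3 / 6.0
    if model == "ellipsoid":
        return math.pi * g.a * g.b * g.c / 6.0
    if model == "mean_radius":
        return 4.0 / 3.0 * math.pi * g.r**3
    return g.a * g.b**2 / 2.0


def macdonald_area(
    mask_slice: np.ndarray, spacing: tuple[float, float] = (1.0, 1.0)
) -> float:
    """Bidimensional tumor size of a 2D slice (mm²).

    Largest diameter = maximal pairwise distance between foreground voxel
    centers (brute force); perpendicular diameter = extent of the mask along
    the direction orthogonal to the largest-diameter axis. Returns their
    product. Degenerate masks (a single voxel, or perfectly collinear
    centers) take one in-plane voxel extent (mean of the two spacings) for
    the vanishing diameter, so a single voxel at 1 mm spacing scores 1 mm².
    """
    mask_slice = np.asarray(mask_slice).astype(bool)
    if mask_slice.ndim != 2:
        raise ValueError("mask_slice must be 2D")
    idx = np.argwhere(mask_slice)
    if idx.size == 0:
        raise ValueError("empty slice has no Macdonald measure")
    voxel_extent = float(np.mean(spacing))
    pts = idx * np.asarray(spacing, dtype=float)
    if len(pts) == 1:
        return voxel_extent * voxel_extent

    dists = squareform(pdist(pts))
    row, col = np.unravel_index(int(np.argmax(dists)), dists.shape)
    longest = float(dists[row, col])
    if longest == 0.0:
        return voxel_extent * voxel_extent
    u = pts[col] - pts[row]
    u /= np.linalg.norm(u)
    perp = np.array([-u[1], u[0]])
    proj = pts @ perp
    perpendicular = float(proj.max() - proj.min())
    if perpendicular == 0.0:
        perpendicular = voxel_extent
    return longest * perpendicular


def macdonald_response(area_baseline: float, area_followup: float) -> bool:
    """Response under the Macdonald criteria: ≥ 50 % reduction in size.

    True iff the follow-up bidimensional area is at most half the baseline
    area (boundary inclusive).
    """
    if area_baseline <= 0:
        raise ValueError("baseline area must be > 0")
    if area_followup < 0:
        raise ValueError("areas must be >= 0")
    return area_followup <= 0.5 * area_baseline


def compare_pair(manual: LabelMap, auto: LabelMap, case_id: str) -> CaseRecord:
    """One row of a manual-vs-automatic comparison table.

    Volumes and voxel counts come from :func:`label_volume`, agreement from
    :func:`dice` reported in percent.
    """
    validate_geometry(manual, auto, strict=True)
    vox_m, vol_m = label_volume(manual)
    vox_a, vol_a = label_volume(auto)
    return CaseRecord(
        case_id=case_id,
        volume_manual_mm3=vol_m,
        volume_auto_mm3=vol_a,
        voxels_manual=vox_m,
        voxels_auto=vox_a,
        dsc_percent=100.0 * dice(manual, auto),
    )


def study_report(records: list[CaseRecord]) -> tuple[pd.DataFrame, StudySummary]:
    """Per-case table plus study summary from ≥ 2 case records.

    The per-case table keeps volumes in mm³; the summary converts them to
    cm³ (÷1000) before summarizing. DSC is summarized in percent. Voxel
    counts are reported as min/max/mean only — a spread on raw counts mixes
    scanners with different spacings and is conventionally omitted.
    """
    if len(records) < 2:
        raise ValueError("study_report needs at least 2 case records")
    table = pd.DataFrame(
        [
            {
                "case_id": r.case_id,
                "volume_manual_mm3": r.volume_manual_mm3,
                "volume_auto_mm3": r.volume_auto_mm3,
                "voxels_manual": r.voxels_manual,
                "voxels_auto": r.voxels_auto,
                "dsc_percent": r.dsc_percent,
            }
            for r in records
        ]
    )
    no_std = lambda s: SummaryStats(min=s.min, max=s.max, mean=s.mean, std=None)
    summary = StudySummary(
        volume_manual_cm3=summarize(table.volume_manual_mm3 / 1000.0),
        volume_auto_cm3=summarize(table.volume_auto_mm3 / 1000.0),
        voxels_manual=no_std(summarize(table.voxels_manual)),
        voxels_auto=no_std(summarize(table.voxels_auto)),
        dsc_percent=summarize(table.dsc_percent),
    )
    return table, summary


def summary_frame(summary: StudySummary) -> pd.DataFrame:
    """StudySummary as a tidy DataFrame (rows min/max/mean/std)."""
    cols = {
        "volume_manual_cm3": summary.volume_manual_cm3,
        "volume_auto_cm3": summary.volume_auto_cm3,
        "voxels_manual": summary.voxels_manual,
        "voxels_auto": summary.voxels_auto,
        "dsc_percent": summary.dsc_percent,
    }
    rows = {}
    for stat in ("min", "max", "mean", "std"):
        rows[stat] = {
            name: getattr(s, stat) if getattr(s, stat) is not None else np.nan
            for name, s in cols.items()
        }
    return pd.DataFrame(rows).T
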