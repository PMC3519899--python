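"""Bundled reference dataset: a ten-case pituitary adenoma volumetry study.

Per-case results of a published clinical comparison between manual
slice-by-slice expert segmentation and semi-automatic GrowCut-based
segmentation of ten pituitary adenomas: tumor volume (mm³), voxel count for
each method, and the Dice Similarity Coefficient (%) between the two. The
rows are printed study values, not recomputable here — the underlying
patient MRIs were never deposited, and per-case voxel spacings were not
published (so volume ≠ count × 1 mm³ for these rows).

They serve as the canonical input for exercising and validating the
reporting pipeline (:func:`growcutvol.metrics.study_report`).
"""

from __future__ import annotations

from .metrics import CaseRecord

__all__ = ["pituitary_adenoma_cases"]

_ROWS = [
    ("1", 6568.69, 7195.0, 72461, 79370, 85.87),
    ("2", 4150.91, 5427.76, 4457, 5828, 84.36),
    ("3", 7180.44, 6481.12, 35701, 32224, 82.11),
    ("4", 5538.25, 5964.5, 61094, 65796, 85.10),
    ("5", 3230.26, 2950.45, 22027, 20119, 77.51),
    ("6", 9858.40, 10410.8, 67224, 70991, 84.46),
    ("7", 6111.79, 5274.89, 52500, 45311, 75.60),
    ("8", 5082.10, 4169.32, 56062, 45993, 80.10),
    ("9", 15271.10, 15838.9, 104133, 108005, 83.41),
    ("10", 757.007, 1016.58, 5162, 6932, 81.21),
]


def pituitary_adenoma_cases() -> list[CaseRecord]:
    """The ten study cases as :class:`~growcutvol.metrics.CaseRecord` rows."""
    return [
        CaseRecord(
            case_id=cid,
            volume_manual_mm3=vm,
            volume_auto_mm3=va,
            voxels_manual=nm,
            voxels_auto=na,
            dsc_percent=dsc,
        )
        for cid, vm, va, nm, na, dsc in _ROWS
    ]
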