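"""Volume file I/O (NRRD / NIfTI), case manifests, and batch study runs.

NRRD is the primary on-disk format (the native format of the Slicer
ecosystem this workflow mirrors); NIfTI-1 (``.nii`` / ``.nii.gz``) is fully
supported. All reading and writing goes through SimpleITK; arrays are kept
in file-header axis order ``(i, j, k)`` with ``spacing[i]`` matching array
axis ``i``, and the orientation matrix is carried through untouched (no
computation depends on it).

Label maps round-trip losslessly (integer type preserved); images are
stored as float64.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import SimpleITK as sitk

from .core import (
    BACKGROUND,
    FOREGROUND,
    ImageGeometry,
    LabelMap,
    ScalarVolume,
    ScribbleSet,
)
from .growcut import GrowCutParams, segment_with_info
from .metrics import CaseRecord, StudySummary, compare_pair, study_report, summary_frame
from .postedit import PosteditStep, apply_postedit

__all__ = [
    "read_volume",
    "read_labelmap",
    "write_volume",
    "CaseManifest",
    "StudyResult",
    "run_study",
]

logger = logging.getLogger(__name__)

SUPPORTED_SUFFIXES = (".nrrd", ".nii", ".nii.gz")

PER_CASE_COLUMNS = [
    "case_id",
    "volume_manual_mm3",
    "volume_auto_mm3",
    "voxels_manual",
    "voxels_auto",
    "dsc_percent",
]


class VolumeFormatError(ValueError):
    """Unsupported file format or broken geometry metadata."""


def _check_suffix(path: Path) -> None:
    name = path.name.lower()
    if not any(name.endswith(s) for s in SUPPORTED_SUFFIXES):
        raise VolumeFormatError(
            f"unsupported volume format: {path.name!r} (expected one of {SUPPORTED_SUFFIXES})"
        )


def _geometry_from_image(img: sitk.Image, path: Path) -> ImageGeometry:
    # SimpleITK reports spacing/origin in (x, y, z); the numpy array is
    # (z, y, x) — reverse so spacing[i] matches array axis i.
    spacing = tuple(reversed(img.GetSpacing()))
    origin = tuple(reversed(img.GetOrigin()))
    if any(not np.isfinite(s) or s <= 0 for s in spacing):
        raise VolumeFormatError(f"{path}: missing or non-positive spacing {spacing}")
    shape = tuple(reversed(img.GetSize()))
    return ImageGeometry(
        shape=shape, spacing=spacing, origin=origin, direction=tuple(img.GetDirection())
    )


def read_volume(path, as_labelmap: bool | None = None):
    """Read a volume as :class:`ScalarVolume` or :class:`LabelMap`.

    Files with an integer pixel type load as label maps (set
    ``as_labelmap`` to force either interpretation). Geometry metadata is
    validated; zero or missing spacing raises :class:`VolumeFormatError`
    naming the offending field.
    """
    path = Path(path)
    _check_suffix(path)
    if not path.exists():
        raise FileNotFoundError(path)
    img = sitk.ReadImage(str(path))
    geom = _geometry_from_image(img, path)
    arr = sitk.GetArrayFromImage(img)
    is_int = np.issubdtype(arr.dtype, np.integer)
    if as_labelmap is None:
        as_labelmap = is_int
    if as_labelmap:
        if not is_int:
            if not np.array_equal(arr, np.round(arr)):
                raise VolumeFormatError(f"{path}: non-integer values in a label map")
            arr = arr.astype(np.int32)
        present = set(np.unique(arr).tolist()) - {0}
        meaning = {FOREGROUND: "tumor", BACKGROUND: "background"}
        meaning.update({int(v): f"label_{int(v)}" for v in present if v not in meaning})
        return LabelMap(geometry=geom, labels=arr, label_meaning=meaning)
    return ScalarVolume(geometry=geom, values=arr.astype(np.float64))


def read_labelmap(path) -> LabelMap:
    """Read a file that must be a label map."""
    return read_volume(path, as_labelmap=True)


def write_volume(v, path) -> Path:
    """Write a ScalarVolume or LabelMap to NRRD/NIfTI.

    Lossless for label maps (integer type preserved); spacing is serialized
    in mm. Round-tripping preserves grid shape, spacing and every value.
    """
    path = Path(path)
    _check_suffix(path)
    if not path.parent.exists():
        raise IOError(f"parent directory does not exist: {path.parent}")
    if isinstance(v, ScribbleSet):
        v = v.as_labelmap()
    if isinstance(v, LabelMap):
        arr = v.labels
        if arr.dtype not in (np.int16, np.int32, np.uint8, np.uint16):
            arr = arr.astype(np.int32)
    else:
        arr = v.values.astype(np.float64)
    img = sitk.GetImageFromArray(arr)
    g = v.geometry
    img.SetSpacing(tuple(reversed(g.spacing)))
    img.SetOrigin(tuple(reversed(g.origin)))
    if g.direction is not None and len(g.direction) == 9:
        img.SetDirection(g.direction)
    sitk.WriteImage(img, str(path), useCompression=False)
    return path


@dataclass(frozen=True)
class CaseManifest:
    """A CSV-backed list of study cases.

    Three row schemas are recognized by column names:

    * evaluation: ``case_id, path_manual, path_auto``
    * segmentation: ``case_id, path_image, path_scribbles, path_reference``
    * precomputed records: the :data:`PER_CASE_COLUMNS` of a per-case table
      (bypasses all image processing; used to summarize published tables)
    """

    frame: pd.DataFrame
    kind: str  # "evaluate" | "segment" | "records"

    @classmethod
    def read(cls, path) -> "CaseManifest":
        frame = pd.read_csv(path, dtype={"case_id": str})
        cols = set(frame.columns)
        if {"case_id", "path_manual", "path_auto"} <= cols:
            kind = "evaluate"
        elif {"case_id", "path_image", "path_scribbles", "path_reference"} <= cols:
            kind = "segment"
        elif set(PER_CASE_COLUMNS) <= cols:
            kind = "records"
        else:
            raise ValueError(f"unrecognized manifest columns: {sorted(cols)}")
        if frame.case_id.duplicated().any():
            dupes = frame.case_id[frame.case_id.duplicated()].tolist()
            raise ValueError(f"duplicate case_ids in manifest: {dupes}")
        return cls(frame=frame, kind=kind)


@dataclass
class StudyResult:
    records: list[CaseRecord]
    summary: StudySummary | None
    failures: list[dict]
    per_case_csv: Path
    summary_csv: Path
    log_path: Path

    @property
    def ok(self) -> bool:
        return not self.failures


def _process_row(row, kind: str, params: GrowCutParams, steps: list[PosteditStep]):
    if kind == "records":
        return CaseRecord(
            case_id=str(row.case_id),
            volume_manual_mm3=float(row.volume_manual_mm3),
            volume_auto_mm3=float(row.volume_auto_mm3),
            voxels_manual=int(row.voxels_manual),
            voxels_auto=int(row.voxels_auto),
            dsc_percent=float(row.dsc_percent),
        ), None
    if kind == "evaluate":
        manual = read_labelmap(row.path_manual)
        auto = read_labelmap(row.path_auto)
        return compare_pair(manual, auto, str(row.case_id)), None
    image = read_volume(row.path_image, as_labelmap=False)
    scribbles = ScribbleSet.from_labelmap(read_labelmap(row.path_scribbles))
    reference = read_labelmap(row.path_reference)
    labels, info = segment_with_info(image, scribbles, params)
    mask = labels.with_labels((labels.labels == FOREGROUND).astype(np.int16))
    mask = apply_postedit(mask, steps)
    return compare_pair(reference, mask, str(row.case_id)), info


def run_study(
    manifest: CaseManifest | str | Path,
    outdir,
    params: GrowCutParams | None = None,
    postedit_steps: list[PosteditStep] | None = None,
    seed: int | None = None,
) -> StudyResult:
    """Run a batch study from a manifest and write per-case + summary CSVs.

    Evaluation manifests compare existing segmentation pairs; segmentation
    manifests run GrowCut + post-editing against the reference; record
    manifests summarize precomputed per-case rows. Unreadable cases are
    recorded as failures and the run continues (``StudyResult.ok`` is False
    at the end). A JSON run log captures parameters, the seed, and
    per-case convergence diagnostics.
    """
    if not isinstance(manifest, CaseManifest):
        manifest = CaseManifest.read(manifest)
    params = params or GrowCutParams()
    steps = (
        postedit_steps
        if postedit_steps is not None
        else [PosteditStep(op="remove_islands", min_size="keep_largest")]
    )
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    records: list[CaseRecord] = []
    failures: list[dict] = []
    case_log = []
    for row in manifest.frame.itertuples(index=False):
        try:
            rec, info = _process_row(row, manifest.kind, params, steps)
        except Exception as exc:  # noqa: BLE001 — failure rows are the contract
            logger.error("case %s failed: %s", row.case_id, exc)
            failures.append({"case_id": str(row.case_id), "error": str(exc)})
            continue
        records.append(rec)
        entry = {"case_id": rec.case_id}
        if info is not None:
            entry.update(
                converged=info.converged,
                iterations=info.iterations,
                changed_trace=list(info.changed_trace),
            )
        case_log.append(entry)

    per_case_csv = outdir / "per_case.csv"
    summary_csv = outdir / "summary.csv"
    log_path = outdir / "run_log.json"

    summary = None
    if records:
        table = pd.DataFrame([asdict(r) for r in records], columns=PER_CASE_COLUMNS)
        table.to_csv(per_case_csv, index=False)
        if len(records) >= 2:
            _, summary = study_report(records)
            summary_frame(summary).to_csv(summary_csv, index_label="stat")
    log = {
        "manifest_kind": manifest.kind,
        "seed": seed,
        "growcut_params": asdict(params),
        "postedit_steps": [asdict(s) for s in steps],
        "n_cases": len(records),
        "n_failures": len(failures),
        "failures": failures,
        "cases": case_log,
    }
    log_path.write_text(json.dumps(log, indent=2))
    return StudyResult(
        records=records,
        summary=summary,
        failures=failures,
        per_case_csv=per_case_csv,
        summary_csv=summary_csv,
        log_path=log_path,
    )
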