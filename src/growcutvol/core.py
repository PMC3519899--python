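"""Shared volumetric data model: grids, physical geometry, label maps, scribbles.

All computation in this package is grid-local: voxel indexing is 0-based with
axis order ``(i, j, k)`` taken in file-header order, and coordinates stay in
voxel units everywhere except volumetry, where they are converted to mm via
the per-axis spacing. Direction/orientation matrices are carried through I/O
untouched but ignored by computation.

Label conventions are fixed package-wide: ``1`` = foreground (tumor),
``2`` = background, ``0`` = unlabeled. Binary masks are derived as
``labels == 1``.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "FOREGROUND",
    "BACKGROUND",
    "UNLABELED",
    "ImageGeometry",
    "ScalarVolume",
    "LabelMap",
    "ScribbleSet",
    "GeometryMismatchError",
    "validate_geometry",
]

UNLABELED = 0
FOREGROUND = 1  # tumor
BACKGROUND = 2

#: relative spacing tolerance used by :func:`validate_geometry`
SPACING_RTOL = 1e-4


class GeometryMismatchError(ValueError):
    """Two volumes do not live on the same physical grid."""

    def __init__(self, a: "ImageGeometry", b: "ImageGeometry"):
        self.geometries = (a, b)
        super().__init__(f"geometry mismatch: {a} vs {b}")


@dataclass(frozen=True)
class ImageGeometry:
    """Physical layout of a 3D voxel grid.

    Parameters
    ----------
    shape
        Voxel counts per axis, three positive integers.
    spacing
        Voxel size in mm per axis, three positive reals. ``spacing[i]``
        belongs to array axis ``i``.
    origin
        Physical offset of voxel (0, 0, 0) in mm.
    direction
        Optional 9-tuple orientation matrix carried through I/O untouched;
        never used by computation.
    """

    shape: tuple[int, int, int]
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)
    direction: tuple[float, ...] | None = None

    def __post_init__(self):
        object.__setattr__(self, "shape", tuple(int(s) for s in self.shape))
        object.__setattr__(self, "spacing", tuple(float(s) for s in self.spacing))
        object.__setattr__(self, "origin", tuple(float(s) for s in self.origin))
        if len(self.shape) != 3 or len(self.spacing) != 3 or len(self.origin) != 3:
            raise ValueError("geometry must be three-dimensional")
        if any(s < 1 for s in self.shape):
            raise ValueError(f"all shape entries must be >= 1, got {self.shape}")
        if any(s <= 0 for s in self.spacing):
            raise ValueError(f"all spacings must be > 0 mm, got {self.spacing}")

    @property
    def voxel_volume_mm3(self) -> float:
        """Volume of one voxel in mm³ (product of spacings)."""
        return float(np.prod(self.spacing))


def _check_extent(geometry: ImageGeometry, array: np.ndarray, what: str) -> None:
    if tuple(array.shape) != geometry.shape:
        raise ValueError(
            f"{what} extent {array.shape} does not match geometry shape {geometry.shape}"
        )


@dataclass(frozen=True)
class ScalarVolume:
    """A 3D intensity grid with physical geometry — the MRI image."""

    geometry: ImageGeometry
    values: np.ndarray

    def __post_init__(self):
        values = np.asarray(self.values, dtype=np.float64)
        _check_extent(self.geometry, values, "intensity array")
        if not np.all(np.isfinite(values)):
            raise ValueError("intensities must be finite")
        object.__setattr__(self, "values", values)


@dataclass(frozen=True)
class LabelMap:
    """A 3D integer grid sharing a ScalarVolume's geometry.

    Used for scribbles, segmentations and ground truth. ``label_meaning``
    names every nonzero label present; 0 is reserved for unlabeled.
    """

    geometry: ImageGeometry
    labels: np.ndarray
    label_meaning: dict[int, str] = field(
        default_factory=lambda: {FOREGROUND: "tumor", BACKGROUND: "background"}
    )

    def __post_init__(self):
        labels = np.asarray(self.labels)
        if not np.issubdtype(labels.dtype, np.integer):
            if not np.array_equal(labels, np.round(labels)):
                raise ValueError("labels must be integer-valued")
            labels = labels.astype(np.int32)
        _check_extent(self.geometry, labels, "label array")
        if labels.size and labels.min() < 0:
            raise ValueError("labels must be non-negative")
        present = set(np.unique(labels).tolist()) - {UNLABELED}
        missing = present - set(self.label_meaning)
        if missing:
            raise ValueError(f"labels {sorted(missing)} missing from label_meaning")
        object.__setattr__(self, "labels", labels)

    @property
    def foreground_mask(self) -> np.ndarray:
        """Boolean mask of the foreground/tumor class (``labels == 1``)."""
        return self.labels == FOREGROUND

    def with_labels(self, labels: np.ndarray) -> "LabelMap":
        return replace(self, labels=labels)


@dataclass(frozen=True)
class ScribbleSet:
    """User seed strokes: 1 = foreground (tumor), 2 = background, 0 = unlabeled.

    The competitive region growing needs seeds of at least two classes, so a
    valid scribble set contains at least one foreground and one background
    voxel.
    """

    geometry: ImageGeometry
    labels: np.ndarray

    def __post_init__(self):
        labels = np.asarray(self.labels)
        if not np.issubdtype(labels.dtype, np.integer):
            labels = labels.astype(np.int32)
        _check_extent(self.geometry, labels, "scribble array")
        extra = set(np.unique(labels).tolist()) - {UNLABELED, FOREGROUND, BACKGROUND}
        if extra:
            raise ValueError(f"scribbles restricted to {{0, 1, 2}}, found {sorted(extra)}")
        if not np.any(labels == FOREGROUND):
            raise ValueError("scribbles need at least one foreground (label 1) voxel")
        if not np.any(labels == BACKGROUND):
            raise ValueError("scribbles need at least one background (label 2) voxel")
        object.__setattr__(self, "labels", labels)

    @classmethod
    def from_labelmap(cls, m: LabelMap) -> "ScribbleSet":
        return cls(geometry=m.geometry, labels=m.labels)

    def as_labelmap(self) -> LabelMap:
        return LabelMap(
            geometry=self.geometry,
            labels=self.labels,
            label_meaning={FOREGROUND: "tumor", BACKGROUND: "background"},
        )


def validate_geometry(a, b, strict: bool = False, rtol: float = SPACING_RTOL) -> bool:
    """Check that two volumes/label maps live on the same grid.

    True iff shapes are identical and spacings agree within relative
    tolerance ``rtol``. With ``strict=True`` a mismatch raises
    :class:`GeometryMismatchError` instead of returning False. Inputs are
    never mutated; origin and direction are deliberately not compared
    (computation is grid-local).
    """
    ga, gb = a.geometry, b.geometry
    ok = ga.shape == gb.shape and all(
        abs(sa - sb) <= rtol * max(abs(sa), abs(sb))
        for sa, sb in zip(ga.spacing, gb.spacing)
    )
    if strict and not ok:
        raise GeometryMismatchError(ga, gb)
    return ok
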