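"""Synthetic contrast-enhancing tumor phantoms with known ground truth.

A phantom emulates the imaging situation the segmentation workflow targets:
a homogeneously contrast-enhancing ellipsoidal lesion in a darker
background, optionally corrupted by additive Gaussian noise. Because the
ground-truth mask is known exactly (voxel centers inside the ellipsoid),
phantoms let the full scribble → GrowCut → post-edit → volumetry pipeline
be validated quantitatively without patient data.

:func:`make_scribbles` emulates the standard user initialization — an area
painted inside the tumor (the eroded ground truth) and a stroke outside it
(a shell around the dilated ground truth) — so end-to-end runs need no
manual input.

Radius presets span the lesion-volume range seen in clinical pituitary
adenoma series, roughly 0.76–15.3 cm³ (small / medium / large).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .core import (
    BACKGROUND,
    FOREGROUND,
    ImageGeometry,
    LabelMap,
    ScalarVolume,
    ScribbleSet,
)

__all__ = ["PhantomParams", "RADIUS_PRESETS", "make_phantom", "make_scribbles"]

#: ellipsoid semi-axes (mm) spanning the clinical volume range ~0.76–15.3 cm³
RADIUS_PRESETS: dict[str, tuple[float, float, float]] = {
    "small": (5.7, 5.6, 5.7),  # ~0.76 cm³
    "medium": (11.6, 11.4, 11.5),  # ~6.4 cm³  (series mean)
    "large": (15.5, 15.2, 15.5),  # ~15.3 cm³
}


@dataclass(frozen=True)
class PhantomParams:
    """Generation parameters for one phantom.

    The ellipsoid (semi-axes ``radii`` in mm, centered at ``center`` voxel
    coordinates, default grid center) must fit strictly inside the grid so
    the background scribble shell fits too. ``noise_sigma`` is the standard
    deviation of additive Gaussian noise; 0 gives a clean two-valued image.
    """

    shape: tuple[int, int, int] = (64, 64, 64)
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    center: tuple[float, float, float] | None = None
    radii: tuple[float, float, float] = RADIUS_PRESETS["medium"]
    intensity_tumor: float = 100.0
    intensity_background: float = 0.0
    noise_sigma: float = 0.0
    rng_seed: int = 0

    def __post_init__(self):
        if any(r <= 0 for r in self.radii):
            raise ValueError("radii must be > 0")
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be >= 0")
        if self.intensity_tumor == self.intensity_background:
            raise ValueError("tumor and background intensities must differ")

    @property
    def center_voxels(self) -> tuple[float, float, float]:
        if self.center is not None:
            return self.center
        return tuple((s - 1) / 2.0 for s in self.shape)


def make_phantom(p: PhantomParams) -> tuple[ScalarVolume, LabelMap]:
    """Generate (image, ground truth) from phantom parameters.

    Ground truth contains every voxel whose center lies strictly inside the
    ellipsoid. The image is ``intensity_tumor`` inside, the background
    intensity outside, plus iid Gaussian noise drawn from a generator
    seeded with ``rng_seed`` — identical parameters give bit-identical
    output. A tumor touching the grid boundary is rejected.
    """
    geom = ImageGeometry(shape=p.shape, spacing=p.spacing)
    grids = np.meshgrid(*[np.arange(s, dtype=np.float64) for s in p.shape], indexing="ij")
    acc = np.zeros(p.shape, dtype=np.float64)
    for g, c, r, sp in zip(grids, p.center_voxels, p.radii, p.spacing):
        acc += ((g - c) * sp / r) ** 2
    gt = acc < 1.0
    if not gt.any():
        raise ValueError("ellipsoid contains no voxel centers; enlarge radii")
    for axis in range(3):
        first = np.take(gt, 0, axis=axis)
        last = np.take(gt, gt.shape[axis] - 1, axis=axis)
        if first.any() or last.any():
            raise ValueError(
                "tumor touches the grid boundary; shrink radii or enlarge shape "
                "(the background scribble shell must fit around it)"
            )
    values = np.where(gt, p.intensity_tumor, p.intensity_background).astype(np.float64)
    if p.noise_sigma > 0:
        rng = np.random.default_rng(p.rng_seed)
        values = values + rng.normal(0.0, p.noise_sigma, size=p.shape)
    volume = ScalarVolume(geometry=geom, values=values)
    truth = LabelMap(
        geometry=geom, labels=gt.astype(np.int16), label_meaning={FOREGROUND: "tumor"}
    )
    return volume, truth


def make_scribbles(
    ground_truth: LabelMap,
    fg_erosion: int = 2,
    bg_offset: int = 4,
    bg_thickness: int = 2,
) -> ScribbleSet:
    """Auto-generated seed strokes from a ground-truth mask.

    Foreground scribble: the ground truth eroded ``fg_erosion`` times (an
    "area inside" the tumor, safely away from the boundary). Background
    scribble: a shell of thickness ``bg_thickness`` at distance roughly
    ``bg_offset`` outside the tumor (dilation by ``bg_offset`` minus
    dilation by ``bg_offset − bg_thickness``). By construction fg ⊆ ground
    truth and bg ∩ ground truth = ∅.
    """
    gt = ground_truth.labels.astype(bool)
    if not gt.any():
        raise ValueError("ground truth is empty")
    if not 0 <= bg_thickness <= bg_offset:
        raise ValueError("need 0 <= bg_thickness <= bg_offset")
    struct = ndimage.generate_binary_structure(3, 1)
    fg = gt if fg_erosion == 0 else ndimage.binary_erosion(gt, struct, iterations=fg_erosion)
    if not fg.any():
        raise ValueError(
            f"fg_erosion={fg_erosion} erased the foreground scribble entirely; "
            "use a smaller fg_erosion"
        )
    outer = ndimage.binary_dilation(gt, struct, iterations=bg_offset)
    inner = (
        gt
        if bg_offset == bg_thickness
        else ndimage.binary_dilation(gt, struct, iterations=bg_offset - bg_thickness)
    )
    bg = outer & ~inner
    labels = np.zeros(gt.shape, dtype=np.int16)
    labels[bg] = BACKGROUND
    labels[fg] = FOREGROUND
    return ScribbleSet(geometry=ground_truth.geometry, labels=labels)
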