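"""Morphological post-editing of segmentation masks.

After the automatic competitive region growing, segmentations are typically
touched up with simple binary morphology: dilation, erosion, and removal of
small disconnected "islands". Here those edits are expressed as an ordered
sequence of :class:`PosteditStep` applied left-to-right, so a whole pipeline
is reproducible from its configuration.

The structuring element follows the step's connectivity: a 6-connected
cross or a full 26-connected cube; a radius r is realized by iterating the
unit operation r times.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .core import FOREGROUND, LabelMap

__all__ = ["PosteditStep", "morph_binary", "remove_islands", "apply_postedit"]

logger = logging.getLogger(__name__)

KEEP_LARGEST = "keep_largest"


@dataclass(frozen=True)
class PosteditStep:
    """One morphological edit.

    op
        ``"dilate"``, ``"erode"`` or ``"remove_islands"``.
    radius
        Iterations of the unit structuring element (dilate/erode only).
    connectivity
        6 (cross) or 26 (cube) structuring element / component adjacency.
    min_size
        For ``remove_islands``: components smaller than this many voxels are
        deleted; the string ``"keep_largest"`` retains only the largest
        component.
    """

    op: str
    radius: int = 1
    connectivity: int = 26
    min_size: int | str = KEEP_LARGEST

    def __post_init__(self):
        if self.op not in ("dilate", "erode", "remove_islands"):
            raise ValueError(f"unknown post-edit op: {self.op!r}")
        if self.connectivity not in (6, 26):
            raise ValueError("connectivity must be 6 or 26")
        if self.op in ("dilate", "erode") and self.radius < 1:
            raise ValueError("radius must be >= 1")
        if self.op == "remove_islands" and self.min_size != KEEP_LARGEST:
            if int(self.min_size) < 1:
                raise ValueError("min_size must be >= 1 or 'keep_largest'")


def _binary_array(mask: LabelMap) -> np.ndarray:
    arr = mask.labels
    uniq = np.unique(arr)
    if not np.all(np.isin(uniq, (0, 1))):
        raise ValueError(f"mask must be binary (labels 0/1), found {uniq.tolist()}")
    return arr.astype(bool)


def _structure(connectivity: int) -> np.ndarray:
    return ndimage.generate_binary_structure(3, 1 if connectivity == 6 else 3)


def morph_binary(
    mask: LabelMap, op: str, radius: int = 1, connectivity: int = 26
) -> LabelMap:
    """Binary dilation or erosion with the connectivity's structuring element.

    Dilation is extensive (output ⊇ input), erosion anti-extensive; geometry
    is preserved. ``radius`` iterates the unit element.
    """
    if op not in ("dilate", "erode"):
        raise ValueError(f"op must be 'dilate' or 'erode', got {op!r}")
    if radius < 1:
        raise ValueError("radius must be >= 1")
    arr = _binary_array(mask)
    struct = _structure(connectivity)
    fn = ndimage.binary_dilation if op == "dilate" else ndimage.binary_erosion
    out = fn(arr, structure=struct, iterations=radius)
    return mask.with_labels(out.astype(mask.labels.dtype))


def remove_islands(
    mask: LabelMap, min_size: int | str = KEEP_LARGEST, connectivity: int = 26
) -> LabelMap:
    """Delete small connected components from a binary mask.

    Components (under the given connectivity) with fewer than ``min_size``
    voxels are zeroed; ``"keep_largest"`` retains only the largest
    component, ties broken by first component in lexicographic scan order.
    An empty mask passes through unchanged.
    """
    arr = _binary_array(mask)
    if not arr.any():
        return mask.with_labels(arr.astype(mask.labels.dtype))
    comp, n = ndimage.label(arr, structure=_structure(connectivity))
    sizes = np.bincount(comp.ravel())
    sizes[0] = 0
    if min_size == KEEP_LARGEST:
        keep = np.zeros(n + 1, dtype=bool)
        keep[int(np.argmax(sizes))] = True  # argmax -> first (scan-order) on ties
    else:
        keep = sizes >= int(min_size)
        keep[0] = False
    out = keep[comp]
    return mask.with_labels(out.astype(mask.labels.dtype))


def apply_postedit(mask: LabelMap, steps: list[PosteditStep]) -> LabelMap:
    """Apply an ordered post-edit sequence; an empty list is the identity.

    The voxel-count delta of each step is logged so edits stay auditable.
    """
    out = mask
    for step in steps:
        before = int(np.count_nonzero(out.labels == FOREGROUND))
        if step.op in ("dilate", "erode"):
            out = morph_binary(out, step.op, step.radius, step.connectivity)
        else:
            out = remove_islands(out, step.min_size, step.connectivity)
        after = int(np.count_nonzero(out.labels == FOREGROUND))
        logger.info("postedit %s: %+d voxels (%d -> %d)", step.op, after - before, before, after)
    return out
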