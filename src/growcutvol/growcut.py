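"""GrowCut: competitive region growing as a cellular automaton.

Every voxel carries a label l and a strength θ ∈ [0, 1]. Seed voxels (the
user's scribbles) start with their scribble label and θ = 1; everything else
is unlabeled with θ = 0. At each synchronous iteration every labeled voxel q
"attacks" its neighbors p with strength

    a(q → p) = g(|c_p − c_q|) · θ_q,      g(x) = 1 − x / max_diff,

and p is conquered (l_p ← l_q, θ_p ← a) when the attack strictly exceeds
θ_p. Since g ≤ 1, attacks never exceed the attacker's strength, θ is
non-decreasing, and seeds (θ = 1) can never be conquered; the automaton
terminates when no voxel changes.

Two implementations share these semantics:

* :func:`segment` — the production path with the standard speed-ups:
  computation restricted to a region of interest around the scribbles
  (axis-aligned bounding box plus margin, a superset of the convex hull),
  neighbor similarity weights precomputed once and reused, and
  saturated/inactive voxel tracking so quiescent regions are skipped and
  termination is detected cheaply.
* :func:`segment_reference` — the naive oracle that visits every voxel and
  every neighbor in every iteration, with none of the above. On any input
  whose ROI covers the full grid the two are voxel-identical.

Updates are synchronous (double-buffered): all reads within an iteration use
the previous iteration's state, so results are deterministic and independent
of traversal order or any parallel partitioning. Ties between equally strong
attackers are broken by a fixed lexicographic neighbor-offset order.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from numba import njit

from .core import (
    BACKGROUND,
    FOREGROUND,
    ImageGeometry,
    LabelMap,
    ScalarVolume,
    ScribbleSet,
    validate_geometry,
)

__all__ = [
    "GrowCutParams",
    "GrowCutState",
    "RoiBox",
    "GrowCutRunInfo",
    "neighbor_offsets",
    "similarity_weight",
    "initialize_state",
    "compute_roi",
    "evolve_step",
    "segment",
    "segment_with_info",
    "segment_reference",
]

logger = logging.getLogger(__name__)


def neighbor_offsets(connectivity: int) -> np.ndarray:
    """Neighbor offsets in fixed lexicographic order (the tie-break order).

    ``connectivity`` is 6 (face neighbors, von Neumann) or 26 (full 3D
    Moore neighborhood).
    """
    if connectivity not in (6, 26):
        raise ValueError(f"connectivity must be 6 or 26, got {connectivity}")
    offs = [
        (di, dj, dk)
        for di in (-1, 0, 1)
        for dj in (-1, 0, 1)
        for dk in (-1, 0, 1)
        if (di, dj, dk) != (0, 0, 0)
        and (connectivity == 26 or abs(di) + abs(dj) + abs(dk) == 1)
    ]
    return np.asarray(sorted(offs), dtype=np.int64)


@dataclass(frozen=True)
class GrowCutParams:
    """Automaton parameters.

    neighborhood
        6- or 26-connectivity; 26 (Moore) is the classical GrowCut choice.
    roi_margin
        Margin in voxels added around the scribble bounding box.
    max_iterations
        Safety cap; normal exit is convergence (no voxel changed).
    max_diff
        Normalizer of the similarity measure. ``None`` (default policy)
        computes the maximum absolute intensity difference over neighbor
        pairs inside the computation domain; a float fixes it explicitly.
    """

    neighborhood: int = 26
    roi_margin: int = 5
    max_iterations: int = 500
    max_diff: float | None = None

    def __post_init__(self):
        if self.neighborhood not in (6, 26):
            raise ValueError("neighborhood must be 6 or 26")
        if self.roi_margin < 0:
            raise ValueError("roi_margin must be >= 0")
        if self.max_iterations < 1:
            raise ValueError("max_iterations must be >= 1")


@dataclass(frozen=True)
class RoiBox:
    """Axis-aligned computation box, inclusive on both ends."""

    lower: tuple[int, int, int]
    upper: tuple[int, int, int]

    def __post_init__(self):
        if any(lo > hi for lo, hi in zip(self.lower, self.upper)):
            raise ValueError(f"empty ROI box: {self.lower}..{self.upper}")
        if any(lo < 0 for lo in self.lower):
            raise ValueError("ROI extends below the image extent")

    @property
    def slices(self) -> tuple[slice, slice, slice]:
        return tuple(slice(lo, hi + 1) for lo, hi in zip(self.lower, self.upper))

    def shape(self) -> tuple[int, int, int]:
        return tuple(hi - lo + 1 for lo, hi in zip(self.lower, self.upper))

    def covers(self, geometry: ImageGeometry) -> bool:
        return self.lower == (0, 0, 0) and self.upper == tuple(
            s - 1 for s in geometry.shape
        )


@dataclass
class GrowCutState:
    """Cellular-automaton state: per-voxel label, strength, bookkeeping.

    ``saturated`` marks voxels whose label/strength can no longer change
    (θ = 1); ``active`` marks voxels eligible for update next iteration
    (a neighbor changed last iteration). Both are pruning devices only —
    they never alter the automaton's results.
    """

    labels: np.ndarray  # int32, 0 = unlabeled
    strength: np.ndarray  # float64 θ in [0, 1]
    saturated: np.ndarray  # bool
    active: np.ndarray  # bool
    seed_mask: np.ndarray = field(repr=False, default=None)


@dataclass(frozen=True)
class GrowCutRunInfo:
    """Convergence diagnostics for one segmentation run."""

    converged: bool
    iterations: int
    changed_trace: tuple[int, ...]
    roi: RoiBox
    max_diff: float


def similarity_weight(c_p: float, c_q: float, max_diff: float) -> float:
    """Similarity g between two intensities, in [0, 1].

    ``1`` for equal intensities, ``0`` at the maximal difference, linear in
    between: ``g = 1 − |c_p − c_q| / max_diff``. A degenerate constant image
    (``max_diff = 0``) yields g ≡ 1. An intensity difference exceeding
    ``max_diff`` means the normalizer was computed incorrectly upstream and
    raises.
    """
    if max_diff < 0:
        raise ValueError("max_diff must be >= 0")
    diff = abs(float(c_p) - float(c_q))
    if max_diff == 0.0:
        if diff > 0.0:
            raise ValueError("nonzero intensity difference with max_diff = 0")
        return 1.0
    if diff > max_diff:
        raise ValueError(
            f"intensity difference {diff} exceeds normalizer max_diff={max_diff}"
        )
    return 1.0 - diff / max_diff


def initialize_state(volume: ScalarVolume, scribbles: ScribbleSet) -> GrowCutState:
    """Seed the automaton from the scribbles.

    Scribbled voxels receive their scribble label with θ = 1; everything
    else is unlabeled with θ = 0. The initial active set is every voxel
    adjacent (26-neighborhood superset) to a seed; no voxel is saturated.
    """
    validate_geometry(volume, scribbles, strict=True)
    seeds = scribbles.labels
    labels = seeds.astype(np.int32).copy()
    strength = (seeds > 0).astype(np.float64)
    saturated = np.zeros(labels.shape, dtype=bool)
    active = _dilate26(seeds > 0) & (seeds == 0)
    return GrowCutState(
        labels=labels,
        strength=strength,
        saturated=saturated,
        active=active,
        seed_mask=(seeds > 0),
    )


def _dilate26(mask: np.ndarray) -> np.ndarray:
    from scipy import ndimage

    return ndimage.binary_dilation(mask, structure=np.ones((3, 3, 3), dtype=bool))


def compute_roi(
    scribbles: ScribbleSet, margin: int, extent: ImageGeometry
) -> RoiBox:
    """Bounding box of all scribbled voxels, expanded by ``margin``, clipped.

    The axis-aligned box is a superset of the convex hull of the labeled
    voxels, so no scribble is ever excluded from computation.
    """
    if margin < 0:
        raise ValueError("margin must be >= 0")
    nz = np.nonzero(scribbles.labels)
    if nz[0].size == 0:
        raise ValueError("cannot compute ROI of empty scribbles")
    lower = tuple(
        max(int(ax.min()) - margin, 0) for ax in nz
    )
    upper = tuple(
        min(int(ax.max()) + margin, s - 1) for ax, s in zip(nz, extent.shape)
    )
    return RoiBox(lower=lower, upper=upper)


def _neighbor_max_diff(values: np.ndarray, offsets: np.ndarray) -> float:
    """Maximum |Δ intensity| over neighbor pairs within ``values``."""
    best = 0.0
    for di, dj, dk in offsets:
        a, b = _shifted_views(values, (di, dj, dk))
        if a.size:
            d = float(np.max(np.abs(a - b)))
            best = max(best, d)
    return best


def _shifted_views(arr: np.ndarray, off: tuple[int, int, int]):
    """Views (center, neighbor) such that neighbor = center + off, in-bounds."""
    sl_c, sl_n = _views_slices(arr.shape, off)
    return arr[sl_c], arr[sl_n]


def _precompute_weights(
    values: np.ndarray, offsets: np.ndarray, max_diff: float
) -> list[np.ndarray]:
    """Similarity g for every neighbor offset, computed once and reused.

    ``weights[m]`` has the shape of the in-bounds center view for offset m
    and holds g(c_p, c_{p+off}). Bit-identical to computing g on the fly:
    the same expression ``1 − |Δ| / max_diff`` evaluated in float64.
    """
    weights = []
    for di, dj, dk in offsets:
        a, b = _shifted_views(values, (int(di), int(dj), int(dk)))
        if max_diff == 0.0:
            weights.append(np.ones_like(a))
        else:
            weights.append(1.0 - np.abs(a - b) / max_diff)
    return weights


def _step_arrays(
    labels: np.ndarray,
    strength: np.ndarray,
    saturated: np.ndarray,
    active: np.ndarray,
    offsets: np.ndarray,
    weights: list[np.ndarray],
):
    """One synchronous update over a (sub)grid. Returns new arrays + changed mask.

    All reads come from the previous state; the best attacker per voxel is
    the maximal a(q→p), first offset in lexicographic order winning ties.
    """
    shape = labels.shape
    best = np.zeros(shape, dtype=np.float64)
    best_label = np.zeros(shape, dtype=np.int32)
    for m, (di, dj, dk) in enumerate(offsets):
        off = (int(di), int(dj), int(dk))
        c_idx, n_idx = _views_slices(shape, off)
        attack = weights[m] * strength[n_idx]
        sub_best = best[c_idx]
        win = attack > sub_best  # strict: first offset keeps ties
        if np.any(win):
            sub_best[win] = attack[win]
            best[c_idx] = sub_best
            sub_lab = best_label[c_idx]
            sub_lab[win] = labels[n_idx][win]
            best_label[c_idx] = sub_lab
    eligible = active & ~saturated
    changed = eligible & (best > strength)
    new_labels = labels.copy()
    new_strength = strength.copy()
    new_labels[changed] = best_label[changed]
    new_strength[changed] = best[changed]
    return new_labels, new_strength, changed


def _views_slices(shape, off):
    sl_c, sl_n = [], []
    for o, n in zip(off, shape):
        if o < 0:
            sl_c.append(slice(-o, n))
            sl_n.append(slice(0, n + o))
        elif o > 0:
            sl_c.append(slice(0, n - o))
            sl_n.append(slice(o, n))
        else:
            sl_c.append(slice(0, n))
            sl_n.append(slice(0, n))
    return tuple(sl_c), tuple(sl_n)


def evolve_step(
    state: GrowCutState,
    volume: ScalarVolume,
    roi: RoiBox,
    params: GrowCutParams,
    _weights: list[np.ndarray] | None = None,
    _max_diff: float | None = None,
):
    """One synchronous automaton iteration restricted to the ROI.

    Returns ``(state, changed_count)``; the state object is updated in
    place. Voxels reaching θ = 1 are marked saturated; the next active set
    is the voxels with at least one changed neighbor. When precomputed
    weights are not supplied they are computed for this call (same formula,
    bit-identical results).
    """
    offsets = neighbor_offsets(params.neighborhood)
    sub = roi.slices
    values = volume.values[sub]
    if _max_diff is None:
        _max_diff = (
            params.max_diff
            if params.max_diff is not None
            else _neighbor_max_diff(values, offsets)
        )
    if _weights is None:
        _weights = _precompute_weights(values, offsets, _max_diff)

    labels = state.labels[sub]
    strength = state.strength[sub]
    new_labels, new_strength, changed = _step_arrays(
        labels, strength, state.saturated[sub], state.active[sub], offsets, _weights
    )
    changed_count = int(np.count_nonzero(changed))
    state.labels[sub] = new_labels
    state.strength[sub] = new_strength
    sat = state.saturated[sub]
    sat |= new_strength >= 1.0
    state.saturated[sub] = sat
    from scipy import ndimage

    nxt = np.zeros_like(state.active)
    if changed_count:
        # next-active = voxels with >= 1 changed neighbor (hollow structure:
        # a voxel's own change alone cannot trigger a further change)
        struct = _structure(params.neighborhood)
        struct[1, 1, 1] = False
        nxt[sub] = ndimage.binary_dilation(changed, structure=struct)
    state.active = nxt
    return state, changed_count


def _structure(connectivity: int) -> np.ndarray:
    from scipy import ndimage

    return ndimage.generate_binary_structure(3, 1 if connectivity == 6 else 3)


def segment_with_info(
    volume: ScalarVolume, scribbles: ScribbleSet, params: GrowCutParams | None = None
) -> tuple[LabelMap, GrowCutRunInfo]:
    """Run the optimized automaton to convergence; return labels + diagnostics.

    Initializes from the scribbles, restricts computation to the scribble
    bounding box plus margin, precomputes all neighbor similarity weights
    once, and iterates synchronous steps until no voxel changes or
    ``max_iterations`` is hit (then a warning is logged and the partial
    result carries ``converged=False``). Voxels outside the ROI keep
    label 0.
    """
    params = params or GrowCutParams()
    validate_geometry(volume, scribbles, strict=True)
    state = initialize_state(volume, scribbles)
    roi = compute_roi(scribbles, params.roi_margin, volume.geometry)
    offsets = neighbor_offsets(params.neighborhood)
    values = volume.values[roi.slices]
    max_diff = (
        params.max_diff
        if params.max_diff is not None
        else _neighbor_max_diff(values, offsets)
    )
    weights = _precompute_weights(values, offsets, max_diff)

    trace = []
    converged = False
    for _ in range(params.max_iterations):
        state, changed = evolve_step(
            state, volume, roi, params, _weights=weights, _max_diff=max_diff
        )
        trace.append(changed)
        if changed == 0:
            converged = True
            break
    if not converged:
        logger.warning(
            "GrowCut did not converge within %d iterations (last changed=%d); "
            "returning partial result",
            params.max_iterations,
            trace[-1],
        )
    out = LabelMap(
        geometry=volume.geometry,
        labels=state.labels,
        label_meaning={FOREGROUND: "tumor", BACKGROUND: "background"},
    )
    info = GrowCutRunInfo(
        converged=converged,
        iterations=len(trace),
        changed_trace=tuple(trace),
        roi=roi,
        max_diff=max_diff,
    )
    return out, info


def segment(
    volume: ScalarVolume, scribbles: ScribbleSet, params: GrowCutParams | None = None
) -> LabelMap:
    """Optimized GrowCut segmentation (see :func:`segment_with_info`)."""
    out, _ = segment_with_info(volume, scribbles, params)
    return out


@njit(cache=False)
def _naive_kernel(values, labels0, strength0, offsets, max_diff, max_iterations):
    """Naive automaton: every voxel visits every neighbor, every iteration."""
    ni, nj, nk = values.shape
    labels = labels0.copy()
    strength = strength0.copy()
    n_off = offsets.shape[0]
    iterations = 0
    converged = False
    for _ in range(max_iterations):
        new_labels = labels.copy()
        new_strength = strength.copy()
        changed = 0
        for i in range(ni):
            for j in range(nj):
                for k in range(nk):
                    best = 0.0
                    best_label = 0
                    for m in range(n_off):
                        qi = i + offsets[m, 0]
                        qj = j + offsets[m, 1]
                        qk = k + offsets[m, 2]
                        if qi < 0 or qi >= ni or qj < 0 or qj >= nj:
                            continue
                        if qk < 0 or qk >= nk:
                            continue
                        d = abs(values[i, j, k] - values[qi, qj, qk])
                        if max_diff == 0.0:
                            g = 1.0
                        else:
                            g = 1.0 - d / max_diff
                        a = g * strength[qi, qj, qk]
                        if a > best:
                            best = a
                            best_label = labels[qi, qj, qk]
                    if best > strength[i, j, k]:
                        new_labels[i, j, k] = best_label
                        new_strength[i, j, k] = best
                        changed += 1
        labels = new_labels
        strength = new_strength
        iterations += 1
        if changed == 0:
            converged = True
            break
    return labels, strength, iterations, converged


def segment_reference(
    volume: ScalarVolume, scribbles: ScribbleSet, params: GrowCutParams | None = None
) -> LabelMap:
    """Naive full-grid GrowCut — the correctness oracle.

    Identical automaton semantics with no ROI restriction, no saturation
    tracking and no weight precomputation: similarity is recomputed for
    every voxel pair in every iteration. On inputs whose scribble bounding
    box plus margin covers the full grid this equals :func:`segment`
    voxel-for-voxel.
    """
    params = params or GrowCutParams()
    validate_geometry(volume, scribbles, strict=True)
    offsets = neighbor_offsets(params.neighborhood)
    max_diff = (
        params.max_diff
        if params.max_diff is not None
        else _neighbor_max_diff(volume.values, offsets)
    )
    seeds = scribbles.labels.astype(np.int32)
    strength0 = (seeds > 0).astype(np.float64)
    labels, _, iterations, converged = _naive_kernel(
        volume.values,
        seeds,
        strength0,
        offsets,
        float(max_diff),
        params.max_iterations,
    )
    if not converged:
        logger.warning(
            "reference GrowCut did not converge within %d iterations", iterations
        )
    return LabelMap(
        geometry=volume.geometry,
        labels=labels,
        label_meaning={FOREGROUND: "tumor", BACKGROUND: "background"},
    )
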