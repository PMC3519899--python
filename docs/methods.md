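# Methods

## The automaton

GrowCut models segmentation as competition between labeled cells on the
voxel grid. State per voxel: label l ∈ {0, 1, 2} (unlabeled / tumor /
background) and strength θ ∈ [0, 1]. Seeds (scribbles) start at θ = 1. One
iteration applies, synchronously for every voxel p,

    q* = argmax_{q ∈ N(p)} g(|c_p − c_q|) · θ_q,
    if g·θ_{q*} > θ_p:  l_p ← l_{q*},  θ_p ← g·θ_{q*}

with all reads taken from the previous iteration's state (double
buffering). Consequences relied on throughout:

* θ is non-decreasing and bounded by 1, so with the strict inequality the
  automaton terminates in finitely many iterations;
* an attack never exceeds the attacker's strength (g ≤ 1), so seeds are
  immutable;
* results are deterministic and independent of traversal order or any
  parallel partitioning — the "multiple small regions updated
  simultaneously" speed-up is a parallelizable contract, not an
  asynchronous race.

**Similarity function.** The classical GrowCut form
g(x) = 1 − x / max_diff is used, with `max_diff` defaulting to the maximum
absolute intensity difference over neighbor pairs inside the computation
domain (the ROI for the optimized engine, the full grid for the
reference). A constant image (max_diff = 0) degenerates to g ≡ 1. The
normalizer can be fixed explicitly via `GrowCutParams.max_diff`.

**Neighborhood.** 26-connectivity (3D Moore) by default — the classical
automaton neighborhood — with 6-connectivity available per parameter.

**Tie-breaking.** Among equally strong attackers the first offset in a
fixed lexicographic order wins. This removes the platform-dependent
nondeterminism an unordered implementation would have; any fixed order
would do, lexicographic is merely canonical.

**Speed-ups** (all result-preserving, verified against the naive
reference):

* *ROI*: computation is restricted to the axis-aligned bounding box of all
  scribbled voxels plus a margin (default 5 voxels). The box is a superset
  of the convex hull of the scribbles, so no labeled voxel can be
  excluded; rasterizing an actual 3D hull would buy nothing for
  correctness. Voxels outside the ROI keep label 0.
* *Precomputed weights*: g is evaluated once per neighbor offset over the
  ROI and reused every iteration; since it is the same float64 expression,
  results are bit-identical to on-the-fly evaluation.
* *Saturation/activity tracking*: voxels at θ = 1 are saturated (they can
  never be conquered); a voxel is active next iteration only if a neighbor
  changed this iteration (an attack on p depends only on N(p), so nothing
  else can newly change). Termination is detected when no voxel changes.

`max_iterations` defaults to 500 as a safety cap — normal exit is
convergence; a hit cap logs a warning and flags the partial result.

## Post-editing

Edits are an ordered sequence of {dilate, erode, remove_islands} steps.
Structuring elements follow the step's connectivity (6 → cross, 26 → full
cube), radius by iteration. Island removal deletes connected components
below `min_size`, or keeps only the largest (`keep_largest`, ties broken
by first component in scan order — scipy's component labeling order, hence
deterministic). The default pipeline applies only `keep_largest`: which
dilations/erosions a case needs is inherently operator- and
case-dependent, so they are opt-in.

## Volumetry and agreement

Physical volume = voxel count × voxel volume (product of spacings, mm³);
study summaries convert to cm³. DSC = 2|A∩B|/(|A|+|B|) on the foreground
masks (`labels == 1`), reported in percent to two decimals and stored
unrounded; two empty masks are defined to agree (DSC 1) — the degenerate
case is otherwise undefined and identity semantics is the least surprising
choice. The **sample** standard deviation (n − 1) is used everywhere.
Voxel-count columns summarize as min/max/mean without a spread: raw counts
mix acquisitions with different spacings, and a standard deviation over
them is not physically meaningful.

Geometric models (for comparison with diameter-based clinical practice):
spherical π d³/6; ellipsoid π a b c/6; mean-radius sphere 4/3 π r̄³ with
r̄ the mean of the three plane radii; caliper a·b²/2 (the transplant-
caliper convention: a the largest diameter, b the perpendicular one). The
Macdonald bidimensional measure is computed on a caller-chosen slice
(clinical convention is in-plane): largest diameter = maximal pairwise
distance between foreground voxel centers (brute force), perpendicular
diameter = extent of the projections onto the orthogonal direction, and
response = follow-up area ≤ 50 % of baseline (boundary inclusive). A
single-voxel mask, or collinear centers, would give a zero diameter;
the convention adopted is one in-plane voxel extent, so an isolated voxel
at 1 mm spacing scores 1 mm².

## Synthetic phantoms

A phantom is an ellipsoidal, homogeneously "contrast-enhancing" lesion
(default intensity 100) in a darker background (0), with optional additive
iid Gaussian noise from a seeded generator — identical parameters give
bit-identical volumes. Ground truth is the set of voxels whose **centers**
lie strictly inside the ellipsoid; center-testing (no partial-volume
weighting) keeps lattice-count oracles exact. Scribbles are auto-generated
the way a user would paint them: the foreground stroke is the ground truth
eroded (default 2 voxels, an "area inside" the tumor), the background
stroke a shell outside it (dilation by 4 minus dilation by 2). Radius
presets small/medium/large (~0.76 / 6.4 / 15.3 cm³) span the lesion-volume
range of clinical pituitary adenoma series.

What the phantoms do **not** emulate: anatomical surroundings (sella,
carotids, optic chiasm), bias fields, Rician noise statistics, partial
volume, or heterogeneous enhancement. Gaussian noise was chosen for
simplicity; the recovery checks are threshold-based and tolerant of the
noise model. Passing the phantom tests therefore shows the machinery is
correct and robust to moderate noise — not that clinical accuracy on
patient MRI equals phantom accuracy.

## Problem sizes and fixed choices

Validation uses 40³ phantom grids with ~8 mm semi-axes (small-preset
scale), noise at 10 % of the tumor-background intensity gap for the noisy
recovery checks (10 fixed seeds), and 50 random 12³ instances with random
two-class scribbles for the optimized-vs-naive equivalence check with the
ROI margin chosen to cover the grid. These sizes exercise every code path
(ROI clipping, saturation, tie-breaks, island removal) while keeping the
suite quick to run.

## Bundled study records

`datasets.pituitary_adenoma_cases()` carries the per-case results of a
published ten-patient comparison of manual slice-by-slice versus
GrowCut-based pituitary adenoma segmentation. The rows are printed values:
the patient images were never deposited and per-case voxel spacings were
not published, so the per-case volumes cannot be recomputed from the voxel
counts — only the reporting pipeline (summaries of the printed columns) is
reproducible, and that is what the tests and the acceptance script check.

## Known limitations

* Two-class workflows only are validated; the engine accepts N labels but
  makes no multi-class quality guarantees.
* No resampling/registration: inputs must share a grid (shape equal,
  spacings within 1e-4 relative).
* Orientation matrices are carried through I/O but ignored by computation;
  volumetry is correct regardless, but left/right semantics are the
  caller's responsibility.
* No DICOM series input; convert to NRRD/NIfTI first.
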