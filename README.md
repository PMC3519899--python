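# growcutvol

Semi-automatic 3D tumor volumetry from MRI label maps: scribble-seeded
**GrowCut** segmentation, morphological post-editing, and Dice/volume
evaluation with study-level reporting.

## The problem

Volumetric change in cerebral pathologies such as pituitary adenomas drives
treatment decisions, and the reference practice — an expert contouring the
tumor slice by slice — is slow and user-intensive. A practical alternative
is interactive competitive region growing: the user paints a small area
inside the tumor and a stroke outside it, and the algorithm propagates
those seeds through the volume. This package implements that workflow end
to end (segmentation → post-editing → volumetry → agreement reporting) for
anyone who needs reproducible, scriptable tumor volumetry or wants to
validate such a pipeline against reference segmentations.

## The algorithm

GrowCut treats the image as a cellular automaton. Each voxel *p* carries a
label *l_p* (0 unlabeled, 1 tumor, 2 background) and a strength
θ_p ∈ [0, 1]. Scribbled voxels start with their seed label and θ = 1. At
every synchronous iteration, each neighbor *q* of *p* attacks with

    a(q → p) = g(|c_p − c_q|) · θ_q,    g(x) = 1 − x / max_diff,

and *p* is conquered (l_p ← l_q, θ_p ← a) when the attack **strictly
exceeds** θ_p. Because g ≤ 1, strengths never decrease and seeds are never
overrun; the automaton terminates when no voxel changes. The production
engine adds the standard speed-ups — computation restricted to a region of
interest around the scribbles, neighbor similarity weights precomputed
once, and saturated/inactive voxel tracking — and is verified voxel-for-
voxel against a naive reference implementation.

Evaluation uses the Dice Similarity Coefficient between binary volumes A
and B, DSC = 2|A∩B| / (|A| + |B|), physical volumes as voxel count × voxel
volume, and optionally the classical geometric approximations (spherical
π d³/6, ellipsoid π a b c/6, mean-radius sphere, caliper a·b²/2) and the
Macdonald bidimensional criteria.

## Worked example

Generate a noisy synthetic tumor phantom with known ground truth and
auto-generated scribbles, segment it, post-edit, and evaluate:

```sh
$ growcutvol phantom --preset small --shape 40 40 40 --noise-sigma 8 --seed 42 --outdir ph
phantom written to ph (preset=small, seed=42)

$ growcutvol segment --image ph/image.nrrd --scribbles ph/scribbles.nrrd --out seg.nrrd
segmentation written to seg.nrrd (iterations=29, converged=True,
changed_trace=[2880, 3925, 5415, 7643, 10479, 12753, 14062, 14515]...)

$ growcutvol postedit --mask seg.nrrd --out edited.nrrd
post-edited mask written to edited.nrrd (1 steps)

$ growcutvol evaluate --manual ph/ground_truth.nrrd --auto edited.nrrd --case-id phantom42
{
  "case_id": "phantom42",
  "volume_manual_mm3": 720.0,
  "volume_auto_mm3": 720.0,
  "voxels_manual": 720,
  "voxels_auto": 720,
  "dsc_percent": 100.0
}
```

The phantom's 720-voxel ellipsoid (720 mm³ at 1 mm isotropic spacing) is
recovered exactly despite the added noise: the segmentation converged in 29
iterations (the `changed_trace` lists conquered-voxel counts per
iteration), and the automatic mask agrees with ground truth at DSC 100 %.

Batch studies run from a CSV manifest; `growcutvol report --manifest
cases.csv --outdir out/` writes a per-case table, a min/max/mean/std
summary (volumes in cm³, DSC in %), and a JSON run log with parameters and
convergence diagnostics. The package bundles the per-case results of a
published ten-patient pituitary adenoma study
(`growcutvol.datasets.pituitary_adenoma_cases()`); summarizing them yields
a mean DSC of 81.97 ± 3.39 % between manual and GrowCut-based
segmentations, with manual volumes of 6.37 ± 3.96 cm³.

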