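# brainshift

Physics-based non-rigid registration for intra-operative brain-shift
compensation.

A floating (pre-operative) 3D volume is aligned to a fixed (intra-operative)
volume by combining sparse block-matching displacements with a linear-elastic
tetrahedral finite-element model.  Three outlier-rejection schemes are
implemented:

* **PBNRR** — iterative point-outlier rejection: alternating
  approximation/interpolation solves of `[K + HᵀSH] U = HᵀS D + F`, discarding
  the matches with the highest interpolation error at each step.
* **NEMNRR** — nested expectation-maximization: fuzzy point correspondence
  (inner EM over displacements and a soft assignment matrix) plus iterative
  growth of a face-connected resection submesh `M_Rem` from mesh elements
  whose displaced centroids fall in the background of the fixed image.
* **ANRR** — adaptive registration: incremental warping with per-increment
  BCC remeshing of the warped segmentation, a sliver/negative-volume quality
  gate, and registration-point-aware mesh-sizing metrics (isotropic k-NN
  spacing and anisotropic metric tensors from minimum-volume enclosing
  ellipsoids of reflected neighbor points).

Also included: a synthetic phantom generator (textured brain / ventricle /
tumor ellipsoids, smooth Gaussian-bump ground-truth deformation, optional
resection cavity), Canny/Hausdorff evaluation, and a unified CLI.

## Tests

```bash
python -m pytest -q tests/
```

`tests/test_acceptance.py` holds the acceptance criteria (rejection-schedule
arithmetic, HD-improvement ratios, FEM correctness, exact block-matching
recovery, phantom parameter recovery, resection-cavity recovery, geometry and
evaluation kernels).  The full suite takes a couple of minutes on one CPU.

## CLI

```bash
# synthetic pre/intra pair with known ground truth
brainshift phantom --out runs/ph --size 64 --amplitude 3 --seed 1

# feature selection and block matching as standalone steps
brainshift features --volume runs/ph/pre.nii.gz --out runs/pts.txt
brainshift match --floating runs/ph/pre.nii.gz --fixed runs/ph/intra.nii.gz \
    --points runs/pts.txt --out runs/matches.tsv

# registration (method: pbnrr | nemnrr | anrr)
brainshift register --method pbnrr \
    --floating runs/ph/pre.nii.gz --fixed runs/ph/intra.nii.gz \
    --labels runs/ph/labels.nii.gz --out runs/reg

# Canny/Hausdorff evaluation of the resulting field
brainshift evaluate --pre runs/ph/pre.nii.gz --intra runs/ph/intra.nii.gz \
    --field runs/reg/field.nii.gz --out runs/eval.json

# mesh-sizing metric export (MEDIT .sol dialect)
brainshift sizing --mesh runs/reg/mesh.vtk --points runs/pts.txt \
    --out runs/metric.sol --metric anisotropic --k 5 --inflation 1.2
```

Volumes and deformation fields are NIfTI with diagonal affines; meshes are
legacy ASCII VTK unstructured grids with a `tissue_label` cell array; point
sets are plain-text `x y z` lists.

## Package layout

```
src/brainshift/
  core.py            volume/mesh/field types, warping, NIfTI/VTK/point I/O
  phantom.py         synthetic pre/intra pairs with known deformation
  features.py        variance-ranked registration points, Canny edge points
  block_matching.py  exhaustive NCC search -> sparse displacements + weights
  fem.py             BCC image-to-mesh, P1 elasticity, barycentric H
  pbnrr.py           hybrid solver with iterative point-outlier rejection
  nemnrr.py          nested EM with resection-submesh growth
  anrr.py            incremental warp/remesh + sizing metrics (MVEE)
  evaluation.py      Hausdorff metrics and registration evaluation
  cli.py             click-based command-line interface
```
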