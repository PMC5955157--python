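# Methods

`petsubvol` implements a longitudinal FDG-PET analysis for head-and-neck
cancer treated by radio-chemotherapy: where, relative to the baseline
intra-tumor uptake distribution, does metabolically active disease reappear
after treatment?  The question matters for dose painting — escalating
radiotherapy dose to image-defined sub-volumes is only sensible if relapse
actually arises inside them.

## Analysis model

For each patient with a baseline and a follow-up PET/CT pair:

1. **Rigid registration.**  The follow-up pair is aligned to the baseline
   pair (the baseline is always the reference).  A region of interest is
   first derived from the baseline PET — the bounding box of voxels above
   30% of SUVmax, dilated by 40 mm — and the two anatomical (CT-like)
   volumes are registered inside that region by maximizing mutual
   information over 6 rigid degrees of freedom.  The resulting transform is
   applied to the follow-up PET (trilinear interpolation; masks would use
   nearest-neighbor).  Deformable registration is deliberately excluded:
   warping the tumor would invalidate intra-tumor volume comparisons.

2. **Sub-volume delineation.**  On the baseline PET, seven metabolic tumor
   sub-volumes I30 … I90 are segmented at fixed thresholds x% of SUVmax
   (x = 30 … 90, step 10); on the aligned follow-up PET, R40 and R90
   characterize the whole recurrence volume and its hottest part.  A
   sub-volume is the 26-connected component, seeded at the SUVmax voxel, of
   all voxels ≥ fraction × SUVmax inside an explicit operator VOI; ties at
   the threshold are included (≥).  Seeding at SUVmax makes the series
   exactly nested and excludes remote physiologic uptake.  Derived scalars:
   MTV (cm³, voxel count × voxel volume, no partial-volume surface
   correction), SUVmean, and TLG = MTV(40%) × SUVmean(40%).

3. **Overlap quantification.**  Five indices per (Ix, R) pair on the common
   grid: Dice, Jaccard, overlap fraction (OF = |∩| / min volume), VcI
   (|∩| / |Ix|) and VcR (|∩| / |R|).  Concordance is graded on a
   Cohen-kappa-style scale in 0.2 steps; the printed bins leave (0.2, 0.21)
   undefined, so the implementation uses half-open bins with the upper edge
   in the lower category.  Patients with zero overlap contribute zeros to
   cohort index means (recorded in table metadata); "overlap present"
   means ≥ 1 shared voxel (configurable).

4. **Group statistics.**  MTV(40%), TLG and SUVmax are compared between
   complete responders (CR) and patients with local recurrence/residual
   disease (LRRD) by two-sided Mann-Whitney U at α = 0.05, unadjusted.
   Summaries are mean ± SD, plus median and range when a D'Agostino-Pearson
   test (n ≥ 8) rejects normality or cannot be run.  The exact Mann-Whitney
   null distribution is enumerated when n₁·n₂ ≤ 400 and the pooled sample
   is tie-free; otherwise the normal approximation with tie and continuity
   corrections is used, and zero-variance pooled data returns p = 1 by
   contract.

## Conventions that everything else depends on

* Arrays are indexed `[i, j, k]` = (x, y, z); indices are 0-based; world
  coordinates (mm) refer to voxel centers, `world = origin + index *
  spacing`; grids are axis-aligned with positive spacing (diagonal NIfTI
  affine — oblique affines are rejected rather than reinterpreted).
* `RigidTransform` maps baseline (reference) world points into follow-up
  world coordinates (the resampling convention; its inverse is the physical
  repositioning map).  Euler order Z–Y–X (`R = Rz·Ry·Rx`), degrees, about
  the fixed-image center.  Composing a transform with its inverse is the
  identity to < 1e-9.
* SUVmax ties are broken by the smallest C-order linear index.

## Registration numerics

The optimizer is two-level derivative-free Powell over
(tx, ty, tz, rx, ry, rz): a smoothed, 2× downsampled level followed by full
resolution with mild (0.7 voxel) smoothing.  Translation is initialized
from intensity centers of mass.  The metric is a 32 × 32 joint-histogram
MI with each image's range clipped to its 1st–99th percentile; inside the
optimizer the moving intensities are binned with linear partial-volume
weights, which removes histogram-quantization jitter (without it the
optimum is visibly displaced by the interpolation-induced bias toward
fractional-voxel offsets on noisy images).  Everything is deterministic
given inputs and options; non-convergence is flagged on the result, never
raised.  On phantoms with true transforms up to 10 mm / 5° and noise SD
0.05 the recovered parameters are accurate to ~0.5 mm / 0.5°
(self-registration: ~0.01 mm).

## The synthetic phantom cohort

Retrospective clinical PET/CT archives of this kind are not publicly
deposited, so the package ships a ground-truthed generator whose defaults
emulate such a cohort:

* **Grid:** 64³ voxels at 4 × 4 × 4 mm (voxel volume 64 mm³ = 0.064 cc).
* **Scene:** defined continuously in baseline world coordinates — a body
  ellipsoid (background SUV 1.5, outside 0.1), broad Gaussian soft-tissue
  density texture plus four high-intensity landmark spheres on the
  anatomical volume (without texture a uniform body leaves the MI surface
  nearly flat and registration unidentifiable), and a tumor: a sum of
  generalized-Gaussian uptake kernels `amp·exp(-r^p)` confined to a tumor
  ellipsoid and rescaled so the noise-free grid maximum equals the target
  SUVmax.  Three kernels with one dominant eccentric focus make I90 a
  small off-center blob and the threshold series spatially structured.
* **Kernel sharpness:** p = 1.8 (baseline) and p = 1.4 (recurrence), chosen
  analytically so the single-kernel model reproduces the clinical volume
  ratios I90/I40 ≈ 0.025 and R90/R40 ≈ 0.008; the satellite kernels enlarge
  the realized 40% region by a measured, near-constant factor 1.26 that the
  sizing divides out.
* **Follow-up:** the same scene observed through the inverse of a known
  rigid repositioning transform, evaluated analytically (no interpolation
  error), with the tumor replaced by a recurrence lesion (LRRD) or plain
  background (CR).  i.i.d. Gaussian noise (default SD 0.1 SUV) is added
  last; PET is clipped at 0.  Identical seeds give bit-identical volumes.
* **Cohort distributions:** MTV(40%) targets are lognormal, median 8.9 cc
  (CR) and 23.5 cc (LRRD; ratio 2.64), log-SD 0.45 (read off the reported
  ranges 3.1–26.1 and 8.3–65.3); SUVmax ~ N(13.2, 3.1²) (CR) and
  N(16.1, 5.2²) (LRRD), truncated above 7 — at SUVmax ≤ 5 the 30%
  threshold reaches the background level and fixed-percentage delineation
  degenerates (the component floods the body), a known failure mode of the
  method that the uniformly high-uptake emulated cohort does not probe.
  Repositioning transforms are uniform within ±8 mm / ±4°.
* **Recurrence placement is edge-weighted:** the lesion centroid sits at a
  uniform 0.55–0.95 fraction of the centroid-to-boundary distance along a
  random direction restricted to the hemisphere away from the dominant
  baseline focus, with a 10 mm keep-out between the recurrence
  40%-isocontour and that focus.  This reproduces the observed clinical
  pattern — relapse at the rim of the baseline uptake distribution, mean
  overlap fraction decreasing with threshold, and essentially no overlap
  between any Ix and the recurrence hot spot R90 at high thresholds.  All
  placement parameters are configurable.

What the generator does **not** emulate: projection-space PET physics
(noise is additive Gaussian, not reconstructed Poisson), scatter and
attenuation, anatomical realism beyond registration anchors, organ motion
or deformation, physiologic uptake that could confound delineation.
Passing tests therefore demonstrate correctness of the analysis chain
and its behavior under the stated geometry and noise — not clinical
performance on real scans.  Absolute overlap levels depend strongly on the
placement geometry: the defaults give mean OF(R40, I30) ≈ 0.15–0.25,
below typical clinical reports (~0.5), while reproducing the qualitative
decreasing-overlap shape; convex single-lesion geometry cannot raise one
without flattening the other.

## Problem sizes

Defaults were chosen for a desk-scale run: full pipeline on 73 phantom
patients (registration included) completes in a few minutes on one CPU;
the test suite's largest fixtures are 100-phantom nesting checks, a
20-phantom registration-recovery sweep and a 38-patient cohort run.

## Known limitations

* Fixed-percentage thresholding overestimates lesion size at low SUVmax
  and is sensitive to the background; adaptive/gradient segmentation is
  out of scope.
* Only NIfTI-1 with diagonal affines is supported; DICOM ingestion and SUV
  computation from injected dose are out of scope (inputs are SUV-valued).
* Overlap indices are voxel-count ratios; no sub-voxel surface estimation,
  no surface-distance metrics (Hausdorff etc.).
* The Mann-Whitney exact/asymptotic switch point (n₁·n₂ ≤ 400) is a
  package choice; results near the switch differ negligibly.
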