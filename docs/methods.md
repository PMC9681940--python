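# Methods

`slnfusion` models, end to end, the image-guidance chain used to bring
preoperative SPECT/CT sentinel-lymph-node (SLN) findings into an
intraoperative setting: a pelvic phantom is imaged twice (a preoperative
SPECT/CT session and an intraoperative CT session, with an unknown rigid
repositioning between them), the two sessions are fused by rigid
registration, and the fused SLN segments are projected into an
endoscope-like camera so that the augmented-reality (AR) overlay error
can be quantified in the image plane.

## The digital phantom

The phantom (`slnfusion.phantom.PhantomSpec`) lives in a right-handed
board-aligned world frame, units mm, origin at the corner of the imaged
field of view (default 200 x 160 x 140 mm). Zero-based voxel indices
address voxel centers. It contains:

* two fillable spheres standing in for SLNs — 8 mm diameter on the left,
  15 mm on the right (the left sphere has the strictly smaller x
  coordinate), mounted at the ends of a tube "vessel tree"
  (4 mm radius polylines) that mimics the iliac vessels;
* a radiopaque bone arch: a posterior half-annulus (inner/outer radius
  54/62 mm) standing in for the pelvic ring;
* a calibration board of six 10 mm diameter spherical fiducials in a
  non-coplanar arrangement, used to compute cross-session transforms.
  Ten-millimetre spheres are typical of commercial multimodality
  markers; six non-coplanar markers make the point-based registration
  well conditioned in all six degrees of freedom.

Voxelization labels a voxel by the structure containing its center, with
precedence fiducial > SLN > vessel > bone > background. The default
simulation grid is finer than either scanner grid (0.35 mm; see
"Numerical choices") so that scanner renders sample a quasi-continuous
object rather than replaying their own voxelization.

## Modality simulation

Both virtual scanners resample the posed phantom onto their own grid by
nearest-neighbor lookup (the phantom is rigid; a structure at board
point p images at scanner point pose(p)), then replace each label with
its mean tissue intensity.

* **CT** (1 mm voxels): HU-like intensities, background 0, vessel 300
  (contrast), SLN 600 (iodinated contrast filling), bone 1200, fiducial
  2500, plus i.i.d. Gaussian noise (sigma 15). The values are plausible
  contrast-enhanced CT magnitudes; only their ordering and separation
  relative to noise matter downstream.
* **SPECT** (4.4 mm voxels): an activity map that is zero everywhere
  except the two spheres (12, the paper's 12 MBq/mL fill, in
  activity-like units), convolved with an isotropic Gaussian PSF of
  10 mm FWHM, then Poisson counting noise (default 25 expected counts
  per activity unit, i.e. a peak of a few hundred counts). Tomographic
  acquisition and OSEM reconstruction are *not* modeled; the emulated
  protocol (60 projections, 128 matrix, OSEM 8x8, energy windows) is
  carried as provenance metadata only. The blur+Poisson model reproduces
  the two properties that matter to the pipeline contracts: partial
  volume (the 8 mm node's peak is only ~0.2 of the 15 mm node's) and
  counting noise.

The unknown repositioning between sessions is drawn uniformly: rotation
axis uniform on the sphere, angle uniform in [0, 10] degrees about the
field-of-view center, translation uniform in the 20 mm ball. These
bounds are deliberately larger than careful phantom handling would
produce, to stress the registration.

## Segmentation

CT structures are recovered by intensity windowing (non-overlapping
intervals per structure) followed by 26-connected component analysis,
discarding components below a minimum size; the two largest components
in the SLN window become the SLN candidates, named left/right by their
first world coordinate (ties break to the larger volume, logged). CT
centroids are geometric. SPECT hotspots are the connected components of
the isocontour at a fraction of the global maximum, with
intensity-weighted centroids (under a 10 mm PSF the intensity-weighted
centroid is the better estimator of the sphere center). The default
fraction is **0.10**: a 0.4 isocontour of the global maximum can never
segment the 8 mm node, whose blurred peak sits at ~0.2 of the 15 mm
node's (a partial-volume fact of the sphere sizes and PSF), and Poisson
noise pushes that peak below 0.15 in some realizations; 0.10 clears the
noisy peak from below while staying far above any disconnected noise.

Fiducials are detected in each CT by windowing + components, and matched
to the board layout by exhaustive assignment on inter-point distance
matrices — a rigid-invariant criterion, so the correspondence is found
without any initial alignment (at most 9 markers; 6 by default).

## Registration

Transforms are 6-DOF rigid maps stored as 4x4 homogeneous matrices
acting on world mm coordinates, direction **moving (preoperative
session) world -> fixed (intraoperative session) world**. Resampling is
trilinear (nearest-neighbor for labelmaps), with a declared fill value
outside the moving field of view.

1. **Fiducial initialization**: closed-form least-squares rigid fit
   (centroid alignment + orthogonal Procrustes with det +1 enforcement)
   of the matched fiducial centroids; the fiducial registration error
   (FRE) is the RMS residual. On the default phantom the FRE is
   ~0.1 mm and the target error at the SLNs ~0.1 mm, limited by the
   differential voxelization of the two renders, not by the fit.
2. **Mutual-information refinement**: MI is estimated from the dense
   32x32 joint histogram after per-image min-max normalization, in bits.
   The optimizer is a coarse-to-fine (4x, 2x, 1x) derivative-free Powell
   search over (rotation vector in degrees about the fixed-image
   foreground center, translation in mm). In the default pipeline the
   refinement runs at full resolution only, inside a trust region of
   1 degree / 3 mm around the fiducial initializer, and the best
   transform over all evaluated candidates — including the initializer
   itself — is returned, so the refinement can never end with a lower
   MI than its starting point.

   Which preoperative image drives MI is configurable. The default is
   the CT arm of the SPECT/CT (`mi_channel="ct"`): a SPECT/CT study is
   internally co-registered, so aligning its CT aligns the SPECT, and
   the bone-rich CT-CT problem has a far sharper MI optimum than the
   10 mm-blurred activity map; aligning on bone also mirrors how such
   fusions are visually validated. `mi_channel="spect"` registers the
   activity map directly.
3. **Evaluation**: target registration error (TRE) is measured at the
   true SLN centers against the known simulated repositioning, a
   quantitative stand-in for visual validation.

## AR projection and overlay metrics

An ideal pinhole camera (f = 1000 px, 1280x720, no distortion) views the
intraoperative scene from 450 mm, standing in for a calibrated
laparoscope. A 3D segment is rendered to 2D by mapping every voxel
center through a rigid transform, projecting, rasterizing, and
solidifying the footprint: morphological closing whose element scales
with the projected voxel pitch f*h/z (a fixed 3x3 element leaves the
footprint porous whenever the pitch exceeds ~2 px), then a dilation by
the projected half-voxel extent (voxels are boxes, not points; without
it the silhouette is systematically half a voxel small), then hole
filling. Occlusion is deliberately ignored — the overlay metrics are
defined on plain 2D surfaces.

For each SLN the AR mask s1 (segment through the *estimated* transform)
and the ground-truth mask s2 (same segment through the *true*
transform) are compared by:

* **normalized barycenter distance** d(b1, b2) / r with
  r = sqrt(area(s1)/pi) the pseudo-radius of the AR surface. The
  normalization by s1's radius follows the definition's accompanying
  figure; since the prose could also be read as normalizing by each
  surface's own radius, the s2-normalized variant is computed and
  reported alongside (`ratio_r_from_s2`), and the two are equal up to
  rasterization here because s1 and s2 are projections of the same
  segment.
* **coverage rate** |s1 n s2| / |s2|, the fraction of the visible
  surface covered by the AR surface.

Masks must share one pixel grid; mismatched sizes are an error, never a
silent resize. Because s1 and s2 come from the same segment, both
statistics measure pure registration error: segmentation bias cancels,
and with the true transform injected (oracle mode) the ratio is exactly
0 and coverage exactly 1.

## The pipeline

Per seed: voxelize the phantom (once), draw the misalignment, render the
intraoperative CT (board frame) and the preoperative CT + SPECT
(misaligned frame), segment, detect fiducials in both CTs, register
(fiducial then MI), project each preoperative SLN segment through the
estimated and true transforms, and score. Stage failures are recorded
per seed and the run continues; aggregates are medians and IQRs over the
surviving seeds. Every random stage derives its own stream from the seed
via `SeedSequence`, so runs are bit-reproducible per seed and removing a
seed never changes another seed's record.

## Numerical choices

* **Simulation grid 0.35 mm**, incommensurate with both scanner grids
  (1/0.35 and 4.4/0.35 are far from integers). Two artifacts shrink as
  this grid refines, both irrelevant to the physics being emulated:
  double-quantization noise in fiducial centroids, and staircase bias in
  the MI optimum. 0.35 mm keeps the labelmap ~100 M voxels (int16),
  built once per experiment in a few seconds.
* **MI refinement smoothing, sigma 3 voxels at the finest level**: the
  MI optimum computed on raw nearest-neighbor renders is biased away
  from the true alignment by ~0.2 mm (a fifth of a CT voxel) by the
  voxelization staircase; pre-smoothing both images roughly halves the
  residual bias. Coarser pyramid levels are smoothed with sigma 0.5 x
  shrink factor as usual.
* **Histogram binning**: 32 bins per axis, min-max normalization; the
  CT noise (sigma 15) is below the ~80 HU bin width, so bin assignment
  is noise-stable for all tissues.
* **Exact-lattice snapping**: resampling coordinates within 1e-9 voxel
  of an integer are snapped, so identity and whole-voxel translations
  reproduce inputs bit-for-bit instead of mixing in 1e-10 interpolation
  residue.
* **Tie-breaks**: connected components sort by (size, first voxel
  index); equal-x SLN candidates resolve by volume, logged.
* **Degenerate inputs**: constant images give MI = 0 with a warning and
  are rejected as registration inputs; collinear fiducials are rejected;
  empty masks/segments raise.

## What the synthetic study does and does not show

The generator reproduces the geometry, contrasts, resolutions and noise
characters that drive the fusion chain, so passing tests demonstrate the
*pipeline* — segmentation, initialization, MI refinement, projection and
metrics — is correct and accurate under the stated conditions. It does
not model tomographic SPECT reconstruction artifacts, attenuation or
scatter, CT beam hardening, gelatin deformation, lens distortion, or
occlusion in the endoscopic view; absolute accuracy numbers on real
acquisitions will be worse than the digital twin's, and the overlay
ground truth s2 here is the projection of the same segment rather than
an independently annotated endoscopic image.

## Problem sizes

The default experiment (20 seeds, full field of view, CT at 1 mm) runs
in a few minutes on one CPU; unit tests use a compact phantom
(110 x 90 x 80 mm) with the same structure inventory so the whole suite
stays fast. Parameter-recovery checks for the full MI search use the
compact phantom with noiseless CT pairs.
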