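# Methods

`pedplan` automates preoperative pedicle-screw planning for posterior lumbar
interbody fusion from CT: segment the lumbosacral vertebrae, localize each
pedicle's screw entry and exit point, convert the bone-screw channel into a
cylindrical screw plan, and grade the plan against clinical criteria.  All
components are developed and validated on procedurally generated vertebra
phantoms with analytic ground truth.

## Imaging model

Volumes are axis-aligned RAS+ grids (`data[i, j, k]`, i→right, j→anterior,
k→superior), 0-based indices, voxel-center convention
(`point = origin + index * spacing`, in mm).  NIfTI input of any orientation
is reoriented to RAS+ on read; axial DICOM series are read slice-wise with a
1e-3 mm tolerance on slice-spacing uniformity (a missing slice is an error,
not a silent gap).  CT intensities are Hounsfield units; before any network
sees them they are windowed to [0, 1] by the standard linear clamp with
window center 150 HU and width 1500 HU (span −600…900 HU), which puts soft
tissue low in the range and bone high.  When grids must be aligned,
intensities are resampled trilinearly and label maps nearest-neighbor so
label identities survive.

## Phantoms

Each phantom is constructive solid geometry: the vertebral body is an
elliptic cylinder (defaults: lateral semi-axis 16 mm, anteroposterior
12 mm, height 26 mm), the posterior elements a 36×10×22 mm slab, and each
pedicle an oblique circular cylinder (default isthmus radius 4 mm) whose
axis is the bone-screw channel, tilted medially by the pedicle transverse
angle (default 10°) and cranially by the sagittal angle (default 5°).
Entry point = intersection of the axis with the posterior slab face; exit
point = anterior intersection with the body ellipse; both are exact.  A
small slab labeled as the superior facet region rides above each channel
mouth with a configurable clearance (default 2 mm).  Bone voxels draw
HU ~ N(700, 30), a 5 mm soft-tissue rim draws N(40, 30), and the remaining
background is exactly −1000 HU (air), so the default CT window separates
the structures the way real bone windows do.  Randomized datasets draw
geometry uniformly from lumbar-realistic intervals (e.g. isthmus radius
3–5 mm, transverse angle 5–15°); generation is bit-reproducible per seed.

Each phantom carries a reference screw plan per pedicle: the channel axis,
80 % of the channel length, and a diameter 0.5 mm short of the isthmus
radius, which by construction stays clear of cortex and facets (the
all-grade-A reference cohort automatic plans are compared against).

What the phantoms do *not* model: cortical/trabecular texture, endplate
curvature, osteophytes, scoliosis or fractures, inter-scanner contrast
drift.  Passing tests therefore demonstrate the correctness of the
geometric rules and the learnability of the synthetic distribution, not
clinical segmentation accuracy.

## Networks

Both networks run on a small in-repo reverse-mode autodiff engine
(`pedplan.nn`) over numpy float32 arrays: 3D convolution (im2col + BLAS),
kernel-2 stride-2 transposed convolution, 2× max pooling, batch
normalization, ReLU, residual/concat/gating ops, fused losses, Adam.
Everything is deterministic per seed on a fixed BLAS.

**Segmenter.**  A 4-stage 3D-UNet: encoder stages of
[conv 3³→ReLU→conv 3³→ReLU→maxpool] with channel widths doubling from
`base_channels` (default 16); decoder stages of [deconv 2×→conv→ReLU→conv→
ReLU]; a 1³ head emits per-voxel class scores softmax-normalized over
classes.  Each skip connection passes through an edge-attention module: the
stage's input features (channel mean, unit-normalized) are run through a
slice-wise 2D Canny detector (σ = 1, hysteresis thresholds 0.1/0.2 — Canny
is inherently 2D and CT is acquired axially), and the binary edge map gates
the skip features multiplicatively with 1 + edge.  An empty edge map makes
the module an identity, so disabling edge attention recovers a plain UNet.
Inputs are zero-padded to multiples of 16 and cropped back.  Loss is
0.5·soft-Dice + 0.5·cross-entropy, the standard composite for
class-imbalanced 3D segmentation, optimizing the Dice metric that is also
reported.

**Keypoint detector.**  A stacked-hourglass network (2 stacks) over a
convolutional stem that pools once, so heatmaps live on a grid downsampled
2× from the input.  Each hourglass has four down- and four upsampling
modules; every module is three groups of [conv 3³→batch-norm→ReLU] with a
residual connection added to the third group; scales are bridged by
skip additions and kernel-2 deconvolutions.  Each stack emits one heatmap
per keypoint (4 per instrumented level: left/right × entry/exit) and is
supervised (intermediate supervision); the last stack is the prediction.
Targets are isotropic Gaussians in physical coordinates (peak 1, default
σ 3 mm; training on 2 mm grids uses 5 mm so the kernel spans the
half-resolution heatmap voxels).  Peaks are read out as per-channel
argmaxes (ties broken toward the lowest (z, y, x) index) with an optional
3³ center-of-mass refinement; all-zero channels are flagged as missing
keypoints rather than raising.

Three design choices differ from the obvious defaults, each adopted after
the default demonstrably failed at this data scale:

* *Per-sample normalization at inference.*  Training batches are single
  volumes, so batch statistics equal the sample's spatial moments; with
  ~20 stacked normalization layers the running averages drift and eval-mode
  activations diverge by orders of magnitude.  Inference therefore
  normalizes by the same per-sample moments (the running buffers are kept
  for introspection only) — the convention instance-norm-based 3D medical
  networks use for exactly this reason.
* *Coordinate channels.*  Three normalized coordinate grids are appended to
  the detector input.  Pure convolutions are translation-equivariant and
  cannot break the left/right mirror symmetry of a vertebra from a handful
  of training volumes; without the coordinates the mirrored exit channels
  collapse onto each other.
* *Spatial-softmax cross-entropy loss* (default; weighted MSE available).
  Each keypoint channel is softmax-normalized over voxels and trained
  against the mass-normalized Gaussian target.  Under MSE a spurious peak
  far from the target costs almost nothing (background weight), which
  corrupts the argmax; under the normalized loss every spurious peak
  competes directly with the true one.  On 8 training phantoms this moved
  held-out exit-point error from ~30 mm to ~3 mm.

## Screw planning

The screw is a capped cylinder along the straight entry→exit segment.
`trace_channel` samples the ray at quarter-voxel steps, takes the longest
contiguous in-bone run as the channel (so endpoints slightly off bone are
tolerated), and reports the isthmus clearance: the largest radius r such
that the Euclidean distance transform of the bone mask, sampled along the
axis but excluding end caps of depth r (at the mouth and tip the nearest
background is the cortex surface the channel legitimately crosses, not the
pedicle wall), stays ≥ r.

Insertion depth is 80 % of the channel length (configurable fraction;
optional snap-down to a hardware catalog step, off by default because
continuous sizes are reported).  The diameter is maximized subject to not
penetrating the cortex: a warm start from the distance transform, then
refinement in 0.1 mm steps against the defining voxelized-containment test
(the screw plus its radial safety shell, diameter + 2·margin, must lie
inside the bone mask).  The warm start alone under-reads by up to half a
voxel because trilinear interpolation of a 1-Lipschitz distance field at
on-axis points averages in off-axis voxels; the containment refinement
removes that bias.  Default margin 0 mm (maximize the inner diameter);
default minimum diameter 4 mm, below which the pedicle is reported too
narrow as a structured planning failure.

Angles: the pedicle transverse angle is the unsigned angle between the
axial-plane projection of the axis and the anteroposterior direction; the
sagittal angle is the signed elevation out of the axial plane (positive
cranial).  An axis perpendicular to the axial plane has no transverse
angle; it is returned as NaN, not an error.  These reference axes are
isolated in one function so another convention can be swapped in.

## Grading

Screws are voxelized by the voxel-center-in-cylinder rule (degenerate
sub-voxel diameters keep a 1-voxel axis chain so the screw never vanishes).
Deviation reports give unsigned angle differences, signed length/diameter
differences (automatic − reference), and the Dice overlap of the two
voxelized screws on the case grid.

Gertzbein-Robbins: breach depth is the largest distance from a screw voxel
outside the vertebra's bone mask to the nearest bone voxel (distance
transform of the complement, center-to-center, so depths are exact on
voxel-aligned constructions and otherwise accurate to about half a voxel).
Classes follow the printed inequalities as half-open intervals: breach 0 →
A, (0, 2) → B, [2, 4) → C, [4, 6) → D, ≥ 6 → E; a 2.0 mm breach grades C.
The perforation direction of every non-A screw is the dominant transverse
component of the offset from the screw axis to the breach centroid —
medial/lateral along x (resolved by the screw's side) or superior/inferior
along z.

Badu (superior-facet violation): 0 if the screw is clear of the facet
region; 1 if it abuts the joint surface without entering (surface gap ≤
0.5 mm by default, approximated as center-to-center distance minus one
voxel); 2 if it invades by ≤ 1 mm (depth read from the distance transform
inside the facet label); 3 if it crosses the joint surface, detected as the
screw extending past the facet's far extent along its own axis.  An
invasion deeper than 1 mm that does not transfix has no class in the
original scale and is assigned grade 3 as the more severe neighbor.

Cohort reports aggregate per-screw rows (deviations + grades) into mean ±
SD per metric and GR/Badu class counts and percentages; unmatched screws
appear as rows, never dropped.

## Problem sizes and tolerances

The test suite and the acceptance script train on 12 phantoms (8 train / 4
held out) of 32³ voxels at 2 mm spacing — a field of view that holds one
L4 vertebra — with `base_channels` 8 for the segmenter (20 epochs) and 8
hourglass channels (60 epochs); geometric and grading checks use 1 mm
phantoms (48×60×36).  These sizes are chosen so the whole study runs on a
single CPU core in minutes while leaving clear headroom against the
documented thresholds (held-out foreground Dice ≈ 0.99 vs the 0.90 bound;
entry-point error ≈ 1.2 voxels vs the 2-voxel bound).  Geometric
quantities are asserted to within one voxel of their analytic or
brute-force values; the coaxial screw-overlap Dice is within 3 % of closed
form at 1 mm spacing.

## Known limitations

Screw selection ignores bone density and biomechanics; trajectories are
straight; thoracic/cervical levels and deformed anatomy are out of scope;
the networks trained here demonstrate learning capacity on phantoms and
are not clinical models.  DICOM support covers single axial series with
identity orientation; oblique acquisitions must be resampled upstream.
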