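# Methods

This note documents the models and procedures implemented in `disguisor`,
the parameters that matter, what the synthetic scenes do and do not emulate,
and the numerical choices behind the defaults.

## Conventions

Pixels are 0-based `(u, v) = (column, row)` with pixel centers at integer
coordinates. Depth is the z-distance along the optical axis in meters (not
ray length). Extrinsics are stored world → camera; calibration is consumed
from JSON, never estimated. Depth maps are 16-bit integers with
`depth_scale` meters per unit (default 1 mm); a stored value of 0 marks an
invalid pixel.

## Multi-view pose fusion

A learned volumetric multi-view pose fuser would need training data that
does not exist at this scale, so the 2D→3D stage is a deterministic
geometric equivalent that is exact on clean input:

* **Association.** All cross-view detection pairs with mean symmetric
  epipolar distance ≤ `tau_epi` (15 px) over joints with confidence ≥
  `c_min` (0.3) are merged greedily in order of increasing cost, under the
  constraint of at most one detection per camera per group; groups spanning
  fewer than two views are dropped. Caveat: for configurations that are
  *exactly* mirror-symmetric (mirror-image people seen by mirror-placed
  cameras) the wrong pairing is also epipolar-consistent and the cost tie is
  broken arbitrarily. Generic (asymmetric) scenes do not hit this; the
  synthetic presets break the symmetry through differing body heights.
* **Triangulation.** Per joint, linear least squares (DLT) over confident
  views. If the mean reprojection error exceeds `r_max` (10 px) the joint is
  re-solved once after dropping the single worst view, otherwise marked
  invalid. Joints seen in fewer than two views are invalid.
* **Tracking.** Greedy frame-to-frame matching of pelvis midpoints gated at
  `d_track` (0.5 m); unmatched skeletons open new tracks.
* **Smoothing.** Gaps of at most `gap_max` (10) frames are filled by linear
  interpolation; each joint then receives a centered moving average of width
  `window` (5, odd) over valid samples. Near track ends the window shrinks
  *symmetrically*, so the filter is unbiased for constant-velocity motion —
  the asymmetric variant biases endpoints by roughly one frame of motion,
  which is visible as a localization error at the sequence boundaries.

External 3D pose estimates can be imported from JSON, bypassing this stage.

## Body template and fitting

The template is a procedural rigid-segment humanoid: one ellipsoidal segment
per bone of a 10-bone tree over the COCO-17 joints (torso, head, upper/lower
arms and legs), every vertex bound to exactly one bone, all dimensions
proportional to body height. The head is a three-axis ellipsoid; its frontal
patch (outward normals within ~75° of the facing direction) is labeled as
the face and carries a planar UV parameterization. A statistical body mesh
can be substituted through the OBJ/PLY + JSON-label loader; the fitting code
only requires labeled head/face vertex sets and one-bone-per-vertex
skinning.

Fitting to a skeleton requires ≥ 8 valid joints including both shoulders and
hips. It estimates one global scale (median ratio of valid bone lengths,
clamped to [0.5, 2]), aligns the root by Kabsch over the torso joints, then
rotates each bone by the minimal rotation taking its (parent-rotated)
canonical direction onto the detected direction, propagating down the tree;
bones with unobserved distal joints inherit the parent rotation. The fit is
equivariant under rigid motions of the input skeleton and exact for
skeletons generated by rigidly posing the same template. Rigid skinning is
adequate here because only the head placement matters downstream and the
registration stage does the precise alignment; pose-dependent deformation is
a documented non-goal.

The skeleton has no dedicated head joint; where a "head position" is needed
the centroid of the five facial keypoints is used.

## Head registration

The fitted head is refined against the fused cloud cropped to a
`crop_radius` = 0.15 m sphere around the head center. A larger crop (0.25 m)
pulls in shoulder and chest points — on head-scale geometry those are ~40 %
of the crop and systematically drag the head downward.

* **Soft-assignment EM.** The transformed model points act as isotropic
  Gaussian mixture centroids; each cloud point is soft-assigned over
  centroids with a uniform outlier component (prior mass `outlier_frac` =
  0.1 over the target bounding volume), and the M-step is a closed-form
  weighted rigid update. σ starts at 1.5× the median cloud-to-model
  nearest-neighbor distance (so an already-aligned initialization is
  refined gently while a gross offset still sees a wide basin), is annealed
  by 0.9 per iteration, and floors at `sigma_min` = 2 mm. A fixed large σ0
  is a poor default in both regimes: it cannot reach 0.5 m offsets and it
  shrink-biases nearly aligned partial clouds by several centimeters.
* **ICP.** Point-to-point with correspondences from each *cloud* point to
  its nearest model sample, gated at `d_icp` = 3 cm; the update is accepted
  only while the gated RMS does not increase, which makes the recorded RMS
  history non-increasing on every input by construction. The moving set is
  the head vertices plus triangle centroids — denser surface sampling
  reduces the lattice-snapping bias of point-to-point correspondences.

Only the head-segment vertices receive the composed transform; the rest of
the body keeps its fitted pose. An empty crop leaves the body unchanged and
is flagged, so the face falls back to the keypoint-fitted placement.

Registering a smooth, nearly rotationally symmetric head surface against a
sparse partial view is inherently slide-ambiguous; residual tangential drift
of up to ~1 cm from an exact initialization remains and is accepted (≈ 1 px
at the synthetic resolution).

## Rendering, visibility and replacement

A software z-buffer rasterizes world-frame triangles at pixel centers with
perspective-correct (1/z-linear) depth; triangles with any vertex behind the
near plane are discarded rather than clipped, which is adequate for scenes
whose geometry stays in front of the cameras. The same rasterizer serves the
anonymizer and the scene generator, so the generator's visibility ground
truth and the anonymizer's depth-disparity check coincide on noise-free
data by construction.

A rendered face is *occluded* at a pixel when the sensor depth is more than
`delta` = 5 cm nearer than the mesh depth; the face is hidden in a view when
the occluded fraction (over mask pixels with valid sensor depth) reaches
`theta` = 0.5. Pixels without sensor depth are excluded from the
denominator, and a face with no valid depth at all defaults to visible —
anonymization errs toward privacy.

Replacement warps a texture through per-triangle barycentric UV
interpolation (bilinear sampling; flat mean-color fill if UVs are missing)
and composites it by Poisson image editing: per channel, the discrete
Poisson equation with the source's 4-neighbor Laplacian as guidance and
Dirichlet boundary values from the target, solved with a sparse direct
factorization. The blend region is the rendered mask dilated by 2 px so the
boundary band lies in target pixels; output outside the blend region is
bit-identical to the input. Conventional baselines: blacken, pixelization
with 8×8-pixel blocks, Gaussian blur with a 61×61 kernel (σ = kernel/6),
each restricted to a box.

## Evaluation

Greedy one-to-one matching by descending IoU at threshold τ = 0.4, with ties
broken toward the lowest ground-truth index (greedy matching can be
sub-optimal on adversarial overlaps; against an exhaustive oracle it is
optimal in ≥ 95 % of random small scenarios and never exceeds the optimum).
Per-camera recall/precision/F1 count only partially visible ground-truth
boxes; precision is undefined (NaN) without predictions and F1 is 0 in
degenerate cases. Holistic recall divides the instances matched in *every*
camera of their visible set by the instances visible in at least one camera;
faces visible nowhere cannot be annotated and are excluded. An instance
invariant — holistic recall never exceeds any per-camera recall restricted
to instances visible there — is asserted on every report. SSIM uses the
standard Gaussian-window form (11×11, σ = 1.5, K1 = 0.01, K2 = 0.03,
L = 255) on ITU-R 601 luma, delegated to scikit-image.

## Synthetic scenes

The generator emulates a four-camera OR acquisition: two workflow cameras at
~1.7 m height with conventional angles, two surgical cameras at ~2.9 m with
steep overhead angles, a floor plane, rectangular occluder panels standing
in for surgical lights, and 3–6 mannequins (the body template posed via the
package's own fitting code, arms lowered 75° from the T-pose — outstretched
T-pose arms would sweep meter-long horizontal occluders through the scene).
Motion is piecewise-linear waypoint interpolation at constant velocity.
Scenes render at 160×120 with ~60° horizontal FOV; depth is stored as 16-bit
millimeters. All randomness derives from the config seed; identical configs
produce byte-identical scenes.

Ground truth is exact: skeleton joints are the posed template joints, face
boxes are the tight rectangles of face-only z-buffer renders, and a face is
*partially visible* in a view when at least 20 % of its face-patch pixels
win the full-scene z-buffer (the annotation criterion is operationalized
this way because human annotation thresholds are not formalizable).

Preset difficulty mirrors the field's scenario taxonomy: `easy` (3 persons,
no occluders), `medium` (5 persons, one panel blocking one person in one
surgical view), `hard` (4 persons, panels fully blocking the two central
persons' faces in the two surgical views). Panels are sized to occlude their
target essentially completely: a face lingering between ~50 % and ~80 %
occlusion falls between the anonymizer's visibility gate (θ = 0.5) and the
annotation threshold (20 % visible), where the two definitions legitimately
disagree — real annotation has the same gray zone.

What the generator does **not** emulate: photometric texture, lighting,
sensor noise models, lens distortion, non-rigid clothing, and person
appearance. Consequences: (1) passing detection metrics demonstrate the
geometry of the pipeline, not robustness to detector noise — noise can be
injected separately (`corrupt`) with Gaussian keypoint/depth perturbations
and dropout; (2) SSIM comparisons are not representative of real imagery —
on flat-shaded faces, block-averaging or blurring an almost uniform region
changes little (high SSIM) while inserting a textured replacement face
changes more, the opposite of the ranking observed on real photographs,
where conventional filters destroy facial structure that the mesh
replacement preserves.

## Problem sizes and determinism

The shipped evaluation scenario is 4 persons × 4 cameras × 20 frames at
160×120, which exercises every stage (≈ 320 registrations and ~1,300 face
rasterizations) while keeping a full run in tens of seconds. The pipeline is
deterministic given its inputs and seed: repeated runs serialize
byte-identical predictions. The only stochastic components are the texture
generator and the noise injector, both seeded.

## Known limitations

* Epipolar association degrades under exact mirror symmetry and very dense
  crowds; a volumetric fuser is the principled replacement and can be
  plugged in through the 3D-pose JSON import.
* Rigid per-bone skinning creates small interpenetrations at joints; heads
  are unaffected.
* The near-plane handling discards, rather than clips, partially-behind
  triangles.
* Holistic recall is undefined (reported as missing, not 0) when no face is
  visible anywhere.
* The depth-disparity visibility check cannot distinguish "occluded" from
  "mesh misplaced behind the true surface"; gross registration failures
  would be suppressed rather than flagged.
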