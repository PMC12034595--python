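# Methods

This note records the models, conventions, parameter choices and known
limitations behind `stereonav`, in the spirit of a methods appendix.

## Coordinate conventions

All geometry lives in the rectified left-camera frame unless stated
otherwise: +x right, +y down, +z into the scene, units mm. The relative
pose of a rig maps left-frame to right-frame coordinates as
`x_r = R (x_l − t)`, with `t` the right camera center expressed in the left
frame; for a rectified rig `R = I`, `t = (|T_x|, 0, 0)`. The signed
baseline `T_x` is negative under this layout so that the Q-matrix entry
`−1/T_x` is positive, and disparity `d = x_left − x_right` is positive for
points in front of the rig, giving `Z = f |T_x| / d`. Slicer-style fiducial
files may be in RAS or LPS; conversion negates x and y, and registration
always operates after both landmark sets are expressed in consistent
metric frames.

## Camera model and calibration

Square pixels (a single focal length per camera), zero skew, and a
Brown–Conrady distortion model with three radial and two tangential
coefficients; higher-order terms are out of scope. Undistortion inverts
the forward model by fixed-point iteration (tolerance 1e−10 normalized
units, hard failure above 1e−8).

Stereo calibration uses the classical plane-based recipe: per-view DLT
homographies with Hartley normalization, closed-form intrinsics from the
absolute-conic constraints (zero-skew variant), per-view extrinsics from
the homography decomposition, quaternion-averaged relative pose, then a
joint `scipy.optimize.least_squares` refinement of both cameras'
intrinsics, distortion, the relative pose and all board poses. At least
three full-corner views are required; fewer, or views that leave the conic
system unsolvable, raise a degenerate-calibration error. On noiseless
synthetic observations the fit recovers focal length and baseline to
machine precision; with 0.2 px corner noise over 15 views the mean
reprojection error of the fit settles near 0.25 px, the regime reported
for clinical stereo endoscopes. "Reprojection error" means the mean
Euclidean pixel distance (an RMS variant is exposed as an option); a
"9 × 7 squares" checkerboard is interpreted as 8 × 6 inner corners, with a
flag for boards quoted directly in corners.

## Rectification and de-interlacing

Rectification splits the relative rotation evenly between the cameras and
aligns the new x-axis with the baseline, so epipolar lines become image
rows; output pixels are inverse-warped (rotate ray, forward-distort,
bilinear sample). Row alignment on synthetic rigs with a 2° relative
rotation is exact to well below 0.1 px. Interlaced VATS frames are split
by row parity and each field restored to full height by linear row
interpolation; the eye-to-parity assignment is hardware-dependent and
therefore a flag (default: even rows → left eye).

## Disparity estimation

Local block matching with a zero-normalized cross-correlation (ZNCC) cost,
chosen for transparency and dependency-lightness over the many equivalent
classical matchers. Defaults: 9×9 blocks, disparity range [0, 64],
uniqueness ratio 0.95 (best competitor outside ±1 px of the winner),
left–right consistency tolerance 1 px, minimum block intensity standard
deviation 1.0 (8-bit units), minimum ZNCC score 0.2. Subpixel refinement
fits a parabola through the three scores around the winner. A 4-path
semi-global aggregation (P1 = 0.03, P2 = 0.5 on the 1−ZNCC cost) can be
toggled on. The texture threshold is deliberately low: ZNCC is
contrast-invariant, so weak but genuine texture still matches reliably,
while truly uniform regions (std ≈ 0) are always rejected. Invalid pixels
are NaN internally, 0xFFFF in fixed-point PNG exports (1/16 px), and NaN in
float TIFF exports. Failure modes are intentional and mirror clinical
experience: featureless regions produce no matches, and pixels occluded in
one eye fail the left–right check, cutting gaps into the cloud behind
instruments.

## Point clouds, picking, measurement

Each valid disparity pixel is triangulated through Q; organized clouds
retain the image grid, per-point disparity and Q so that image clicks can
be lifted to 3D. A landmark pick takes the median disparity over valid
pixels in an odd window (default 5×5) centered on the click and reprojects
at the clicked pixel — robust to single-pixel dropouts; an all-invalid
window raises a no-depth error rather than guessing. Distances are
Euclidean between two picks. The median absolute error statistic uses
linear-interpolation quartiles so reported values are bit-reproducible.
Statistical outlier removal drops points whose mean k-NN distance exceeds
the global mean by `std_ratio` standard deviations (defaults k = 8,
ratio = 2). Note that such removal is not strictly idempotent — a second
pass recomputes the global statistics and may trim a further boundary
point or two; the guaranteed properties are that the point count never
grows and iteration reaches a fixed point quickly.

## Rigid registration

Correspondence is strictly by landmark order/name; no automatic matching.
The fit is the closed-form Kabsch/Umeyama solution (centroid subtraction,
SVD of the cross-covariance, determinant-sign correction to exclude
reflections, translation from centroids). No scale is fitted by default
since both frames are metric; similarity scaling is an expert-mode flag.
Fewer than three pairs, or a collinear moving set, are hard errors — the
rotation would be unconstrained and any downstream overlay arbitrary.
Under isotropic Gaussian noise of standard deviation σ applied to the
fixed set, the expected squared RMSD after the fit is σ²(3n−6)/n (six
rigid degrees of freedom absorbed); at σ = 4.7 mm and n = 6 landmarks this
gives ≈ 6.6 mm, the fiducial-error regime reported for landmark-based
thoracoscopic registration. The suite verifies this law by Monte Carlo.

## Overlay rendering

A deterministic software rasterizer (screen-space barycentric coverage,
perspective-correct z-buffer) rather than a GPU pipeline: at desk scale
determinism and testability outweigh speed, and the offline minutes-scale
budget of the intended workflow permits it. Compositing is back-to-front
by fragment depth; fragments nearer than the cloud's depth buffer blend at
the structure opacity, fragments behind it at opacity × a behind-surface
multiplier (default 0.4) — "visible underneath the surface" is realized as
attenuation, not hiding, since the clinical figures show hidden structures
drawn through overlying tissue without documenting a compositing rule.
Default colors: artery red, vein blue, bronchus green, tumor yellow.
Labels are plain text with a 1 px outline at projected anchor pixels, with
no occlusion test (labels float over structures). Spherical cropping keeps
faces whose vertices all lie inside the sphere; the zoomed-out context
view is a focal-length override, not a separate renderer. Within one mesh
the z-buffer keeps the nearest fragment per pixel; self-transparency of a
single closed surface is not modeled.

## Synthetic scenes: what they emulate, and what not

The generator stands in for the two inputs a clinical deployment would
have — intraoperative stereo recordings and CT segmentations — while
keeping exact ground truth:

- **Rig presets.** `vats` (f = 1432.8 px, c = (988.53, 546.98), 1920×1080)
  and `rats` (f = 1013.3 px, c = (672, 523.24), 1264×1010) reproduce the
  published endoscope reprojection matrices; their baselines are recovered
  from the printed −1/T_x entries (T_x = −1/0.16406 and −1/0.25266 mm)
  because baselines are not published directly. The `desk` preset
  (f = 840 px, 640×512, B = 5 mm) is RATS-like geometry at roughly half
  resolution so that full renders and matching stay in the seconds range
  while retaining ~2 mm of depth per disparity pixel at the ~90 mm working
  distance — comparable depth resolution to the clinical rigs.
- **Vessel trees.** Binary trees of trimesh cylinders with spheres at the
  joints; study defaults are segmental-artery scale (root radius 2.2 mm,
  trunk 14 mm, decay 0.8/0.72 per level, branch angle 35° ± 10°, depth 3 →
  seven bifurcations) with branching planes twisting ±55° between nodes so
  the landmark set has genuine 3D extent. Landmarks are the *visible
  surface points* at each bifurcation (depth-map lookup at the projected
  centerline node, tree geometry only): image clicks can only ever pick
  surface points, and the preoperative landmark is defined as the
  corresponding surface point so the pair is exact by construction. Each
  landmark lies within one tube radius of its centerline node.
- **Rendering.** Z-buffer rasterization into both rectified cameras with
  Lambertian shading under a fixed light and multi-octave 3D value-noise
  texture (base scale 2 mm, 4 octaves) evaluated at the surface point —
  a pure function of 3D position, so the two views are photometrically
  consistent and block-matchable, emulating well-textured tissue. True
  disparity is f·|T_x|/Z at every covered left pixel; a ground-truth
  occlusion mask marks left pixels invisible from the right camera.
  Occluders are instrument-like extruded bars placed across the line of
  sight to a bifurcation.
- **Displacement.** The "preoperative" frame is the camera-frame scene
  pulled back by a random rigid displacement (rotation 7.5–25°, anatomy
  landing within 20 mm of the preop origin — CT segmentation coordinates
  sit near the scan isocenter, not meters away). Landmark observation
  noise is i.i.d. isotropic Gaussian.

What the generator does **not** emulate — and hence what passing tests do
not claim about real data: non-rigid deformation of the deflated lung
(the dominant clinical error source), specular highlights, blood and smoke,
sensor noise and rolling shutter, repetitive real-tissue texture,
mis-segmented CT models, and human variability in landmark clicking.
End-to-end recovery numbers on synthetic scenes therefore bound the
*geometric* pipeline error only, not clinical overlay accuracy.

## Problem sizes and numerical choices

Default study sizes keep the full suite in the low minutes on one CPU:
640×512 renders, disparity range ≤ 64, trees of ~2,500 faces, 1000-replicate
Monte Carlo for the RMSD law, a 20-object measurement campaign, planes at
three depths spanning the 84–168 mm working range. Ties in block matching
resolve to the smallest disparity (argmax convention); subpixel offsets are
clamped to ±0.5 px; rasterization drops faces with any vertex nearer than
1 mm instead of clipping; quartiles interpolate linearly; the undistortion
and rigid-fit tolerances are stated above. All generators are pure
functions of (parameters, seed); repeated pipeline runs are byte-identical.

## Known limitations

- Rigid registration only: no ICP refinement, non-rigid/deformable models,
  or temporal tracking; these are explicitly downstream extensions.
- The block matcher is local; strongly slanted or thin structures show
  edge-fattening bias at depth discontinuities (visible as a few tenths of
  a millimeter of pick bias at bifurcation crotches).
- The rasterizer keeps one fragment per pixel per mesh, so a transparent
  mesh does not blend with its own back faces.
- Calibration assumes square pixels and zero skew; fisheye/omnidirectional
  optics and rolling-shutter effects are out of scope.
- DICOM/CT volume handling and segmentation are upstream of this package;
  meshes and fiducials arrive as files (PLY/OBJ/STL, Slicer CSV/JSON).
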