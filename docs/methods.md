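# Methods

This note documents the models, conventions and numerical choices behind
`opmcoreg`, and what the synthetic phantom does and does not emulate.

## Coordinate frames and transforms

All geometry lives in millimetres in one of five tagged frames: `device`
(helmet CAD), `digitizer` (stylus transmitter), `scan` (optical scanner),
`head`, and `mri`. A `RigidTransform` is a proper rigid motion
`p ↦ R·p + t` with `RᵀR = I` and `det R = +1`, validated at construction to
1e-8; similarity/reflection fits are deliberately impossible — helmet and
MRI are both metric, so any apparent scale difference is a data error worth
surfacing, not absorbing. Orientation vectors transform by `R` alone and
are renormalized to exactly unit length.

The head frame is built from three landmarks (nasion, left/right
pre-auricular points, or three face picks in the order front / left cheek /
right cheek): origin at the ear midpoint, +X the unit vector to the nasion,
+Z = X × unit(LPA − origin), +Y = Z × X. The nasion lies on +X and the LPA
has positive Y and zero Z by construction. Because transform 1 and
transform 2 are estimated *in the same constructed frame*, a perturbation of
that frame (noisy fiducials, arbitrary face-pick placement) cancels in the
composition `T2∘T1`; only the landmark order matters.

## Rigid point alignment (Kabsch)

`kabsch_align` solves `min Σ‖R·sᵢ + t − tᵢ‖²` by SVD of the centred
cross-covariance, with the sign of the smallest singular direction flipped
when needed so `det R = +1` (mirrored inputs yield a proper rotation with a
large residual instead of a reflection). Degeneracy is detected on the
centred source matrix: second singular value < 1e-6 × the largest means the
points are collinear or coincident and the in-plane rotation is
underdetermined. (Planar sets — any three points — are fine; the *smallest*
singular value of a planar set is always zero and is not used.) The
reported FRE is the RMS residual after alignment.

## Trimmed ICP

`icp_register` is point-to-point ICP onto the *vertices* of the target
cloud: per iteration, nearest-vertex correspondences via `scipy.spatial.cKDTree`,
optional gating at `max_pair_distance`, discarding of the `trim_fraction`
worst pairs, full Kabsch refit from the original source, stop when the
retained-pair RMS changes by less than `convergence_tol`. Defaults:
`max_iterations = 100`, `convergence_tol = 1e-4 mm`, `trim_fraction = 0.1`,
no distance gate; all exposed in the config file and as CLI flags. The
retained-pair RMS at the final pose is reported as the "ICP fitting error";
RMS (rather than mean or median distance) was chosen because it is the
quantity the Kabsch step actually minimizes. Fewer than three retained
correspondences at any iteration raises a registration failure.

Point-to-point against vertices is adequate here because every target in
the workflows is a dense surface (segmented MRI scalp, optical scan);
point-to-plane and non-rigid variants are out of scope. The retained-pair
RMS is provably non-increasing across iterations when no distance gate is
set, and the tests assert this on every run they perform.

**Initialization matters.** Like all greedy ICP, the method converges to
the nearest fixed point. On smooth head-shaped surfaces the capture basin
for in-plane slides is roughly 2–3 mm / 2–3°; the workflows therefore always
seed ICP with a landmark alignment (digitized fiducials onto MRI fiducials
for the stylus; ≥ 4 user-picked coarse pairs for the scans — the four-pair
minimum is enforced). Identity initialization is only appropriate when head
and MRI frames are already roughly aligned.

## Marker extraction (structured-light)

Painted helmet markers are isolated by a closed box in HSV space (hue on a
0–1 scale, non-wrapping; wrap-around windows are supplied as two ranges).
The default window targets green paint: H 0.2–0.66, S 0.3–1, V 0.16–1.
Selected vertices are grouped by single-linkage connected components under
a `linkage_radius = 10 mm` adjacency (markers are small, well-separated
patches, so any density-based grouping agrees); components with fewer than
`min_cluster_size = 5` vertices are dropped as specks, and the surviving
count must equal the designed marker count. Detected centroids are matched
to the designed reference points by exhaustive assignment search (K ≤ 8, so
at most 8! ≈ 40k Kabsch fits): the permutation with the smallest FRE wins,
and if the runner-up scores within a factor 2 of the winner the
configuration is reported as ambiguous (e.g. an equilateral marker
triangle) rather than silently guessed. Marker layouts should be scalene.

## Depth correction

The design-frame sensor position is the vapor-cell center with the sensor
bottomed in its slot. When a sensor is partially withdrawn, the correction
along the slot-radial axis is `depth = l − t − h` (sensor height − helmet
thickness − exposed height, all mm); flush insertion `h = l − t` gives zero.
Stored orientations are taken to point *inward* (helmet → scalp), so
positive depth moves the sensor toward the scalp; a `--flip-depth-direction`
flag serves arrays stored with outward normals. Depths beyond ±50 mm
trigger an implausibility warning. Depth application commutes with rigid
transforms, so it may be applied before or after co-registration.

## The synthetic phantom

The phantom generates every workflow input from a handful of parameters and
one seed (all randomness flows from `numpy.random.default_rng(seed)`; equal
seeds give bit-identical output):

* **Scalp**: an ellipsoid (semi-axes 90 × 70 × 100 mm) plus Gaussian
  angular bumps — a 25 mm nose and fixed smaller brow/chin relief with
  deliberate left/right asymmetry. A single rotationally-symmetric nose
  leaves face registration free to spin about the nose axis; the asymmetric
  relief makes the face pose well-determined, as on a real face.
* **Helmet**: the scalp offset 6 mm outward along the ellipsoid normal,
  covering the head to 110° from vertex while clearing the face; 85 sensor
  slots spread by farthest-point sampling, vapor-cell centers 2.5 mm above
  the helmet shell, radial orientations pointing inward.
* **Markers**: 4 (default) painted patches of 5 mm radius at well-separated
  helmet sites. The reference point of each marker is the centroid of its
  noiseless painted patch, so marker detection is exactly consistent with
  the CAD by construction.
* **Measurements**: the stylus session digitizes fiducials, reachable scalp
  points and helmet references in a random transmitter frame; optical scans
  sample the visible face and helmet in a random scanner frame, painted
  pure green on the marker patches and skin/grey elsewhere (chosen so the
  default HSV window selects exactly the markers). Isotropic Gaussian noise
  defaults per modality: stylus 0.5 mm, structured light 0.3 mm, laser
  0.1 mm.

**One surface realization, nested lattices.** All surfaces are evaluated on
icosphere direction lattices that nest exactly: the designed helmet on the
coarse lattice (subdivision 4, ≈3.5 mm pitch at head scale), the scans one
subdivision finer, the MRI scalp mesh one finer still (≈1.75 mm — segmented
MRI surfaces are denser than optical scans, and the finer target visibly
improves ICP convergence). Because every modality samples the *same*
realization of the surfaces, a noiseless pipeline run sits at an exact
fixed point of ICP and recovers the ground-truth transforms to numerical
precision; added noise is then the only error source, which is what the
test suite exploits.

What this idealizes away: real scans sample independently of the MRI mesh
(adding a surface-quantization floor of roughly 0.4 × vertex pitch to the
ICP residual), have holes, specular dropout and spatially correlated error;
real scalp segmentations have their own bias; real marker paint is not a
perfect HSV box. Passing phantom tests therefore demonstrates correctness
of the geometry and algorithms, not device-level accuracy on real data.

## Benchmarks (`opmcoreg.validation`, `scripts/acceptance.py`)

Two seeded desk-scale benchmarks reproduce the registration-quality bounds
users are told to watch:

* **Face fit**: ≈1500-point face region, scan noise 0.5 mm, coarse
  initialization within 5 mm/5° of the truth (the bounded wobble rotates
  about the face centroid — about a distant origin the same angle would
  displace the face several-fold more), trimmed ICP onto the noiseless
  scalp mesh; mean retained-pair RMS over 20 seeds, expected < 2 mm.
* **Helmet fit**: designed helmet mesh (≈1400 vertices) onto a laser scan
  with 0.1 mm noise after a four-pair coarse match; mean RMS over 20 seeds,
  expected < 0.8 mm.

`python scripts/acceptance.py --seed <s> --out <json>` runs both with trial
seeds `s … s+19` and writes the means. Problem sizes (subdivision depths,
20 trials, 200 digitized points) were chosen so the full suite and the
benchmarks complete in seconds on one CPU while keeping every surface dense
enough for stable registration.

## Known limitations

* Rigid helmets only; flexible caps (per-sensor pose) are out of scope.
* Point-to-point ICP needs a fair initialization (see above); there is no
  global/feature-based registration fallback.
* Marker correspondence is exhaustive and limited to 8 markers; highly
  symmetric layouts are rejected as ambiguous by design.
* PLY I/O accepts ASCII and binary-little-endian dialects; big-endian files
  are rejected explicitly.
* MRI scalp segmentation is upstream of this package; it consumes the
  resulting surface mesh.
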