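# Methods

## Problem and measurement model

After scaling and root planing (SRP), periodontal soft tissue shrinks by
amounts below the resolution of a periodontal probe.  The digital protocol
this package implements quantifies that shrinkage from a pair of intraoral
surface scans per patient — baseline (STL0) and one-month re-evaluation
(STL1) — per tooth:

1. **Segmentation.** Each tooth plus its gingival collar is extracted from
   the arch scan.  Interactive selection is replaced by a declarative
   equivalent: a seed point and radius (`crop_region`), or explicit label
   sidecars marking vertices CROWN / GINGIVA / OTHER.  STL carries neither
   labels nor units; labels travel in a JSON sidecar parallel to the merged
   vertex order, and coordinates are millimetres by convention.
2. **Superimposition.** The clinical crown is the only surface assumed
   unchanged between visits, so STL1 is rigidly aligned onto STL0 using
   crown geometry alone: principal-axes initialisation followed by trimmed
   point-to-point ICP, where every CROWN vertex of STL1 is matched to its
   closest point on STL0's CROWN triangles (exact closest-point queries via
   a voxel-grid-pruned search), the largest-distance `trim_fraction` of
   matches is discarded, and the update is the closed-form cross-covariance
   SVD with det = +1 enforced.  Defaults: `max_iter` 100, `tol` 1e-6 mm
   (minimum RMS improvement per iteration), `trim_fraction` 0.10.  Trimming
   absorbs segmentation-boundary faces and root surface newly exposed by
   recession.  The trimmed RMS is non-increasing across iterations.
3. **Sectioning.** One tooth frame is estimated on STL0 — axis = principal
   eigenvector of the crown vertex covariance, oriented from the gingiva
   centroid toward the crown centroid; origin = crown centroid — and a plane
   containing that axis cuts both (aligned) meshes.  The radial direction of
   the cut (buccal/lingual/mesial) is a per-tooth configuration input
   (`azimuth`); without one, the second principal crown direction is used.
   Triangle/plane intersection segments are chained into polylines by their
   generating mesh edges (exact chaining; vertices exactly on the plane are
   nudged 1e-12 mm along the normal first), the polyline nearest the frame
   origin is kept, and points are projected to in-plane (u, v) coordinates
   with v along the axis, coronal positive.
4. **Margin landmarks.** On the shared plane: P1 = most coronal
   GINGIVA-labelled point of the STL0 section, P2 = same for STL1 (v-ties
   break toward smaller u, i.e. deeper in the sulcus); L = the horizontal
   line v = v(P2); P3 = the crossing of L with the STL0 section whose u is
   nearest u(P2).  Height loss = |P1P2| (planar Euclidean), width loss =
   |P2P3|; both reported as nonnegative distances to 3 decimals mm, with the
   signed axial component v(P1) − v(P2) and signed width u(P3) − u(P2) kept
   as diagnostics.  Only the positive-u half of the profile is measured.
   Whether "the distance between P1 and P2" should be Euclidean or axial is
   not operationally fixed by the protocol; both are computed and the
   Euclidean value is primary.
5. **Cohort statistics.** Teeth cluster within patients.  For a mean, a
   GEE linear model with identity link reduces exactly to the grand mean
   with the cluster-sum sandwich variance, implemented directly:
   se² = Σᵢ(Σⱼ(xᵢⱼ − x̄))² / n², CI = x̄ ± 1.96·se, Wald χ² = (x̄/se)²
   against χ²₁.  Descriptive rows use SD with n−1 and linearly interpolated
   quartiles.  Paired bleeding-on-probing is tested with the exact binomial
   McNemar test, p = min(1, 2·P(X ≤ min(b, c))), X ~ Bin(b+c, ½) — valid at
   any discordant count (the observed "appeared" count is 1).

## Synthetic phantom

No scan data are published with the study, so every stage is validated on
surfaces of revolution with closed-form ground truth.  The profile, revolved
about the z axis, is a single connected curve mimicking what a scanner sees:
gingival collar outer wall → margin rim → sulcus floor → visible tooth
surface → tapered crown → cap.  Labels: tooth and cap CROWN, collar and rim
GINGIVA, sulcus floor OTHER.

Geometry defaults (mm): crown radius 3.5, crown height 8, collar height 3,
collar thickness at the rim 1.0, collar base thickness 1.2, sulcus depth
0.1.  The crown carries an azimuthal modulation
r·(1 + w(z)·(0.15·cos 2θ + 0.09·cos 3θ)) ramping in over z ∈ [0.1, 0.6] above
the margin: real crowns are not bodies of revolution, and without the lobes
the about-axis rotation would be unconstrained for the best-fit step.  The
margin zone and collar remain exactly axisymmetric.

The deformation encodes the study's measured effects, and the defaults are
the study's cohort means: `delta_h` = 0.196 (apical margin displacement) and
`delta_w` = 0.344 (horizontal thickness loss at the new margin level).

* The re-evaluation rim sits directly below the baseline rim
  (same radius, `delta_h` lower), so true height loss = `delta_h` exactly
  (and equals its axial component).  With `delta_h` = 0 the rim instead
  insets radially by `delta_w`.
* The baseline collar bulges outward below the rim, reaching radius
  rim + `delta_w` above the measurement level and then running vertically
  through it (a cylindrical band v ∈ [−delta_h − 0.15, −delta_h + min(0.06,
  0.4·delta_h)]), so the P3 abscissa is insensitive to small errors in the
  P2 level; a steep 0.02 mm "mini-lip" right below the rim keeps the rim the
  unambiguous most-coronal point under noise.  The re-evaluation wall tapers
  linearly from the collar base to its rim, so the width loss tapers to zero
  at the collar base.  True width loss = `delta_w` exactly.
* Both scans receive Gaussian scanner noise (default sd 0.02 mm, the order
  of intraoral-scanner accuracy) along vertex normals, low-pass filtered
  over 3 neighbour-averaging passes and rescaled to the target sd: scanner
  residuals are smooth waviness, not independent vertex jitter.  White and
  isotropic noise remain available (`noise_smooth_iters=0`,
  `noise_mode="isotropic"`).
* STL1 additionally carries a rigid `pose`; all randomness flows from one
  seed, making pairs bit-reproducible.

Meshing: the profile is sampled at `mesh_resolution` (default 0.08 mm) in
the collar/margin zone with exact vertex rings at every control point, and
at `crown_step` (default max(resolution, 0.25) mm) on the crown; the
azimuthal step is 0.3 mm.  Generation refuses `mesh_resolution` >
`delta_h`/2, which could not represent the margin displacement.  The tooth
wall uses a fixed absolute z-grid so the two time points share crown vertex
rings exactly on their common surface.

What the phantom does **not** emulate: anatomical crown/emergence shapes,
papillae and interdental col geometry, saliva/reflection artefacts,
scan-stitching distortion, or soft-tissue biomechanics.  Passing recovery
tests therefore shows the chain is correct and noise-stable on labelled,
well-formed surfaces — not that margin labelling on real scans is solved;
on real data the labels come from the segmentation step, and no automatic
curvature-based margin detector is attempted.

The clinical-chart generator draws the probing-depth change of tooth j in
patient i as mean_change + bᵢ + eᵢⱼ (bᵢ ~ N(0, sd_between²), eᵢⱼ ~ N(0,
sd_within²)); recorded depths are means of three per-site readings rounded
to 0.5 mm (hence values like 2.67).  Defaults are the study's observed
values: mean change −0.34 mm, baseline mean 2.74 mm, bleeding prevalence
0.74 with resolve probability 52/97 and appearance probability 1/34,
recession probability 4/131.  The study reports no variance decomposition;
sd_between = 0.3 / sd_within = 0.4 are chosen so the cluster-robust CI is
visibly wider than the naive one, qualitatively matching why GEE was needed,
without claiming to match the printed CI widths numerically.

## Numerical choices and tie-breaks

* Vertex merge tolerance 1e-6 mm (grid snap, first occurrence kept) — far
  below scanner resolution, so real geometry never collapses.
* Closest-point ties between triangles break toward the lowest triangle
  index; correspondence trimming uses a stable sort.
* Section polyline selection: minimum point distance to the frame origin,
  rounded at 1e-9 mm; ties go to the longer polyline.  Section point labels
  come from the nearer endpoint of the generating mesh edge (ties: lower
  vertex index).
* Horizontal crossings deduplicate at 1e-9 mm; exact-vertex crossings count
  once; equidistant crossings resolve to smaller u.
* Reflections are excluded everywhere (det = +1 in every SVD update).
* Degenerate inputs raise typed errors (ambiguous axis, empty section,
  missing gingiva, no crossing); the pipeline converts them to per-tooth
  "unmeasurable" statuses without touching other teeth.

## Calibration and known limitations

* The cluster-robust CI uses the 1.96 normal multiplier as stated for the
  Wald basis.  With only 12 clusters this interval under-covers (~91%
  empirically): the calibration check therefore runs at 50 patients × 11
  teeth, where coverage sits within 95% ± 3% while the naive sd/√n interval
  collapses to ~67-69% under patient clustering.  Small-cluster corrections
  (CR2, t quantiles) are deliberately out of scope.
* Margin landmarking is a max-statistic and inherits the protocol's
  point-selection sensitivity: with scanner noise, the most coronal point is
  biased coronally, and for small `delta_h` combined with large `delta_w`
  the width measurement is ill-conditioned (the baseline profile is nearly
  horizontal just below the rim).  The phantom's vertical band makes the
  ground truth recoverable; on real anatomy this conditioning problem is
  intrinsic to the method.
* ICP recovers the about-axis rotation only as well as the crown deviates
  from rotational symmetry; under noise the residual about-axis error is a
  few tenths of a degree, which does not affect the (axisymmetric-margin)
  measurements.
* Binary STL stores float32; round-trip accuracy of 1e-6 mm holds for
  coordinates below ~16 mm, which all phantom and single-tooth geometry
  satisfies.
* Only one azimuth (one radial side) is measured per tooth, as a
  configuration choice; the protocol leaves the sectioned direction and
  side unstated.
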