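# Methods

## The measurement model

An AP pelvis radiograph is treated as two hips in one raster coordinate
frame (x rightward, y downward; "superior" = smaller y).  Patient sides are
recorded, not image sides: the patient-right hip sits on the image left, so
the lateral direction is decreasing x for the right hip and increasing x
for the left.  All inputs are pixel coordinates from manual delineation;
no pixel spacing is needed because every reported quantity is an angle and
therefore invariant under translation and uniform scaling.

Manual input per hip: the acetabulum contour, the femoral-head contour,
optionally the proximal femur contour, and three marked points — the
lateral (external upper) acetabular edge *b*, the inferior acetabular edge
*g* (teardrop), and the inferomedial end of the sourcil *s*.  Everything
else is constructed:

- *d* = uppermost head-contour vertex (ties: nearest the contour centroid
  x, then lowest index — a deterministic rule so measurements never depend
  on input ordering).
- *e* = outermost head-contour vertex.  If the delineation continues into
  the femoral neck, the search is first restricted to the arc superior to
  the head/neck inflection, detected as the first sign change of the
  discrete turning angle (5-vertex window) walking inferolaterally from
  *d*.  Default annotations are head-only, keeping the default path free
  of curvature estimation.
- *f* = crossing of the head contour by the ray from *e* through *g*,
  taking the crossing farthest from *e*.  The ray is extended past *g* (to
  four bounding-box diagonals) so the construction also works when *g*
  falls inside the head circle; since the head contour is circle-convex
  there are at most two crossings and the far one is on the inferior arc.
- Head center *a* and radius: circumcircle of (*d*, *e*, *f*), solved from
  the two perpendicular-bisector equations.  Exactly three points are used
  by design — the method's defining construction — rather than a
  least-squares fit to all vertices.
- Vertical reference *c*: *a* displaced along the superior perpendicular of
  the baseline joining the two head centers.  Because the reference follows
  the anatomy rather than the image axes, in-plane film rotation cancels.

The three angles are unsigned arccos angles in [0, 180]°.  The baseline
vectors in the sharp and Tönnis angles are directed from the contralateral
landmark to the ipsilateral one; the opposite direction would give the
supplement, and this orientation yields the acute clinical angles.  CE is
not given a negative sign when the lateral edge falls medial to the
vertical line; severely subluxed hips whose delineated arc omits the true
apex are measured from the delineated extremes, with no claim of clinical
validity in that regime.

Numerical tolerances are scale-free: collinearity is declared when twice
the triangle area is below 1e−9 × (bounding-box diagonal)²; contour
intersections merge within 1e−7 × diagonal.  Degenerate inputs (zero
vectors, coincident points, collinear d/e/f, a tangent e–g ray) raise typed
errors tagged with the image and side.

## Clustering

Each hip contributes x = (θ_CE, θ_sharp, θ_Tönnis)ᵀ in degrees.  Local
density is ρᵢ = Σ_{j≠i} exp(−‖xᵢ−xⱼ‖²/(2h²)); samples are processed in
descending ρ (ties by index, making the partition invariant to input
permutation); the first sample founds cluster 0 and each later sample joins
its nearest already-processed sample's cluster if within the linking radius
r, else founds a new cluster.  The peak cluster — the one seeded by the
global density maximum — is taken as normal development; everything else is
outlying.  No sample is discarded before clustering.

Defaults: h from Silverman's multivariate rule (d = 3) using the mean
per-axis standard deviation, r = 3h.  Both are overridable.  The three axes
are commensurate (all degrees, similar spread), so no standardization by
default; a z-scaling flag exists.  The choice of a Gaussian kernel and the
nearest-assigned linking rule is this package's concrete realization of
density-descending clustering; published variants differ in kernel (cutoff
vs Gaussian) and linking details, and the defaults here were fixed once as
the minimal deterministic rule with one dominant cluster plus outliers.

## Diagnostic model

The peak cluster's triplets are modeled as trivariate normal with μ the
sample mean and Σ the unbiased (n−1) covariance; positive definiteness is
verified at fit and load time (minimum eigenvalue above 1e−10 of the
largest).  Classification: normal iff (x−μ)ᵀΣ⁻¹(x−μ) ≤ χ²₃(q), default
q = 0.95.  The quantile is configurable because no canonical cutoff exists
for this criterion; 0.95 matches the usual coverage convention.  The
ellipsoid's principal axes (eigenvectors of Σ, half-lengths
√(λᵢ·χ²₃(q))) are exposed for inspection — the long axis is the natural
normal-to-abnormal direction — but the default classifier is the full
ellipsoid, which is a complete decision rule rather than a direction.

The knowledge-driven comparator classifies on CE alone: dysplastic below
20°, normal above 25°, borderline on the closed interval [20°, 25°]
(boundary values are borderline).  A combined-rule flag additionally
requires Tönnis > 10° for a dysplastic call, demoting CE-dysplastic hips
that fail it to borderline.

## Synthetic data

The generator stands in for a hospital dataset and defines the conditions
under which the package is validated.

*Triplet level*: a two-component Gaussian mixture.  Defaults — 240 normal
hips at μ = (30, 40, 8)° with per-axis SD (4, 3, 2.5)°, and 60 dysplastic
hips at μ = (14, 48, 18)° with SD 4° per axis — chosen once as clinically
plausible values: normal adult CE clusters near 30°, sharp near 40° and
Tönnis in the single digits, while dysplastic hips show low CE, a steep
sharp angle and an up-tilted roof, at an 80/20 prevalence typical of a
referral sample.  Draws outside [0, 180]° are redrawn (probability < 1e−3
at these defaults, so the truncation is negligible).

*Pelvis level*: the inverse construction places both head circles on a
horizontal baseline (radius 100 px, centers 400 px apart — values chosen
for numeric conditioning, not anatomy), then inverts each angle definition:
*b* at the CE rotation from the superior perpendicular at 1.3 R from the
center; both *g* on a shared horizontal teardrop line whose height is the
midpoint of the two sides' feasibility intervals (each side's sharp angle
fixes the horizontal run from *b* given that height, and the teardrop's
medial offset is constrained to 0.3–1.9 R and to stay clear of the
midline); *s* medial of *b* by 0.8 R at the Tönnis slope.  The head
contour is the circular arc from ~20° below the lateral point over the
apex to ~15° past *f*, sampled with `contour_points` vertices (an
adaptively ~220–260° arc, emulating the superior head outline a clinician
can actually see).  Vertex noise (Gaussian, per coordinate) is applied to
contour vertices only — marked landmarks are clicked points, not traced
ones — followed by a global in-plane rotation about the pelvis center.
Infeasible angle combinations (no common teardrop line, arc span > 340°)
raise a construction error naming the constraint; dataset generation
rejects and redraws rather than clamping, so planted distributions stay
clean.

With zero noise the forward measurement reproduces the prescribed angles
almost exactly: all contour vertices lie on the true circle, so the
three-point fit is exact and the only discretization effect is the vertex
selection of *e* and the chordal position of *f* (error → 0 as
`contour_points` → ∞; < 0.001° at 180 vertices).  What the generator does
*not* emulate: real delineation bias (systematic over/under-tracing),
non-circular femoral heads, occluded inferior arcs, inter-observer landmark
variation beyond i.i.d. jitter, and appearance differences between DR
machines.  Passing round-trip tests therefore validates the geometry and
statistics chain, not the clinical accuracy of manual delineation.

## Problem sizes and seeds

Validation runs use the study's natural scale: 143 radiographs (286 hips)
for the end-to-end pipeline, 300-sample mixtures for clustering and model
recovery, 5000 draws for coverage checks, 1000 random configurations for
the angle-formula oracle.  Clustering-recovery checks use a mixture with
per-axis SD 2° so the component separation exceeds 8× the within-component
spread — the regime in which density clustering is expected to recover the
planted partition essentially exactly; the generator defaults (separation
≈ 5σ) are the harder, realistic regime in which the peak cluster may
absorb a few tail samples.  All stochastic tests fix seeds; every dataset,
model file, and manifest is byte-reproducible from its config seed.

## Known limitations

- The measurement chain assumes both femoral heads are delineated; a
  single-hip film cannot provide the vertical reference.
- CE is unsigned; true negative CE (head center lateral to the acetabular
  rim) reads as a small positive angle.
- The clustering realization is one concrete member of the
  density-descending family; results can differ from variants with cutoff
  kernels or density-gap linking, especially at weak separation.
- The Gaussian model has no borderline class and fits a single pooled
  model for both sides.
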