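# hipdx

Semi-automatic measurement and diagnosis of developmental dysplasia of the
hip (DDH) on pelvic radiographs.

Screening for DDH in adults rests on a handful of angles read off an AP
pelvis film — the center-edge (CE) angle of Wiberg, the sharp angle, and the
Tönnis (acetabular roof) angle — and on fixed clinical thresholds for them.
Automatic segmentation of the acetabulum is unreliable, so this package
takes the pragmatic middle road: a clinician delineates the joint contours
and marks a few landmark points; everything after that is automatic.  It is
aimed at radiology research groups who have (or can produce) such
delineations and want objective, reproducible angle measurements plus a
data-driven diagnostic criterion instead of single-angle cutoffs.

## What it computes

From a per-radiograph annotation (contours of acetabulum and femoral head,
plus three marked landmarks per hip), the pipeline:

1. **Constructs the femoral-head center** as the circumcenter of three
   automatically selected head-contour points: the uppermost point *d*, the
   outermost point *e*, and *f*, where the line from *e* through the
   inferior acetabular edge *g* re-crosses the head contour.
2. **Measures the three angles** (unsigned, via arccos of normalized dot
   products):
   - θ_CE = ∠(a→c, a→b) — at the head center *a*, between the vertical
     reference *c* (perpendicular to the line joining the two head centers)
     and the lateral acetabular edge *b*;
   - θ_sharp = ∠(g→b, g′→g) — at the inferior acetabular edge, against the
     inter-teardrop baseline (g′ is the contralateral edge);
   - θ_Tönnis = ∠(s→b, g′→g) — the sourcil line (inferomedial sourcil
     point *s* to *b*) against the same baseline.
3. **Clusters** all hips' triplets x = (θ_CE, θ_sharp, θ_Tönnis)ᵀ by
   processing samples in descending local (Gaussian-kernel) density; the
   highest-density-peak cluster is taken as normal development.
4. **Fits the diagnostic model** — a trivariate normal
   p(x) = (2π)^(−3/2)|Σ|^(−1/2) exp(−½(x−μ)ᵀΣ⁻¹(x−μ)) on that cluster —
   and classifies new hips as normal/abnormal by the χ²₃ quantile ellipsoid
   of the Mahalanobis distance (default quantile 0.95).  The classical
   knowledge-driven rule (dysplastic θ_CE < 20°, normal θ_CE > 25°,
   borderline between; optionally θ_Tönnis > 10°) is implemented alongside
   for comparison.

A synthetic-pelvis generator inverse-constructs annotations with prescribed
ground-truth angles, so the whole chain is testable without radiographs.

## Worked example

`examples/` contains one short script per capability.  Measuring a single
pelvis with known ground truth (`examples/01_measure_single_pelvis.py`):

```
right femoral head: center=(300.0, 500.0) px, radius=100.0 px
right: CE  30.00° (true  30.0°)  sharp  40.00° (true  40.0°)  Tönnis   5.00° (true   5.0°)
 left: CE  18.00° (true  18.0°)  sharp  48.00° (true  48.0°)  Tönnis  14.00° (true  14.0°)
```

The head circle is recovered exactly from the three contour points and the
measured angles match the planted truth; the left hip (CE 18° < 20°) is the
dysplastic one.  Training the model on a 143-radiograph synthetic study
(`examples/03_train_diagnostic_model.py`):

```
measured 286 hips (0 failures)
density clustering: 2 clusters, bandwidth 2.51°, peak cluster holds 225/286 hips
fitted normal-development model:
  mu    = [29.51 40.04  7.8 ]  (CE, sharp, Tönnis in degrees)
  sigma diag = [13.03  9.57  5.99]  (degrees²)
```

The peak cluster isolates the ~80% planted-normal hips and the fitted mean
recovers the planted normal component (30, 40, 8)°.

The same pipeline is available from the shell:

```sh
hipdx simulate --out ds --n-pelves 143 --seed 7
hipdx measure  --annotations ds --out angles.csv
hipdx train    --angles angles.csv --model model.json
hipdx classify --model model.json --angles angles.csv --out diagnosis.csv
```

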