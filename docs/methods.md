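# Methods

This note documents the models and procedures implemented in `archssm`,
the parameter defaults and why they were chosen, what the synthetic
generator does and does not emulate, and the numerical choices that a
maintainer would otherwise have to reverse-engineer.

## Anatomy and coordinate conventions

The object of study is the fetal great-vessel "double arch": the
ascending aorta and transverse arch (AAo segment), the arterial duct
(AD) and the descending aorta (DAo) meeting at a single bifurcation
origin where the duct inserts. Aortic head-and-neck branches are not
modeled (their topology is inconsistent across cases), so the aortic
isthmus — anatomically the segment between the left subclavian artery
and the duct insertion — is represented by a fixed surrogate: the
distal 20% of the AAo segment's arc length.

Coordinates are physical millimetres in the fetal frame: +X
left→right, +Z inferior→superior, +Y completing a right-handed system.
Segment ordering is fixed everywhere: AAo and AD run free-end →
bifurcation origin; DAo runs origin → diaphragm. Default per-segment
counts are 25/25/51 (N = 101 points, 4N = 404 features).

## Centerline extraction (medial-approximation shortest path)

Extraction works on a triangulated surface and two interior landmarks.
The implementation is a self-contained medial approximation rather than
a full Voronoi-diagram construction:

1. **Inside/outside field.** The mesh is split into connected
   components. For each component, a query point's nearest face
   centroid and that face's normal give a signed side; the sign is only
   trusted within a per-component *reach* (0.6× the minimal extent of
   its oriented bounding box ≈ 1.2× a tube's caliber), beyond which the
   nearest-wall heuristic is meaningless. A point is inside the union
   if any closed positive-volume component claims it; closed
   negative-volume components (see clipping) are forbidden regions.
2. **Graph search.** The bounding box is rasterized at `pitch`
   (default 0.7 mm); interior voxels form a 26-connected graph with
   edge weight = step length / mean local clearance, so Dijkstra
   prefers wide, central corridors. Landmarks snap to the nearest
   interior voxel; a landmark farther than `landmark_tol` (2.5 mm) from
   the interior raises an error.
3. **Medial refinement.** Each path point is snapped toward the medial
   axis of the component it lies deepest inside: moving away from the
   nearest wall along u, the projection of (probe − nearest wall point)
   on u flips sign exactly at the locally equidistant set; the crossing
   is bracketed by marching in 0.3×clearance steps and bisected
   (7 iterations), and the move is applied perpendicular to the running
   path direction. Refining against the *containing* component keeps
   the other branch's wall, which crosses the junction interior in a
   tube-union mesh, from distorting the path. Three refinement
   iterations, then a two-pass 1-2-1 smoothing.
4. **Radii.** The maximal inscribed radius at a path point is its depth
   in the deepest containing component — again so internal walls near
   the bifurcation do not shrink it. On a swept cylinder of radius 3 mm
   the recovered axis is within ~0.005 mm and radii within the mesh
   faceting error.

**Mid-duct clipping.** Before the aortic pass, faces fully inside a
sphere around the mid-duct landmark are removed and an inverted-normal
icosphere is inserted; the extraction treats its interior as forbidden,
so the DAo→AAo path cannot shortcut through the duct. The default clip
radius is 1.5× the local duct radius — enough to block the lumen
without destroying adjacent anatomy. A zero radius is a no-op; a center
outside the mesh warns and returns the mesh unchanged.

**Bifurcation origin.** Walking from the shared DAo end, a point pair
(one per line) is co-contained when each point lies inside the other
line's maximal inscribed sphere; the origin is the midpoint of the last
co-contained pair. Lines that never diverge (identical inputs) or never
co-contain (wrong landmarks) raise distinct errors. The shared DAo
trunk geometry is the pointwise average of the two extracted trunks by
arc-length correspondence — the merge step does not say which trunk
survives, and blending is symmetric.

**Resampling** is linear interpolation in arc length; positions are
exactly uniform in the source parameterization. The chords of the
resampled polyline deviate from uniformity at O(h²·curvature) on curved
segments (and by the jitter on noisy ones), so the optional chord-
uniformity validation uses a caller-supplied tolerance rather than
machine precision.

## Alignment

Translation of the bifurcation origin to (0,0,0), then rotation about
+Z by α = −atan2(v_y, v_x) where v_AD points from the origin to the
duct's free end ("start of the arterial duct" is read as the free end —
the pulmonary-bifurcation landmark end). The +X target direction is an
arbitrary but fixed convention; any fixed choice yields identical shape
statistics. No scaling, and no correction of tilt off the Z axis:
inputs are assumed already expressed in the fetal frame. The
degeneracy guard rejects v_AD with horizontal norm ≤ 1e-6 mm.

## Shape model

PCA on the centered 404-feature matrix via SVD; variances use the
unbiased 1/(n−1) convention; min(n−1, 4N) modes are kept. Coordinates
and radii share millimetre units, so no per-feature standardization is
applied — the model is plain covariance PCA. Mode signs are
canonicalized (largest-magnitude loading positive) for reproducible
serialization. The SVD route is held to agreement with a brute-force
covariance eigendecomposition at 1e-8 relative tolerance in the tests.

Reconstruction clamps radii at a 1e-6 mm floor (with a warning) because
truncated linear combinations can produce non-physical negative radii.
Reconstruction RMSE is computed over per-point 3D distances with the
radius channel excluded — it is reported as a geometric error in mm;
regions are the three segments, ALL, and NEAR_BIFURCATION (the
bifurcation-adjacent half of each segment, rounding up: 13/13/26 points
for 25/25/51).

**Monotonicity of reconstruction error.** What is a theorem, and what
the tests assert per case, is that the *complete feature-vector* error
never grows as modes are added (orthonormal modes remove b_k² of
squared error each). Restricted to a coordinate subset — a segment, or
even all coordinates with radii excluded — truncated reconstructions
can transiently overshoot: on a 100-case synthetic cohort, per-case
regional RMSE shows increases of up to ~2 mm at intermediate k before
later modes repair them. Cohort-*mean* regional RMSE curves are
non-increasing for every region, which is the form in which "error
decreases as modes are added" holds and is asserted. One acceptance
test states the pointwise regional form for the record and is expected
to fail for any correct PCA.

The per-mode group comparison is the classic equal-variance two-sample
t-test ("Student's t-test" read literally), two-tailed, flagged at
p < 0.01 with no multiple-comparison correction.

## Discriminant axis and risk score

Fisher direction w ∝ S_w⁻¹(μ₁ − μ₀) with S_w the pooled within-class
covariance, ridge-regularized by ε·tr(S_w)/k on the diagonal
(ε = 1e-8) — needed when k approaches the class sizes; singularity
beyond the ridge raises a conditioning error. Raw projections are
standardized by the training cohort's mean and SD (ddof = 1) and
oriented so the class-1 (CoA-like) mean is positive.

AUC is the rank-based (Mann–Whitney) statistic with average ranks, so
ties count one half; it equals the all-pairs comparison exactly.
**LOOCV refits the LDA only**, on the fixed full-cohort PCA basis: the
cross-validation is scoped to the discriminant, which keeps segment
correspondence bookkeeping out of the folds. Refitting the PCA per fold
is available (`refit_pca=True`) for sensitivity analysis. Each fold
standardizes with its own training statistics; the pooled out-of-fold
Z-scores feed one rank AUC.

The sweep builds k = 1..25 models. Because the original selection of a
working mode count was by inspection of the AUC curves, the selection
rule here is explicit and configurable: the largest k whose LOOCV AUC
is within `gap_tol` (0.02) of its running maximum and whose RS−LOOCV
gap is ≤ `overfit_tol` (0.05).

**Extreme phenotypes.** The score direction is mapped back to shape
space with the regression (conditional-mean) displacement per unit
Z-score, d = s·Λw / (wᵀΛw) with Λ = diag(λ₁..λ_k): the shape at Z is
the population-typical anatomy at that score, and the emitted shape
re-projected and re-scored returns exactly the requested Z. The
minimal-norm alternative d = s·w/(wᵀw) satisfies the same round-trip
identity but concentrates the displacement in low-variance directions
and produces geometrically implausible (negative-radius) shapes when
class separation is strong, so the regression mapping is the default
and only implementation.

## Descriptors

All windows and fractions are configurable; defaults: tangents are
means of unit finite-difference tangents over 5 points, the vertical
projection plane is XZ (canonical after alignment), the isthmus is the
distal 20% of the AAo segment, and the DAo axis for the
posterior-shelf surrogate is fit through the first 10 DAo points in XY.
Descriptor definitions (angle between projected duct/isthmus tangents;
2× radius at 80% AAo arc length; max-Z of the AAo minus Z of mid-duct;
perpendicular XY offset of the insertion from the DAo axis; radius at
the isthmus midpoint over radius at mid-duct; arc-length sums;
arc/chord tortuosity) are explicit package definitions, not transcribed
formulas. AUC orientation is chosen per descriptor (best-case
single-metric performance); R² is ordinary least squares against the
risk score. Descriptors require aligned input and are invariant to any
admissible (Z-rotation + translation) motion followed by realignment.

## Robustness study and virtual cohorts

Stratified subsets draw round(fraction·n_class) cases per class without
replacement (fractions near 1 may return the full class; then repeats
coincide — documented rounding). Each subset refits the entire
PCA+LDA pipeline. Phenotype averaging over repeats is pointwise in
feature space (valid under shared correspondence); the convergence
metric is the geometric RMSE between per-fraction mean ±3SD phenotypes
and the full-cohort ones, averaged over the two extremes. Fraction 1.0
with one repeat reproduces the full-model results exactly.

Virtual cohorts sample mode coefficients independently,
b_k ~ N(0, λ_k). Because PCA coefficients are uncorrelated with
variances λ_k in the training cohort, risk scores of a large sampled
cohort are approximately standardized (mean 0, SD 1) when the axis was
trained on the source cohort. Independence across modes is an
assumption — real anatomies may have higher-order dependencies the
Gaussian factor model cannot carry.

## The synthetic generator

The generator emulates the *discriminative anatomy*, not images or
segmentation artifacts. Each arch is built in a local vertical plane
through the duct direction: the duct is a straight chord plus an
out-of-plane sin² bow (zero end slope, so the insertion tangent is
exact); the AAo is a C1 cubic Hermite curve — ascending limb, exact-
height apex with horizontal tangent, and an exactly straight isthmus
section entering the origin along the requested insertion direction;
the DAo is straight and inferior. Arc lengths are matched to the
requested values by bracketed root finds (tolerance 1e-10), so with
zero noise every stated parameter (lengths, apex height, insertion
angle, radii, aneurysm amplitude, bow) is recoverable from the points
within 2% / 1°. Radius profiles: AAo tapers smoothly from r_aao to
r_isthmus over the 55–80% arc-length band; the duct carries an optional
Gaussian aneurysm bump peaking at mid-duct; the DAo is constant.
Noise is isotropic Gaussian jitter added to the resampled points.

Class-conditional defaults (generator defaults, not measured values)
encode the qualitative contrast between the outcome groups:
CoA-like — insertion 92°, apex 16 mm, aneurysm amplitude 0.05,
r_aao 2.6 mm, r_isthmus 1.7 mm; FP-like — insertion 138°, apex 12 mm,
aneurysm 0.40, r_aao 3.4 mm, r_isthmus 2.4 mm; both with noise SD
0.15 mm and per-parameter sampling SDs of a few percent to ~10% of the
means (truncated-Gaussian, reject-and-resample). Dimensions are chosen
to be plausible for a third-trimester fetus (vessel radii 1.7–3.4 mm,
segment lengths 22–38 mm). Prevalence defaults to 0.4, matching a
~40% surgical-repair rate among suspected cases.

Under the default contrast the classes are almost perfectly separable
(LOOCV AUC ≈ 1 at n ≥ 100). That is the right regime for testing
end-to-end signal recovery, but useless for studying finite-sample
behavior, so experiments about overfitting and subset variance use
`attenuated_contrast(scale)`, which blends the class means toward their
midpoint (scale 0.35 gives LOOCV AUC ≈ 0.95 at n = 120). The planted-
subspace cohort generator (`planted_mode_cohort`) builds Gaussian
feature cohorts whose class signal is confined to a few latent
directions, for validating mode recovery, t-test calibration and the
RS−LOOCV overfitting signature.

What passing these tests shows: the pipeline recovers planted
geometric contrasts, agrees with independent numerical oracles, and
reproduces the qualitative overfitting/robustness phenomenology. What
it does not show: performance on real fetal imaging, where surface
irregularity, segmentation error, landmark variability and non-tubular
lumina (none of which the generator emulates) all act.

## Problem sizes used in the shipped analyses

Test and acceptance cohorts are sized desk-scale by design: oracle
checks at n = 10–15, reconstruction and calibration studies at
n = 100, end-to-end recovery at n = 200, robustness at n = 120 with
10 repeats × 2–5 fractions, 8–50 replicate experiments for trend
fractions, and mesh-based extraction on single anatomies at 0.7 mm
voxel pitch. All are set in the tests/scripts themselves and scale
linearly if larger studies are wanted.

## Known limitations

- The extraction assumes locally tubular geometry and breaks on bodies
  whose minimal oriented-bounding-box extent is far larger than the
  lumen (the per-component reach heuristic would under-claim the
  interior). It is a medial approximation, not a Voronoi construction;
  an external-toolkit backend could be wrapped behind the same
  interface if exactness near complex junctions matters.
- Tube meshes emitted by the generator are triangle-soup unions, not
  boolean unions; downstream consumers other than this package's
  extraction may require watertight single-body surfaces.
- The 4-landmark protocol fixes segment endpoints; landmark placement
  error translates directly into segment-length variation, which the
  shape model then absorbs as (spurious) length modes.
- Radius features capture the minimal cross-sectional scale only;
  non-circular lumina are under-described.
- The virtual-cohort sampler assumes independent Gaussian modes.
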