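# Methods

This note documents the models, conventions and numerical choices behind
fetalmorph, what the synthetic phantoms do and do not emulate, and the
known limitations.

## Geometric conventions

Voxel indices are 0-based; world coordinates follow the NIfTI affine (RAS,
mm). Spacing is derived from the affine column norms; a volume is flagged
isotropic when the spacing spread is below 1e−6 mm. Closed surface meshes
carry outward normals (signed volume > 0), enforced at load and after
marching cubes; this fixes the global sign of the principal curvatures so
that convex structures (gyri) have positive shape index. Default label
codes are background 0, unmyelinated white matter 1, ventricles 2,
cerebellum 3, overridable via a JSON sidecar.

## Volumetry and surfaces

Structure volume is the labeled-voxel count times the voxel volume; no
partial-volume weighting is attempted, so the error scales with
(surface area × spacing)/volume — about 1–2% for brain-sized structures at
0.8 mm. Surfaces come from marching cubes at iso-level 0.5 on the binary
mask (zero-padded so structures touching the array edge still close), with
the largest connected component kept by default to suppress speckle labels.
Smoothing is Taubin's non-shrinking λ|μ filter (λ = 0.5, μ = −0.53, 10
iterations by default): unlike Laplacian smoothing it does not deflate the
mesh, keeping mesh-derived volume consistent with voxel volume (the two
agree within ~3% for structures of ≥1000 voxels; the mesh area of a
voxelized surface still overestimates a smooth surface's area by several
percent, which is why surface-area truth is evaluated against parameterized
surfaces, not voxelized ones). The global shape parameter is surface area /
volume (mm⁻¹); it scales as 1/length, so growth lowers it and folding
raises it.

Gestational ages given as "weeks+days" strings are parsed as W + D/7
decimal weeks. Paired rates are (post − pre)/Δweeks, which presumes a
linear growth trajectory between the two scans; over the ~2-week
post-operative interval this is the conventional approximation, and no
higher-order model is attempted.

## Curvature descriptors

Principal curvatures are estimated per vertex by fitting the osculating
quadric h(x, y) = ax² + bxy + cy² + dx + ey over the 2-ring neighborhood
(configurable) in the tangent frame of the area-weighted vertex normal,
then taking the eigenvalues of the shape operator −I⁻¹II of the Monge
patch. The quadric fit was chosen over cotangent-based discrete operators
because it is markedly more robust on the irregular, near-degenerate
triangles marching cubes produces. Vertices with fewer than 5 neighbors are
flagged invalid. On an icosphere of radius 10 mm the estimator recovers
k₁ ≈ k₂ ≈ 0.1 mm⁻¹ within 5% on essentially all vertices.

Curvedness C = √((k₁² + k₂²)/2) measures bending magnitude and scales as
1/length. Shape index SI = (2/π)·atan((k₁ + k₂)/(k₁ − k₂)) is
scale-invariant and spans cup (−1) through saddle (0) to dome (+1); at
umbilic points (k₁ = k₂) it is defined by continuity as sign(k₁), and it is
masked invalid where C < 1e−4 mm⁻¹ (planar points, where SI is undefined).
Field summaries (mean, median, gyral fraction) are area-weighted with
barycentric lumped vertex areas.

## Spectral correspondence

Longitudinal pre/post surface pairs are matched in three stages.

1. **Rigid CPD.** The post surface's vertices (subsampled to ≤1500 for
   this stage) are registered to the pre surface by the rigid/similarity
   coherent-point-drift EM (Gaussian mixture with uniform outlier weight
   w = 0.1, tolerance 1e−6, ≤200 iterations). Clouds are internally
   centered and RMS-normalized; the returned transform is in world units.
   A deterministic-annealing floor σ₀²·0.9^iter keeps the kernel wide early
   on, which both widens the rotational convergence basin (30° rotations of
   folded surfaces are recovered to machine precision) and suppresses the
   degenerate s→0 attractor of the free-scale model. An optional
   principal-axes multi-start (`init="pca"`) is available for large
   misalignments. Note that GMM registration fundamentally cannot recover
   rotations of *featureless* isotropic clouds — rotational information
   lives in surface structure, which anatomical surfaces have.

2. **Dual-layer joint eigenmodes.** Each surface contributes its cotangent
   Laplacian (half-cotangent edge weights, degenerate negative weights
   clamped to a small positive floor to preserve PSD-ness) with barycentric
   lumped mass. Mutual nearest neighbors after CPD provide inter-layer
   links, weighted γ = 1 relative to the mean intra-layer edge weight. The
   joint generalized eigenproblem yields shared modes, sign- and
   order-consistent across layers by construction. All mutual-NN links are
   kept by default: experiments showed that linking only a small fraction
   of vertices (e.g. a tenth) lets antisymmetric modes — opposite sign
   across layers — into the retained low band, which destroys
   nearest-neighbor matching; with dense links those modes are pushed above
   the band and self-matching is exactly the identity.

3. **Matching and transfer.** Each post vertex is matched to its nearest
   pre vertex in the combined feature space of the k = 30 lowest
   non-constant joint modes (scaled 1/√λ) and the CPD-aligned coordinates
   (normalized to the spectral feature scale). Scalar fields are pulled
   back post→pre by nearest-neighbor assignment (lowest match cost wins;
   pre vertices selected by no post vertex inherit the value of the nearest
   matched pre vertex), so transferred values never extrapolate beyond the
   source range. Per-vertex change maps are post − pre.

On ten seeded longitudinal phantom pairs (~10% volume growth plus fold
deepening over 2 weeks) the recovered correspondence coincides with the
ground-truth identity parameterization to well under one edge length.

## Parcellation and biometry

Lobe labels ({L,R} × {F,T,P,O}) are transferred from any fully labeled
reference mesh by rigid CPD alignment plus nearest-neighbor assignment,
followed by a one-pass closed-1-ring mode filter that removes isolated
labels (ties keep the incumbent label, making the transfer idempotent).
This replaces deformable atlas registration, which requires external atlas
data; transfer accuracy is instead validated against the phantom's analytic
8-sector labels (≥95% agreement after rigid perturbation). Regional
statistics are area-weighted; empty regions are flagged missing rather than
reported as zero.

Biometry is landmark-driven: TCD and VW are Euclidean distances between
their landmark pairs (plane selection is encoded in landmark placement);
CHL is the signed perpendicular distance of the lowest cerebellar point
from the foramen-magnum plane with the normal oriented caudally, so
positive values mean herniation below the plane and post-operative
improvement is a decrease; CSO is the angle between the clivus and
supraocciput direction vectors as drawn, reported in [0°, 180°] without
folding to ≤90° because the anatomical angle can be obtuse — consequently
reversing a drawn line's direction maps the angle to 180° − θ, which is the
documented convention rather than an order-independence property.

## Synthetic phantoms

The phantom emulates the *segmented geometry* of a fetal brain at
mid-gestation, not its MRI appearance: an ellipsoidal white-matter
compartment (default semi-axes 30 × 25 × 20 mm, about 60 cm³ with the
enclosed ventricle), an interior ventricular ellipsoid (scale 0.35 of the
brain axes), and a separate posterior-inferior cerebellar ellipsoid. The
outer surface is modulated radially by a band-limited sum of real spherical
harmonics of a single degree (default 6) with seeded random coefficients,
normalized to unit peak so `fold_amplitude` is a world-mm amplitude;
amplitudes up to min(semi-axes)/2 cannot self-intersect. Because the
surface is radially parameterized over the unit sphere, exact reference
values are available: compartment volumes by closed form (ellipsoids) and
by Gauss–Legendre × trapezoid quadrature of the exact radial integral
(folded surface, 160 × 320 nodes — converged far beyond the voxelization
error it calibrates), surface area from a subdivision-5 parameterized mesh,
and vertex-level ground-truth correspondence for longitudinal pairs, which
share one fold pattern that grows only in amplitude.

Voxelization at the default 0.8 mm isotropic spacing (the resolution of
modern super-resolution fetal reconstructions) recovers the truth volumes
within 2% on all three structures.

A geometric note on gyrification summaries: the unfolded phantom is convex
everywhere, so its gyral (SI > 0) area fraction starts at exactly 1 and
*falls* as folding carves sulci, and no sulcal area exists at all until the
fold curvature exceeds the base-ellipsoid curvature (≈1.5 mm amplitude at
degree 6 on this geometry). Strictly monotone folding measures across
amplitudes {0…4} mm are therefore the area-weighted mean curvedness
(increasing) and the area-weighted mean shape index (decreasing from its
ceiling), both with |Spearman| = 1 exactly; the sulcal fraction is
monotone only above its onset threshold. Real fetal brains are not convex
at baseline, so on patient data the gyral fraction need not saturate this
way.

### Synthetic cohorts

`generate_cohort` draws a case–control study shaped like a fetal-surgery
cohort: n operated subjects imaged pre (≈23.9 ± 1.0 weeks) and ≈2.4 weeks
post surgery, plus pair-matched early (≈23.3 weeks) and late (≈28.9 weeks)
control fetuses imaged once each; an early/late control pair shares one
growth trajectory so paired per-week rates exist for controls too.
Structure volumes follow linear growth with lognormal per-week rates
located at published control-range magnitudes (ventricles: median
648 mm³/week, log-σ 0.327 ≈ IQR 371–896; the default operated arm carries
median 3699 mm³/week, log-σ 0.438), with 2% multiplicative measurement
noise; baselines at 23 weeks default to 5000/60000/2500 mm³ for
ventricles/white matter/cerebellum. Per-lobe shape-index trajectories rise
by default 0.012/week, with the operated arm regionally elevated (left
temporal 0.039, left parietal 0.032, right occipital 0.027 per week).
`EffectConfig.null()` removes every group difference — these are the
conditions under which the pipeline's type-I error is calibrated (the
ventricular-rate Kruskal–Wallis rejects in ~4–6% of 200 null cohorts at
α = 0.05) — and `with_ventricular_effect_sd(5)` injects a location shift of
five control-rate standard deviations, detected with power ≥ 0.95 over 100
replicates at n = 12 + 12. Every subject carries a phantom spec derived
from its volumes, so any row can be materialized as a voxel phantom; the
statistical simulations run on the tabulated metrics without voxelizing
every subject, which is what keeps 300 cohort replicates within seconds.

What the phantoms do **not** emulate: MRI intensities, noise or
segmentation error beyond the measurement-noise term; skull/extra-axial
CSF; the Chiari-II hindbrain descent geometry; multi-compartment
ventricular subdivisions (CSP/cavum vergae are merged); non-ellipsoidal
baseline anatomy. Passing tests therefore demonstrate correctness of the
measurement and matching machinery under known geometry and growth — not
robustness to segmentation artifacts or pathology-specific shape.

## Statistics

Small fetal cohorts (n ≈ 12/group) are typically non-normal, which the
Anderson–Darling test (case: estimated mean and variance, small-sample
corrected critical values, α = 0.05) is used to confirm; group comparisons
then use the Kruskal–Wallis H test with tie correction. The default p-value
is the χ² approximation (df = groups − 1); an exact permutation p
(enumeration of all assignments, intended for total n ≤ 12; 70 assignments
for two groups of 4) is available because n = 12 sits near the
approximation's comfort zone — in the decision-relevant tail the two agree
to well under 0.02. Descriptives are medians with 25th–75th percentile IQRs
using type-7 (linear interpolation) quantiles, recorded in the report
metadata. Pearson correlations carry strength labels binned on |r| with
boundaries assigned upward (0.5 → moderate) so labeling is deterministic;
the sign is reported separately. No multiple-testing correction is applied,
matching common practice in these exploratory cohorts; report consumers
should treat the per-metric p-values accordingly. Group contrasts default
to operated-pre vs early controls, operated-post vs late controls, and
operated vs control paired rates; the contrast set is configurable and all
configured contrasts are emitted.

## Numerical choices and degenerate inputs

- Eigen-solves use shift-invert Lanczos (σ = −1e−3) with a fixed constant
  start vector, making embeddings deterministic for a given mesh.
- Eigenvector sign is fixed by making the largest-magnitude entry positive.
- Cotangent weights from degenerate triangles are clamped to ≥1e−8;
  a combinatorial Laplacian remains available.
- Zero-area faces contribute nothing to area sums (with a warning);
  repeated-index faces are rejected at construction.
- Disconnected meshes raise by default (`require_connected=False` to
  override); constant samples raise in the normality and correlation
  routines; identical pooled values give H = 0, p = 1.
- Problem sizes in the validation suites — subdivision-3 surfaces
  (642 vertices) for matching, ten longitudinal pairs, 200 null and 100
  effect cohorts — were chosen as the smallest sizes at which the measured
  quantities are stable to well within the asserted tolerances.

## Known limitations

- Correspondence is evaluated on phantoms whose pre/post surfaces share a
  parameterization; real longitudinal pairs have no ground truth, and JSM
  accuracy there is bounded only by the self- and rigid-match properties.
- Mesh surface area of voxelized structures inherits marching-cubes bias;
  comparisons between subjects scanned at the same resolution are
  consistent, absolute areas are resolution-dependent.
- The lobe parcellation is as good as the supplied reference; no deformable
  registration is performed.
- Landmark placement is upstream of the package (manual in practice,
  constructed on phantoms); biometric accuracy is limited by it.
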