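# Methods

## Measurement model

All measurements operate on a triangulated surface in millimetres with
per-vertex anatomic regions and three manually supplied landmarks C, D,
E on the articular margin. Nothing assumes a global pose: every derived
axis, plane and scalar is built from the mesh and landmarks themselves,
so the pipeline is equivariant under rigid motion (verified by property
tests to ~1e-3 relative for the full pipeline, 1e-6 for the geometric
primitives).

**Shaft axis.** The upper shaft is modelled as a circular cylinder. The
fit minimises the sum of squared radial residuals Σ(dᵢ − r)² over five
parameters (two orientation, two position, one radius) with a
Levenberg–Marquardt solver, initialised from the principal component of
the shaft point cloud (the shaft is strongly elongated, so this start is
reliable); tolerances 1e-10, at most 200 iterations. On noiseless
cylinder samples the axis is recovered to < 1e-6 degrees and the radius
to < 1e-6 mm. Degenerate inputs are rejected: fewer than 6 points,
coplanar clouds (a flat ring constrains no axial direction), or axial
extent below half a radius. The axis sign is canonicalised toward the
articular centroid so "superior" is well defined.

**Planes and derived landmarks.** Plane 1 (anatomic neck) passes through
C, D, E with its normal oriented toward the articular centroid, making
head-side distances positive. The phrase "plane 2 via G parallel to the
transverse axis of the shaft" is geometrically underdetermined (every
transverse direction is perpendicular to the shaft axis); plane 2 is
therefore taken perpendicular to the shaft axis through G, which makes
TSH a difference of axial coordinates — the only reading under which TSH
is well defined. Similarly the "vertical plane through the midpoint of
CD" (plane 3) is taken with normal parallel to CD, so that
plane 1 ∩ plane 3 is the in-plane neck diameter perpendicular to CD.
Both readings are recorded assumptions. Argmax landmarks (F, G, H)
resolve ties by lowest vertex index, so results are deterministic; each
equals exhaustive search over the labelled vertices by construction and
by test. I and J come from sectioning the articular-labelled faces with
plane 3 and taking the extreme section points along the
plane 1 ∩ plane 3 line; for a cap that touches plane 1 only at its rim
this lands on the rim crossing edges, with O(h²/R) error at mesh edge
length h.

**Simulated radiographs.** A film is modelled as orthographic projection
onto the coronal plane followed by a uniform magnification factor
(default 1.10, a typical shoulder AP film value given the
humerus-to-detector distance). An orthographic projection can only
shorten distances, so magnification is what gives the radiographic
measurements their systematic positive size bias against 3-D values;
angles are unaffected. Beam divergence across the field, patient
positioning and film calibration are not modelled — in particular the
small positive NSA offset real films show (a positioning effect) is not
produced by this projection model, and the cohort simulator draws the
radiographic NSA from its reported film distribution instead. The 2-D
shaft axis is the least-squares midline of the left/right shaft
silhouette edges (20 height bins over the central shaft window); the
neck segment is the projected C–D chord; NSA₂ = 90° plus the acute angle
between them.

## Synthetic humerus

The generator emulates the surface a CT segmentation would produce:
cylinder shaft (radius 12.5 mm, length 60 mm) along +z, an articular cap
of radius R cut by the neck plane at distance d from the head centre and
inclined α to the shaft axis, an anteroposterior scale factor s applied
to the head (s = 1 is a sphere), a conical metaphyseal fillet joining
rim to shaft, and a greater-tuberosity bump on the lateral fillet whose
apex is pinned exactly `tuberosity_height_offset` below the articular
apex. The fillet carries no region label, so it cannot perturb argmax
landmarks. Closed-form truth: NSA = α + 90°, HHT = R − d,
cASD = 2√(R² − d²), aASD = s·cASD, TSH = the tuberosity offset. C, D, E
and the cap pole are exact mesh vertices, so NSA/HHT/cASD are recovered
to numerical precision at any resolution; aASD and TSH carry the
discretisation error (≲ 0.01 mm at the default 0.5 mm edge length,
comparable to a 0.625 mm CT reconstruction interval). The ring count is
kept ≡ 2 (mod 4) so no vertex falls exactly on the axial section plane.
Meshes are watertight with consistent outward winding, and generation is
deterministic (identical parameters give identical bytes).

The default parameters are the mean anatomy of the reference
population: NSA 132.1°, HHT 18.8 mm, cASD 44.2 mm, aASD 40.4 mm,
TSH 7.2 mm, inverted to (R ≈ 22.39 mm, d ≈ 3.59 mm, α = 42.1°,
s ≈ 0.914). The inversion is exact: ρ = cASD/2 and HHT = R − d give
R = (ρ² + HHT²)/(2·HHT). Parameter draws that violate the geometry
(tuberosity apex at or above the rim point C, which needs
TSH > R(1 − cos(β_rim − γ)) plus one fillet ring) are clamped to the
boundary; the generated bone's own truth record is always authoritative.

## Cohort and rater simulation

Per-sex parameter vectors (NSA, TSH, HHT, cASD, aASD) are drawn from
multivariate normals with the reference per-sex means/SDs
(54 M / 66 F) and the reported 3-D correlation matrix (e.g.
r(cASD, aASD) = 0.907); the matrix is repaired to positive definite by
eigenvalue clipping if a user-supplied spec needs it. Radiographic
values are drawn conditionally on their 3-D counterparts from the
reported film distributions with a within-subject modality correlation
of 0.8 — a deliberate choice (the coupling is not reported anywhere);
it affects the paired-test power but not the means or the bias
direction. Rater replicates follow a two-way crossed model,
value = subject truth + rater effect + residual, with residual SD set to
1/3.2 of each parameter's pooled SD in 3-D and 1/2 on film, and rater SD
1/10 and 1/8 respectively — chosen once so simulated ICCs land in the
reported ranges (3-D ≈ 0.88–0.94, film ≈ 0.74–0.86). The simulated
campaign mirrors the study design: every subject measured once by the
main examiner, a 36-subject random subset re-measured after an interval
and once by each of two further examiners.

Two composition effects are worth knowing when reading simulated
tables. Pooling the two sexes raises the latent cASD–aASD correlation
above its within-sex value (the sex mean differences are strongly
aligned): within-sex 0.907 becomes ≈ 0.95 in the pooled mixture. Rater
noise then attenuates any *measured* correlation by
√(reliability² ) ≈ 0.90, so the simulated measured pooled r comes out
near 0.87 ± 0.02 at n = 120 — the same latent-vs-measured chain a real
single-examiner table embodies.

What the generator does **not** emulate: real cortical geometry and
surface texture, segmentation artefacts, inter-observer disagreement in
*placing* C/D/E (landmarks are exact), population asymmetry or
non-normality, and radiographic positioning effects. Passing tests
therefore demonstrate correctness of the measurement constructions and
statistics under the stated geometric and distributional model, not
clinical accuracy on patient data.

## Statistics

Sex comparisons use pooled-variance (not Welch) independent-samples t
tests — recomputing the reference summary table from its printed
per-sex mean/SD/n reproduces the printed t-values only under pooled
variance, which identifies the variant used. Modality comparisons are
paired t tests; correlations are Pearson with the t-transform p-value;
normality screening is Kolmogorov–Smirnov with the Lilliefors
correction, since the null normal's parameters are estimated from the
sample. No multiple-testing adjustment is applied (α = 0.05
throughout). ICC is ICC(2,1) — two-way random effects, absolute
agreement, single measures — for both the intra-observer design
(sessions as columns) and the inter-observer design (three raters as
one joint table), with the standard F-based confidence interval; the
estimator is delegated to `pingouin` and cross-checked in the tests
against the hand-computed mean-squares formula. Reliability-subset
planning follows Bonett's large-sample variance
2(1−ρ)²(1+(k−1)ρ)²/(k(k−1)(n−1)): the sample size is the smallest n
whose expected CI width meets the target, found by scanning n (verified
against brute force).

## Numerical choices and problem sizes

Degeneracy thresholds are 1e-9 in mm-scaled coordinates throughout
(collinear landmarks, parallel planes, zero-length directions).
Zero-variance comparisons flag an infinite t (p = 0) rather than raising.
The acceptance evaluation uses 20 bones at 0.5 mm resolution for
parameter recovery, 30 replicates at n = 500 for ICC bias and 200
replicates at n = 36 for CI coverage, and 12 bones at 1.2 mm for the
modality-bias check; these sizes give Monte-Carlo error comfortably
below the tolerances being checked while keeping a single-CPU run in
tens of seconds.

## Known limitations

* Landmarks C/D/E are inputs; no automatic detection on clinical meshes.
* The projection model omits magnification calibration, beam divergence
  and positioning, so film-specific offsets beyond uniform scaling
  (notably in NSA) are reproduced distributionally, not mechanistically.
* The ICC model form used by the original SPSS analysis is not
  identifiable from the published values; ICC(2,1) is a fixed choice.
* The glenoid and bilateral comparisons are out of scope.
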