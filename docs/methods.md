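# Methods

This note documents the models implemented in `neolaminar`, the choices
made where the design was genuinely open, and what the synthetic phantom
does and does not establish about real data.

## Equivolumetric depth surfaces

Cortical layers keep a roughly constant *volume* fraction across folds,
while their Euclidean spacing compresses toward the white matter in gyri
and toward the pial surface in sulci. The construction therefore places
intermediate surfaces at equal volume fractions, modelling the column
above each vertex as a frustum whose cross-sectional area interpolates
linearly from the white-side vertex area to the pial-side vertex area.
Curvature enters only through that area ratio; no curvature tensor is
computed. Vertex areas are barycentric (one third of each incident
triangle), which conserves total surface area exactly.

Choices and caveats:

* **Depth grid.** Default is 12 fractions equally spaced on [0, 1]
  *inclusive* of both boundaries (index 1 = pial, 12 = white, so larger
  μ₁ always means deeper signal balance). `boundary=False` switches to
  the interior grid `(d − 0.5)/12` for users who want to avoid
  partial-volume contamination at the boundary surfaces.
* **Near-equal areas.** The closed form cancels catastrophically when
  `A_out ≈ A_in`; below a relative difference of 1e−9 the exact flat-sheet
  limit `ρ = α` is used.
* **Linear-area error.** On a concentric-sphere shell the true area grows
  quadratically with depth. The resulting inequality of true shell
  volumes is below 2% when shell thickness is ≲25% of the curvature
  radius (the cortical regime) and reaches ~4% on an extreme shell whose
  thickness is half its inner radius; the test suite pins both numbers.

## Sampling and central moments

Sampling is trilinear (8-voxel weighted average) under the convention
that voxel centres sit at integer 0-based voxel indices and the NIfTI
affine maps indices to world mm; this makes the voxel-centre identity
exact and trilinear interpolation exact on affine intensity fields.
Vertices whose interpolation support leaves the array are masked, never
clamped or zero-filled — silent zeros would corrupt the moments.

A profile is reduced to the mean (μ₁) and standard deviation (μ₂) of the
depth distribution obtained by treating intensities as frequencies over
depth bins 1..12. μ₂ keeps the conventional name "variance" from the
histology-derived profiling literature but is reported on the SD scale.
Depth units are bin indices, not millimetres: moments are then invariant
to cortical thickness and to positive intensity rescaling, which is what
makes the T1w/T2w ratio (whose absolute level carries transmit-field
bias) usable across subjects. Negative sampled intensities are rejected
by default (`clamp_negative` opts into clipping at zero) because silent
clamping changes moments.

Parcel aggregation averages profiles first and takes moments of the
parcel-mean profile (moments of a mean, not mean of moments); vertex
masking precedes averaging. One mathematical point is worth stating
plainly: the flat profile does *not* globally maximize μ₂ over all
nonnegative profiles with fixed sum (mass split between the two extreme
depths reaches the upper bound 5.5). The statement "flatter profile ⇔
higher μ₂" holds along the flat-vs-peaked axis that real profiles occupy,
and the tests assert exactly that (widening a symmetric mid-depth peak
monotonically raises μ₂ toward the flat value).

## Developmental models and inference

Per parcel, ordinary least squares with an intercept, a two-sided t test
on the term of interest with n − k degrees of freedom, and no robust
errors. Postmenstrual age (PMA) equals gestational (GA) plus postnatal
(PNA) age exactly, so model specs containing all three are rejected as
perfectly collinear. The GA×PNA interaction uses mean-centred ages, so
its t value is invariant to shifting either age axis. Multiplicity is
handled by Benjamini–Hochberg step-up at α = 0.025 (two moments are
tested, keeping the family-level rate at 0.05); the FDR family is the
analyzed parcels of one (moment, term, model) triple — the narrowest
defensible family — and is configurable. Model comparison reports AIC,
R², adjusted R², and F tests for strictly nested predictor subsets;
thickness-augmented models are the same engine with one more column.

Fits are computed from the closed-form normal equations, vectorized
across parcels that share a design matrix; a unit test pins coefficient,
SE, t, p, R² and AIC agreement with an independent OLS implementation to
10 significant digits. Numerically perfect fits (residual sum of squares
at round-off level) are snapped to zero so that a constant response
yields t = 0 rather than a 0/0 artifact.

## Geometric eigenmodes

Linear (P1) finite elements on the triangle mesh: cotangent stiffness
matrix (rows sum to zero) and *consistent* mass matrix (entries sum to
the surface area); a lumped-mass option exists for comparison. The
generalized eigenproblem is solved in shift-invert mode with a fixed,
generic start vector — without it the solver returns an arbitrary basis
of degenerate eigenspaces (the sphere's l-multiplets) and runs would not
be reproducible. Eigenvector sign is fixed by making the largest-|·|
loading positive (ties → lowest vertex index). Mode numbering is
1-based with mode 1 constant, so "modes 2–4" are indices 2, 3, 4. On a
unit sphere the spectrum obeys λ = l(l+1) with multiplicity 2l+1; the
subdivision-4 icosphere reproduces eigenvalues 2–9 within 0.3%.
Eigenmodes are computed on the phantom's own midthickness mesh; with
real data one would typically use a population-template surface, and the
two are not asserted equivalent.

## Spin permutation inference

One map is carried along uniform random rotations of its spherical
projection (Haar sampling via QR of a Gaussian matrix with sign and
determinant correction) and reassigned to vertices by exact nearest
neighbour; the correlation with the unrotated second map is recomputed
per rotation. The test is two-tailed with the add-one rule
`p = (1 + #{|r_null| ≥ |r_obs|})/(1 + n_perm)`, so the smallest
achievable p is 1/(n_perm + 1). Missing vertices (excluded parcels,
medial wall) are dropped pairwise per permutation by default; a
nearest-valid-source variant is available. The phantom is a single
closed surface, so no hemisphere pairing or mirroring is implemented.
Under isotropic smooth null maps the p distribution is uniform (KS-tested
in the suite). Eigenmode variance decomposition regresses the effect map
on mode-loading subsets (default all subsets of {2, 3, 4}) over valid
vertices and reports R², which is monotone over nested subsets.

## The synthetic phantom

**Cohort.** GA is a two-component truncated normal mixture — preterm
(27%, centre 33 w, SD 3.5 w, truncated to [23, 37)) and term (centre
39.6 w, SD 1.6 w, truncated to [37, 42.3]) — giving the long left tail of
a mixed neonatal sample (median ≈ 38.9 w). PNA is a monotone transform
of a latent Gaussian into an exponential quantile function truncated to
[0, 7] weeks (scale 1.24 w, median ≈ 0.86 w, most scans in the first
postnatal week). The latent coupling between the two is root-found per
draw so the *sample* GA–PNA Pearson correlation equals the target
(default −0.43: preterm infants are scanned later after birth); this
calibration is part of the generator's contract, deterministic per seed.
Sex is a balanced 0/1 code; PMA = GA + PNA exactly. Optional thickness
grows mildly with PMA around 1.1 mm.

**Geometry.** The white surface is an icosphere (default radius used in
the validation experiments: 8–28 mm depending on the check; a scaled-down
hemisphere) perturbed radially by a smooth random degree-≤2 harmonic
(±3% by default); the pial surface lies a 2 mm thickness field further
out along each ray. Because the perturbation is an analytic function of
direction, every voxel's fractional depth between the surfaces is known
in closed form — sampling error is measurable independently of mesh
processing. Parcels are Voronoi cells of k-means centres on the sphere
(contiguous by convexity). The voxel grid is 0.5 mm isotropic, matching
super-resolution neonatal processing.

**Signal.** Each parcel group has a 12-depth template: a baseline rising
gently toward the white matter (1.0 → 1.5, mimicking the myelin-driven
T1w/T2w depth gradient) plus per-depth linear effects of GA, PNA, sex
and optionally GA×PNA, evaluated at the voxel's analytic depth with
linear interpolation, plus i.i.d. Gaussian voxel noise (default SD 0.1,
~7% of baseline). The default recovery experiment plants a GA slope of
+0.02 intensity/week at depths 9–12 and a PNA slope at depths 1–4 in
half the parcels (odd labels), leaving the rest null.

**Boundary handling.** Outside-ribbon voxels continue the template's
edge value by default (clamped depth), with explicit CSF/WM constants
available. The gray/white boundary of real tissue is not sharp and
partial-volume correction is known to have little effect on central
moments; the clamped default lets the noiseless fidelity check measure
geometric sampling error specifically rather than boundary mixing.

**Interior-vertex margin.** Trilinear sampling mixes voxels within about
one voxel of each sample point, so vertices near a parcel border pick up
the neighbouring parcel's template. The recovery experiments therefore
restrict parcel averaging to vertices ≥1 mm (two voxels) from the
nearest Voronoi boundary (`PhantomGeometry.interior_vertex_mask`);
without the margin, effect leakage across borders makes genuinely null
parcels test significant. Real-data analyses face the same issue at
atlas boundaries; the margin utility is exposed for that reason.

## Validation scale and what it shows

The simulations in the test suite and acceptance script use problem
sizes chosen to exercise every code path at desktop scale: recovery runs
100 cohorts of n = 150 on a subdivision-3 sphere (642 vertices, 33
parcels, 10 mm radius); FDR calibration uses 500 null replicates × 66
parcels; spin calibration 200 map pairs × 500 rotations on 162 vertices;
the noiseless fidelity check uses a 28 mm-radius ribbon on the full
0.5 mm grid (133³ voxels). Passing these establishes internal
correctness — closed forms, calibrated error rates, sign and location
recovery, determinism — not neuroscientific claims: the phantom has no
folding beyond smooth radial perturbation, no acquisition physics (bias
fields, motion), spatially white noise, and linear age effects by
construction. Results on real cohorts additionally depend on
registration, surface reconstruction and atlas quality, which are out of
scope here.

## Known limitations

* Equidistant (non-equivolumetric) surfaces exist only as the flat-sheet
  degenerate case; no alternative depth models.
* Higher profile moments (skewness, kurtosis) and profile-covariance
  analyses are not implemented.
* No mixed-effects or nonlinear age models; the design is cross-sectional.
* Spin tests assume a spherical projection exists; no variogram-matching
  null alternative.
* `lapy`-style volumetric or graph-Laplacian modes are out of scope; the
  eigenmode solver is surface-FEM only.
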