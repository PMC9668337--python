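# Methods

## Spectral shape descriptors

The Laplace–Beltrami operator on a closed 2-manifold generalizes the
Laplacian to curved surfaces; its Helmholtz eigenproblem `Δf = −λf` has a
discrete spectrum `0 = λ₁ ≤ λ₂ ≤ …` whose values depend only on the
intrinsic geometry. The package discretizes the weak form with Lagrange
finite elements on the triangle mesh:

- **Linear (P1) elements** (default): the classical cotangent stiffness
  matrix with the consistent (non-lumped) mass matrix. The stiffness
  annihilates constants and the total mass equals the surface area; both
  properties are asserted in tests.
- **Cubic (P3) elements**: 10 nodes per triangle (vertices, two per edge,
  one interior). Shape functions come from the degree-3 monomial basis
  through the inverse Vandermonde at the reference nodes; reference
  stiffness/mass integrals are evaluated once with a Duffy-transformed
  8×8 Gauss–Legendre rule, which is exact for the polynomial integrands.
  Cubic elements converge faster for a given mesh but triple the node
  count; for area-normalized low-order eigenvalues the linear solution
  converges to the same values under refinement (verified by the
  refinement tests), so P1 is the dependency-light default.

**Eigensolve.** The generalized problem `K f = λ M f` is solved in sparse
shift-invert Lanczos mode. The shift is a small *negative* multiple of the
spectral scale, `σ = −10⁻³ · trace(K)/trace(M)`: a negative shift keeps
the factorized matrix definite despite the zero mode, and scaling it to
the spectrum keeps the factorization well-conditioned for meshes of any
physical size (a fixed absolute shift would degenerate for
brain-scale meshes whose eigenvalues are ~10⁻⁴ mm⁻²). `k+2` values are
requested and extras discarded. Systems with ≤ 600 nodes use a dense
solve. Degenerate eigenvalues are returned ascending with stable ties;
individual eigenfunctions within a degenerate subspace are
solver-dependent and not part of the public contract. The zero-mode check
is `λ₁ < 10⁻⁶ · λ₂`.

**Accuracy observed on the analytic sphere oracle** (eigenvalues
`L(L+1)/R²`, multiplicity `2L+1`): the first 50 P1 eigenvalues of a
10 242-vertex icosphere are within 0.6 % of the analytic values, and the
least-squares slope of the area-normalized spectrum over indices 100–300
is within 4 % of the Weyl constant 4π. Note the faceted mesh is an
inscribed polyhedron, so its area and volume slightly undershoot the
smooth sphere's; spectra are compared as meshes, not as idealized spheres.

## Size normalization

Two normalizations are provided:

- **Area** (the default for asymmetry work): `λ′ = area · λ`, exactly
  equivalent to dividing vertex coordinates by √area, since scaling
  coordinates by s scales eigenvalues by 1/s². This makes spectra of
  same-shape objects identical regardless of size and aligns all spectral
  slopes at 4π.
- **Volume**: `λ′ = v^{2/D} λ`. For a surface bounding a solid, the
  natural reading of v is the *enclosed 3-D volume* with D = 3, and that
  is the default here. The distinction matters: volume normalization
  equalizes volume but not area, so spectral slopes still differ between
  shapes — the synthetic ellipsoid test reproduces exactly this contrast.
  (Reading v as the 2-manifold's Riemannian volume — its area, D = 2 —
  would collapse the two normalizations into one, contradicting their
  observed difference; the enclosed-volume reading is therefore used and
  documented.)

The SAS is defined **only** on area-normalized spectra; passing other
normalizations is an error rather than a warning, because size
independence is the point of the signature. The "overall asymmetry" of a
SAS vector is provided in both signed-sum and absolute-sum variants —
they answer different questions (net direction vs overall level) and
neither is privileged.

For the regional (non-spectral) asymmetry indices, the revised index
subtracts the subject mean M — computed over the union of both
hemispheres' regions — from each side before forming the classical
`(l−r)/(½(l+r))` ratio, which cancels the additive whole-brain term that
survives in the traditional index. Regions whose recentred denominator
vanishes are flagged undefined and reported, not dropped silently.

## Eigen-groups and wavelengths

On a sphere, eigenvalues come in degenerate groups of size 2L+1 per
spherical-harmonic degree L; a genus-0 surface inherits this indexing as
a scale decomposition (group L spans 1-based indices `L²+1 … (L+1)²`;
groups 0–11 hold the first 144 eigenvalues). The group wavelength is the
spherical approximation `W = 2πRs/√(L(L+1))` with Rs the equivalent-
sphere radius `√(area/4π)`; wavelengths are kept unrounded internally and
rounded only for display. Eigenvalue indexing is 1-based everywhere in
the public API, with index 1 the zero mode.

## Identifiability

Features (spectra or SAS vectors) from two sessions give an N×N Pearson
correlation matrix; Glass's Δ standardizes the within/between-subject
separation by the SD of the between-subject (control) population —
appropriate because the two populations have very different spreads. The
off-diagonal population is all N²−N entries of the (non-symmetric)
matrix, SD with ddof = 1.

The constant first feature (λ₁ ≈ 0, SAS₁ ≈ 0) is excluded from
correlations by default: it carries no variance and distorts small-k
Pearson values; a flag restores the literal first-k convention, in which
k = 2 produces degenerate two-point correlations of ±1 (flagged in the
result). Sweep peaks break ties toward the smallest k — the coarsest
scale — favouring parsimony. The permutation test shuffles the t2 subject
order and recomputes the *peak* of the full sweep each iteration; because
shuffling only permutes matrix columns, the prefix-correlation stack is
computed once and each of the 1000+ permutations costs O(K·N). p-values
are reported both as the raw proportion (which can be 0) and with the
(count+1)/(n+1) correction, the corrected value being the default for
inference. A rank-1 identification accuracy is available as a
supplementary output only; the continuous score is the primary metric.

## Permutation GLM, CCA, multiplicity

The GLM permutation test uses the Freedman–Lane scheme: the
covariates-only residuals of the outcome are permuted and the coefficient
of the residualized predictor recomputed. (Shuffling the raw predictor
instead is anti-conservative when the predictor is collinear with
covariates — this failure mode was observed directly and is covered by a
regression test.) Permutations exchange whole family blocks among blocks
of identical size, never splitting a family; singleton blocks reduce to
unrestricted permutation. Handedness-type predictors are treated as
continuous by default, with optional categorization at ±70 or ±50.

The CCA pipeline reduces the behavioural block to the fewest standardized
principal components reaching 80 % explained variance (complete cases
required), then computes canonical correlations classically — QR of each
centred block, SVD of `Qx'Qy` — which makes them exactly invariant to
invertible affine transforms of either block. Mode significance uses a
max-statistic permutation: each iteration permutes behavioural rows by
whole family blocks and records the largest canonical correlation (Roy's
largest root); each observed mode is compared to that null with step-down
monotonicity enforced. Loadings are structure correlations of the inputs
with the first canonical variate; whole-block bootstrap gives SEs, normal
z-tests and BH-FDR within each side. Covariate adjustment in the CCA is
optional and off by default. Type-I error of both procedures is verified
to sit inside the binomial 95 % interval at α = 0.05 over 500 null
simulations.

## Twin variance components

Phenotypic variance is decomposed into additive genetic (A), common
environmental (C), twin-specific environmental (T) and unique
environmental (E) parts by maximizing the per-family multivariate-normal
likelihood with expected covariances: MZ co-twins `a²+c²+t²`, DZ co-twins
`½a²+c²+t²`, twin–sibling and sibling–sibling `½a²+c²` (MZ–sibling and
DZ–sibling covariances are modelled identically, the standard choice; T
applies equally to MZ and DZ pairs). Components are bounded ≥ 0
(L-BFGS-B, two starting points); likelihood evaluation groups families by
pattern so each covariance is factorized once per evaluation. Boundary
constraints make likelihood-ratio tests of A and C conservative; no 50:50
mixture correction is applied, matching common practice. AIC is
`2·(free parameters) − 2·loglik` counting the mean; ties go to the
simpler model. The AIC selection runs over the seven-model family ACTE,
ACE, ATE, CTE, TE, CE, E; the LRT comparator may fall outside it (e.g.
testing A when the best model is E compares E against AE) so that the
"with and without the parameter" comparison is always defined. The
pipeline applies the strict IQR rule (`Q1−1.5·IQR < v < Q3+1.5·IQR`),
age/sex residualization, per-feature fits with failures isolated, and
BH-FDR across features; full-ACTE estimates are emitted alongside the
selected-model estimates for robustness comparison. For twin pairs with
several non-twin siblings one sibling is kept at random (fixed seed).

## Synthetic generators: what they emulate, and what not

Surface cohorts start from a subdivided icosahedron (default subdivision
4, 2 562 vertices — enough for ~150 accurate eigenvalues at seconds per
solve) and displace vertices radially by random real-spherical-harmonic
fields, so injected signal has a controllable spatial scale aligned with
the eigen-groups. Each hemisphere mesh is

    base sphere × (1 + subject field + hemisphere field + session field),

with the subject field shared across hemispheres and sessions, the
hemisphere (asymmetry) field stable across sessions, and session noise
drawn fresh. The right hemisphere is the mirror image (one coordinate
negated, winding fixed) of the displaced base, giving the SAS an exact
zero reference: with asymmetry and session amplitudes zero the
hemispheres are mirror-isometric and the SAS vanishes to solver
tolerance. Default amplitudes (3 % subject, 1 % asymmetry, 0.3 % session,
signal at degrees 1–6, noise through degree 10, radius 67 mm) represent a
strong-signal test-retest regime: within-subject spectral correlations
far above between-subject ones.

These surfaces are *not* cortices: no folding, no sulcal anatomy, no
hemispheric torque, and their spectra are small perturbations of the
degenerate sphere spectrum. Passing tests therefore demonstrate that the
machinery recovers known signal scales, calibrates its null distributions
and respects its invariances — not that any particular empirical effect
size in real brains is reproduced. Results tied to restricted imaging
datasets (specific identifiability scores, sex/cognition/heritability
effects) are out of scope by design.

Twin phenotypes are drawn from the generative ACTE model with exact
latent-variable sharing (MZ genetic correlation 1, DZ/sibling ½ via a
shared parental component), family-constant C, twin-pair-constant T, and
default family counts at the scale of a large twin imaging cohort (138 MZ
pairs, 79 DZ pairs, 160 twin+sibling trios). How many sibling families
attach to MZ vs DZ pairs is not specified by that design, so trios
alternate zygosity deterministically. Age is shared within a family
(±5 y for siblings) and twin pairs are same-sex.

## Problem sizes in the test suite

The suite uses the smallest configurations that make each scientific
check sharp: icosphere(5) (10 242 vertices, 302 eigenvalues) for the
sphere-oracle and Weyl checks; the default 10-subject icosphere(4) cohort
with 121 eigenvalues for scale recovery and permutation inference
(1 000 permutations); 500 null simulations with 99–199 permutations each
for the calibration checks; 500+500 twin pairs for ACE recovery and the
default family counts for the pipeline regimes. The whole suite runs in
about two minutes on one CPU.

## Known limitations

- Cubic-element spectra differ from linear-element spectra at fine scales
  on coarse meshes; exact numerical agreement with any particular
  external Shape-DNA implementation is not claimed, only convergence to
  the same continuum eigenvalues.
- Meshes are accepted as given; no retopologization, remeshing or quality
  improvement is performed before assembly (degenerate triangles are a
  hard error naming the face).
- The identifiability permutation test treats subjects as exchangeable
  under the null; family structure in the *identification* cohorts is not
  modelled (it is in the GLM/CCA/bootstrap machinery).
- ACE-type estimates from a few hundred families carry sampling SDs of
  several hundredths; single-draw recovery tests are seeded and should be
  read as regression tests at a representative draw, not as bounds on the
  estimator's dispersion.
- Genus > 0 or non-manifold meshes are rejected for spectral analysis
  rather than handled; eigenfunction export is limited to debugging.
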