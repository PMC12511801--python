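# Methods

## Surfaces and discretization

Each hemisphere is a closed (boundary-less) triangle mesh. Treating the
cortical sheet as closed is a deliberate simplification — the physical
boundary at the medial wall is handled by masking the *estimated*
connectivity post hoc, never by changing the operator. Integration over the
surface is discretized by lumped barycentric vertex areas m_i (one third of
each incident face's area), so ∑ m_i equals the total mesh area exactly.
All package invariants — kernel rows integrating to 1, densities having
unit total mass, basis orthonormality — are stated against diag(m).

The icosphere generator refines the icosahedron by uniform 1-to-4
subdivision with projection to the sphere, appending midpoint vertices
after their parents. Level-k vertices are therefore a prefix of level-(k+1)
vertices, the same nesting the fsaverage-icoN template family uses
(ico4 = 2562, ico6 = 40 962, ico7 = 163 842 vertices), and fine-to-coarse
basis downsampling is a row selection.

## Laplace–Beltrami spectrum

The operator is assembled as the cotangent stiffness matrix S with the
lumped mass m, and eigenpairs solve S f = λ diag(m) f. Small or near-full
problems are solved densely after symmetric whitening by diag(m)^(1/2);
large truncated problems use shift-invert Lanczos (shift −0.01, tolerance
1e-10) with a starting vector drawn from an explicit seed, so spectra are
reproducible. λ₀ is clamped to exactly 0 inside a 1e-8 tolerance (the
constant nullspace is analytic on a closed mesh) and eigenvector signs are
fixed by making each column's largest-magnitude entry positive; every
downstream quantity is sign-invariant regardless.

Spectrum quality is validated through Weyl's law: on a 2-manifold,
λ_m grows linearly in m, so the OLS slope of log λ_m on log m should be 1
where the mesh resolves the eigenfunctions. On the subdiv-5 unit icosphere
the slope over indices 10–500 is 0.984.

A subtlety worth recording: the *tail* behaviour of the discrete spectrum
depends on the mass discretization. With the consistent (full FEM) mass
matrix, tail eigenvalues of a coarse mesh inflate above the Weyl line
(ico4: mid-spectrum slope 1.05, tail slope 1.29); with lumped mass they
saturate instead (tail slope ≈ 0.67). `compute_spectrum` therefore exposes
`mass="consistent"` for spectrum validation, while lumped mass remains the
default everywhere else because the kernel normalization and quadrature
identities require a diagonal mass. The two discretizations agree on
well-resolved low modes (within 2% for spherical degree ≤ 2 on a
642-vertex sphere).

Downsampled fine-mesh eigenvectors are used as-is by default — restriction
to coarse vertices with the coarse mass is only approximately orthonormal
(within 1.5% for the modes the coarse grid resolves), and an opt-in
Cholesky re-orthonormalization is provided for users who prefer an exactly
orthonormal basis over fidelity to the fine-mesh eigenfunctions.

## Kernels

Spectral kernels are K = F Φ(Λ) Fᵀ with Φ(λ) = exp(−κ²λ/2) (diffusion) or
(2ν/κ² + λ)^(−ν−1) (Matérn, intrinsic dimension 2). The normalizing
constants of the underlying covariance families are not pinned down by the
estimator, so the package defines `unit_mass` normalization Φ̃ = Φ/Φ(0):
because the constant eigenfunction is the only mode surviving integration
against diag(m), every unit-mass kernel row then integrates to exactly 1 —
precisely what a KDE kernel must do. A `raw` mode exposes the unnormalized
spectral sum. Truncation can produce small negative kernel entries; they
are kept (clamping would silently break the normalization identities) and
the most negative entry is reported per matrix.

The spherical heat kernel follows its closed series form with the 1/4π
prefactor and truncation at the smallest J with (2J+1)e^(−J(J+1)σ) < 0.001
(J = 368 at σ = 0.0001, J = 14 at σ = 0.05). It integrates to 1 over S²
analytically, so no discrete renormalization is applied; mass-weighted row
sums land within ~1% of 1 (quadrature error only). On the unit sphere the
diffusion kernel with κ²/2 = σ is analytically identical to the spherical
heat kernel (addition theorem); the implementations agree within 0.5%
relative sup-norm on a subdiv-5 icosphere, and the test budget allows 2%
for FEM eigen-error.

Bandwidth grids are 10 log-spaced values, κ ∈ [0.6252, 18.9204] and
σ ∈ [0.0001, 0.05]. The σ spacing is not uniquely determined by the grid's
endpoints; log spacing is the default (matching κ) with linear spacing
available. κ is interpreted in the mesh's coordinate units; σ is unitless
on the unit sphere.

## Estimation

Endpoints given as coordinates are snapped once at ingestion to the
Euclidean-nearest vertex (ties to the lowest index; raw coordinates are
retained in metadata). No distance cutoff rejects far-off endpoints. The
adjacency A = UVᵀ + VUᵀ counts streamlines symmetrically — a streamline
with both endpoints at one vertex contributes 2 to that diagonal entry and
the total sum is always 2N. The production estimator P = (1/2N)·K A Kᵀ and
the explicit O(M²N) reference loop are both implemented and agree to
1e-12; the loop exists purely as an oracle. With unit-mass kernels the
pre-mask double sum ∑ P_ij m_i m_j is 1 to 1e-8. The medial-wall mask
zeroes rows and columns after estimation without renormalization, so the
masked matrix is deliberately *not* a density.

## Reliability metrics

For scans X_ij (subject i, repeat j), dICC = 1 − MSD̂_w/MSD̂_b, where the
mean squared distances average over all within-subject and between-subject
scan pairs respectively, with full-matrix Frobenius distance by default
(upper-triangle-only is an option). dICC ≤ 1 always; it is ≈ 0 for
exchangeable scans and reports below 0.4 carry a poor-reliability flag.
Similarity between two matrices is the mean of row-wise Pearson
correlations, excluding rows with zero variance in either matrix.
Identifiability is |μ_intra − μ_inter|/s where s is the two-sample pooled
standard deviation of the within- and between-subject similarity samples —
the standard pooled-variance reading, since the metric's source does not
fix a formula.

## Synthetic data

The simulator draws endpoint pairs from a bundle mixture: each bundle
connects two centers and contributes ½[g(x|c₁)g(y|c₂) + g(x|c₂)g(y|c₁)]
with g a unit-mass diffusion-kernel column at the center. Built this way
the truth is band-limited and exactly representable on the vertex grid, so
estimation error (mass-weighted L² distance) is unambiguous. Negative
kernel excursions are clamped to zero and the density renormalized exactly.
The packaged scenario has two equal-weight bundles with spreads 0.35 and
0.5 on the unit sphere (mid-grid relative to the surface radius) and
centers drawn once from a fixed seed. Sampling treats the symmetric density
against the product measure π(i, j) ∝ p(i, j) m_i m_j; pairs are
i.i.d. and every stochastic operation takes an explicit seed — there is no
hidden global RNG state.

Multi-scan collections perturb the mixture per subject (log-normal weight
shifts scaled by `subject_effect`, plus center relocation with probability
min(1, subject_effect)) and sample repeats independently. The generator
emulates the *statistical* structure of repeated-scan connectomes —
subject separation, within-subject sampling noise, controlled streamline
counts. It does not emulate cortical geometry, spatially correlated
scanner noise, registration error, or tractography biases (gyral bias,
bottleneck effects), so passing tests demonstrate correctness of the
estimator and metrics under the stated sampling model, not performance on
real dMRI data.

Consistency experiments share endpoint samples across kernels (paired
comparison) at N ∈ {25, 50, 100, 200, 400} with 20 replicates — sizes
chosen so the full experiment runs in seconds on one CPU while Monte-Carlo
standard errors stay small enough to resolve the error decay. On the
packaged scenario the diffusion kernel attains the lowest mean error at
small N (its bandwidth class matches the generating bundles), and every
kernel's error falls with N toward its bias floor.

## Local inference

Connectivity matrices are compressed onto K_b mass-orthonormal basis
functions with local support via S_k = ξ_kᵀ diag(m) P diag(m) ξ_k — the
diagonal (ξ_k ⊗ ξ_k) projection. The default basis partitions vertices
into contiguous patches by farthest-point region growing from a seeded
start; disjoint supports make mass-normalized indicators exactly
orthonormal. An externally estimated basis can be loaded instead — the
construction is pluggable by design. Group differences are per-coefficient
Welch t-tests (a seeded permutation test is the distribution-free
alternative) with Benjamini–Hochberg FDR control at 0.05 by default
(Bonferroni available); coefficients with zero variance in both groups get
p = 1. The difference region is the union of supports of significant basis
functions. Calibration is verified by simulation: null p-values pass KS
uniformity, empirical FDR stays at or below the nominal level, and a
3-pooled-SD shift at n = 60 per group is detected in over 95% of runs.

## Trait prediction

Matrices are vectorized over the upper triangle (including the diagonal —
the symmetric lower triangle adds no information), reduced by centered PCA
(at most n − 1 components), and a ridge regression predicts the trait from
the first K components. The ridge penalty is tuned per training fold by
internal 5-fold cross-validation over a log grid 10⁻³–10³ with MSE scoring;
features are standardized on the training fold by default (a flag disables
it). Repeated seeded 80/20 splits give out-of-sample MSE and
prediction–outcome correlation; bandwidth selection takes the argmin of
mean test MSE (or argmax correlation), ties to the smaller bandwidth.

## Degenerate inputs and tie-breaking

Zero-area faces raise at assembly; snapping ties break to the lowest
vertex index; zero-variance rows are dropped from similarity, and
all-degenerate input raises; dICC raises when between-subject spread is
zero, identifiability when the pooled SD is zero. Downsampling requires at
least one retained streamline.

## Known limitations

* Icosphere fixtures share the topology of fsaverage meshes but not
  cortical geometry; nothing here speaks to anatomy.
* The spherical-heat-kernel path assumes vertices already lie on the unit
  sphere; no spherical registration is provided.
* The reduced-rank test localizes differences only up to the resolution of
  the chosen basis; the packaged patch basis is a default, not a
  data-driven optimum.
* Masked matrices are not renormalized; quantities that require a density
  must be computed pre-mask.
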