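# Methods

This note documents the models, numerical conventions and design choices
behind each stage of the package, and what the synthetic-data tests do and
do not establish about real crown data.

## Elliptic Fourier analysis

Outlines are closed polygons in mm; orientation is forced counter-clockwise
on construction (signed-area test, first point kept) so chirality
conventions are uniform. Resampling places 64 points (configurable, ≥ 8) at
equal arc-length steps along the polygon, starting at the original first
point.

The forward transform uses the chain (polygon) formulation: the incremental
changes Δx, Δy over each edge, parameterized by cumulative chord length t,
give per-harmonic coefficients

a_n = T/(2n²π²) Σᵢ (Δxᵢ/Δtᵢ)[cos(2πn tᵢ/T) − cos(2πn tᵢ₋₁/T)],

and analogously b_n (sine), c_n, d_n (for y). These are the *exact* Fourier
integrals of the piecewise-linear curve; the test suite checks them to 1e-8
against an independent dense-quadrature oracle. A plain DFT of the sampled
x(t), y(t) series is *not* an exact oracle — it is the trapezoid
approximation of the same integrals and differs at O(N⁻²) — which is why
the cross-check integrates rather than FFTs. The DC terms (A0, C0) are the
exact means of the piecewise-linear coordinates, so reconstruction is
positioned correctly.

Normalization standardizes size, orientation and starting point by the
first-harmonic ellipse: the start phase θ = ½·atan2(2(a₁b₁ + c₁d₁),
a₁² + c₁² − b₁² − d₁²) rotates the parameter origin onto the major axis,
the orientation ψ = atan2(c₁*, a₁*) rotates the major axis onto +x, and the
semi-major length scales everything to A₁ = 1, B₁ = C₁ = 0. θ is only
defined modulo a half turn, and the two candidates differ by a sign flip of
the even harmonics; the tie is broken by choosing the lexicographically
larger coefficient vector, which is deterministic and invariant under
rotation, scaling, translation and start-point choice (asserted to 1e-6 on
random outlines). Reflection is deliberately *not* removed: mirrored
(left/right) outlines yield different coefficients and must be reflected
explicitly before joint analysis.

Harmonic counts default to 9 for the upper first molar (32 shape variables
after dropping the first harmonic) and 5 for the lower (16 variables), both
configurable; the error-versus-information criterion behind those counts is
taken as given, not re-derived.

## Morphospace statistics

PCA runs on the covariance matrix — the Fourier coefficients share units
after size normalization, so variables are not standardized. All
min(n − 1, p) components are kept (explained fractions sum to one);
component signs are fixed by forcing each component's largest-magnitude
loading positive, and scores are computed by explicit projection of the
centered data onto the loadings so that bit-identical specimens receive
bit-identical scores — this matters because the downstream rank transform
resolves only exact ties.

The number of retained axes is the smallest k whose cumulative explained
fraction reaches the threshold (default 0.95), additionally capped at
N − 2 so the exact F transform's error degrees of freedom stay positive.
Retained coordinates are rank-transformed column-wise (midranks for ties),
making the test invariant to monotone distortions of the scores. The
two-group Wilks statistic Λ = det(W)/det(W + B) maps exactly to
F = ((1 − Λ)/Λ)((N − p − 1)/p) with df (p, N − p − 1); for two groups this
is the Hotelling-T² relation, and the implementation is checked against
that identity to 1e-9 and against an independent MANOVA implementation.

Bilateral teeth: by default outlines sharing a specimen label are averaged
in normalized-coefficient space, so each animal contributes one
observation (a 54-animal survey then gives df₂ = 54 − 1 − 11 = 42 at
p = 11); a flag treats sides as independent instead.

Extreme outlines are rebuilt by Fourier synthesis from the mean coefficient
vector ± multiplier·SD along a component's loading, with the first
harmonic and perimeter taken from the mean-shape template. The pipeline
reports extremes along the most discriminant retained axis (largest
standardized group mean difference) unless an axis is requested.

## Crown statistics

Morphotype frequencies count tooth sides in the named state among scored
sides of a cohort ("missing" excluded from the denominator). The packaged
survey transcribes per-specimen upper-molar scores of 33 mutant and 21
wild-type mice, both sides; "-" encodes the unremarkable state of each
trait (spur present, c1 normal) and "no spur" its absence.

The measurement tests are the textbook pooled-variance two-sided t test
(sign = mean(x) − mean(y)) and the two-sided variance-ratio F test
F = s²ₓ/s²ᵧ, with p = 2·min(cdf, 1 − cdf).

The DE-marking rule flags a gene when (i) at least `min_count` (default 10)
counts occur in at least ⌈group size/2⌉ samples of one group, (ii)
p ≤ 0.05, and (iii) |log2 fold change| ≥ 0.5. The fold-change threshold is
read on the log2 scale and symmetric in direction — a linear fold change of
0.5 as a lower bound would be vacuous for upregulated genes — and both the
threshold and its interpretation are arguments. The statistical test
producing p is outside the package's scope (any count-model fit may supply
it); only the marking rule and the 2×2 Fisher enrichment test are
implemented. qPCR quantification is the comparative ΔCt formula
2^−(Ct_target − Ct_housekeeping).

## Mesh morphing

Landmark alignment is the Umeyama closed-form least-squares similarity fit
(rotation, translation, uniform scale; reflections excluded). Collinear or
coincident landmark configurations are rejected by a singular-value test.
Point-to-plane ICP refinement linearizes the small-motion update and
accepts a step only if the RMS point-to-surface distance does not increase,
stopping at 1e-6 mm improvement or 100 iterations; scale is inherited from
the initial transform.

Dense correspondence casts a line through every source vertex along its
normal (both senses at once) and keeps the nearest target intersection
within the cutoff (default 5× the mean source edge length) as a
"projected" match; unhit vertices fall back to the nearest target-surface
point within the cutoff ("closest"); the remainder ("interpolated") receive
target points by iterative graph-neighbor averaging (discrete Laplacian
relaxation) over the source mesh until the maximum change falls below
1e-9 — a well-defined realization of linear interpolation on irregular
meshes. Spatial queries run on a purpose-built kernel: closest-point
lookups prune candidates with a KD-tree over triangle centroids (the true
nearest triangle's centroid provably lies within the search ball), and ray
casting is vectorized Möller–Trumbore. Note that projection-based
correspondence produces near-normal displacement vectors: a laterally
shifted cusp appears as the old peak deflating while a new peak grows, not
as a lateral vector at the apex.

The displacement field is target point − source vertex, pinned to zero on
a boundary band emulating the cervical margin (default: vertices in the
lowest 15% of crown height, configurable — the original placement "below
the functional surfaces" fixes no coordinates). Transfer onto a third mesh
aligns it into the source frame via the cusp homology pairing, samples the
field at the nearest source-surface point with barycentric interpolation
over the source triangle, zeroes displacements beyond the cutoff, and maps
vectors back to the native frame dividing by the alignment scale — so the
deformation is stored geometry-independently and rescales with the target
anatomy. A per-cusp mode partitions both surfaces by nearest paired
landmark and samples each region independently; the global mode is the
default.

Height-map averaging superimposes each scan on a reference (phase-
correlation in-plane shift plus least-squares z offset), estimates a dense
2D displacement to the reference with iterative Lucas–Kanade optical flow
(radius 8; chosen over TV-L1 because it tracks narrow cusp-scale features
over multi-pixel displacements substantially better on our dome
constructions), averages the *corresponding* x, y, z coordinates, removes
the mean rigid offsets so the result sits at the barycenter of the inputs,
and regrids to the reference lattice. This dense-registration step is a
standard substitute for the proprietary registration used in the original
scan-averaging tooling; cell-wise averaging is available for comparison
and demonstrably attenuates shifted features.

## Synthetic data: what it does and does not show

Outlines are star-shaped radius functions r(θ) = ellipse + Gaussian cusp
bumps + radial Gaussian noise — radial noise preserves closure and
ordering. Defaults emulate a mouse upper first molar: semi-axes
1.1 × 0.72 mm, five cusps of 0.08–0.12 mm amplitude, 0.01 mm measurement
noise; the genotype effect shifts cusp 1 by Δθ (0.3 rad in the study
conditions) and/or rescales its amplitude. Crowns are z = dome + Gaussian
cusps on a regular grid (four distal cusps, σ = 0.15 mm, dome 0.3 mm) with
landmarks at the analytic apices (Nelder–Mead on the height function; the
dome slope pulls apices slightly off the Gaussian centers). Morphotype
records are per-side Bernoulli draws at the survey's observed rates; counts
are negative-binomial with variance μ + φμ² and a spiked log2-fold-change
subset.

Passing tests on these generators establish that the *computations* are
correct and that injected effects of realistic size are recovered at
calibrated error rates. They do not establish that real crown outlines
satisfy the star-shape assumption (deeply folded outlines are not
star-shaped), that real scan noise is radial/Gaussian, or that mouse-to-
human transfer is anatomically valid — the cusp homology is a modeling
assumption, and predictions for real dentitions remain unvalidated here.

## Problem sizes and determinism

Simulation-based checks use 30 specimens per cohort, 200 replicates for the
type-I calibration, crown grids of 32–48 points per axis (1–2.3k vertices)
and 64×64 height maps — sizes at which every stage and the full acceptance
recomputation complete in seconds while leaving the statistics well
resolved. All generators are pure functions of (parameters, seed); the
pipeline derives named per-stage substreams from one seed by hashing, and
two runs with the same config are bit-identical.

## Known limitations

* Normalization does not remove reflection; mirrored outlines must be
  handled explicitly upstream.
* The exact Wilks→F transform applies to two groups only; more groups are
  out of scope.
* Dense correspondence is one-directional (source→target) and purely
  geometric; it does not enforce feature homology beyond the landmark
  alignment.
* The optical-flow registration in surface averaging assumes mostly
  in-plane feature displacement and overlapping valid regions; it is a
  stand-in for specialized scan-registration tooling.
* Mesh repair is limited to duplicate-vertex merging and degenerate-face
  removal.
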