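# Methods

## Signal model

A voxel is modeled as a slow-exchange ensemble of microscopic Gaussian
diffusion tensors that share one orthonormal eigenframe (ε₁, ε₂, ε₃) — the
constrained diffusion tensor distribution (cDTD). The ensemble is then fully
described by the joint distribution of principal diffusivities, discretized
as non-negative point masses p ≥ 0 on a logarithmically spaced grid:

* **3D**: p(λ₁, λ₂, λ₃); under a general symmetric PSD b-tensor **b** the
  signal is Σ p·exp(−Σᵢ λᵢ·εᵢᵀ**b**εᵢ); under single diffusion encoding
  (rank-1 **b** = b**gg**ᵀ) the weightings reduce to b·g′ᵢ² with
  g′ = [ε₁ ε₂ ε₃]ᵀ**g**. The two forms agree identically on rank-1
  b-tensors (tested to float round-off).
* **2D (axisymmetric)**: p(λ_r, λ_t) with weightings b·cos²φ_g and
  b·sin²φ_g, φ_g = arccos(ε₁ᵀ**g**). Equivalent to a 3D spectrum with
  λ₂ = λ₃ = λ_t.
* **1D (isotropic)**: p(λ₀), direction-independent mono-exponential
  mixture.

Signals are dimensionless attenuations (S = total spectral mass at b = 0);
s0 is absorbed into the total mass during reconstruction and reported as a
separate map. Units: b in s/mm², diffusivities in µm²/ms, with an explicit
10⁻³ factor in every exponent so b·λ is dimensionless. A delta spectrum
reproduces the single-tensor DTI signal exactly, so conventional DTI is the
one-point limit of the model.

The point-mass (sum, not cell-integral) discretization is deliberate: the
forward simulator and the inversion's design matrix share it, making the
pair adjoint-consistent to machine precision — the design matrix applied to
a ground-truth weight vector reproduces the simulator output exactly.

## Inversion

Per voxel, the design matrix A (encodings × grid nodes, entries
exp(−Σ_axis w_axis·λ_node·10⁻³)) is inverted by non-negative least squares
on the Tikhonov-augmented system [A; αI], [s; 0]:

p̂ = argmin_{p≥0} ‖Ap − s‖² + α²‖p‖²

solved with the deterministic active-set NNLS of `scipy.optimize.nnls`.
The identity damping operator penalizes total spectral energy; smoothness
operators are a possible extension, not implemented. The default grid is 12
nodes per axis on [0.01, 2.00] µm²/ms; peak-localization analyses use finer
grids (32×32 in 2D, 16³ in 3D).

**Regularization weight.** α is selected once per volume (not per voxel,
for speed and spatial consistency) by an L-curve corner search over a
13-point log ladder spanning 10⁻⁴…1: for each candidate the damped problem
is solved and the curvature of the (log residual norm, log solution norm)
curve, parameterized by log α, is estimated by central differences; the
interior candidate with maximum curvature wins. Positivity alone already
prevents overfitting in this problem, so for noiseless or exactly
representable data the curve is flat and has no corner; when the maximum
interior curvature falls below 0.1 the selector falls back to the smallest
candidate, where damping costs nothing. Noiseless demonstrations and the
3D validation reconstruction use light fixed damping (α = 10⁻³); recovered
peak locations are insensitive to α across [0, 0.1].

## Reference frames

The voxel frame is the eigen-decomposition of the net diffusion tensor,
fitted by weighted linear least squares on log-signals with weights
proportional to the squared signal (the standard first-order
heteroskedasticity correction for log-transformed Rician data);
non-positive signals are excluded with a warning. Only shells with
b ≤ 2500 s/mm² feed the frame fit by default, keeping it in the
near-Gaussian DTI regime; the cutoff is configurable. Eigenvalues are
sorted descending and clamped at zero; each eigenvector's largest-magnitude
component is made positive to prevent spurious sign flips between
neighboring voxels. Frames with FA < 0.05 are flagged degenerate: 2D
reconstruction then requires an externally supplied radial direction field
(an injection hook; structural-scan or tensor-interpolation proxies are out
of scope). Per-encoding weightings satisfy w₁+w₂+w₃ = b (3D) and
w_r+w_t = b (2D) exactly.

## Synthetic ground truth

Test spectra are mixtures of axis-independent log-normal components. Each
component is stated by its **linear-space mode** ("peak", µm²/ms) and
**linear-space standard deviation**; log-space (m, s) are solved per axis
from mode = e^{m−s²} and the log-normal variance identity, so the printed
peak coordinates are reproduced exactly in the implied linear-space
density. The built-in defaults are the validation mixtures: 2D components
at (0.9, 0.4), (0.4, 1.0), (1.4, 1.4) µm²/ms and 3D components at
(1.4, 1.0, 0.4), (1.1, 0.2, 0.9), (0.3, 1.3, 1.2) µm²/ms, all with 0.1
µm²/ms standard deviation. Component fractions default to equal thirds
(the mixture weighting is not otherwise specified). Node weights are the
mixture density in log-diffusivity space times the log-bin measure,
renormalized to the fraction sum.

The default acquisition is the six-shell SDE protocol — b = 100, 1,000,
2,500, 4,500, 7,000, 10,000 s/mm² with 3, 9, 15, 21, 28, 36 directions (112
encodings), pulse timings δ = 6 ms, Δ = 28 ms carried as metadata only (no
diffusion-time dependence is modeled). Directions are spread per shell by
antipodally symmetric electrostatic (Coulomb) repulsion — projected
gradient descent with adaptive step from a seeded random start — followed
by a joint pass that rigidly rotates whole shells (first shell fixed,
Powell search over rotation vectors, two sweeps) to minimize cross-shell
repulsion energy. Deterministic for a fixed seed.

**Curved-cortex phantom.** A cylindrical cortical ribbon of curvature
radius R sampled at voxel size x, lattice axes (depth, arc, axial). The
curvature bound on intravoxel frame dispersion is
θ_max = atan(x·√3/(2R)) — the half-diagonal of a cubic voxel subtended at
radius R; for the study geometry (x = 0.2 mm, R = 5 mm) it evaluates to
1.98°, which truncates to the reported "±1.9°", and inverting
θ_max = 10° gives x/R = 0.204 → 0.2. The voxel frames follow the local
radial direction with an angular pitch of exactly θ_max per arc step, so
the lattice realizes the maximal adjacent-frame rotation the curvature
admits; depth and axial neighbors share frames, and R = ∞ gives a flat
ribbon with constant frames. Layers are contiguous depth bands. The
phantom exercises the frame machinery and the curvature bound; it does not
emulate realistic folding meshes, partial-volume mixing across voxel
faces, or susceptibility/eddy artifacts — so passing tests say nothing
about those effects in real data.

**Noise.** Rician: S_noisy = √((S+n₁)² + n₂²) with n₁, n₂ i.i.d. zero-mean
Gaussians of standard deviation σ = s0/SNR, constant across encodings
(tied to the unattenuated signal). SNR = ∞ is the identity. At SNR 100 the
noise floor σ√(π/2) ≈ 0.0125 dominates the b ≥ 7,000 s/mm² shells for the
default diffusivities.

## Derived spectra

Each grid node maps to a microscopic tensor — (λ₀,λ₀,λ₀), (λ_r,λ_t,λ_t) or
(λ₁,λ₂,λ₃) — with fractional anisotropy
α = √(½[(λ₁−λ₂)²+(λ₂−λ₃)²+(λ₃−λ₁)²]/(λ₁²+λ₂²+λ₃²)) ∈ [0,1] and mean
diffusivity µ = (λ₁+λ₂+λ₃)/3. Node masses accumulate into an 11×11 joint
histogram with FA bins uniform on [0, 1] and MD bins uniform on
[0, grid max] (the MD range is otherwise unspecified; masses outside it go
to the edge bin with a warning). Moments — µFA = mean of p_FA, its
variance, mean MD — are computed from the **unbinned** node values, which
is exact; the binned versions exist for display parity. Marginals and
spectral-ROI integrations conserve mass to 10⁻⁹ or better; ROIs are named
rectangular λ-ranges or explicit bin masks in YAML.

## Evaluation

The Monte-Carlo harness synthesizes noiseless signals from a ground-truth
spectrum, draws n independent Rician replicates per SNR level (default
n = 500 per the study design; desk-scale runs use 20–50), reconstructs
each, and aggregates the mean and per-bin standard deviation of the
normalized spectra. Seeding uses `numpy.random.SeedSequence` spawning, so
results are exactly reproducible and levels are independent. Scores
against the normalized ground truth:

* **MSE** — mean squared bin difference;
* **SSIM** — `skimage.metrics.structural_similarity` with Gaussian
  weighting, the standard 11-bin window truncated to the grid, dynamic
  range = joint maximum (3D spectra are compared slice-stacked);
* **JSD** — Jensen-Shannon divergence, log base 2, so symmetric and in
  [0, 1] with 0 iff equal (the square of `scipy`'s Jensen-Shannon
  distance).

**Peak finding** is a steepest-ascent watershed on the full 8- (2D) or 26-
(3D) neighborhood; ties break toward the lower flat index (ascent on
amplitude equals ascent on log amplitude since log is monotone). Local
maxima with amplitude ≥ min_fraction (default 0.05) of the global maximum
are reported at the mass-weighted geometric-mean diffusivity of their
basin — geometric because the grid is log-spaced — with the basin mass.

## Numerical and design choices

* The lowest shell (b = 100 s/mm²) is *not* treated as b = 0; total
  spectral mass absorbs s0.
* NNLS iteration cap 10× the unknown count; per-voxel residual norms are
  recorded.
* b = 0 encodings accept any direction vector; validation requires unit
  gradients only when b > 0.
* bvec files are FSL dialect (three rows, image coordinate frame) and are
  never silently reoriented; round-trips are lossless to 6 significant
  digits.
* Spectrum maps are 5D NIfTI (x, y, z, 1, bins) with bins flattened in C
  order plus a JSON sidecar naming axes and nodes.

## Known limitations

* **Spectral resolution at moderate SNR.** At SNR 100 under the 112-
  encoding protocol, the three-component 2D validation mixture is not
  identifiable: a one/two-component spectrum reproduces its signal to
  within the noise norm, so per-replicate reconstructions — and hence the
  replicate-mean spectrum — merge the components into a single dominant
  mode near (0.8, 0.7) µm²/ms. The same pipeline separates all three
  components from roughly SNR 500 and recovers them exactly without noise.
  This is the classic resolution limit of multi-exponential inversion, not
  a solver artifact; the corresponding validation test is expected to fail
  at SNR 100 and documents this.
* The L-curve corner is weak for positivity-constrained problems (the
  residual is nearly flat in α); the selected α errs toward heavy
  smoothing on noisy data.
* No diffusion-time dependence, exchange, or restriction effects; δ and Δ
  are metadata.
* Oblate vs prolate assignment of reconstructed components assumes the
  axisymmetric 2D model is appropriate for the voxel.
* Only the FSL gradient-table dialect is supported; no DICOM ingestion.
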