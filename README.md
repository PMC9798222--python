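# cortecs

Non-parametric **constrained diffusion tensor distribution (cDTD) imaging**
for high-resolution diffusion MRI of organized tissue such as cortical gray
matter — for MR physicists and neuroimaging researchers who want to resolve
*sub-voxel* mixtures of diffusion tensor processes without a parametric
tissue model.

## The idea

At mesoscopic resolution (~100–200 µm) diffusion in the cortex aligns with
the local radial (columnar) and tangential (laminar) tissue axes, so all
microscopic diffusion tensors in a voxel can be assumed to share the voxel's
orthonormal DTI eigenframe (ε₁, ε₂, ε₃). The voxel then carries a joint
spectrum of principal diffusivities instead of a full 6-D tensor
distribution, and a single-diffusion-encoded (SDE) measurement with b-value
*b* and gradient **g** reads

S(b, **g**) = Σₖ pₖ · exp(−b·(g′₁²λ₁ᵏ + g′₂²λ₂ᵏ + g′₃²λ₃ᵏ)),  g′ = [ε₁ ε₂ ε₃]ᵀ**g**

a Laplace transform of the non-negative spectrum p(λ₁, λ₂, λ₃) (3D), of
p(λ_r, λ_t) in the axisymmetric cortical case with weightings
b·cos²φ_g / b·sin²φ_g, or of p(λ₀) for isotropic pools. Inverting it is a
classic ill-posed inverse Laplace transform, solved here per voxel by
non-negative least squares with L2 (Tikhonov) damping on a log-spaced
diffusivity grid (default 12 nodes per axis on 0.01–2.00 µm²/ms). From the
spectrum the package derives distributions of microscopic fractional
anisotropy α and mean diffusivity µ, their joint 11×11 correlation spectrum,
the µFA (mean of p_FA), marginals, and spectral-ROI component-fraction maps.
The validity of the shared-frame assumption is governed by the curvature
bound θ_max = atan(x·√3/(2R)) for voxel size x and cortical curvature
radius R.

The package contains:

- `acquisition` — multi-shell SDE protocols (default: six shells,
  b = 100…10,000 s/mm², 112 encodings), electrostatic-repulsion direction
  sampling, FSL bval/bvec and b-tensor table I/O
- `phantom` — log-normal mixture ground truths, curved-cortex frame fields,
  Rician noise
- `forward` — signal synthesis for 1D/2D/3D spectra under SDE and general
  b-tensors
- `frames` — voxel-wise DTI fits, eigenframe extraction, per-encoding
  radial/tangential (or per-axis) diffusivity weightings
- `recon` — design-matrix assembly, damped NNLS inversion, L-curve
  regularization selection, volume-wise reconstruction
- `derived` — µFA/MD spectra, moments, marginals, spectral ROIs
- `evaluation` — Monte-Carlo harness, MSE/SSIM/JSD scores, watershed peak
  finding
- a thin `cortecs` CLI (`simulate`, `frames`, `recon`, `derive`, `mc`,
  `peaks`) over NIfTI + bval/bvec files

## Worked example

Reconstruct the three-component 2D ground-truth mixture from noiseless
signals under the 112-encoding protocol
(`python examples/03_reconstruct_spectrum.py`):

```
damping weight alpha = 0.001
recovered spectral peaks (lambda_r, lambda_t in um^2/ms; mass = signal fraction):
  (1.35, 1.35)  mass 0.37  [oblate/isotropic]
  (0.41, 1.00)  mass 0.32  [oblate/isotropic]
  (0.91, 0.40)  mass 0.31  [prolate (radial > tangential)]
```

The three recovered peaks sit within one log grid spacing of the generating
components (0.9, 0.4), (0.4, 1.0) and (1.4, 1.4) µm²/ms, with the expected
equal one-third mass split: the inversion localizes each sub-voxel water
pool in the radial–tangential diffusivity plane. The other scripts in
`examples/` walk through protocol construction, phantom simulation, derived
µFA/MD maps, and the Monte-Carlo harness.

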