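"""Voxel reference-frame estimation from DTI and per-encoding weightings.

The voxel frame is the orthonormal eigenvector triad of the net (voxel
mean) diffusion tensor. Projecting each encoding onto the frame yields the
non-negative diffusivity weightings that drive the spectral inversion:
``w_i = b (eps_i^T g)^2`` per axis in 3D, or the radial/tangential split
``(b cos^2 phi_g, b sin^2 phi_g)`` in the axisymmetric 2D case.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .acquisition import B_LAMBDA_SCALE, AcquisitionScheme

__all__ = [
    "VoxelFrame",
    "EncodingWeights",
    "fit_dti",
    "eigenframe",
    "compose_tensor",
    "encoding_weights",
    "weights_from_direction",
    "DEFAULT_FRAME_MAX_B",
    "DEFAULT_FA_THRESHOLD",
]

#: Shells at or below this b-value (s/mm^2) feed the DTI frame fit by default,
#: keeping the fit in the near-Gaussian low-b regime.
DEFAULT_FRAME_MAX_B = 2500.0

#: Below this fractional anisotropy the frame is flagged degenerate.
DEFAULT_FA_THRESHOLD = 0.05


def _fa(eigvals: np.ndarray) -> float:
    lam = np.asarray(eigvals, dtype=float)
    denom = float(np.sum(lam**2))
    if denom == 0:
        return 0.0
    num = 0.5 * ((lam[0] - lam[1]) ** 2 + (lam[1] - lam[2]) ** 2 + (lam[2] - lam[0]) ** 2)
    return float(np.sqrt(num / denom))


@dataclass
class VoxelFrame:
    """Orthonormal eigenvector triad with voxel-mean DTI eigenvalues.

    ``eigenvectors`` is a 3x3 matrix with eigenvectors as columns, sorted
    by descending eigenvalue; ``valid`` is False when the tensor is too
    isotropic for the principal direction to be meaningful.
    """

    eigenvectors: np.ndarray  # columns eps1, eps2, eps3
    eigenvalues: np.ndarray  # descending, um^2/ms
    fa: float
    valid: bool

    def __post_init__(self) -> None:
        V = np.asarray(self.eigenvectors, dtype=float).reshape(3, 3)
        lam = np.asarray(self.eigenvalues, dtype=float).reshape(3)
        if not np.allclose(V.T @ V, np.eye(3), atol=1e-8):
            raise ValueError("eigenvectors must be orthonormal")
        if np.any(np.diff(lam) > 1e-12):
            raise ValueError("eigenvalues must be sorted descending")
        self.eigenvectors = V
        self.eigenvalues = lam

    @property
    def e1(self) -> np.ndarray:
        return self.eigenvectors[:, 0]


@dataclass
class EncodingWeights:
    """Per-encoding non-negative diffusivity weightings (s/mm^2).

    ``values`` has shape (n_encodings, 3) in 3D mode or (n, 2) in 2D mode
    (radial, tangential); each row sums to the encoding's b-value.
    """

    values: np.ndarray
    bvals: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.bvals = np.asarray(self.bvals, dtype=float).ravel()
        if self.values.ndim != 2 or self.values.shape[1] not in (1, 2, 3):
            raise ValueError("weights must be (n, 1|2|3)")
        if self.values.shape[0] != self.bvals.size:
            raise ValueError("one weight row per encoding required")
        if np.any(self.values < -1e-12):
            raise ValueError("weights must be non-negative")

    @property
    def ndim(self) -> int:
        return self.values.shape[1]


def fit_dti(
    signals: np.ndarray,
    scheme: AcquisitionScheme,
    max_b: float = DEFAULT_FRAME_MAX_B,
) -> tuple[np.ndarray, float]:
    """Weighted log-linear least-squares DTI fit.

    Fits ``ln S = ln s0 - sum_ij b_ij D_ij`` over all encodings with
    ``b <= max_b`` using weights proportional to the squared signal (the
    standard first-order correction for log-transformed noise). Returns
    the symmetric tensor (um^2/ms) and the estimated s0.

    Non-positive signals are excluded with a warning; a design with fewer
    than 7 usable encodings or rank-deficient directions is an error.
    """
    signals = np.asarray(signals, dtype=float).ravel()
    if signals.size != len(scheme):
        raise ValueError("signal count must match the scheme")
    bvals = scheme.bvals
    bvecs = scheme.bvecs
    sel = bvals <= max_b
    pos = signals > 0
    if np.any(sel & ~pos):
        warnings.warn("excluding non-positive signals from DTI fit", stacklevel=2)
    sel &= pos
    if sel.sum() < 7:
        raise ValueError("DTI fit requires >= 7 usable encodings at b <= max_b")

    b = bvals[sel]
    g = bvecs[sel]
    s = signals[sel]
    # design columns: ln s0, then -b * {gx^2, gy^2, gz^2, 2 gx gy, 2 gx gz, 2 gy gz}
    bb = b[:, None] * B_LAMBDA_SCALE
    X = np.column_stack(
        [
            np.ones_like(b),
            -bb[:, 0] * g[:, 0] ** 2,
            -bb[:, 0] * g[:, 1] ** 2,
            -bb[:, 0] * g[:, 2] ** 2,
            -bb[:, 0] * 2 * g[:, 0] * g[:, 1],
            -bb[:, 0] * 2 * g[:, 0] * g[:, 2],
            -bb[:, 0] * 2 * g[:, 1] * g[:, 2],
        ]
    )
    w = s  # sqrt of weights s^2
    Xw = X * w[:, None]
    yw = np.log(s) * w
    if np.linalg.matrix_rank(Xw) < 7:
        raise ValueError("degenerate DTI design: directions are not independent")
    coef, *_ = np.linalg.lstsq(Xw, yw, rcond=None)
    s0 = float(np.exp(coef[0]))
    dxx, dyy, dzz, dxy, dxz, dyz = coef[1:]
    D = np.array([[dxx, dxy, dxz], [dxy, dyy, dyz], [dxz, dyz, dzz]])
    return D, s0


def eigenframe(tensor: np.ndarray, fa_threshold: float = DEFAULT_FA_THRESHOLD) -> VoxelFrame:
    """Eigen-decompose a symmetric tensor into a canonical voxel frame.

    Eigenvalues are sorted descending and clamped at zero; each
    eigenvector's largest-magnitude component is made positive so signs do
    not flip spuriously between neighboring voxels. Frames with FA below
    ``fa_threshold`` (including exactly isotropic tensors) are flagged
    invalid: the eigenvectors are then an arbitrary orthonormal basis.
    """
    T = np.asarray(tensor, dtype=float).reshape(3, 3)
    if not np.allclose(T, T.T, atol=1e-8):
        raise ValueError("tensor must be symmetric")
    lam, V = np.linalg.eigh((T + T.T) / 2)
    order = np.argsort(lam)[::-1]
    lam = lam[order]
    V = V[:, order]
    lam_clamped = np.maximum(lam, 0.0)
    for i in range(3):
        j = int(np.argmax(np.abs(V[:, i])))
        if V[j, i] < 0:
            V[:, i] = -V[:, i]
    fa = _fa(lam_clamped)
    valid = bool(fa >= fa_threshold) and lam_clamped[0] > 0
    return VoxelFrame(eigenvectors=V, eigenvalues=lam_clamped, fa=fa, valid=valid)


def compose_tensor(frame: VoxelFrame) -> np.ndarray:
    """Rebuild the symmetric tensor ``sum_i lambda_i eps_i eps_i^T``."""
    V = frame.eigenvectors
    return (V * frame.eigenvalues) @ V.T


def weights_from_direction(
    radial_dir: np.ndarray, scheme: AcquisitionScheme
) -> EncodingWeights:
    """2D radial/tangential weightings from an explicit symmetry axis."""
    e1 = np.asarray(radial_dir, dtype=float).reshape(3)
    if abs(np.linalg.norm(e1) - 1.0) > 1e-9:
        raise ValueError("radial direction must be a unit vector")
    b = scheme.bvals
    cos2 = (scheme.bvecs @ e1) ** 2
    wr = b * cos2
    wt = b - wr
    return EncodingWeights(np.column_stack([wr, wt]), b)


def encoding_weights(
    frame: VoxelFrame,
    scheme: AcquisitionScheme,
    mode: str = "2d",
    override_dir: np.ndarray | None = None,
) -> EncodingWeights:
    """Per-encoding diffusivity weightings in a voxel's reference frame.

    mode "3d": ``w_i = b (eps_i^T g)^2`` for each eigenvector; mode "2d":
    radial/tangential split about eps1. An invalid (degenerate) frame
    raises unless ``override_dir`` supplies the radial axis (2D only).
    """
    mode = mode.lower()
    if mode not in ("2d", "3d"):
        raise ValueError("mode must be '2d' or '3d'")
    if not frame.valid:
        if mode == "2d" and override_dir is not None:
            return weights_from_direction(override_dir, scheme)
        raise ValueError(
            "degenerate voxel frame: supply override_dir (2D) or mask the voxel"
        )
    if mode == "2d":
        return weights_from_direction(frame.e1, scheme)
    b = scheme.bvals
    proj = scheme.bvecs @ frame.eigenvectors  # (n, 3): eps_i^T g per column
    return EncodingWeights(b[:, None] * proj**2, b)
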