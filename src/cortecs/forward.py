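"""Forward diffusion-signal models for 1D/2D/3D cDTDs.

Each discrete spectrum is a set of point masses at grid nodes; the signal
is the mass-weighted sum of mono-exponential attenuations whose decay
rates are the projections of the encoding onto the voxel reference frame:

* 3D, general b-tensor: ``S = sum_k p_k exp(-sum_i lambda_i eps_i^T b eps_i)``
* 3D, single diffusion encoding (rank-1 b-tensor ``b g g^T``):
  ``S = sum_k p_k exp(-b (g'_1^2 lambda_1 + g'_2^2 lambda_2 + g'_3^2 lambda_3))``
  with ``g' = [eps1 eps2 eps3]^T g``
* 2D axisymmetric: ``S = sum_k p_k exp(-lambda_r b cos^2 phi_g
  - lambda_t b sin^2 phi_g)``, ``phi_g = arccos(eps1^T g)``
* 1D isotropic: ``S = sum_k p_k exp(-b lambda_0)``

Signals are dimensionless attenuations (S = total mass at b = 0); any s0
scaling is the caller's business. b in s/mm^2, diffusivities in um^2/ms,
with the explicit 1e-3 unit factor in every exponent.
"""

from __future__ import annotations

import numpy as np

from .acquisition import B_LAMBDA_SCALE, AcquisitionScheme
from .grids import CDTDSpectrum

__all__ = [
    "signal_btensor_3d",
    "signal_sde_3d",
    "signal_sde_2d",
    "signal_1d",
    "scheme_signals",
]


def _check_frame(frame: np.ndarray) -> np.ndarray:
    F = np.asarray(frame, dtype=float).reshape(3, 3)
    if not np.allclose(F.T @ F, np.eye(3), atol=1e-8):
        raise ValueError("frame must be an orthonormal 3x3 matrix (eigenvector columns)")
    return F


def signal_btensor_3d(
    spectrum: CDTDSpectrum, frame: np.ndarray, btensor: np.ndarray
) -> float:
    """Signal of a 3D cDTD under a general (symmetric PSD) b-tensor.

    ``frame`` holds the eigenvectors as columns. The three scalar
    weightings ``eps_i^T b eps_i`` are non-negative and sum to trace(b).
    """
    if spectrum.grid.ndim != 3:
        raise ValueError("signal_btensor_3d requires a 3-axis spectrum")
    F = _check_frame(frame)
    bt = np.asarray(btensor, dtype=float).reshape(3, 3)
    w = np.einsum("ji,jk,ki->i", F, bt, F)  # eps_i^T b eps_i, i = 1..3
    nodes = spectrum.grid.meshnodes()  # (n, 3)
    decay = nodes @ (w * B_LAMBDA_SCALE)
    return float(spectrum.flat() @ np.exp(-decay))


def signal_sde_3d(
    spectrum: CDTDSpectrum, frame: np.ndarray, b: float, g: np.ndarray
) -> float:
    """Signal of a 3D cDTD under single diffusion encoding (b, g)."""
    if spectrum.grid.ndim != 3:
        raise ValueError("signal_sde_3d requires a 3-axis spectrum")
    F = _check_frame(frame)
    g = np.asarray(g, dtype=float).reshape(3)
    if b > 0 and abs(np.linalg.norm(g) - 1.0) > 1e-9:
        raise ValueError("gradient direction must be a unit vector")
    gp = F.T @ g
    w = b * gp**2
    nodes = spectrum.grid.meshnodes()
    decay = nodes @ (w * B_LAMBDA_SCALE)
    return float(spectrum.flat() @ np.exp(-decay))


def signal_sde_2d(
    spectrum: CDTDSpectrum, radial_dir: np.ndarray, b: float, g: np.ndarray
) -> float:
    """Signal of an axisymmetric 2D cDTD under single diffusion encoding.

    ``radial_dir`` is the symmetry axis (eps1); the gradient's angle to it,
    phi_g, splits b into radial and tangential weightings.
    """
    if spectrum.grid.ndim != 2:
        raise ValueError("signal_sde_2d requires a 2-axis spectrum")
    e1 = np.asarray(radial_dir, dtype=float).reshape(3)
    if abs(np.linalg.norm(e1) - 1.0) > 1e-9:
        raise ValueError("radial direction must be a unit vector")
    g = np.asarray(g, dtype=float).reshape(3)
    if b > 0 and abs(np.linalg.norm(g) - 1.0) > 1e-9:
        raise ValueError("gradient direction must be a unit vector")
    cos2 = float(np.dot(e1, g)) ** 2
    wr, wt = b * cos2, b * (1.0 - cos2)
    nodes = spectrum.grid.meshnodes()  # (n, 2): (lambda_r, lambda_t)
    decay = (nodes[:, 0] * wr + nodes[:, 1] * wt) * B_LAMBDA_SCALE
    return float(spectrum.flat() @ np.exp(-decay))


def signal_1d(spectrum: CDTDSpectrum, b: float) -> float:
    """Signal of an isotropic 1D cDTD; independent of gradient direction."""
    if spectrum.grid.ndim != 1:
        raise ValueError("signal_1d requires a 1-axis spectrum")
    if b < 0:
        raise ValueError("b-value must be non-negative")
    nodes = spectrum.grid.nodes[0]
    return float(spectrum.weights @ np.exp(-b * nodes * B_LAMBDA_SCALE))


def scheme_signals(
    spectrum: CDTDSpectrum,
    scheme: AcquisitionScheme,
    frame: np.ndarray | None = None,
    radial_dir: np.ndarray | None = None,
) -> np.ndarray:
    """Vector of signals across a whole scheme, dispatched on dimensionality.

    3D spectra require ``frame`` (eigenvector columns; b-tensor encodings
    are honored when present), 2D require ``radial_dir``; 1D need neither.
    """
    ndim = spectrum.grid.ndim
    out = np.empty(len(scheme))
    for m, enc in enumerate(scheme.encodings):
        if ndim == 1:
            out[m] = signal_1d(spectrum, enc.b)
        elif ndim == 2:
            if radial_dir is None:
                raise ValueError("2D spectra require radial_dir")
            out[m] = signal_sde_2d(spectrum, radial_dir, enc.b, enc.g)
        else:
            if frame is None:
                raise ValueError("3D spectra require a frame")
            if enc.btensor is not None:
                out[m] = signal_btensor_3d(spectrum, frame, enc.btensor)
            else:
                out[m] = signal_sde_3d(spectrum, frame, enc.b, enc.g)
    return out
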