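"""Synthetic ground truth: log-normal cDTD mixtures, curved-cortex frame
fields, and Rician measurement noise.

The ground-truth spectra are mixtures of axis-independent log-normal
distributions of principal diffusivities. Each component is stated by its
linear-space mode ("peak", um^2/ms) and linear-space standard deviation;
the log-space parameters (m, s) are solved numerically per axis so the
printed peak locations are reproduced exactly.

The geometric test bed is a cylindrical cortical ribbon of curvature radius
``R`` sampled at voxel size ``x``: voxel reference frames follow the local
radial direction, so the frame field rotates tangentially at the maximal
rate admitted by the curvature bound ``theta_max = atan(x*sqrt(3)/(2R))``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.optimize import brentq

from .grids import CDTDSpectrum, SpectralGrid

__all__ = [
    "theta_max",
    "lognormal_params_from_mode_sd",
    "lognormal_mixture_spectrum",
    "mixture_2d_default",
    "mixture_3d_default",
    "GROUND_TRUTH_2D_PEAKS",
    "GROUND_TRUTH_3D_PEAKS",
    "GROUND_TRUTH_SD",
    "PhantomVolume",
    "curved_cortex_phantom",
    "add_rician_noise",
]

#: Three-component 2D (radial, tangential) ground-truth peak modes, um^2/ms.
GROUND_TRUTH_2D_PEAKS = ((0.9, 0.4), (0.4, 1.0), (1.4, 1.4))
#: Three-component 3D ground-truth peak modes, um^2/ms.
GROUND_TRUTH_3D_PEAKS = ((1.4, 1.0, 0.4), (1.1, 0.2, 0.9), (0.3, 1.3, 1.2))
#: Linear-space standard deviation of every component, um^2/ms.
GROUND_TRUTH_SD = 0.1


def theta_max(x: float, R: float) -> float:
    """Maximum intravoxel angular deviation (degrees) due to curvature.

    ``theta_max = atan(x * sqrt(3) / (2 R))`` for voxel size ``x`` and
    minimum radius of curvature ``R`` (same length units). ``R = inf``
    (flat anatomy) gives 0.
    """
    if x <= 0:
        raise ValueError("voxel size x must be positive")
    if R <= 0:
        raise ValueError("radius of curvature R must be positive")
    if np.isinf(R):
        return 0.0
    return float(np.degrees(np.arctan(x * np.sqrt(3.0) / (2.0 * R))))


def lognormal_params_from_mode_sd(mode: float, sd: float) -> tuple[float, float]:
    """Log-space (m, s) of a log-normal with given linear-space mode and sd.

    Solves mode = exp(m - s^2) and var = (exp(s^2) - 1) exp(2m + s^2)
    simultaneously; unique for mode, sd > 0.
    """
    if mode <= 0:
        raise ValueError("mode must be positive")
    if sd <= 0:
        raise ValueError("standard deviation must be positive")
    ratio2 = (sd / mode) ** 2

    # with m = ln(mode) + s^2:  var / mode^2 = (e^{s^2}-1) e^{3 s^2}
    def f(s: float) -> float:
        s2 = s * s
        return float(np.expm1(s2) * np.exp(3.0 * s2) - ratio2)

    hi = 1.0
    while f(hi) < 0:
        hi *= 2.0
        if hi > 64:  # pragma: no cover - unreachable for finite sd/mode
            raise RuntimeError("log-normal parameter solve failed to bracket")
    s = brentq(f, 1e-12, hi, xtol=1e-14)
    m = np.log(mode) + s * s
    return float(m), float(s)


def lognormal_mixture_spectrum(
    peaks,
    sds,
    fractions=None,
    grid: SpectralGrid | None = None,
) -> CDTDSpectrum:
    """Discretize a mixture of axis-independent log-normals onto a grid.

    Parameters
    ----------
    peaks :
        Component modes in linear diffusivity space, one k-tuple per
        component (k = grid dimensionality), um^2/ms.
    sds :
        Linear-space standard deviation per component (scalar each;
        shared across axes).
    fractions :
        Component weights; default equal. The spectrum's total mass equals
        their sum.
    grid :
        Target :class:`SpectralGrid`; default 12-node grid per axis on
        [0.01, 2.00] um^2/ms with the dimensionality of the peaks.

    The weight at each node is the mixture density in log-diffusivity
    space times the log-space bin measure (a point-mass representation,
    matching the forward model), renormalized to the fraction sum.
    """
    peaks = [np.atleast_1d(np.asarray(p, dtype=float)) for p in peaks]
    k = peaks[0].size
    if any(p.size != k for p in peaks):
        raise ValueError("all peaks must have the same dimensionality")
    sds = np.asarray(sds, dtype=float).ravel()
    if sds.size == 1:
        sds = np.repeat(sds, len(peaks))
    if sds.size != len(peaks):
        raise ValueError("one sd per component required")
    if np.any(sds <= 0):
        raise ValueError("standard deviations must be positive")
    if fractions is None:
        fractions = np.full(len(peaks), 1.0 / len(peaks))
    fractions = np.asarray(fractions, dtype=float).ravel()
    if fractions.size != len(peaks) or np.any(fractions < 0):
        raise ValueError("fractions must be non-negative, one per component")
    if grid is None:
        grid = SpectralGrid.logspaced(k)
    if grid.ndim != k:
        raise ValueError("grid dimensionality must match the peaks")

    lo = np.array([ax[0] for ax in grid.nodes])
    hi = np.array([ax[-1] for ax in grid.nodes])
    log_nodes = [np.log(ax) for ax in grid.nodes]

    weights = np.zeros(grid.shape)
    for peak, sd, frac in zip(peaks, sds, fractions):
        clipped = np.clip(peak, lo, hi)
        if np.any(clipped != peak):
            warnings.warn(
                f"component peak {tuple(peak)} outside grid bounds; clipped",
                stacklevel=2,
            )
        dens = np.ones(grid.shape)
        for axis in range(k):
            m, s = lognormal_params_from_mode_sd(float(clipped[axis]), float(sd))
            z = (log_nodes[axis] - m) / s
            pdf1d = np.exp(-0.5 * z * z) / (s * np.sqrt(2 * np.pi))
            shape = [1] * k
            shape[axis] = -1
            dens = dens * pdf1d.reshape(shape)
        total = dens.sum()
        if total > 0:
            weights += frac * dens / total
    return CDTDSpectrum(grid, weights)


def mixture_2d_default(grid: SpectralGrid | None = None) -> CDTDSpectrum:
    """Three-peak 2D (lambda_r, lambda_t) ground-truth mixture."""
    if grid is None:
        grid = SpectralGrid.logspaced(2)
    return lognormal_mixture_spectrum(
        GROUND_TRUTH_2D_PEAKS, [GROUND_TRUTH_SD] * 3, grid=grid
    )


def mixture_3d_default(grid: SpectralGrid | None = None) -> CDTDSpectrum:
    """Three-peak 3D (lambda1, lambda2, lambda3) ground-truth mixture."""
    if grid is None:
        grid = SpectralGrid.logspaced(3)
    return lognormal_mixture_spectrum(
        GROUND_TRUTH_3D_PEAKS, [GROUND_TRUTH_SD] * 3, grid=grid
    )


@dataclass
class PhantomVolume:
    """Voxel lattice of ground-truth spectra and reference frames.

    Lattice axes are (depth, arc, axial) on the cortical ribbon. ``frames``
    holds one orthonormal 3x3 matrix per voxel whose *columns* are the
    eigenvectors (eps1 = radial). ``layer_index`` maps each voxel to an
    entry of ``layer_spectra``.
    """

    shape: tuple[int, int, int]
    voxel_size: float  # mm
    curvature_radius: float  # mm
    frames: np.ndarray  # shape + (3, 3)
    layer_index: np.ndarray  # shape, int
    layer_spectra: list[CDTDSpectrum]

    @property
    def theta_max(self) -> float:
        return theta_max(self.voxel_size, self.curvature_radius)

    def spectrum_at(self, idx: tuple[int, int, int]) -> CDTDSpectrum:
        return self.layer_spectra[int(self.layer_index[idx])]

    def radial_directions(self) -> np.ndarray:
        """Per-voxel radial unit vector (eps1), shape + (3,)."""
        return self.frames[..., :, 0]


def curved_cortex_phantom(
    shape: tuple[int, int, int],
    x: float,
    R: float,
    layer_spectra: list[CDTDSpectrum],
    seed: int = 0,
) -> PhantomVolume:
    """Cylindrical cortical-ribbon phantom with curvature-bounded frames.

    The ribbon is parameterized in cylindrical coordinates (depth, arc,
    axial): the radial eigenvector rotates in-plane by exactly
    ``theta_max(x, R)`` per arc step, so the lattice realizes the maximal
    adjacent-frame rotation admitted by the curvature bound; depth and
    axial neighbors share identical frames. ``R = inf`` yields a flat
    ribbon with constant frames. Layers are contiguous depth bands,
    assigned in order of ``layer_spectra``.
    """
    if not np.isinf(R) and R <= x:
        raise ValueError("curvature radius R must exceed the voxel size x")
    if len(layer_spectra) < 1:
        raise ValueError("at least one layer spectrum required")
    n_depth, n_arc, n_axial = shape
    dphi = 0.0 if np.isinf(R) else np.radians(theta_max(x, R))

    frames = np.zeros(shape + (3, 3))
    for j in range(n_arc):
        phi = j * dphi
        radial = np.array([np.cos(phi), np.sin(phi), 0.0])
        tangent = np.array([-np.sin(phi), np.cos(phi), 0.0])
        axial = np.array([0.0, 0.0, 1.0])
        F = np.stack([radial, tangent, axial], axis=1)
        frames[:, j, :, :, :] = F

    depth_edges = np.linspace(0, n_depth, len(layer_spectra) + 1)
    layer_index = np.zeros(shape, dtype=int)
    for i in range(n_depth):
        layer = int(np.searchsorted(depth_edges[1:-1], i, side="right"))
        layer_index[i, :, :] = layer

    return PhantomVolume(
        shape=tuple(shape),
        voxel_size=float(x),
        curvature_radius=float(R),
        frames=frames,
        layer_index=layer_index,
        layer_spectra=list(layer_spectra),
    )


def add_rician_noise(
    signals: np.ndarray,
    snr: float,
    s0: float = 1.0,
    seed: int | np.random.Generator = 0,
) -> np.ndarray:
    """Rician-corrupt magnitude signals at a given SNR.

    The noise standard deviation is ``sigma = s0 / snr`` in both quadrature
    channels: the output is ``sqrt((S + n1)^2 + n2^2)``. ``snr = inf``
    returns the input unchanged. SNR is defined as the mean magnitude
    signal divided by the noise standard deviation.
    """
    signals = np.asarray(signals, dtype=float)
    if not (snr > 0):
        raise ValueError("snr must be positive (or inf)")
    if np.isinf(snr):
        return signals.copy()
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    sigma = s0 / snr
    n1 = rng.normal(0.0, sigma, signals.shape)
    n2 = rng.normal(0.0, sigma, signals.shape)
    return np.sqrt((signals + n1) ** 2 + n2**2)
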