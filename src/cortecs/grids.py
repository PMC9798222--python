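"""Log-spaced diffusivity grids and discrete cDTD spectra.

A constrained diffusion tensor distribution (cDTD) assigns all microscopic
tensors in a voxel a common orthonormal eigenframe, so the distribution is
fully described by the joint distribution of principal diffusivities.
Discretized, that is a non-negative weight array over a logarithmically
spaced grid with 1 (isotropic, ``lambda0``), 2 (axisymmetric, ``lambda_r``,
``lambda_t``) or 3 (``lambda1``, ``lambda2``, ``lambda3``) axes.

Diffusivities are in um^2/ms throughout.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["SpectralGrid", "CDTDSpectrum", "DEFAULT_GRID_BOUNDS", "DEFAULT_GRID_N"]

#: Default spectral range (um^2/ms) and nodes per axis for reconstruction.
DEFAULT_GRID_BOUNDS = (0.01, 2.00)
DEFAULT_GRID_N = 12

_AXIS_NAMES = {
    1: ("lambda0",),
    2: ("lambda_r", "lambda_t"),
    3: ("lambda1", "lambda2", "lambda3"),
}


@dataclass(frozen=True)
class SpectralGrid:
    """Logarithmically spaced diffusivity grid with 1, 2 or 3 axes.

    Parameters
    ----------
    nodes :
        Tuple of strictly increasing, strictly positive node arrays
        (um^2/ms), one per axis.
    names :
        Axis names; defaults depend on dimensionality
        (``lambda0`` / ``lambda_r, lambda_t`` / ``lambda1..3``).
    """

    nodes: tuple[np.ndarray, ...]
    names: tuple[str, ...] = field(default=())

    def __post_init__(self) -> None:
        nodes = tuple(np.asarray(ax, dtype=float) for ax in self.nodes)
        if not 1 <= len(nodes) <= 3:
            raise ValueError("grid must have 1, 2 or 3 axes")
        for ax in nodes:
            if ax.ndim != 1 or ax.size < 1:
                raise ValueError("each axis must be a 1D array of nodes")
            if np.any(ax <= 0):
                raise ValueError("diffusivity nodes must be positive")
            if np.any(np.diff(ax) <= 0):
                raise ValueError("diffusivity nodes must be strictly increasing")
        object.__setattr__(self, "nodes", nodes)
        names = self.names or _AXIS_NAMES[len(nodes)]
        if len(names) != len(nodes):
            raise ValueError("one name per axis required")
        object.__setattr__(self, "names", tuple(names))

    @classmethod
    def logspaced(
        cls,
        ndim: int,
        n: int = DEFAULT_GRID_N,
        bounds: tuple[float, float] = DEFAULT_GRID_BOUNDS,
        names: tuple[str, ...] | None = None,
    ) -> "SpectralGrid":
        """Build an ``ndim``-axis grid of ``n`` log-spaced nodes per axis."""
        lo, hi = bounds
        if not (0 < lo < hi):
            raise ValueError("bounds must satisfy 0 < min < max")
        axis = np.geomspace(lo, hi, n)
        return cls(tuple(axis.copy() for _ in range(ndim)), names or ())

    @property
    def ndim(self) -> int:
        return len(self.nodes)

    @property
    def shape(self) -> tuple[int, ...]:
        return tuple(ax.size for ax in self.nodes)

    @property
    def size(self) -> int:
        return int(np.prod(self.shape))

    def meshnodes(self) -> np.ndarray:
        """All grid nodes as an (n_nodes, ndim) array in C (row-major) order."""
        mesh = np.meshgrid(*self.nodes, indexing="ij")
        return np.stack([m.ravel() for m in mesh], axis=-1)

    def log_spacing(self, axis: int = 0) -> float:
        """Uniform spacing of one axis in natural-log diffusivity."""
        ax = self.nodes[axis]
        if ax.size < 2:
            return 0.0
        return float(np.log(ax[1]) - np.log(ax[0]))

    def to_dict(self) -> dict:
        return {
            "names": list(self.names),
            "nodes": [ax.tolist() for ax in self.nodes],
            "units": "um^2/ms",
        }

    @classmethod
    def from_dict(cls, d: dict) -> "SpectralGrid":
        return cls(tuple(np.asarray(ax) for ax in d["nodes"]), tuple(d["names"]))


@dataclass
class CDTDSpectrum:
    """Non-negative weights over a :class:`SpectralGrid`.

    ``weights`` has the grid's shape; weights are dimensionless signal
    fractions. A normalized spectrum sums to 1.
    """

    grid: SpectralGrid
    weights: np.ndarray

    def __post_init__(self) -> None:
        w = np.asarray(self.weights, dtype=float)
        if w.shape != self.grid.shape:
            raise ValueError(
                f"weights shape {w.shape} does not match grid shape {self.grid.shape}"
            )
        if np.any(w < 0):
            raise ValueError("spectrum weights must be non-negative")
        self.weights = w

    @property
    def mass(self) -> float:
        return float(self.weights.sum())

    def normalized(self) -> "CDTDSpectrum":
        """Unit-mass copy; a zero spectrum is returned unchanged."""
        m = self.mass
        if m == 0:
            return CDTDSpectrum(self.grid, self.weights.copy())
        return CDTDSpectrum(self.grid, self.weights / m)

    def flat(self) -> np.ndarray:
        """Weights flattened in C order, matching ``grid.meshnodes()``."""
        return self.weights.ravel()
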