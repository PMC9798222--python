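"""Derived spectra: microscopic FA / MD distributions, their joint
correlation spectrum, marginals, moments, and spectral-ROI component maps.

Every node of a cDTD spectrum corresponds to one microscopic diffusion
tensor: (lambda0, lambda0, lambda0) in 1D, (lambda_r, lambda_t, lambda_t)
in the axisymmetric 2D case, or (lambda1, lambda2, lambda3) in 3D. The
node's microscopic fractional anisotropy

    alpha = sqrt( 0.5 * [(l1-l2)^2 + (l2-l3)^2 + (l3-l1)^2]
                  / (l1^2 + l2^2 + l3^2) )  in [0, 1]

and mean diffusivity mu = (l1 + l2 + l3)/3 place its mass into an
(alpha, mu) bin; the resulting joint histogram and its marginals conserve
the parent spectrum's mass. Moments (e.g. the microscopic anisotropy muFA
= mean of p_FA) are computed from the unbinned node values, which is exact;
binned versions exist only for display parity.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import yaml

from .grids import CDTDSpectrum, SpectralGrid

__all__ = [
    "micro_fa",
    "micro_md",
    "node_tensors",
    "DerivedSpectra",
    "fa_md_spectrum",
    "marginalize",
    "SpectralROI",
    "integrate_roi",
    "spectrum_moments",
    "load_rois",
    "save_rois",
    "DEFAULT_FA_MD_BINS",
]

#: Default bin count per axis of the FA-MD correlation spectrum.
DEFAULT_FA_MD_BINS = 11


def micro_fa(l1, l2, l3):
    """Fractional anisotropy of a microscopic tensor; vectorized, in [0, 1]."""
    l1, l2, l3 = np.broadcast_arrays(
        np.asarray(l1, float), np.asarray(l2, float), np.asarray(l3, float)
    )
    if np.any(l1 < 0) or np.any(l2 < 0) or np.any(l3 < 0):
        raise ValueError("eigenvalues must be non-negative")
    denom = l1**2 + l2**2 + l3**2
    if np.any(denom == 0):
        raise ValueError("FA undefined for an all-zero tensor")
    num = 0.5 * ((l1 - l2) ** 2 + (l2 - l3) ** 2 + (l3 - l1) ** 2)
    out = np.sqrt(num / denom)
    return float(out) if out.ndim == 0 else out


def micro_md(l1, l2, l3):
    """Mean diffusivity (l1 + l2 + l3) / 3 of a microscopic tensor."""
    out = (np.asarray(l1, float) + np.asarray(l2, float) + np.asarray(l3, float)) / 3.0
    return float(out) if out.ndim == 0 else out


def node_tensors(grid: SpectralGrid) -> np.ndarray:
    """(n_nodes, 3) eigenvalue triples implied by a 1/2/3-axis grid."""
    nodes = grid.meshnodes()
    if grid.ndim == 1:
        return np.repeat(nodes, 3, axis=1)
    if grid.ndim == 2:  # (lambda_r, lambda_t) -> (lambda_r, lambda_t, lambda_t)
        return np.column_stack([nodes[:, 0], nodes[:, 1], nodes[:, 1]])
    return nodes


@dataclass
class DerivedSpectra:
    """Joint and marginal FA/MD distributions plus exact moments."""

    p_fa_md: np.ndarray  # (n_fa_bins, n_md_bins)
    fa_edges: np.ndarray
    md_edges: np.ndarray
    mu_fa: float  # mean microscopic FA (exact, unbinned)
    var_fa: float
    mean_md: float  # um^2/ms

    @property
    def p_fa(self) -> np.ndarray:
        return self.p_fa_md.sum(axis=1)

    @property
    def p_md(self) -> np.ndarray:
        return self.p_fa_md.sum(axis=0)

    @property
    def fa_centers(self) -> np.ndarray:
        return 0.5 * (self.fa_edges[:-1] + self.fa_edges[1:])

    @property
    def md_centers(self) -> np.ndarray:
        return 0.5 * (self.md_edges[:-1] + self.md_edges[1:])


def fa_md_spectrum(
    spectrum: CDTDSpectrum,
    fa_bins: int = DEFAULT_FA_MD_BINS,
    md_bins: int = DEFAULT_FA_MD_BINS,
    md_range: tuple[float, float] | None = None,
) -> DerivedSpectra:
    """Accumulate a cDTD's node masses into an FA x MD histogram.

    FA bins are uniform on [0, 1]; MD bins uniform on ``md_range``
    (default [0, grid max]). Node masses falling outside the MD range go
    to the nearest edge bin with a warning. Moments are mass-weighted over
    the unbinned node values.
    """
    lam = node_tensors(spectrum.grid)
    p = spectrum.flat()
    alpha = micro_fa(lam[:, 0], lam[:, 1], lam[:, 2])
    mu = micro_md(lam[:, 0], lam[:, 1], lam[:, 2])

    if md_range is None:
        md_range = (0.0, float(max(ax[-1] for ax in spectrum.grid.nodes)))
    fa_edges = np.linspace(0.0, 1.0, fa_bins + 1)
    md_edges = np.linspace(md_range[0], md_range[1], md_bins + 1)
    if np.any((mu < md_edges[0]) | (mu > md_edges[-1])):
        warnings.warn("node MD outside histogram range; assigned to edge bin",
                      stacklevel=2)
    i = np.clip(np.searchsorted(fa_edges, alpha, side="right") - 1, 0, fa_bins - 1)
    j = np.clip(np.searchsorted(md_edges, mu, side="right") - 1, 0, md_bins - 1)
    joint = np.zeros((fa_bins, md_bins))
    np.add.at(joint, (i, j), p)

    mass = p.sum()
    if mass > 0:
        mu_fa = float(np.sum(p * alpha) / mass)
        var_fa = float(np.sum(p * (alpha - mu_fa) ** 2) / mass)
        mean_md = float(np.sum(p * mu) / mass)
    else:
        mu_fa = var_fa = mean_md = float("nan")
    return DerivedSpectra(joint, fa_edges, md_edges, mu_fa, var_fa, mean_md)


def marginalize(spectrum: CDTDSpectrum, keep_axes) -> CDTDSpectrum:
    """Sum a spectrum over the axes not listed in ``keep_axes``.

    ``keep_axes`` may hold axis indices or axis names; mass is conserved
    exactly. The result's axes keep their original order and names.
    """
    if isinstance(keep_axes, (int, str)):
        keep_axes = [keep_axes]
    idx = []
    for ax in keep_axes:
        if isinstance(ax, str):
            if ax not in spectrum.grid.names:
                raise ValueError(f"unknown axis name {ax!r}")
            idx.append(spectrum.grid.names.index(ax))
        else:
            idx.append(int(ax))
    if not idx:
        raise ValueError("keep_axes must not be empty")
    if len(set(idx)) != len(idx) or not all(0 <= k < spectrum.grid.ndim for k in idx):
        raise ValueError("keep_axes must be distinct valid axes")
    idx = sorted(idx)
    drop = tuple(k for k in range(spectrum.grid.ndim) if k not in idx)
    w = spectrum.weights.sum(axis=drop) if drop else spectrum.weights.copy()
    sub = SpectralGrid(
        tuple(spectrum.grid.nodes[k] for k in idx),
        tuple(spectrum.grid.names[k] for k in idx),
    )
    return CDTDSpectrum(sub, w)


@dataclass
class SpectralROI:
    """Named boolean membership mask over a spectral grid's bins."""

    name: str
    mask: np.ndarray

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=bool)

    @classmethod
    def from_ranges(cls, name: str, grid: SpectralGrid, ranges: dict) -> "SpectralROI":
        """Rectangular ROI from per-axis (min, max) diffusivity ranges.

        ``ranges`` maps axis names to inclusive [lo, hi] bounds in
        um^2/ms; unnamed axes are unconstrained.
        """
        mask = np.ones(grid.shape, dtype=bool)
        for axis_name, (lo, hi) in ranges.items():
            if axis_name not in grid.names:
                raise ValueError(f"unknown axis name {axis_name!r}")
            k = grid.names.index(axis_name)
            within = (grid.nodes[k] >= lo) & (grid.nodes[k] <= hi)
            shape = [1] * grid.ndim
            shape[k] = -1
            mask &= within.reshape(shape)
        return cls(name, mask)


def integrate_roi(
    spectrum_map: np.ndarray,
    rois: list[SpectralROI],
    grid: SpectralGrid,
    partition: bool = False,
) -> dict[str, np.ndarray]:
    """Per-voxel fraction of (normalized) spectral mass inside each ROI.

    ``spectrum_map`` is (..., n_bins) with bins in C order over the grid.
    In ``partition`` mode the ROIs must be pairwise disjoint, so fractions
    sum to the voxel's total mass.
    """
    spectrum_map = np.asarray(spectrum_map, dtype=float)
    if spectrum_map.shape[-1] != grid.size:
        raise ValueError("spectrum_map bin count must match the grid")
    if partition:
        stacked = np.stack([r.mask.ravel() for r in rois])
        if np.any(stacked.sum(axis=0) > 1):
            raise ValueError("partition ROIs must be disjoint")
    out = {}
    for roi in rois:
        if roi.mask.shape != grid.shape:
            raise ValueError(f"ROI {roi.name!r} mask shape must match the grid")
        out[roi.name] = spectrum_map @ roi.mask.ravel().astype(float)
    return out


def spectrum_moments(values: np.ndarray, masses: np.ndarray) -> tuple[float, float]:
    """Mass-weighted mean and variance of a 1D distribution."""
    values = np.asarray(values, dtype=float).ravel()
    masses = np.asarray(masses, dtype=float).ravel()
    total = masses.sum()
    if total <= 0:
        raise ValueError("moments undefined for zero total mass")
    mean = float(np.sum(masses * values) / total)
    var = float(np.sum(masses * (values - mean) ** 2) / total)
    return mean, var


def load_rois(path, grid: SpectralGrid) -> list[SpectralROI]:
    """Read ROI definitions from YAML (named per-axis ranges or bin masks)."""
    with open(path) as f:
        doc = yaml.safe_load(f)
    rois = []
    for entry in doc["rois"]:
        if "ranges" in entry:
            rois.append(SpectralROI.from_ranges(entry["name"], grid, {
                k: tuple(v) for k, v in entry["ranges"].items()
            }))
        else:
            rois.append(SpectralROI(entry["name"],
                                    np.asarray(entry["mask"]).reshape(grid.shape)))
    return rois


def save_rois(rois: list[SpectralROI], path) -> None:
    doc = {"rois": [{"name": r.name, "mask": r.mask.astype(int).ravel().tolist()}
                    for r in rois]}
    with open(path, "w") as f:
        yaml.safe_dump(doc, f)
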