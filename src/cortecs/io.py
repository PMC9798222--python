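"""NIfTI / sidecar I/O and run manifests.

Spectrum maps are stored as 5D NIfTI (x, y, z, 1, n_bins) with bins
flattened in C (row-major) order over the grid axes, accompanied by a
JSON sidecar naming the axes and listing the node diffusivities. Frame
fields are 4D NIfTI with 9 components (the 3x3 eigenvector-column matrix
flattened row-major). Every pipeline run writes a manifest recording
inputs, parameters and seeds.
"""

from __future__ import annotations

import json
from pathlib import Path

import nibabel as nib
import numpy as np

from .grids import SpectralGrid

__all__ = [
    "save_scalar_map",
    "load_scalar_map",
    "save_spectrum_map",
    "load_spectrum_map",
    "save_frames",
    "load_frames",
    "save_dwi",
    "load_dwi",
    "write_manifest",
]


def _affine(voxel_size: float = 1.0) -> np.ndarray:
    aff = np.eye(4)
    aff[:3, :3] *= voxel_size
    return aff


def save_scalar_map(data: np.ndarray, path: str | Path, voxel_size: float = 1.0) -> None:
    nib.save(nib.Nifti1Image(np.asarray(data, dtype=np.float64), _affine(voxel_size)),
             str(path))


def load_scalar_map(path: str | Path) -> np.ndarray:
    return np.asarray(nib.load(str(path)).get_fdata())


def save_spectrum_map(
    spectra: np.ndarray,
    grid: SpectralGrid,
    path: str | Path,
    voxel_size: float = 1.0,
) -> None:
    """Write an (x, y, z, n_bins) spectrum map as 5D NIfTI + JSON sidecar."""
    spectra = np.asarray(spectra, dtype=np.float64)
    if spectra.shape[-1] != grid.size:
        raise ValueError("bin count must match the grid")
    img5d = spectra.reshape(spectra.shape[:3] + (1, grid.size))
    nib.save(nib.Nifti1Image(img5d, _affine(voxel_size)), str(path))
    sidecar = Path(str(path)).with_suffix("").with_suffix("")  # strip .nii[.gz]
    with open(str(sidecar) + ".json", "w") as f:
        json.dump({"grid": grid.to_dict(), "bin_order": "C"}, f, indent=2)


def load_spectrum_map(path: str | Path) -> tuple[np.ndarray, SpectralGrid]:
    data = np.asarray(nib.load(str(path)).get_fdata())
    if data.ndim == 5:
        data = data.reshape(data.shape[:3] + (data.shape[-1],))
    sidecar = Path(str(path)).with_suffix("").with_suffix("")
    with open(str(sidecar) + ".json") as f:
        meta = json.load(f)
    return data, SpectralGrid.from_dict(meta["grid"])


def save_frames(frames: np.ndarray, path: str | Path, voxel_size: float = 1.0) -> None:
    """Write an (x, y, z, 3, 3) frame field as a 9-component 4D NIfTI."""
    frames = np.asarray(frames, dtype=np.float64)
    flat = frames.reshape(frames.shape[:3] + (9,))
    nib.save(nib.Nifti1Image(flat, _affine(voxel_size)), str(path))


def load_frames(path: str | Path) -> np.ndarray:
    data = np.asarray(nib.load(str(path)).get_fdata())
    return data.reshape(data.shape[:3] + (3, 3))


def save_dwi(dwis: np.ndarray, path: str | Path, voxel_size: float = 1.0) -> None:
    nib.save(nib.Nifti1Image(np.asarray(dwis, dtype=np.float64), _affine(voxel_size)),
             str(path))


def load_dwi(path: str | Path) -> np.ndarray:
    return np.asarray(nib.load(str(path)).get_fdata())


def write_manifest(path: str | Path, **fields) -> None:
    """JSON manifest of a run: parameters, seeds, file paths, version."""
    from . import __version__

    doc = {"tool": "cortecs", "version": __version__}
    doc.update(fields)

    def default(o):
        if isinstance(o, np.ndarray):
            return o.tolist()
        if isinstance(o, (np.floating, np.integer)):
            return o.item()
        if isinstance(o, Path):
            return str(o)
        raise TypeError(f"not JSON-serializable: {type(o)}")

    with open(str(path), "w") as f:
        json.dump(doc, f, indent=2, default=default)
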