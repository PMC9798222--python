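"""Diffusion-encoding schemes: shells, gradient directions, b-tensors.

Conventions
-----------
* b-values in s/mm^2, diffusivities elsewhere in um^2/ms; exponents use an
  explicit 1e-3 conversion so ``b * lambda`` is dimensionless.
* bvec files follow the FSL dialect: three whitespace-separated rows
  (x, y, z), one column per volume, in the image coordinate frame. No
  reorientation is applied on read or write.
* Gradient directions are generated by antipodally symmetric electrostatic
  (Coulomb) repulsion per shell, followed by a joint across-shell spread
  pass that rigidly rotates whole shells to minimize their mutual repulsion
  energy. Deterministic for a fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.optimize import minimize
from scipy.spatial.transform import Rotation

__all__ = [
    "Encoding",
    "AcquisitionScheme",
    "PROTOCOL_SHELLS",
    "DEFAULT_DELTA_MS",
    "DEFAULT_BIG_DELTA_MS",
    "B_LAMBDA_SCALE",
    "uniform_directions",
    "build_protocol",
    "btensor_from_sde",
    "read_bvals_bvecs",
    "write_bvals_bvecs",
    "read_btensor_table",
    "write_btensor_table",
]

#: Conversion so that b [s/mm^2] x diffusivity [um^2/ms] is dimensionless.
B_LAMBDA_SCALE = 1e-3

#: Six-shell acquisition: (b-value s/mm^2, direction count), 112 encodings.
PROTOCOL_SHELLS: tuple[tuple[float, int], ...] = (
    (100, 3),
    (1000, 9),
    (2500, 15),
    (4500, 21),
    (7000, 28),
    (10000, 36),
)

#: Gradient pulse duration / separation (ms); metadata only.
DEFAULT_DELTA_MS = 6.0
DEFAULT_BIG_DELTA_MS = 28.0


@dataclass(frozen=True)
class Encoding:
    """One diffusion weighting: b-value, direction, timings, optional b-tensor."""

    b: float
    g: np.ndarray
    delta: float = DEFAULT_DELTA_MS
    Delta: float = DEFAULT_BIG_DELTA_MS
    btensor: np.ndarray | None = None

    def __post_init__(self) -> None:
        g = np.asarray(self.g, dtype=float).reshape(3)
        if self.b < 0:
            raise ValueError("b-value must be non-negative")
        if self.b > 0 and abs(np.linalg.norm(g) - 1.0) > 1e-9:
            raise ValueError("gradient direction must be a unit vector when b > 0")
        object.__setattr__(self, "g", g)
        if self.btensor is not None:
            bt = np.asarray(self.btensor, dtype=float).reshape(3, 3)
            if abs(np.trace(bt) - self.b) > 1e-6 * max(1.0, self.b):
                raise ValueError("trace of b-tensor must equal the b-value")
            if np.min(np.linalg.eigvalsh((bt + bt.T) / 2)) < -1e-6 * max(1.0, self.b):
                raise ValueError("b-tensor must be positive semidefinite")
            object.__setattr__(self, "btensor", bt)


@dataclass
class AcquisitionScheme:
    """Ordered list of encodings plus the shell table that produced them."""

    encodings: list[Encoding]
    shell_table: list[tuple[float, int]] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.shell_table:
            expected = sum(n for _, n in self.shell_table)
            if expected != len(self.encodings):
                raise ValueError(
                    "total encoding count must equal the sum of shell counts"
                )

    def __len__(self) -> int:
        return len(self.encodings)

    @property
    def bvals(self) -> np.ndarray:
        return np.array([e.b for e in self.encodings])

    @property
    def bvecs(self) -> np.ndarray:
        """(n, 3) array of gradient directions."""
        return np.array([e.g for e in self.encodings])

    @classmethod
    def from_tables(
        cls,
        bvals: np.ndarray,
        bvecs: np.ndarray,
        delta: float = DEFAULT_DELTA_MS,
        Delta: float = DEFAULT_BIG_DELTA_MS,
    ) -> "AcquisitionScheme":
        bvals = np.asarray(bvals, dtype=float).ravel()
        bvecs = np.asarray(bvecs, dtype=float)
        if bvecs.shape == (3, bvals.size):
            bvecs = bvecs.T
        if bvecs.shape != (bvals.size, 3):
            raise ValueError("bvecs must be (n, 3) or (3, n) matching bvals")
        encs = []
        for b, g in zip(bvals, bvecs):
            nrm = np.linalg.norm(g)
            if b > 0 and nrm > 0:
                g = g / nrm
            elif nrm == 0:
                g = np.array([1.0, 0.0, 0.0])
            encs.append(Encoding(float(b), g, delta, Delta))
        return cls(encs)


def _pair_energy_and_force(u: np.ndarray) -> tuple[float, np.ndarray]:
    """Antipodal Coulomb energy and per-point tangent forces on the sphere."""
    n = u.shape[0]
    energy = 0.0
    force = np.zeros_like(u)
    for i in range(n):
        d = u[i] - u[i + 1 :]
        s = u[i] + u[i + 1 :]
        dn = np.linalg.norm(d, axis=1)
        sn = np.linalg.norm(s, axis=1)
        dn = np.maximum(dn, 1e-12)
        sn = np.maximum(sn, 1e-12)
        energy += float(np.sum(1.0 / dn) + np.sum(1.0 / sn))
        fd = d / dn[:, None] ** 3
        fs = s / sn[:, None] ** 3
        force[i] += fd.sum(axis=0) + fs.sum(axis=0)
        force[i + 1 :] += -fd + fs
    # project onto tangent planes
    force -= (np.sum(force * u, axis=1, keepdims=True)) * u
    return energy, force


def uniform_directions(n: int, seed: int = 0) -> np.ndarray:
    """``n`` unit vectors spread by antipodally symmetric Coulomb repulsion.

    Projected-gradient descent with adaptive step from a seeded random start;
    bit-for-bit reproducible for fixed ``(n, seed)``.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    u = rng.standard_normal((n, 3))
    u /= np.linalg.norm(u, axis=1, keepdims=True)
    if n == 1:
        return u
    step = 0.1
    energy, force = _pair_energy_and_force(u)
    for _ in range(2000):
        trial = u + step * force
        trial /= np.linalg.norm(trial, axis=1, keepdims=True)
        e_new, f_new = _pair_energy_and_force(trial)
        if e_new < energy:
            u, energy, force = trial, e_new, f_new
            step *= 1.1
        else:
            step *= 0.5
            if step < 1e-12:
                break
    return u


def _cross_energy(a: np.ndarray, b: np.ndarray) -> float:
    """Antipodal Coulomb energy between two point sets."""
    d = a[:, None, :] - b[None, :, :]
    s = a[:, None, :] + b[None, :, :]
    dn = np.maximum(np.linalg.norm(d, axis=-1), 1e-12)
    sn = np.maximum(np.linalg.norm(s, axis=-1), 1e-12)
    return float(np.sum(1.0 / dn) + np.sum(1.0 / sn))


def _joint_spread(shell_dirs: list[np.ndarray]) -> list[np.ndarray]:
    """Rigidly rotate shells (first held fixed) to spread directions jointly."""
    dirs = [d.copy() for d in shell_dirs]
    for _ in range(2):  # two sweeps suffice; energy changes are tiny after that
        for k in range(1, len(dirs)):
            others = np.vstack([d for j, d in enumerate(dirs) if j != k])

            def cost(rotvec: np.ndarray, k: int = k, others: np.ndarray = others) -> float:
                rot = Rotation.from_rotvec(rotvec).as_matrix()
                return _cross_energy(dirs[k] @ rot.T, others)

            res = minimize(cost, np.zeros(3), method="Powell",
                           options={"xtol": 1e-6, "ftol": 1e-9, "maxiter": 200})
            dirs[k] = dirs[k] @ Rotation.from_rotvec(res.x).as_matrix().T
            dirs[k] /= np.linalg.norm(dirs[k], axis=1, keepdims=True)
    return dirs


def build_protocol(
    shells: list[tuple[float, int]] | tuple[tuple[float, int], ...] = PROTOCOL_SHELLS,
    delta: float = DEFAULT_DELTA_MS,
    Delta: float = DEFAULT_BIG_DELTA_MS,
    seed: int = 0,
) -> AcquisitionScheme:
    """Multi-shell scheme with per-shell repulsion-optimized directions.

    Each shell's directions minimize antipodal Coulomb energy independently,
    then shells are jointly spread by rigid rotations. The default shells
    give the six-shell, 112-encoding protocol.
    """
    shells = [(float(b), int(n)) for b, n in shells]
    for b, n in shells:
        if b < 0:
            raise ValueError("b-values must be non-negative")
        if n < 1:
            raise ValueError("direction counts must be >= 1")
    shell_dirs = [uniform_directions(n, seed=seed + i) for i, (_, n) in enumerate(shells)]
    if len(shells) > 1:
        shell_dirs = _joint_spread(shell_dirs)
    encodings = []
    for (b, _), dirs in zip(shells, shell_dirs):
        for g in dirs:
            encodings.append(Encoding(b, g, delta, Delta))
    return AcquisitionScheme(encodings, shell_table=shells)


def btensor_from_sde(b: float, g: np.ndarray) -> np.ndarray:
    """Rank-1 b-tensor ``b * g g^T`` of a single-diffusion-encoding pulse."""
    g = np.asarray(g, dtype=float).reshape(3)
    if b < 0:
        raise ValueError("b-value must be non-negative")
    if b > 0 and abs(np.linalg.norm(g) - 1.0) > 1e-9:
        raise ValueError("gradient direction must be a unit vector")
    if b == 0:
        return np.zeros((3, 3))
    return b * np.outer(g, g)


# ---------------------------------------------------------------------------
# FSL-style gradient table I/O

def read_bvals_bvecs(bval_path: str | Path, bvec_path: str | Path) -> tuple[np.ndarray, np.ndarray]:
    """Read FSL bval (one row) and bvec (three rows) files.

    Returns ``(bvals, bvecs)`` with bvecs as an (n, 3) array.
    """
    bvals = np.loadtxt(bval_path).ravel()
    bvecs = np.loadtxt(bvec_path)
    if bvecs.ndim == 1:
        bvecs = bvecs.reshape(3, -1)
    if bvecs.shape[0] != 3:
        raise ValueError("bvec file must have three rows (x, y, z)")
    if bvecs.shape[1] != bvals.size:
        raise ValueError("bval/bvec column counts disagree")
    return bvals, bvecs.T


def write_bvals_bvecs(
    scheme: AcquisitionScheme, bval_path: str | Path, bvec_path: str | Path
) -> None:
    """Write bval/bvec text files; round-trips losslessly to 6 significant digits."""
    bvals = scheme.bvals
    bvecs = scheme.bvecs.T  # 3 x n
    with open(bval_path, "w") as f:
        f.write(" ".join(f"{b:.6g}" for b in bvals) + "\n")
    with open(bvec_path, "w") as f:
        for row in bvecs:
            f.write(" ".join(f"{v:.6g}" for v in row) + "\n")


_UT_IDX = [(0, 0), (0, 1), (0, 2), (1, 1), (1, 2), (2, 2)]


def read_btensor_table(path: str | Path) -> np.ndarray:
    """Read a plain-text b-tensor table (bxx bxy bxz byy byz bzz per row, s/mm^2)."""
    rows = np.atleast_2d(np.loadtxt(path))
    if rows.shape[1] != 6:
        raise ValueError("b-tensor table must have six columns (upper triangle)")
    out = np.zeros((rows.shape[0], 3, 3))
    for k, (i, j) in enumerate(_UT_IDX):
        out[:, i, j] = rows[:, k]
        out[:, j, i] = rows[:, k]
    return out


def write_btensor_table(btensors: np.ndarray, path: str | Path) -> None:
    bt = np.asarray(btensors, dtype=float).reshape(-1, 3, 3)
    with open(path, "w") as f:
        for t in bt:
            f.write(" ".join(f"{t[i, j]:.6g}" for i, j in _UT_IDX) + "\n")
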