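"""Diffusion-tensor data model and the deviatoric tensor metric.

Tensors are stored as 6-vectors in lower-triangular order
``(Dxx, Dxy, Dyy, Dxz, Dyz, Dzz)`` (the NIfTI symmetric-matrix convention),
with units mm^2/s.  All tensor arithmetic is vectorized over leading axes, so
the same functions serve single tensors and whole volumes.

The similarity metric used for registration is the deviatoric (non-Euclidean)
tensor norm: the Frobenius distance between the anisotropic parts of the two
tensors, scaled by sqrt(8*pi/15).  An isotropic difference between two tensors
therefore contributes nothing — the metric sees only disagreement in
anisotropy, which is what makes it suitable for aligning white-matter
structure.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import nibabel as nib
import numpy as np

logger = logging.getLogger(__name__)

#: index pairs of the 6 unique components in the 3x3 matrix
_TRI_IDX = [(0, 0), (0, 1), (1, 1), (0, 2), (1, 2), (2, 2)]
#: multiplicity of each component in the full symmetric matrix
_TRI_WEIGHT = np.array([1.0, 2.0, 1.0, 2.0, 2.0, 1.0])
#: positions of the diagonal components Dxx, Dyy, Dzz in the 6-vector
_DIAG = [0, 2, 5]

DEVIATORIC_SCALE = np.sqrt(8.0 * np.pi / 15.0)


class GeometryError(ValueError):
    """Raised when two volumes do not share grid shape and affine."""


class InvalidSchemeError(ValueError):
    """Raised when a gradient scheme cannot support tensor fitting."""


# ---------------------------------------------------------------------------
# tensor algebra on (..., 6) arrays
# ---------------------------------------------------------------------------

def tensor_to_matrix(t6: np.ndarray) -> np.ndarray:
    """Expand (..., 6) lower-triangular components to (..., 3, 3) matrices."""
    t6 = np.asarray(t6, dtype=float)
    out = np.empty(t6.shape[:-1] + (3, 3), dtype=float)
    for k, (i, j) in enumerate(_TRI_IDX):
        out[..., i, j] = t6[..., k]
        out[..., j, i] = t6[..., k]
    return out


def matrix_to_tensor(m: np.ndarray) -> np.ndarray:
    """Collapse symmetric (..., 3, 3) matrices to (..., 6) components."""
    m = np.asarray(m, dtype=float)
    return np.stack([m[..., i, j] for (i, j) in _TRI_IDX], axis=-1)


def tensor_trace(t6: np.ndarray) -> np.ndarray:
    t6 = np.asarray(t6, dtype=float)
    return t6[..., _DIAG].sum(axis=-1)


def deviatoric(t6: np.ndarray) -> np.ndarray:
    """Anisotropic part of a tensor: D minus (trace(D)/3) * I.

    Each diagonal term is evaluated as (2a - b - c) / 3, which cancels
    exactly (not just to round-off) when the tensor is isotropic, so an
    isotropic difference has a deviatoric part of exactly zero.
    """
    t6 = np.asarray(t6, dtype=float)
    out = t6.copy()
    dxx, dyy, dzz = t6[..., 0], t6[..., 2], t6[..., 5]
    out[..., 0] = (2 * dxx - dyy - dzz) / 3.0
    out[..., 2] = (2 * dyy - dxx - dzz) / 3.0
    out[..., 5] = (2 * dzz - dxx - dyy) / 3.0
    return out


def tensor_norm_sq(t6: np.ndarray) -> np.ndarray:
    """Squared Frobenius norm of the full symmetric matrix from 6 components."""
    t6 = np.asarray(t6, dtype=float)
    return (_TRI_WEIGHT * t6 * t6).sum(axis=-1)


def tensor_distance(d1: np.ndarray, d2: np.ndarray) -> np.ndarray:
    """Deviatoric tensor distance sqrt(8*pi/15) * ||dev(D1) - dev(D2)||_F.

    Zero whenever D1 - D2 is isotropic; a pseudometric on tensors, a true
    metric on their anisotropic parts.
    """
    diff = deviatoric(np.asarray(d1, dtype=float) - np.asarray(d2, dtype=float))
    return DEVIATORIC_SCALE * np.sqrt(tensor_norm_sq(diff))


def fa(t6: np.ndarray) -> np.ndarray:
    """Fractional anisotropy via the Frobenius formula.

    FA = sqrt(3/2) * ||dev(D)||_F / ||D||_F, clamped to [0, 1]; a zero tensor
    has FA 0 by convention.  No eigen-decomposition is needed, so fitted
    tensors with small negative eigenvalues are handled without clipping.
    """
    t6 = np.asarray(t6, dtype=float)
    num = tensor_norm_sq(deviatoric(t6))
    den = tensor_norm_sq(t6)
    with np.errstate(divide="ignore", invalid="ignore"):
        out = np.sqrt(1.5 * num / den)
    out = np.where(den > 0, out, 0.0)
    return np.clip(out, 0.0, 1.0)


def principal_direction(t6: np.ndarray) -> np.ndarray:
    """Unit eigenvector of the largest eigenvalue, (..., 3)."""
    m = tensor_to_matrix(t6)
    _, vecs = np.linalg.eigh(m)
    return vecs[..., :, -1]


def rotate_tensor(t6: np.ndarray, r: np.ndarray) -> np.ndarray:
    """Apply R D R^T; ``r`` is (..., 3, 3) broadcastable against ``t6``."""
    m = tensor_to_matrix(t6)
    rot = np.einsum("...ij,...jk,...lk->...il", r, m, r)
    return matrix_to_tensor(rot)


# ---------------------------------------------------------------------------
# gradient schemes
# ---------------------------------------------------------------------------

@dataclass
class GradientScheme:
    """Diffusion-encoding table: one unit direction and b-value per volume.

    Parameters
    ----------
    directions : (n, 3) array
        Gradient directions; rows for b=0 volumes may be zero.
    b_values : (n,) array
        Diffusion weightings in s/mm^2 (0 for b0 volumes).
    """

    directions: np.ndarray
    b_values: np.ndarray

    def __post_init__(self) -> None:
        self.directions = np.atleast_2d(np.asarray(self.directions, dtype=float))
        self.b_values = np.asarray(self.b_values, dtype=float).ravel()
        if self.directions.shape != (self.b_values.size, 3):
            raise InvalidSchemeError(
                f"directions shape {self.directions.shape} does not match "
                f"{self.b_values.size} b-values"
            )
        norms = np.linalg.norm(self.directions[~self.b0_mask], axis=1)
        if norms.size and np.any(np.abs(norms - 1.0) > 1e-6):
            raise InvalidSchemeError("non-b0 directions must have unit norm")

    @property
    def b0_mask(self) -> np.ndarray:
        return self.b_values == 0

    @property
    def n_volumes(self) -> int:
        return self.b_values.size

    @property
    def n_dwi(self) -> int:
        return int((~self.b0_mask).sum())

    def validate_for_fitting(self) -> None:
        if not self.b0_mask.any():
            raise InvalidSchemeError("at least one b0 volume is required")
        if self.n_dwi < 6:
            raise InvalidSchemeError(
                f"tensor fitting needs >= 6 non-b0 directions, got {self.n_dwi}"
            )

    # -- plain-text I/O: one row per volume ---------------------------------
    def to_files(self, bval_path: str | Path, bvec_path: str | Path) -> None:
        np.savetxt(bval_path, self.b_values, fmt="%.6g")
        np.savetxt(bvec_path, self.directions, fmt="%.8f")

    @classmethod
    def from_files(cls, bval_path: str | Path, bvec_path: str | Path) -> "GradientScheme":
        bvals = np.loadtxt(bval_path)
        bvecs = np.loadtxt(bvec_path)
        return cls(directions=bvecs, b_values=bvals)


def uniform_directions(n: int, seed: int = 0) -> np.ndarray:
    """Approximately uniform unit directions via a golden-spiral lattice."""
    i = np.arange(n) + 0.5
    phi = np.arccos(1 - 2 * i / n)
    theta = np.pi * (1 + 5**0.5) * i
    return np.column_stack(
        [np.sin(phi) * np.cos(theta), np.sin(phi) * np.sin(theta), np.cos(phi)]
    )


def default_scheme(n_directions: int = 30, b_value: float = 1000.0) -> GradientScheme:
    """One b0 plus ``n_directions`` unit directions at ``b_value`` s/mm^2."""
    dirs = np.vstack([np.zeros(3), uniform_directions(n_directions)])
    bvals = np.concatenate([[0.0], np.full(n_directions, b_value)])
    return GradientScheme(directions=dirs, b_values=bvals)


# ---------------------------------------------------------------------------
# volumes
# ---------------------------------------------------------------------------

def _check_affine(affine: np.ndarray) -> np.ndarray:
    affine = np.asarray(affine, dtype=float)
    if affine.shape != (4, 4):
        raise GeometryError("affine must be 4x4")
    if abs(np.linalg.det(affine[:3, :3])) < 1e-12:
        raise GeometryError("affine must be invertible")
    return affine


@dataclass
class ScalarVolume:
    """A 3D scalar field with voxel-to-world affine and optional mask."""

    data: np.ndarray
    affine: np.ndarray = field(default_factory=lambda: np.eye(4))
    mask: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 3:
            raise GeometryError("ScalarVolume data must be 3D")
        self.affine = _check_affine(self.affine)
        if self.mask is not None:
            self.mask = np.asarray(self.mask, dtype=bool)
            if self.mask.shape != self.data.shape:
                raise GeometryError("mask shape must match data shape")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape  # type: ignore[return-value]

    def same_geometry(self, other: "ScalarVolume | TensorVolume") -> bool:
        return self.shape == other.shape and np.allclose(self.affine, other.affine)

    def to_nifti(self, path: str | Path) -> None:
        nib.save(nib.Nifti1Image(self.data.astype(np.float32), self.affine), str(path))

    @classmethod
    def from_nifti(cls, path: str | Path) -> "ScalarVolume":
        img = nib.load(str(path))
        return cls(data=np.asarray(img.get_fdata(), dtype=float), affine=img.affine)


@dataclass
class TensorVolume:
    """A 3D lattice of symmetric diffusion tensors.

    ``data`` has shape (nx, ny, nz, 6) in lower-triangular component order;
    ``mask`` marks foreground voxels (zero tensors outside).
    """

    data: np.ndarray
    affine: np.ndarray = field(default_factory=lambda: np.eye(4))
    mask: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 4 or self.data.shape[-1] != 6:
            raise GeometryError("TensorVolume data must have shape (nx, ny, nz, 6)")
        self.affine = _check_affine(self.affine)
        if self.mask is None:
            self.mask = np.ones(self.data.shape[:3], dtype=bool)
        else:
            self.mask = np.asarray(self.mask, dtype=bool)
        if self.mask.shape != self.data.shape[:3]:
            raise GeometryError("mask shape must match tensor grid shape")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape[:3]  # type: ignore[return-value]

    @property
    def voxel_size(self) -> np.ndarray:
        return np.sqrt((self.affine[:3, :3] ** 2).sum(axis=0))

    def same_geometry(self, other: "TensorVolume | ScalarVolume") -> bool:
        return self.shape == other.shape and np.allclose(self.affine, other.affine)

    def fa_map(self) -> ScalarVolume:
        return ScalarVolume(data=fa(self.data), affine=self.affine.copy(),
                            mask=self.mask.copy())

    def to_nifti(self, path: str | Path) -> None:
        nib.save(nib.Nifti1Image(self.data.astype(np.float32), self.affine), str(path))

    @classmethod
    def from_nifti(cls, path: str | Path,
                   mask: np.ndarray | None = None) -> "TensorVolume":
        img = nib.load(str(path))
        return cls(data=np.asarray(img.get_fdata(), dtype=float), affine=img.affine,
                   mask=mask)


# ---------------------------------------------------------------------------
# fitting and forward simulation
# ---------------------------------------------------------------------------

def _design_matrix(scheme: GradientScheme) -> np.ndarray:
    """Rows: [1, -b*gx^2, -2b*gx*gy, -b*gy^2, -2b*gx*gz, -2b*gy*gz, -b*gz^2]."""
    g = scheme.directions
    b = scheme.b_values
    gx, gy, gz = g[:, 0], g[:, 1], g[:, 2]
    cols = np.column_stack(
        [gx * gx, 2 * gx * gy, gy * gy, 2 * gx * gz, 2 * gy * gz, gz * gz]
    )
    return np.column_stack([np.ones_like(b), -b[:, None] * cols])


def forward_signal(tensors: np.ndarray, scheme: GradientScheme,
                   s0: np.ndarray | float = 1.0) -> np.ndarray:
    """Noise-free DWI signal S = S0 * exp(-b g^T D g) for each scheme volume.

    ``tensors`` is (..., 6); returns (..., n_volumes).
    """
    x = _design_matrix(scheme)  # (n, 7)
    t6 = np.asarray(tensors, dtype=float)
    expo = t6 @ x[:, 1:].T  # (..., n) of -b g^T D g
    s0 = np.asarray(s0, dtype=float)
    return s0[..., None] * np.exp(expo) if s0.ndim else s0 * np.exp(expo)


def fit_tensor(dwi: np.ndarray, scheme: GradientScheme,
               mask: np.ndarray | None = None,
               affine: np.ndarray | None = None) -> TensorVolume:
    """Log-linear least-squares tensor fit of a 4D DWI stack.

    Fits ``log S = log S0 - b g^T D g`` per voxel by ordinary least squares
    (unweighted).  Masked-out voxels get zero tensors; voxels with any
    non-positive signal inside the mask are zeroed and logged as a warning.
    """
    scheme.validate_for_fitting()
    dwi = np.asarray(dwi, dtype=float)
    if dwi.ndim != 4 or dwi.shape[-1] != scheme.n_volumes:
        raise ValueError(
            f"dwi must be 4D with {scheme.n_volumes} volumes, got {dwi.shape}"
        )
    grid = dwi.shape[:3]
    if mask is None:
        mask = np.ones(grid, dtype=bool)
    mask = np.asarray(mask, dtype=bool)
    if affine is None:
        affine = np.eye(4)

    signals = dwi[mask]  # (nvox, n)
    bad = (signals <= 0).any(axis=1)
    if bad.any():
        n_bad = int(bad.sum())
        warnings.warn(
            f"{n_bad} masked voxels had non-positive DWI signal; "
            "their tensors were set to zero", RuntimeWarning, stacklevel=2)
        logger.warning("zeroed %d voxels with non-positive signal", n_bad)

    x = _design_matrix(scheme)
    pinv = np.linalg.pinv(x)
    coeffs = np.zeros((signals.shape[0], 7))
    good = ~bad
    if good.any():
        coeffs[good] = (pinv @ np.log(signals[good]).T).T
    tensors = np.zeros(grid + (6,))
    vals = coeffs[:, 1:]
    vals[bad] = 0.0
    tensors[mask] = vals
    out_mask = mask.copy()
    out_mask[mask] = good
    return TensorVolume(data=tensors, affine=affine, mask=out_mask)


# ---------------------------------------------------------------------------
# volume-level operations
# ---------------------------------------------------------------------------

def volume_distance(v1: TensorVolume, v2: TensorVolume,
                    mask: np.ndarray | None = None) -> float:
    """Registration objective: sum over masked voxels of squared tensor distance."""
    if not v1.same_geometry(v2):
        raise GeometryError("volumes must share grid shape and affine")
    if mask is None:
        mask = v1.mask & v2.mask
    diff = deviatoric(v1.data[mask] - v2.data[mask])
    return float(DEVIATORIC_SCALE**2 * tensor_norm_sq(diff).sum())


def average_tensor_volumes(volumes: Sequence[TensorVolume]) -> TensorVolume:
    """Component-wise (Euclidean) mean; mask is the intersection of input masks."""
    volumes = list(volumes)
    if not volumes:
        raise ValueError("cannot average an empty sequence of volumes")
    ref = volumes[0]
    for v in volumes[1:]:
        if not ref.same_geometry(v):
            raise GeometryError("all volumes must share grid shape and affine")
    data = np.mean([v.data for v in volumes], axis=0)
    mask = np.logical_and.reduce([v.mask for v in volumes])
    return TensorVolume(data=data, affine=ref.affine.copy(), mask=mask)
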