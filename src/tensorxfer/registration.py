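"""Piecewise-affine registration of tensor and scalar volumes.

The registration estimates a transform ``phi`` from the *target* (template)
grid into the *source* (subject) volume — a pull-back map: the warped source
at output voxel centre ``x`` (world mm) is the source resampled at
``phi(x)``.  ``phi`` is a block-wise affine map: the target domain is
partitioned into a regular grid of blocks, each with its own affine, and the
per-block maps are blended with trilinear weights over the block centres so
the composite map is continuous.  A 1x1x1 block grid is an ordinary global
affine.

The tensor objective is the masked sum of squared deviatoric tensor
distances between the warped source and the target (the scalar baseline uses
a plain sum of squared intensity differences).  Optimization is a
coarse-to-fine, derivative-free coordinate search: at each pyramid level a
global affine is refined and then (optionally) split into finer block grids;
each of a block's 12 pose parameters (translation / rotation / log-scale /
shear) is probed with +/- steps and a step is accepted only if the full
blended objective decreases, so recorded objective trajectories are
non-increasing by construction.

Warped tensors are reoriented with the finite-strain rotation (the
orthogonal polar factor of the local linear part of ``phi``).  During
optimization the rotation of the block containing each voxel is used; final
resampling uses the exact per-voxel rotation of the blended map.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
from scipy.ndimage import gaussian_filter, map_coordinates

from .tensor_core import (
    DEVIATORIC_SCALE,
    ScalarVolume,
    TensorVolume,
    deviatoric,
    rotate_tensor,
    tensor_norm_sq,
)


class RegistrationError(RuntimeError):
    """Raised when a registration cannot be carried out."""


# ---------------------------------------------------------------------------
# transforms
# ---------------------------------------------------------------------------

@dataclass
class AffineTransform:
    """World-coordinate affine map x -> A x + t, with det(A) > 0."""

    a: np.ndarray
    t: np.ndarray

    def __post_init__(self) -> None:
        self.a = np.asarray(self.a, dtype=float).reshape(3, 3)
        self.t = np.asarray(self.t, dtype=float).reshape(3)
        if np.linalg.det(self.a) <= 0:
            raise ValueError("affine linear part must have positive determinant")

    @classmethod
    def identity(cls) -> "AffineTransform":
        return cls(a=np.eye(3), t=np.zeros(3))

    def map_points(self, pts: np.ndarray) -> np.ndarray:
        pts = np.atleast_2d(np.asarray(pts, dtype=float))
        return pts @ self.a.T + self.t

    def linear_part(self, pts: np.ndarray) -> np.ndarray:
        pts = np.atleast_2d(np.asarray(pts, dtype=float))
        return np.broadcast_to(self.a, (pts.shape[0], 3, 3)).copy()


@dataclass
class ComposedTransform:
    """Composition outer(inner(x)), with chain-rule linear part."""

    outer: "Transform"
    inner: "Transform"

    def map_points(self, pts: np.ndarray) -> np.ndarray:
        return self.outer.map_points(self.inner.map_points(pts))

    def linear_part(self, pts: np.ndarray) -> np.ndarray:
        pts = np.atleast_2d(np.asarray(pts, dtype=float))
        ji = self.inner.linear_part(pts)
        jo = self.outer.linear_part(self.inner.map_points(pts))
        return np.einsum("nij,njk->nik", jo, ji)


class PiecewiseAffineTransform:
    """Block-wise affine map over an axis-aligned world-space domain.

    Parameters
    ----------
    block_grid : (bx, by, bz)
        Number of blocks per axis.
    domain_lo, domain_hi : (3,) world coordinates
        Bounding box of the template domain the blocks tile.
    a : (n_blocks, 3, 3), t : (n_blocks, 3)
        Per-block linear parts and translations, C-ordered over the grid.
        Each block's map is ``A (x - c) + c + t`` about its centre ``c``.
    """

    def __init__(self, block_grid: Sequence[int], domain_lo, domain_hi,
                 a: np.ndarray | None = None, t: np.ndarray | None = None):
        self.block_grid = tuple(int(b) for b in block_grid)
        if any(b < 1 for b in self.block_grid):
            raise ValueError("block counts must be >= 1")
        self.domain_lo = np.asarray(domain_lo, dtype=float).reshape(3)
        self.domain_hi = np.asarray(domain_hi, dtype=float).reshape(3)
        if np.any(self.domain_hi <= self.domain_lo):
            raise ValueError("domain_hi must exceed domain_lo on every axis")
        nb = int(np.prod(self.block_grid))
        self.a = (np.broadcast_to(np.eye(3), (nb, 3, 3)).copy()
                  if a is None else np.asarray(a, dtype=float).reshape(nb, 3, 3))
        self.t = (np.zeros((nb, 3)) if t is None
                  else np.asarray(t, dtype=float).reshape(nb, 3))
        self._cell = (self.domain_hi - self.domain_lo) / np.array(self.block_grid)
        # block centres, flattened C-order
        axes = [self.domain_lo[k] + (np.arange(self.block_grid[k]) + 0.5) * self._cell[k]
                for k in range(3)]
        cx, cy, cz = np.meshgrid(*axes, indexing="ij")
        self.centers = np.column_stack([cx.ravel(), cy.ravel(), cz.ravel()])

    @property
    def n_blocks(self) -> int:
        return self.a.shape[0]

    @classmethod
    def identity(cls, block_grid, domain_lo, domain_hi) -> "PiecewiseAffineTransform":
        return cls(block_grid, domain_lo, domain_hi)

    # -- blending -----------------------------------------------------------
    def _axis_coords(self, pts: np.ndarray):
        """Continuous block coordinates, floor indices, fractions, gradients."""
        b = np.array(self.block_grid)
        u_raw = (pts - (self.domain_lo + 0.5 * self._cell)) / self._cell
        u = np.clip(u_raw, 0.0, np.maximum(b - 1, 0))
        i0 = np.clip(np.floor(u).astype(int), 0, np.maximum(b - 2, 0))
        f = u - i0
        # derivative of the fraction w.r.t. world position (0 where clamped
        # or where the axis has a single block)
        active = (u_raw > 0) & (u_raw < b - 1) & (b > 1)
        df = np.where(active, 1.0 / self._cell, 0.0)
        return i0, f, df

    def _corners(self, pts: np.ndarray, with_grad: bool = False):
        """Yield (flat block index, weight[, weight gradient]) for 8 corners."""
        i0, f, df = self._axis_coords(pts)
        bx, by, bz = self.block_grid
        strides = np.array([by * bz, bz, 1])
        out = []
        for cxb in (0, 1):
            for cyb in (0, 1):
                for czb in (0, 1):
                    bits = np.array([cxb, cyb, czb])
                    if np.any(bits >= np.array(self.block_grid)):
                        # single-block axes only have corner 0
                        continue
                    idx = ((i0 + bits) * strides).sum(axis=1)
                    wax = np.where(bits, f, 1.0 - f)  # (n, 3)
                    w = wax.prod(axis=1)
                    if with_grad:
                        sign = np.where(bits, 1.0, -1.0)  # (3,)
                        gw = np.empty_like(wax)
                        for k in range(3):
                            others = wax[:, [a for a in range(3) if a != k]].prod(axis=1)
                            gw[:, k] = sign[k] * df[:, k] * others
                        out.append((idx, w, gw))
                    else:
                        out.append((idx, w))
        return out

    def map_points(self, pts: np.ndarray) -> np.ndarray:
        pts = np.atleast_2d(np.asarray(pts, dtype=float))
        if self.n_blocks == 1:
            c = self.centers[0]
            return (pts - c) @ self.a[0].T + c + self.t[0]
        out = np.zeros_like(pts)
        for idx, w in self._corners(pts):
            a = self.a[idx]
            c = self.centers[idx]
            phi = np.einsum("nij,nj->ni", a, pts - c) + c + self.t[idx]
            out += w[:, None] * phi
        return out

    def linear_part(self, pts: np.ndarray) -> np.ndarray:
        pts = np.atleast_2d(np.asarray(pts, dtype=float))
        if self.n_blocks == 1:
            return np.broadcast_to(self.a[0], (pts.shape[0], 3, 3)).copy()
        jac = np.zeros((pts.shape[0], 3, 3))
        for idx, w, gw in self._corners(pts, with_grad=True):
            a = self.a[idx]
            c = self.centers[idx]
            phi = np.einsum("nij,nj->ni", a, pts - c) + c + self.t[idx]
            jac += w[:, None, None] * a + phi[:, :, None] * gw[:, None, :]
        return jac

    def cell_index(self, pts: np.ndarray) -> np.ndarray:
        """Flat index of the block cell containing each point."""
        pts = np.atleast_2d(np.asarray(pts, dtype=float))
        b = np.array(self.block_grid)
        i = np.clip(np.floor((pts - self.domain_lo) / self._cell).astype(int),
                    0, b - 1)
        bx, by, bz = self.block_grid
        return i[:, 0] * by * bz + i[:, 1] * bz + i[:, 2]

    # -- serialization ------------------------------------------------------
    def to_dict(self) -> dict:
        return {
            "block_grid": list(self.block_grid),
            "domain_lo": self.domain_lo.tolist(),
            "domain_hi": self.domain_hi.tolist(),
            "blocks": [np.column_stack([self.a[i], self.t[i]]).ravel().tolist()
                       for i in range(self.n_blocks)],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "PiecewiseAffineTransform":
        nb = len(d["blocks"])
        a = np.empty((nb, 3, 3))
        t = np.empty((nb, 3))
        for i, row in enumerate(d["blocks"]):
            m = np.asarray(row, dtype=float).reshape(3, 4)
            a[i] = m[:, :3]
            t[i] = m[:, 3]
        return cls(d["block_grid"], d["domain_lo"], d["domain_hi"], a=a, t=t)

    def save_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict()))

    @classmethod
    def load_json(cls, path: str | Path) -> "PiecewiseAffineTransform":
        return cls.from_dict(json.loads(Path(path).read_text()))


Transform = AffineTransform | PiecewiseAffineTransform | ComposedTransform


# ---------------------------------------------------------------------------
# resampling
# ---------------------------------------------------------------------------

def _grid_world_points(shape, affine) -> np.ndarray:
    idx = np.indices(shape).reshape(3, -1).T.astype(float)
    return idx @ affine[:3, :3].T + affine[:3, 3]


def _world_to_voxel(pts: np.ndarray, affine: np.ndarray) -> np.ndarray:
    inv = np.linalg.inv(affine)
    return pts @ inv[:3, :3].T + inv[:3, 3]


def _polar_rotations(mats: np.ndarray) -> np.ndarray:
    """Batch orthogonal polar factors (finite-strain rotations) of (n,3,3)."""
    u, _, vt = np.linalg.svd(mats)
    r = u @ vt
    neg = np.linalg.det(r) < 0
    if np.any(neg):
        u = u.copy()
        u[neg, :, -1] *= -1
        r = u @ vt
    return r


def _sample_scalar(data, vox, order):
    return map_coordinates(data, vox.T, order=order, mode="constant", cval=0.0,
                           prefilter=False)


def _infield(vox: np.ndarray, shape) -> np.ndarray:
    ok = np.ones(vox.shape[0], dtype=bool)
    for k in range(3):
        ok &= (vox[:, k] >= 0) & (vox[:, k] <= shape[k] - 1)
    return ok


def apply_transform_scalar(v: ScalarVolume, phi: Transform, out_grid,
                           interpolation: str = "linear") -> ScalarVolume:
    """Pull-back resample ``v`` onto ``out_grid`` (object with shape/affine).

    Output voxels sampling outside the source field of view (or outside the
    source mask, if present) are set to 0 and excluded from the output mask.
    """
    order = {"linear": 1, "nearest": 0}[interpolation]
    shape = tuple(out_grid.shape)
    pts = _grid_world_points(shape, out_grid.affine)
    vox = _world_to_voxel(phi.map_points(pts), v.affine)
    data = _sample_scalar(v.data, vox, order).reshape(shape)
    mask = _infield(vox, v.data.shape)
    if v.mask is not None:
        mask &= _sample_scalar(v.mask.astype(float), vox, 0) > 0.5
    data[~mask.reshape(shape)] = 0.0
    return ScalarVolume(data=data, affine=np.asarray(out_grid.affine, dtype=float),
                        mask=mask.reshape(shape))


def apply_transform_tensor(v: TensorVolume, phi: Transform,
                           out_grid, reorient: bool = True) -> TensorVolume:
    """Pull-back resample a tensor volume with finite-strain reorientation.

    Components are interpolated linearly; each output tensor is then rotated
    by the transpose of the orthogonal polar factor of the local linear part
    of ``phi``, so principal directions stay anatomically consistent.
    """
    shape = tuple(out_grid.shape)
    pts = _grid_world_points(shape, out_grid.affine)
    vox = _world_to_voxel(phi.map_points(pts), v.affine)
    samp = np.column_stack([_sample_scalar(v.data[..., k], vox, 1)
                            for k in range(6)])
    if reorient:
        rot = _polar_rotations(phi.linear_part(pts))
        samp = rotate_tensor(samp, np.swapaxes(rot, -1, -2))
    mask = _infield(vox, v.data.shape[:3])
    mask &= _sample_scalar(v.mask.astype(float), vox, 0) > 0.5
    samp[~mask] = 0.0
    return TensorVolume(data=samp.reshape(shape + (6,)),
                        affine=np.asarray(out_grid.affine, dtype=float),
                        mask=mask.reshape(shape))


def jacobian_map(phi: Transform, grid) -> ScalarVolume:
    """Voxel-wise determinant of the local linear part of ``phi`` on ``grid``."""
    shape = tuple(grid.shape)
    pts = _grid_world_points(shape, grid.affine)
    det = np.linalg.det(phi.linear_part(pts))
    return ScalarVolume(data=det.reshape(shape),
                        affine=np.asarray(grid.affine, dtype=float))


def parcel_jacobian_features(jac: ScalarVolume, parcellation: np.ndarray,
                             include_background: bool = False):
    """Mean Jacobian determinant per parcel, labels in ascending order.

    Returns ``(labels, means)``; a label with no voxels (possible when the
    caller passes an explicit label list via a labelled but empty region)
    yields NaN with a warning.
    """
    labels = np.unique(parcellation)
    if not include_background:
        labels = labels[labels != 0]
    means = np.empty(labels.size)
    for i, lab in enumerate(labels):
        sel = parcellation == lab
        if not sel.any():
            warnings.warn(f"parcel {lab} is empty; feature set to NaN",
                          RuntimeWarning, stacklevel=2)
            means[i] = np.nan
        else:
            means[i] = jac.data[sel].mean()
    return labels, means


def mean_displacement_error(phi_a: Transform, phi_b: Transform, grid,
                            mask: np.ndarray | None = None,
                            units: str = "voxel") -> float:
    """Mean |phi_a(x) - phi_b(x)| over grid voxels, in voxels or mm."""
    shape = tuple(grid.shape)
    pts = _grid_world_points(shape, grid.affine)
    if mask is not None:
        pts = pts[np.asarray(mask, dtype=bool).ravel()]
    d = np.linalg.norm(phi_a.map_points(pts) - phi_b.map_points(pts), axis=1)
    if units == "voxel":
        vox = np.sqrt((np.asarray(grid.affine)[:3, :3] ** 2).sum(axis=0)).mean()
        return float(d.mean() / vox)
    return float(d.mean())


# ---------------------------------------------------------------------------
# registration configuration and result
# ---------------------------------------------------------------------------

@dataclass
class RegistrationConfig:
    """Multi-resolution schedule and optimizer settings.

    ``levels`` is a sequence of ``(downsample_factor, stages)`` pairs, coarse
    to fine; each stage is either the string ``"affine"`` (global affine,
    i.e. a 1x1x1 block grid) or a block-grid triple.  Steps are probed
    coordinate-wise and halved when a sweep yields no improvement.
    """

    levels: tuple = (
        (4, ("affine",)),
        (2, ("affine", (2, 2, 2))),
        (1, ((4, 4, 4),)),
    )
    max_sweeps: int = 50
    rel_tol: float = 1e-4
    step_rotation: float = 0.05     # radians
    step_scale: float = 0.05        # log-scale units
    step_shear: float = 0.05
    step_translation: float | None = None  # mm; default: one voxel at level
    min_step_factor: float = 1 / 32
    reorient: bool = True
    #: accepted blocks keep det(A) within these bounds — a sanity prior on
    #: inter-subject volume change that blocks degenerate collapses
    det_bounds: tuple[float, float] = (0.25, 4.0)
    #: never downsample below this many voxels per axis
    min_level_extent: int = 8

    @classmethod
    def fast(cls) -> "RegistrationConfig":
        """Light schedule for desk-scale (32^3) synthetic volumes."""
        return cls(levels=((4, ("affine",)), (2, ("affine",))), max_sweeps=12,
                   min_step_factor=1 / 8)

    @classmethod
    def affine_only(cls) -> "RegistrationConfig":
        return cls(levels=((4, ("affine",)), (2, ("affine",)), (1, ("affine",))))


@dataclass
class RegistrationResult:
    """Transform estimate plus optimizer diagnostics.

    ``objective_trajectory`` is the accepted-step trajectory of the final
    stage at the finest level (objectives at different pyramid levels are
    sums over different voxel counts and are kept separately in
    ``stage_trajectories``).  Every per-stage trajectory is non-increasing.
    """

    transform: PiecewiseAffineTransform
    objective_trajectory: list[float]
    stage_trajectories: list[list[float]]
    converged: bool
    n_evaluations: int = 0

    def validate(self) -> None:
        for traj in self.stage_trajectories:
            arr = np.asarray(traj)
            if np.any(np.diff(arr) > 1e-9 * np.maximum(arr[:-1], 1e-30)):
                raise AssertionError("objective trajectory increased")


# ---------------------------------------------------------------------------
# objective machinery
# ---------------------------------------------------------------------------

class _Problem:
    """Precomputed residual machinery for one pyramid level."""

    def __init__(self, source, target, mode: str, reorient: bool):
        self.mode = mode
        self.reorient = reorient and mode == "tensor"
        mask = target.mask if target.mask is not None else np.ones(
            target.shape, dtype=bool)
        if not mask.any():
            raise RegistrationError("target mask is empty")
        if source.mask is not None and not source.mask.any():
            raise RegistrationError("source mask is empty")
        idx = np.argwhere(mask).astype(float)
        self.pts = idx @ target.affine[:3, :3].T + target.affine[:3, 3]
        self.n = self.pts.shape[0]
        self.src_affine = source.affine
        if mode == "tensor":
            self.tgt = deviatoric(target.data[mask])
            self.src_comps = [np.ascontiguousarray(source.data[..., k])
                              for k in range(6)]
            self.src_shape = source.data.shape[:3]
        else:
            self.tgt = target.data[mask]
            self.src_comps = [np.ascontiguousarray(source.data)]
            self.src_shape = source.data.shape
        self.n_evals = 0

    def residuals(self, phi: PiecewiseAffineTransform,
                  sel: np.ndarray | None = None) -> np.ndarray:
        """Per-voxel squared error at the selected target voxels."""
        self.n_evals += 1
        pts = self.pts if sel is None else self.pts[sel]
        vox = _world_to_voxel(phi.map_points(pts), self.src_affine)
        if self.mode == "scalar":
            s = _sample_scalar(self.src_comps[0], vox, 1)
            tgt = self.tgt if sel is None else self.tgt[sel]
            return (s - tgt) ** 2
        samp = np.column_stack([_sample_scalar(c, vox, 1)
                                for c in self.src_comps])
        if self.reorient:
            rot = _polar_rotations(phi.a)  # one rotation per block
            r = rot[phi.cell_index(pts)]
            samp = rotate_tensor(samp, np.swapaxes(r, -1, -2))
        tgt = self.tgt if sel is None else self.tgt[sel]
        return DEVIATORIC_SCALE**2 * tensor_norm_sq(deviatoric(samp) - tgt)

    def supports(self, phi: PiecewiseAffineTransform) -> list[np.ndarray]:
        """For each block, indices of target voxels its weight can touch."""
        if phi.n_blocks == 1:
            return [np.arange(self.n)]
        touch = [[] for _ in range(phi.n_blocks)]
        for idx, w in phi._corners(self.pts):
            pos = np.nonzero(w > 1e-12)[0]
            blocks = idx[pos]
            order = np.argsort(blocks, kind="stable")
            blocks_sorted = blocks[order]
            pos_sorted = pos[order]
            bounds = np.searchsorted(blocks_sorted,
                                     np.arange(phi.n_blocks + 1))
            for b in range(phi.n_blocks):
                seg = pos_sorted[bounds[b]:bounds[b + 1]]
                if seg.size:
                    touch[b].append(seg)
        return [np.unique(np.concatenate(s)) if s else np.empty(0, dtype=int)
                for s in touch]


# perturbation generators: 12 pose parameters per block
_SHEAR_PAIRS = [(0, 1), (0, 2), (1, 2)]


def _perturbed(a: np.ndarray, t: np.ndarray, kind: str, axis: int, s: float):
    if kind == "translation":
        e = np.zeros(3)
        e[axis] = s
        return a, t + e
    if kind == "rotation":
        m = np.eye(3)
        i, j = [(1, 2), (0, 2), (0, 1)][axis]
        c, sn = np.cos(s), np.sin(s)
        m[i, i] = c
        m[j, j] = c
        m[i, j] = -sn
        m[j, i] = sn
        return m @ a, t
    if kind == "scale":
        m = np.eye(3)
        m[axis, axis] = np.exp(s)
        return m @ a, t
    if kind == "shear":
        m = np.eye(3)
        i, j = _SHEAR_PAIRS[axis]
        m[i, j] = s
        return m @ a, t
    raise ValueError(kind)


def _optimize_stage(problem: _Problem, phi: PiecewiseAffineTransform,
                    cfg: RegistrationConfig, voxel_mm: float):
    """Coordinate-descent over all blocks; returns (trajectory, converged)."""
    supports = problem.supports(phi)
    err = problem.residuals(phi)
    total = float(err.sum())
    traj = [total]
    sweep_totals = [total]
    steps = {
        "translation": cfg.step_translation or voxel_mm,
        "rotation": cfg.step_rotation,
        "scale": cfg.step_scale,
        "shear": cfg.step_shear,
    }
    init_steps = dict(steps)
    params = [(kind, axis) for kind in
              ("translation", "rotation", "scale", "shear") for axis in range(3)]
    converged = False
    for _ in range(cfg.max_sweeps):
        improved = False
        for b in range(phi.n_blocks):
            sel = supports[b]
            if sel.size == 0:
                continue
            for kind, axis in params:
                base_sum = float(err[sel].sum())
                best = None
                best_sgn = 1.0
                for sgn in (1.0, -1.0):
                    a_new, t_new = _perturbed(phi.a[b], phi.t[b], kind, axis,
                                              sgn * steps[kind])
                    det = np.linalg.det(a_new)
                    if not cfg.det_bounds[0] <= det <= cfg.det_bounds[1]:
                        continue
                    a_old, t_old = phi.a[b].copy(), phi.t[b].copy()
                    phi.a[b], phi.t[b] = a_new, t_new
                    r = problem.residuals(phi, sel)
                    phi.a[b], phi.t[b] = a_old, t_old
                    delta = float(r.sum()) - base_sum
                    if delta < -1e-12 * max(total, 1e-30) and (
                            best is None or delta < best[0]):
                        best = (delta, a_new, t_new, r)
                        best_sgn = sgn
                if best is not None:
                    delta, a_new, t_new, r = best
                    sgn_best = best_sgn
                    phi.a[b] = a_new
                    phi.t[b] = t_new
                    err[sel] = r
                    total += delta
                    traj.append(total)
                    improved = True
                    # pattern-search acceleration: keep stepping in the
                    # accepted direction while the objective drops
                    for _ in range(20):
                        a_new, t_new = _perturbed(phi.a[b], phi.t[b], kind,
                                                  axis, sgn_best * steps[kind])
                        det = np.linalg.det(a_new)
                        if not cfg.det_bounds[0] <= det <= cfg.det_bounds[1]:
                            break
                        a_old, t_old = phi.a[b].copy(), phi.t[b].copy()
                        phi.a[b], phi.t[b] = a_new, t_new
                        r = problem.residuals(phi, sel)
                        delta = float(r.sum()) - float(err[sel].sum())
                        if delta < -1e-12 * max(total, 1e-30):
                            err[sel] = r
                            total += delta
                            traj.append(total)
                        else:
                            phi.a[b], phi.t[b] = a_old, t_old
                            break
        sweep_totals.append(total)
        if improved:
            ref = sweep_totals[-4] if len(sweep_totals) >= 4 else None
            if ref is not None and ref - total < cfg.rel_tol * max(ref, 1e-30):
                converged = True
                break
        else:
            steps = {k: v / 2 for k, v in steps.items()}
            if all(steps[k] < init_steps[k] * cfg.min_step_factor
                   for k in steps):
                converged = True
                break
    return traj, converged


# ---------------------------------------------------------------------------
# pyramid helpers
# ---------------------------------------------------------------------------

def _downsample(vol, factor: int):
    if factor == 1:
        return vol
    new_affine = vol.affine @ np.diag([factor, factor, factor, 1.0])
    mask = vol.mask if vol.mask is not None else np.ones(
        vol.data.shape[:3] if vol.data.ndim == 4 else vol.data.shape, bool)
    mask_ds = gaussian_filter(mask.astype(float), factor / 2.0,
                              mode="nearest")[::factor, ::factor, ::factor] > 0.5
    if isinstance(vol, TensorVolume):
        comps = [gaussian_filter(vol.data[..., k], factor / 2.0,
                                 mode="nearest")[::factor, ::factor, ::factor]
                 for k in range(6)]
        return TensorVolume(data=np.stack(comps, axis=-1), affine=new_affine,
                            mask=mask_ds)
    data = gaussian_filter(vol.data, factor / 2.0,
                           mode="nearest")[::factor, ::factor, ::factor]
    return ScalarVolume(data=data, affine=new_affine, mask=mask_ds)


def _target_domain(target):
    shape = np.array(target.shape, dtype=float)
    corners = np.array([[i, j, k] for i in (0.0, 1.0) for j in (0.0, 1.0)
                        for k in (0.0, 1.0)]) * (shape - 1)
    world = corners @ target.affine[:3, :3].T + target.affine[:3, 3]
    lo, hi = world.min(axis=0), world.max(axis=0)
    pad = 0.5 * np.sqrt((target.affine[:3, :3] ** 2).sum(axis=0))
    return lo - pad, hi + pad


def _refine_blocks(phi: PiecewiseAffineTransform,
                   grid, lo, hi) -> PiecewiseAffineTransform:
    """Re-express ``phi`` on a finer block grid by local affinization."""
    new = PiecewiseAffineTransform.identity(grid, lo, hi)
    a = phi.linear_part(new.centers)
    mapped = phi.map_points(new.centers)
    new.a = a
    new.t = mapped - new.centers
    return new


# ---------------------------------------------------------------------------
# top-level registration
# ---------------------------------------------------------------------------

def _register(source, target, config: RegistrationConfig | None,
              mode: str) -> RegistrationResult:
    cfg = config or RegistrationConfig()
    lo, hi = _target_domain(target)
    phi: PiecewiseAffineTransform | None = None
    stage_trajs: list[list[float]] = []
    converged = False
    n_evals = 0
    for factor, stages in cfg.levels:
        max_factor = max(1, min(target.shape) // cfg.min_level_extent)
        factor = min(factor, max_factor)
        src_l = _downsample(source, factor)
        tgt_l = _downsample(target, factor)
        problem = _Problem(src_l, tgt_l, mode, cfg.reorient)
        voxel_mm = float(np.sqrt((tgt_l.affine[:3, :3] ** 2).sum(axis=0)).mean())
        for stage in stages:
            grid = (1, 1, 1) if stage == "affine" else tuple(stage)
            if phi is None:
                phi = PiecewiseAffineTransform.identity(grid, lo, hi)
            elif grid != phi.block_grid:
                phi = _refine_blocks(phi, grid, lo, hi)
            traj, converged = _optimize_stage(problem, phi, cfg, voxel_mm)
            stage_trajs.append(traj)
        n_evals += problem.n_evals
    assert phi is not None
    result = RegistrationResult(transform=phi,
                                objective_trajectory=stage_trajs[-1],
                                stage_trajectories=stage_trajs,
                                converged=converged, n_evaluations=n_evals)
    result.validate()
    return result


def register_tensor(source: TensorVolume, target: TensorVolume,
                    config: RegistrationConfig | None = None) -> RegistrationResult:
    """Register ``source`` onto ``target`` under the deviatoric tensor metric.

    Returns the pull-back transform phi (target/world -> source/world):
    ``apply_transform_tensor(source, phi, target)`` is the warped source.
    """
    if not isinstance(source, TensorVolume) or not isinstance(target, TensorVolume):
        raise TypeError("register_tensor expects TensorVolume inputs")
    return _register(source, target, config, "tensor")


def register_scalar(source: ScalarVolume, target: ScalarVolume,
                    config: RegistrationConfig | None = None) -> RegistrationResult:
    """Scalar (intensity SSD) baseline registration, same optimizer."""
    if not isinstance(source, ScalarVolume) or not isinstance(target, ScalarVolume):
        raise TypeError("register_scalar expects ScalarVolume inputs")
    return _register(source, target, config, "scalar")


# ---------------------------------------------------------------------------
# common-space construction
# ---------------------------------------------------------------------------

@dataclass
class CommonSpace:
    """Averaged template plus per-subject pull-back transforms onto it."""

    mean_template: TensorVolume | ScalarVolume
    transforms: dict[int, PiecewiseAffineTransform]
    template_id: int
    results: dict[int, RegistrationResult] = field(default_factory=dict)


def _average(volumes):
    if isinstance(volumes[0], TensorVolume):
        from .tensor_core import average_tensor_volumes
        return average_tensor_volumes(volumes)
    data = np.mean([v.data for v in volumes], axis=0)
    mask = np.logical_and.reduce(
        [v.mask if v.mask is not None else np.ones(v.shape, bool)
         for v in volumes])
    return ScalarVolume(data=data, affine=volumes[0].affine.copy(), mask=mask)


def build_common_space(subjects: Sequence[TensorVolume] | Sequence[ScalarVolume],
                       template_id: int = 0,
                       config: RegistrationConfig | None = None) -> CommonSpace:
    """Two-pass template construction.

    1. Register every subject onto the designated template subject and warp.
    2. Average the warped volumes into the mean template (the common grid).
    3. Re-register each ORIGINAL subject volume onto the mean; these second
       transforms are the per-subject maps ``phi_s`` used to project
       functional data into the common coordinates.
    """
    subjects = list(subjects)
    if len(subjects) < 2:
        raise ValueError("need at least 2 subjects to build a common space")
    if not 0 <= template_id < len(subjects):
        raise ValueError("template_id out of range")
    is_tensor = isinstance(subjects[0], TensorVolume)
    reg = register_tensor if is_tensor else register_scalar
    app = apply_transform_tensor if is_tensor else apply_transform_scalar
    template = subjects[template_id]
    warped = []
    for i, sub in enumerate(subjects):
        if i == template_id:
            warped.append(template)
            continue
        try:
            res = reg(sub, template, config)
        except Exception as exc:  # noqa: BLE001 - annotate subject, re-raise
            raise RegistrationError(
                f"registration of subject {i} onto the template failed: {exc}"
            ) from exc
        warped.append(app(sub, res.transform, template))
    mean = _average(warped)
    transforms: dict[int, PiecewiseAffineTransform] = {}
    results: dict[int, RegistrationResult] = {}
    for i, sub in enumerate(subjects):
        try:
            res = reg(sub, mean, config)
        except Exception as exc:  # noqa: BLE001
            raise RegistrationError(
                f"re-registration of subject {i} onto the mean template "
                f"failed: {exc}") from exc
        transforms[i] = res.transform
        results[i] = res
    return CommonSpace(mean_template=mean, transforms=transforms,
                       template_id=template_id, results=results)
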