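"""Voxel-wise discordance between two registration routes.

Each subject's native fractional-anisotropy (FA) map is warped into the
common coordinates once through the tensor-based registration and once
through the scalar (T1-style) baseline.  The per-subject signed subtraction
map ``l_diff = FA_tensor-route - FA_scalar-route`` measures where the two
routes disagree; the discordance map is the voxel-wise mean of |l_diff|
over subjects.  Discordance concentrated at the edges of gray matter —
where FA gradients are steep — is the signature that the two routes align
tissue boundaries differently.

Tissue stratification is FA-threshold based: white matter is FA above a
threshold inside the brain mask, the edge of gray matter is the gray-matter
shell adjacent to white matter, and the exponential tail of the discordance
distribution within each class is summarized by its maximum-likelihood
rate.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.ndimage import binary_dilation, generate_binary_structure

from .registration import Transform, apply_transform_scalar
from .tensor_core import GeometryError, ScalarVolume, TensorVolume


@dataclass
class DiscordanceMap:
    """Mean |FA difference| between two registration routes, per voxel."""

    map: ScalarVolume
    subject_maps: list[np.ndarray]  # signed per-subject l_diff volumes
    n_subjects: int


@dataclass
class TissueMasks:
    """Disjoint gray-matter / edge-of-gray-matter / white-matter volumes."""

    gray_matter: np.ndarray
    edge_of_gray_matter: np.ndarray
    white_matter: np.ndarray

    def __post_init__(self) -> None:
        gm = self.gray_matter
        edge = self.edge_of_gray_matter
        wm = self.white_matter
        if (gm & edge).any() or (gm & wm).any() or (edge & wm).any():
            raise ValueError("tissue masks must be pairwise disjoint")

    def items(self):
        return [("gray_matter", self.gray_matter),
                ("edge_of_gray_matter", self.edge_of_gray_matter),
                ("white_matter", self.white_matter)]


@dataclass
class TailFit:
    """Exponential tail exp(-a x) fitted to exceedances over a threshold."""

    rate: float
    stderr: float
    threshold: float
    n_exceedances: int


def registered_fa(subject: TensorVolume, phi: Transform,
                  out_grid) -> ScalarVolume:
    """Native-space FA, warped onto the common grid with trilinear sampling."""
    return apply_transform_scalar(subject.fa_map(), phi, out_grid,
                                  interpolation="linear")


def discordance_map(fa_route_a: Sequence[ScalarVolume],
                    fa_route_b: Sequence[ScalarVolume]) -> DiscordanceMap:
    """Mean over subjects of |FA_a - FA_b|, both lists on the common grid."""
    fa_route_a = list(fa_route_a)
    fa_route_b = list(fa_route_b)
    if len(fa_route_a) != len(fa_route_b):
        raise ValueError("the two registration routes must have the same "
                         "number of subjects")
    if not fa_route_a:
        raise ValueError("need at least one subject")
    ref = fa_route_a[0]
    diffs = []
    for a, b in zip(fa_route_a, fa_route_b):
        if not (a.same_geometry(ref) and b.same_geometry(ref)):
            raise GeometryError("all FA maps must share the common grid")
        diffs.append(a.data - b.data)
    mean_abs = np.mean(np.abs(diffs), axis=0)
    vol = ScalarVolume(data=mean_abs, affine=ref.affine.copy())
    return DiscordanceMap(map=vol, subject_maps=diffs,
                          n_subjects=len(fa_route_a))


def tissue_masks(template: TensorVolume, fa_wm: float = 0.25,
                 connectivity: int = 1) -> TissueMasks:
    """FA-threshold tissue classes on the template.

    WM = FA >= ``fa_wm`` within the brain mask; GM = the rest of the brain;
    edge-of-GM = GM voxels face-adjacent (6-connectivity for
    ``connectivity=1``) to WM.  The returned gray-matter class excludes its
    edge, so the three classes partition the brain.
    """
    fa = template.fa_map().data
    brain = template.mask
    wm = brain & (fa >= fa_wm)
    if not wm.any():
        raise ValueError("white-matter class is empty at this FA threshold")
    gm_all = brain & ~wm
    if not gm_all.any():
        raise ValueError("gray-matter class is empty at this FA threshold")
    struct = generate_binary_structure(3, connectivity)
    edge = gm_all & binary_dilation(wm, structure=struct)
    if not edge.any():
        raise ValueError("edge-of-gray-matter class is empty")
    gm = gm_all & ~edge
    if not gm.any():
        raise ValueError("gray-matter interior class is empty")
    return TissueMasks(gray_matter=gm, edge_of_gray_matter=edge,
                       white_matter=wm)


def tail_fit(values: np.ndarray, threshold_quantile: float = 0.5,
             n_boot: int = 1000, seed: int = 0) -> TailFit:
    """Maximum-likelihood exponential rate of the upper tail.

    The threshold is the given quantile of ``values``; the rate of the
    exceedances over the threshold is ``a = 1 / mean(value - threshold)``
    (the exponential MLE).  A seeded bootstrap over the exceedances gives
    the standard error.
    """
    values = np.asarray(values, dtype=float).ravel()
    threshold = float(np.quantile(values, threshold_quantile))
    exceed = values[values > threshold] - threshold
    if exceed.size < 30:
        raise ValueError(
            f"only {exceed.size} exceedances above the threshold; need >= 30")
    rate = 1.0 / exceed.mean()
    rng = np.random.default_rng(seed)
    boot = 1.0 / rng.choice(exceed, size=(n_boot, exceed.size),
                            replace=True).mean(axis=1)
    return TailFit(rate=float(rate), stderr=float(boot.std(ddof=1)),
                   threshold=threshold, n_exceedances=int(exceed.size))


def stratified_summary(dmap: DiscordanceMap, masks: TissueMasks,
                       tail_quantile: float = 0.5,
                       seed: int = 0) -> pd.DataFrame:
    """Median / mean / exponential tail rate of discordance per tissue class."""
    rows = []
    for name, sel in masks.items():
        if sel.shape != dmap.map.shape:
            raise GeometryError("tissue masks must be on the discordance grid")
        vals = dmap.map.data[sel]
        if vals.size == 0:
            rows.append({"tissue": name, "n_voxels": 0, "median": np.nan,
                         "mean": np.nan, "tail_rate": np.nan,
                         "tail_stderr": np.nan})
            continue
        try:
            tf = tail_fit(vals, threshold_quantile=tail_quantile, seed=seed)
            rate, se = tf.rate, tf.stderr
        except ValueError:
            rate, se = np.nan, np.nan
        rows.append({"tissue": name, "n_voxels": int(vals.size),
                     "median": float(np.median(vals)),
                     "mean": float(vals.mean()),
                     "tail_rate": rate, "tail_stderr": se})
    return pd.DataFrame(rows)
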