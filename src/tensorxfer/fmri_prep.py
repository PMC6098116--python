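"""Functional-run preprocessing into trial patterns.

A run is a 4D EPI time series plus an event table.  Each trial has three
phases — Rest (8–16 s), Control (4 s), Attention (8 s) at TR = 2 s — and the
Attention phase carries the attend-left / attend-right label (+1 left,
-1 right).  Preprocessing turns a run into one multi-voxel pattern per
trial:

1. drop the first ``drop_volumes`` volumes (T1-equilibration),
2. shift phase windows by the hemodynamic delay (in TRs),
3. per-voxel linear detrend,
4. winsorize temporal outliers beyond ``winsorize_mads`` MADs of the voxel
   median,
5. average volumes within the Attention phase of each trial,
6. subtract the same trial's Control-phase mean (baseline),
7. z-score each voxel across the run's trials.

Patterns keep their native grid geometry so they can later be projected onto
the common anatomical coordinates and restricted to an ROI.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.ndimage import map_coordinates

from .registration import Transform, _infield, _world_to_voxel
from .tensor_core import GeometryError, ScalarVolume

LABEL_LEFT = 1
LABEL_RIGHT = -1


@dataclass
class FunctionalRun:
    """One task run: (T, nx, ny, nz) signal plus an event table.

    ``events`` has columns ``onset`` (s), ``duration`` (s), ``phase``
    (rest/control/attention) and ``side`` (left/right, attention rows only).
    """

    data: np.ndarray
    events: pd.DataFrame
    tr: float = 2.0
    subject_id: int = 0
    run_id: int = 0
    affine: np.ndarray = field(default_factory=lambda: np.eye(4))

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 4:
            raise ValueError("run data must be 4D (time, x, y, z)")
        self.affine = np.asarray(self.affine, dtype=float)
        ev = self.events
        needed = {"onset", "duration", "phase"}
        if not needed.issubset(ev.columns):
            raise ValueError(f"events must have columns {sorted(needed)}")
        dur_s = self.data.shape[0] * self.tr
        if ((ev["onset"] < 0) | (ev["onset"] + ev["duration"] > dur_s + 1e-9)).any():
            raise ValueError("events must lie within the run duration")

    @property
    def n_volumes(self) -> int:
        return self.data.shape[0]

    @property
    def grid_shape(self) -> tuple[int, int, int]:
        return self.data.shape[1:]


@dataclass
class TrialPattern:
    """One trial's multi-voxel feature vector with its attention label."""

    features: np.ndarray
    label: int
    subject_id: int
    run_id: int
    grid_shape: tuple[int, int, int] | None = None
    affine: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.features = np.asarray(self.features, dtype=float)
        if self.label not in (LABEL_LEFT, LABEL_RIGHT):
            raise ValueError("label must be +1 (left) or -1 (right)")

    def as_volume(self) -> ScalarVolume:
        if self.grid_shape is None or self.affine is None:
            raise ValueError("pattern does not carry grid geometry")
        return ScalarVolume(data=self.features.reshape(self.grid_shape),
                            affine=self.affine)


@dataclass
class ROIMask:
    """Binary region-of-interest on the common grid."""

    data: np.ndarray
    affine: np.ndarray = field(default_factory=lambda: np.eye(4))
    name: str = "roi"

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=bool)
        if self.data.ndim != 3:
            raise GeometryError("ROI mask must be 3D")
        if not self.data.any():
            raise ValueError("ROI mask is empty")
        self.affine = np.asarray(self.affine, dtype=float)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape  # type: ignore[return-value]

    @property
    def n_voxels(self) -> int:
        return int(self.data.sum())


@dataclass
class PreprocessConfig:
    """Knobs for the trial-pattern pipeline (defaults follow the module doc)."""

    drop_volumes: int = 5
    hemodynamic_delay_trs: int = 2
    detrend: bool = True
    winsorize_mads: float = 4.0
    baseline_control: bool = True
    zscore: bool = True


def _phase_indices(onset_s: float, duration_s: float, tr: float,
                   delay_trs: int) -> np.ndarray:
    start = int(round(onset_s / tr)) + delay_trs
    n = int(round(duration_s / tr))
    return np.arange(start, start + n)


def preprocess_run(run: FunctionalRun,
                   config: PreprocessConfig | None = None) -> list[TrialPattern]:
    """Turn one functional run into one z-scored pattern per trial."""
    cfg = config or PreprocessConfig()
    k = cfg.drop_volumes
    if run.n_volumes <= k:
        raise ValueError("run shorter than the number of dropped volumes")
    grid_shape = run.grid_shape
    data = run.data[k:].reshape(run.n_volumes - k, -1).astype(float)
    nt = data.shape[0]

    if cfg.detrend:
        t = np.arange(nt, dtype=float)
        t -= t.mean()
        slope = (t @ data) / (t @ t)
        data = data - np.outer(t, slope)
        data -= data.mean(axis=0)

    if cfg.winsorize_mads and cfg.winsorize_mads > 0:
        med = np.median(data, axis=0)
        mad = np.median(np.abs(data - med), axis=0)
        lim = cfg.winsorize_mads * mad
        ok = mad > 0
        lo = np.where(ok, med - lim, -np.inf)
        hi = np.where(ok, med + lim, np.inf)
        data = np.clip(data, lo, hi)

    ev = run.events.sort_values("onset").reset_index(drop=True)
    ev = ev.assign(onset=ev["onset"] - k * run.tr)
    attention = ev[ev["phase"].str.lower() == "attention"]
    controls = ev[ev["phase"].str.lower() == "control"]

    feats, labels = [], []
    for _, att in attention.iterrows():
        idx = _phase_indices(att["onset"], att["duration"], run.tr,
                             cfg.hemodynamic_delay_trs)
        if idx[0] < 0:
            continue  # attention phase fell inside the dropped volumes
        if idx[-1] >= nt:
            warnings.warn(
                f"trial at onset {att['onset']:.1f}s truncated by run end; "
                "dropped", RuntimeWarning, stacklevel=2)
            continue
        f = data[idx].mean(axis=0)
        if cfg.baseline_control:
            prior = controls[controls["onset"] < att["onset"]]
            if prior.empty:
                warnings.warn("attention phase without a preceding control "
                              "phase; trial dropped", RuntimeWarning,
                              stacklevel=2)
                continue
            ctl = prior.iloc[-1]
            cidx = _phase_indices(ctl["onset"], ctl["duration"], run.tr,
                                  cfg.hemodynamic_delay_trs)
            cidx = cidx[(cidx >= 0) & (cidx < nt)]
            f = f - data[cidx].mean(axis=0)
        feats.append(f)
        side = str(att.get("side", "")).lower()
        labels.append(LABEL_LEFT if side == "left" else LABEL_RIGHT)

    if not feats:
        return []
    x = np.array(feats)  # (n_trials, n_voxels)
    if cfg.zscore:
        mu = x.mean(axis=0)
        sd = x.std(axis=0)
        # (near-)zero-variance voxels carry no information; the tolerance is
        # relative so detrending residue at machine precision stays zero
        tol = 1e-10 * np.maximum(np.abs(x).max(axis=0), 1.0)
        nz = sd > tol
        x = np.where(nz, (x - mu) / np.where(nz, sd, 1.0), 0.0)
    return [TrialPattern(features=x[i], label=labels[i],
                         subject_id=run.subject_id, run_id=run.run_id,
                         grid_shape=grid_shape, affine=run.affine)
            for i in range(x.shape[0])]


# ---------------------------------------------------------------------------
# ROI extraction in common space
# ---------------------------------------------------------------------------

def extract_roi(patterns: Sequence[TrialPattern], mask: ROIMask,
                phi_s: Transform | None = None) -> list[TrialPattern]:
    """Project patterns onto the common grid and keep the ROI voxels.

    ``phi_s`` is the subject's pull-back transform (common grid -> subject
    space); ``None`` means the patterns already live on the common grid.
    The feature order is the ascending flat voxel index within the mask,
    hence identical for every subject.
    """
    patterns = list(patterns)
    if not patterns:
        return []
    sel = mask.data  # boolean indexing follows ascending C-order voxel index
    out = []
    if phi_s is None:
        for p in patterns:
            if p.grid_shape != mask.shape:
                raise GeometryError("pattern grid does not match ROI grid")
            out.append(TrialPattern(features=p.features.reshape(mask.shape)[sel],
                                    label=p.label, subject_id=p.subject_id,
                                    run_id=p.run_id))
        return out
    # warp coordinates are shared by all trials of the subject: compute the
    # pull-back sample locations of the masked common-grid voxels once
    ref = patterns[0]
    if ref.grid_shape is None or ref.affine is None:
        raise ValueError("patterns must carry grid geometry for warping")
    pts = np.argwhere(sel).astype(float) @ mask.affine[:3, :3].T + mask.affine[:3, 3]
    vox = _world_to_voxel(phi_s.map_points(pts), ref.affine)
    infield = _infield(vox, ref.grid_shape)
    if not infield.any():
        raise ValueError("ROI has empty intersection with the subject data field")
    coords = vox.T
    for p in patterns:
        feats = map_coordinates(p.features.reshape(p.grid_shape), coords,
                                order=1, mode="constant", cval=0.0,
                                prefilter=False)
        feats[~infield] = 0.0
        out.append(TrialPattern(features=feats, label=p.label,
                                subject_id=p.subject_id, run_id=p.run_id))
    return out


# ---------------------------------------------------------------------------
# tabular pattern I/O
# ---------------------------------------------------------------------------

def patterns_to_frame(patterns: Sequence[TrialPattern]) -> pd.DataFrame:
    """Pattern set as a table: subject, run, label, then one voxel column."""
    rows = [{"subject": p.subject_id, "run": p.run_id, "label": p.label,
             **{f"v{i}": v for i, v in enumerate(p.features)}}
            for p in patterns]
    return pd.DataFrame(rows)


def patterns_from_frame(frame: pd.DataFrame) -> list[TrialPattern]:
    voxel_cols = [c for c in frame.columns if c.startswith("v")]
    return [TrialPattern(features=row[voxel_cols].to_numpy(float),
                         label=int(row["label"]),
                         subject_id=int(row["subject"]),
                         run_id=int(row["run"]))
            for _, row in frame.iterrows()]


def save_patterns(patterns: Sequence[TrialPattern], path) -> None:
    patterns_to_frame(patterns).to_csv(path, sep="\t", index=False)


def load_patterns(path) -> list[TrialPattern]:
    return patterns_from_frame(pd.read_csv(path, sep="\t"))


# ---------------------------------------------------------------------------
# supervised, subject-transfer voxel selection
# ---------------------------------------------------------------------------

def select_voxels(reference_patterns: Sequence[Sequence[TrialPattern]],
                  mask: ROIMask, fraction: float) -> ROIMask:
    """Rank ROI voxels by summed |Welch t| over reference subjects.

    For each reference subject a two-sample Welch t statistic (attend-left
    vs attend-right trials) is computed per voxel; the selection score is
    the sum of absolute t values over subjects.  The top
    ``ceil(fraction * n)`` voxels are kept, ties broken by ascending voxel
    index.  The target subject's data must never be passed in.
    """
    if not (0 < fraction <= 1):
        raise ValueError("fraction must be in (0, 1]")
    if fraction == 1.0:
        return mask
    voxel_idx = np.flatnonzero(mask.data)
    score = np.zeros(voxel_idx.size)
    for subject_patterns in reference_patterns:
        x = np.array([p.features for p in subject_patterns])
        y = np.array([p.label for p in subject_patterns])
        if x.shape[1] != voxel_idx.size:
            raise ValueError("pattern length does not match ROI size")
        left, right = x[y == LABEL_LEFT], x[y == LABEL_RIGHT]
        if len(left) < 2 or len(right) < 2:
            raise ValueError("need >= 2 trials per class per reference subject")
        t = stats.ttest_ind(left, right, axis=0, equal_var=False).statistic
        score += np.abs(np.nan_to_num(t))
    k = int(np.ceil(fraction * voxel_idx.size))
    order = np.lexsort((voxel_idx, -score))  # score desc, then index asc
    keep = np.sort(voxel_idx[order[:k]])
    data = np.zeros(mask.shape, dtype=bool)
    data.flat[keep] = True
    return ROIMask(data=data, affine=mask.affine,
                   name=f"{mask.name}_top{fraction:g}")
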