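"""Synthetic multi-subject phantom cohorts.

The generator emulates the structure the transfer-decoding method assumes:

* a template "tensor brain" — an ellipsoidal head containing a curved
  white-matter tract (anisotropic tensors aligned with the tract tangent)
  wrapped in a weakly anisotropic gray-matter band, the rest isotropic;
* per-subject ground-truth piecewise-affine deformations of that template
  (global rotation / translation / scaling plus per-block jitter), with
  tensor reorientation;
* 30-direction b = 1000 s/mm^2 diffusion-weighted signals with noise,
  acquired twice and averaged in signal space before fitting;
* task-fMRI runs whose informative voxels sit in the gray-matter shell
  adjacent to the white matter — i.e. at the edge of gray matter — and
  move with each subject's anatomy, so anatomical registration (not the
  functional data itself) is what can bring them into correspondence across
  subjects;
* a scalar "pseudo-T1" volume with tissue-dependent intensities, a smooth
  bias field and noise, so the scalar-baseline registration route runs on
  the same cohort.

Trials follow the task timing: Rest 8-16 s, Control 4 s, Attention 8 s at
TR = 2 s.  During Attention, informative voxels gain a side-dependent
signal (+effect for their preferred side, -effect otherwise); Control adds
the same symmetric signal for both sides and therefore carries no label
information.
"""

from __future__ import annotations

import dataclasses
import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.ndimage import binary_dilation, gaussian_filter, generate_binary_structure

from .fmri_prep import FunctionalRun
from .registration import (
    PiecewiseAffineTransform,
    _target_domain,
    apply_transform_scalar,
    apply_transform_tensor,
    jacobian_map,
)
from .tensor_core import (
    GradientScheme,
    ScalarVolume,
    TensorVolume,
    default_scheme,
    fit_tensor,
    forward_signal,
)

LABEL_BG, LABEL_CSF, LABEL_GM, LABEL_WM = 0, 1, 2, 3


@dataclass
class PhantomSpec:
    """All knobs of the synthetic cohort generator.

    Deformation magnitudes are upper bounds of the uniform draws; all
    magnitudes must be non-negative and the grid at least 16 per axis.
    """

    grid_shape: tuple[int, int, int] = (32, 32, 32)
    voxel_size: float = 2.0                      # mm, isotropic
    # anatomy (voxel units)
    tract_radius: float = 3.0
    tract_amplitude: float = 2.5                 # sinusoidal bend of the tract
    tract_taper: float = 0.3                     # radius modulation along the tract
    gm_thickness: float = 2.0
    brain_axes_frac: tuple[float, float, float] = (0.44, 0.46, 0.44)
    # tensors (mm^2/s)
    wm_eigenvalues: tuple[float, float, float] = (1.7e-3, 0.3e-3, 0.3e-3)
    gm_eigenvalues: tuple[float, float, float] = (0.9e-3, 0.7e-3, 0.7e-3)
    csf_diffusivity: float = 2.5e-3
    # DWI acquisition
    n_directions: int = 30
    b_value: float = 1000.0
    dwi_s0: float = 100.0
    dwi_noise_sd: float = 2.0
    rician_noise: bool = False
    n_dwi_acquisitions: int = 2                  # averaged in signal space
    # ground-truth deformation
    deformation_translation_vox: float = 2.0
    deformation_rotation_deg: float = 5.0
    deformation_scale: float = 0.05
    deformation_block_jitter_mm: float = 1.0
    # fMRI task
    fmri_effect: float = 1.0                     # z-units
    fmri_noise_sd: float = 1.0
    informative_pattern_smoothness: float = 1.0  # voxels; see template_geometry
    fmri_drift_sd: float = 0.01                  # per-voxel slope SD per TR
    trials_per_run: int = 25
    runs_per_subject: int = 5
    tr: float = 2.0
    rest_durations_s: tuple[float, ...] = (8.0, 10.0, 12.0, 14.0, 16.0)
    control_duration_s: float = 4.0
    attention_duration_s: float = 8.0
    hemodynamic_delay_s: float = 4.0
    initial_rest_s: float = 10.0
    # pseudo-T1
    t1_intensities: tuple[float, float, float] = (0.3, 0.7, 1.0)  # csf, gm, wm
    t1_bias_amplitude: float = 0.1
    t1_noise_sd: float = 0.03
    seed: int = 0

    def __post_init__(self) -> None:
        if any(n < 16 for n in self.grid_shape):
            raise ValueError("grid must be at least 16 voxels per axis")
        for name in ("tract_radius", "gm_thickness", "dwi_noise_sd",
                     "deformation_translation_vox", "deformation_rotation_deg",
                     "deformation_scale", "deformation_block_jitter_mm",
                     "fmri_effect", "fmri_noise_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")

    @property
    def affine(self) -> np.ndarray:
        return np.diag([self.voxel_size] * 3 + [1.0])

    @classmethod
    def desk(cls, **overrides) -> "PhantomSpec":
        """Scaled-down run lengths for quick desk-scale experiments."""
        params = dict(trials_per_run=10, runs_per_subject=3)
        params.update(overrides)
        return cls(**params)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return {k: (list(v) if isinstance(v, tuple) else v)
                for k, v in d.items()}

    @classmethod
    def from_dict(cls, d: dict) -> "PhantomSpec":
        fields = {f.name for f in dataclasses.fields(cls)}
        kwargs = {}
        for k, v in d.items():
            if k not in fields:
                raise ValueError(f"unknown phantom parameter {k!r}")
            kwargs[k] = tuple(v) if isinstance(v, list) else v
        return cls(**kwargs)


# ---------------------------------------------------------------------------
# template anatomy
# ---------------------------------------------------------------------------

@dataclass
class TemplateGeometry:
    """Template tissue labels and informative-voxel structure."""

    labels: np.ndarray            # 0 bg / 1 csf / 2 gm / 3 wm
    informative_mask: np.ndarray  # edge-of-GM band
    informative_sign: np.ndarray  # +1 / -1 side preference, 0 elsewhere

    @property
    def brain_mask(self) -> np.ndarray:
        return self.labels > 0


def template_geometry(spec: PhantomSpec) -> TemplateGeometry:
    nx, ny, nz = spec.grid_shape
    cx, cy, cz = (nx - 1) / 2.0, (ny - 1) / 2.0, (nz - 1) / 2.0
    x, y, z = np.meshgrid(np.arange(nx), np.arange(ny), np.arange(nz),
                          indexing="ij")
    ax, ay, az = (spec.brain_axes_frac[0] * nx, spec.brain_axes_frac[1] * ny,
                  spec.brain_axes_frac[2] * nz)
    brain = (((x - cx) / ax) ** 2 + ((y - cy) / ay) ** 2
             + ((z - cz) / az) ** 2) <= 1.0

    r_max = spec.tract_radius * (1 + abs(spec.tract_taper))
    outer = spec.tract_amplitude + r_max + spec.gm_thickness
    if cx + outer >= nx - 1 or cx - outer <= 0 or cz + r_max \
            + spec.gm_thickness >= nz - 1:
        raise ValueError("tract (with its gray-matter band) leaves the grid")

    xc = cx + spec.tract_amplitude * np.sin(2 * np.pi * y / ny)
    # the tract thins and thickens along its course so that position along
    # the tract is anatomically identifiable
    radius = spec.tract_radius * (
        1 + spec.tract_taper * np.sin(4 * np.pi * y / ny))
    dist = np.sqrt((x - xc) ** 2 + (z - cz) ** 2)
    wm = brain & (dist <= radius)
    gm = brain & (dist > radius) & (dist <= radius + spec.gm_thickness)
    labels = np.zeros(spec.grid_shape, dtype=np.int8)
    labels[brain] = LABEL_CSF
    labels[gm] = LABEL_GM
    labels[wm] = LABEL_WM

    struct = generate_binary_structure(3, 1)  # 6-connectivity
    informative = gm & binary_dilation(wm, structure=struct)
    # Side preference is a fine-grained pattern fixed in template space and
    # carried along by each subject's deformation: functional elements sit at
    # corresponding anatomical positions but form an idiosyncratic spatial
    # pattern, so voxel-level correspondence (registration) is what makes the
    # pattern transferable across subjects.
    rng = np.random.default_rng(spec.seed)
    fld = gaussian_filter(rng.standard_normal(spec.grid_shape),
                          max(spec.informative_pattern_smoothness, 1e-6))
    sign = np.zeros(spec.grid_shape, dtype=np.int8)
    sign[informative] = np.where(fld[informative] >= 0, 1, -1)
    return TemplateGeometry(labels=labels, informative_mask=informative,
                            informative_sign=sign)


def make_template(spec: PhantomSpec,
                  geometry: TemplateGeometry | None = None) -> TensorVolume:
    """Deterministic tensor-brain template for the given phantom spec."""
    geo = geometry or template_geometry(spec)
    nx, ny, nz = spec.grid_shape
    cx, cz = (nx - 1) / 2.0, (nz - 1) / 2.0
    x, y, z = np.meshgrid(np.arange(nx), np.arange(ny), np.arange(nz),
                          indexing="ij")
    data = np.zeros(spec.grid_shape + (6,))

    def anisotropic(axis, lam_par, lam_perp):
        """lam_perp * I + (lam_par - lam_perp) * axis axis^T, in 6 components."""
        axx, ayy, azz = axis[..., 0], axis[..., 1], axis[..., 2]
        out = np.zeros(axis.shape[:-1] + (6,))
        d = lam_par - lam_perp
        out[..., 0] = lam_perp + d * axx * axx
        out[..., 1] = d * axx * ayy
        out[..., 2] = lam_perp + d * ayy * ayy
        out[..., 3] = d * axx * azz
        out[..., 4] = d * ayy * azz
        out[..., 5] = lam_perp + d * azz * azz
        return out

    # WM: principal axis along the tract tangent (dx_c/dy, 1, 0)
    slope = spec.tract_amplitude * 2 * np.pi / ny * np.cos(2 * np.pi * y / ny)
    tangent = np.stack([slope, np.ones_like(slope), np.zeros_like(slope)],
                       axis=-1)
    tangent /= np.linalg.norm(tangent, axis=-1, keepdims=True)
    wm = geo.labels == LABEL_WM
    lam1, lam2, _ = spec.wm_eigenvalues
    data[wm] = anisotropic(tangent, lam1, lam2)[wm]

    # GM: weak anisotropy along the in-plane radial direction
    xc = cx + spec.tract_amplitude * np.sin(2 * np.pi * y / ny)
    radial = np.stack([x - xc, np.zeros_like(slope), z - cz], axis=-1).astype(float)
    rn = np.linalg.norm(radial, axis=-1, keepdims=True)
    radial = np.divide(radial, rn, out=np.zeros_like(radial), where=rn > 0)
    gm = geo.labels == LABEL_GM
    g1, g2, _ = spec.gm_eigenvalues
    data[gm] = anisotropic(radial, g1, g2)[gm]

    csf = geo.labels == LABEL_CSF
    for k in (0, 2, 5):
        data[..., k][csf] = spec.csf_diffusivity

    return TensorVolume(data=data, affine=spec.affine, mask=geo.brain_mask)


def pseudo_t1(labels: np.ndarray, spec: PhantomSpec,
              rng: np.random.Generator) -> ScalarVolume:
    """Tissue-intensity scalar volume with a smooth bias field and noise."""
    lut = np.array([0.0, *spec.t1_intensities])
    data = lut[labels]
    if spec.t1_bias_amplitude > 0:
        bias = gaussian_filter(rng.standard_normal(labels.shape), 6.0)
        bias *= spec.t1_bias_amplitude / max(np.abs(bias).max(), 1e-12)
        data = data * (1.0 + bias)
    if spec.t1_noise_sd > 0:
        data = data + rng.normal(0.0, spec.t1_noise_sd, labels.shape)
    data[labels == LABEL_BG] = 0.0
    return ScalarVolume(data=data, affine=spec.affine, mask=labels > 0)


# ---------------------------------------------------------------------------
# subjects
# ---------------------------------------------------------------------------

@dataclass
class SubjectData:
    """One synthetic subject: anatomy, DWI, functional runs, ground truth.

    ``true_warp`` is the generation pull-back map (subject grid -> template
    coordinates): the subject volume is the template resampled through it,
    so composing an estimated template->subject transform with ``true_warp``
    should give the identity.
    """

    subject_id: int
    true_warp: PiecewiseAffineTransform
    true_tensors: TensorVolume
    tensors: TensorVolume            # fitted from the noisy DWI
    dwi: np.ndarray
    scheme: GradientScheme
    pseudo_t1: ScalarVolume
    runs: list[FunctionalRun]
    labels: np.ndarray               # warped tissue labels, subject space
    informative_mask: np.ndarray
    informative_sign: np.ndarray


@dataclass
class SyntheticCohort:
    """Template phantom plus generated subjects (subject 0 = template-only)."""

    spec: PhantomSpec
    template: TensorVolume
    geometry: TemplateGeometry
    subjects: list[SubjectData]

    @property
    def analysis_subjects(self) -> list[SubjectData]:
        """Subjects entering decoding (the template subject is excluded)."""
        return [s for s in self.subjects if s.subject_id != 0]


def _identity_warp(template: TensorVolume) -> PiecewiseAffineTransform:
    lo, hi = _target_domain(template)
    return PiecewiseAffineTransform.identity((1, 1, 1), lo, hi)


def _sample_deformation(spec: PhantomSpec, template: TensorVolume,
                        rng: np.random.Generator) -> PiecewiseAffineTransform:
    """Ground-truth pull-back deformation; rejects folding draws (<= 10 tries)."""
    lo, hi = _target_domain(template)
    rot = np.deg2rad(spec.deformation_rotation_deg)
    tmax = spec.deformation_translation_vox * spec.voxel_size
    for _ in range(10):
        angles = rng.uniform(-rot, rot, 3)
        scales = rng.uniform(1 - spec.deformation_scale,
                             1 + spec.deformation_scale, 3)
        trans = rng.uniform(-tmax, tmax, 3)
        rx, ry, rz = angles
        def _r(i, j, ang):
            m = np.eye(3)
            m[i, i] = m[j, j] = np.cos(ang)
            m[i, j] = -np.sin(ang)
            m[j, i] = np.sin(ang)
            return m
        a = _r(0, 1, rz) @ _r(0, 2, ry) @ _r(1, 2, rx) @ np.diag(scales)
        phi = PiecewiseAffineTransform((2, 2, 2), lo, hi)
        glob = PiecewiseAffineTransform((1, 1, 1), lo, hi,
                                        a=a[None], t=trans[None])
        phi.a = glob.linear_part(phi.centers)
        phi.t = glob.map_points(phi.centers) - phi.centers
        if spec.deformation_block_jitter_mm > 0:
            phi.t = phi.t + rng.normal(0.0, spec.deformation_block_jitter_mm,
                                       phi.t.shape)
        if jacobian_map(phi, template).data.min() > 0:
            return phi
    raise RuntimeError("could not sample a fold-free deformation in 10 tries")


def _simulate_dwi(true_tensors: TensorVolume, spec: PhantomSpec,
                  rng: np.random.Generator):
    scheme = default_scheme(spec.n_directions, spec.b_value)
    clean = forward_signal(true_tensors.data, scheme, spec.dwi_s0)
    clean[~true_tensors.mask] = 0.0
    acq = np.zeros_like(clean)
    for _ in range(max(spec.n_dwi_acquisitions, 1)):
        if spec.rician_noise:
            n1 = rng.normal(0, spec.dwi_noise_sd, clean.shape)
            n2 = rng.normal(0, spec.dwi_noise_sd, clean.shape)
            acq += np.sqrt((clean + n1) ** 2 + n2 ** 2)
        else:
            acq += clean + rng.normal(0, spec.dwi_noise_sd, clean.shape)
    dwi = acq / max(spec.n_dwi_acquisitions, 1)
    dwi[~true_tensors.mask] = 0.0
    return dwi, scheme


def _simulate_run(spec: PhantomSpec, brain: np.ndarray, informative: np.ndarray,
                  sign: np.ndarray, rng: np.random.Generator,
                  subject_id: int, run_id: int) -> FunctionalRun:
    tr = spec.tr
    sides = np.array([1, -1]).repeat(int(np.ceil(spec.trials_per_run / 2)))
    sides = sides[:spec.trials_per_run]
    rng.shuffle(sides)
    rows = []
    t = spec.initial_rest_s
    for side in sides:
        rest = float(rng.choice(spec.rest_durations_s))
        rows.append((t, rest, "rest", ""))
        t += rest
        rows.append((t, spec.control_duration_s, "control", ""))
        t += spec.control_duration_s
        rows.append((t, spec.attention_duration_s, "attention",
                     "left" if side > 0 else "right"))
        t += spec.attention_duration_s
    # leave room for the hemodynamically delayed response of the last trial
    n_vol = int(np.ceil((t + spec.hemodynamic_delay_s) / tr))
    events = pd.DataFrame(rows, columns=["onset", "duration", "phase", "side"])

    data = np.zeros((n_vol,) + spec.grid_shape, dtype=np.float32)
    flat = data.reshape(n_vol, -1)
    bidx = np.flatnonzero(brain)
    flat[:, bidx] = 100.0 + rng.normal(
        0.0, spec.fmri_noise_sd, (n_vol, bidx.size)).astype(np.float32)
    if spec.fmri_drift_sd > 0:
        slope = rng.normal(0.0, spec.fmri_drift_sd, bidx.size)
        flat[:, bidx] += (np.arange(n_vol)[:, None] * slope).astype(np.float32)

    iidx = np.flatnonzero(informative)
    s_v = sign.reshape(-1)[iidx].astype(np.float32)
    delay = spec.hemodynamic_delay_s
    for onset, dur, phase, side in rows:
        if phase == "rest":
            continue
        v0 = int(round((onset + delay) / tr))
        v1 = v0 + int(round(dur / tr))
        v1 = min(v1, n_vol)
        if phase == "control":
            flat[v0:v1, iidx] += np.float32(0.5 * spec.fmri_effect)
        else:
            s = 1.0 if side == "left" else -1.0
            flat[v0:v1, iidx] += (s * s_v * spec.fmri_effect).astype(np.float32)
    return FunctionalRun(data=data, events=events, tr=tr,
                         subject_id=subject_id, run_id=run_id,
                         affine=spec.affine)


def make_subject(template: TensorVolume, spec: PhantomSpec,
                 subject_seed: int, subject_id: int = 1,
                 geometry: TemplateGeometry | None = None,
                 deform: bool = True) -> SubjectData:
    """Generate one subject: warped anatomy, DWI, pseudo-T1 and task runs."""
    geo = geometry or template_geometry(spec)
    rng = np.random.default_rng(subject_seed)
    if deform:
        warp = _sample_deformation(spec, template, rng)
        true_tensors = apply_transform_tensor(template, warp, template)
        lab = apply_transform_scalar(
            ScalarVolume(geo.labels.astype(float), template.affine),
            warp, template, interpolation="nearest")
        labels = np.rint(lab.data).astype(np.int8)
        sgn = apply_transform_scalar(
            ScalarVolume(geo.informative_sign.astype(float), template.affine),
            warp, template, interpolation="nearest")
        sign = np.rint(sgn.data).astype(np.int8)
    else:
        warp = _identity_warp(template)
        true_tensors = TensorVolume(template.data.copy(),
                                    template.affine.copy(),
                                    template.mask.copy())
        labels = geo.labels.copy()
        sign = geo.informative_sign.copy()
    informative = sign != 0
    brain = labels > 0

    dwi, scheme = _simulate_dwi(true_tensors, spec, rng)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        fitted = fit_tensor(dwi, scheme, mask=brain, affine=template.affine)
    t1 = pseudo_t1(labels, spec, rng)
    runs = [_simulate_run(spec, brain, informative, sign, rng, subject_id, r)
            for r in range(spec.runs_per_subject)]
    return SubjectData(subject_id=subject_id, true_warp=warp,
                       true_tensors=true_tensors, tensors=fitted, dwi=dwi,
                       scheme=scheme, pseudo_t1=t1, runs=runs, labels=labels,
                       informative_mask=informative, informative_sign=sign)


def make_cohort(n_subjects: int, spec: PhantomSpec) -> SyntheticCohort:
    """Template subject (id 0, undeformed) plus deformed analysis subjects."""
    if n_subjects < 3:
        raise ValueError("a cohort needs at least 3 subjects "
                         "(template + 2 analysis subjects)")
    geo = template_geometry(spec)
    template = make_template(spec, geo)
    children = np.random.SeedSequence(spec.seed).spawn(n_subjects)
    subjects = []
    for i in range(n_subjects):
        seed = int(children[i].generate_state(1)[0] % (2**31 - 1))
        subjects.append(make_subject(template, spec, seed, subject_id=i,
                                     geometry=geo, deform=(i != 0)))
    return SyntheticCohort(spec=spec, template=template, geometry=geo,
                           subjects=subjects)


# ---------------------------------------------------------------------------
# on-disk layout
# ---------------------------------------------------------------------------

def save_cohort(cohort: SyntheticCohort, outdir: str | Path) -> Path:
    """Write the cohort in the directory layout the CLI consumes."""
    import nibabel as nib

    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    (out / "spec.json").write_text(json.dumps(cohort.spec.to_dict(), indent=1))
    tdir = out / "template"
    tdir.mkdir(exist_ok=True)
    cohort.template.to_nifti(tdir / "tensors.nii.gz")
    aff = cohort.template.affine
    nib.save(nib.Nifti1Image(cohort.geometry.labels.astype(np.int16), aff),
             str(tdir / "labels.nii.gz"))
    nib.save(nib.Nifti1Image(
        cohort.geometry.informative_sign.astype(np.int16), aff),
        str(tdir / "informative_sign.nii.gz"))
    truth = out / "truth"
    truth.mkdir(exist_ok=True)
    for sub in cohort.subjects:
        sid = f"sub-{sub.subject_id:02d}"
        for d in ("dwi", "func", "anat"):
            (out / sid / d).mkdir(parents=True, exist_ok=True)
        nib.save(nib.Nifti1Image(sub.dwi.astype(np.float32), aff),
                 str(out / sid / "dwi" / "dwi.nii.gz"))
        sub.scheme.to_files(out / sid / "dwi" / "dwi.bval",
                            out / sid / "dwi" / "dwi.bvec")
        sub.pseudo_t1.to_nifti(out / sid / "anat" / "pseudo-t1.nii.gz")
        nib.save(nib.Nifti1Image(sub.labels.astype(np.int16), aff),
                 str(out / sid / "anat" / "labels.nii.gz"))
        for run in sub.runs:
            stem = out / sid / "func" / f"run-{run.run_id}"
            nib.save(nib.Nifti1Image(
                np.moveaxis(run.data, 0, -1), aff), str(stem) + ".nii.gz")
            run.events.to_csv(str(stem) + "_events.tsv", sep="\t", index=False)
        sub.true_warp.save_json(truth / f"{sid}_warp.json")
        nib.save(nib.Nifti1Image(sub.informative_sign.astype(np.int16), aff),
                 str(truth / f"{sid}_informative_sign.nii.gz"))
    return out


def load_cohort(path: str | Path) -> SyntheticCohort:
    """Rebuild a cohort from the on-disk layout written by :func:`save_cohort`."""
    import nibabel as nib

    root = Path(path)
    spec = PhantomSpec.from_dict(json.loads((root / "spec.json").read_text()))
    geo = template_geometry(spec)
    template = make_template(spec, geo)
    subjects = []
    for subdir in sorted(root.glob("sub-*")):
        sid = int(subdir.name.split("-")[1])
        dwi = np.asarray(nib.load(
            str(subdir / "dwi" / "dwi.nii.gz")).get_fdata())
        scheme = GradientScheme.from_files(subdir / "dwi" / "dwi.bval",
                                           subdir / "dwi" / "dwi.bvec")
        labels = np.rint(np.asarray(nib.load(
            str(subdir / "anat" / "labels.nii.gz")).get_fdata())).astype(np.int8)
        t1 = ScalarVolume.from_nifti(subdir / "anat" / "pseudo-t1.nii.gz")
        t1.mask = labels > 0
        sign = np.rint(np.asarray(nib.load(
            str(root / "truth" / f"{subdir.name}_informative_sign.nii.gz")
        ).get_fdata())).astype(np.int8)
        warp = PiecewiseAffineTransform.load_json(
            root / "truth" / f"{subdir.name}_warp.json")
        true_tensors = apply_transform_tensor(template, warp, template)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            fitted = fit_tensor(dwi, scheme, mask=labels > 0,
                                affine=template.affine)
        runs = []
        for f in sorted(subdir.glob("func/run-*.nii.gz")):
            run_id = int(f.name.split("-")[1].split(".")[0])
            data = np.moveaxis(np.asarray(nib.load(str(f)).get_fdata(),
                                          dtype=np.float32), -1, 0)
            events = pd.read_csv(str(f)[:-7] + "_events.tsv", sep="\t",
                                 keep_default_na=False)
            runs.append(FunctionalRun(data=data, events=events, tr=spec.tr,
                                      subject_id=sid, run_id=run_id,
                                      affine=spec.affine))
        subjects.append(SubjectData(
            subject_id=sid, true_warp=warp, true_tensors=true_tensors,
            tensors=fitted, dwi=dwi, scheme=scheme, pseudo_t1=t1, runs=runs,
            labels=labels, informative_mask=sign != 0,
            informative_sign=sign))
    return SyntheticCohort(spec=spec, template=template, geometry=geo,
                           subjects=subjects)
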