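"""End-to-end orchestration on (synthetic) cohorts.

Ties the pieces together: build the common anatomical coordinates from the
cohort's anatomy (tensor route, scalar pseudo-T1 route, or no registration
at all), project every subject's trial patterns into that space, and run
the transfer / self decoders.  Also provides the discordance analysis
between the two registration routes and deformation (Jacobian) features
for the subject-similarity statistics.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .decoding import DecodingResult, conjunction_decode, self_decode, voting_decode
from .discordance import (
    DiscordanceMap,
    TissueMasks,
    discordance_map,
    registered_fa,
    stratified_summary,
    tissue_masks,
)
from .fmri_prep import PreprocessConfig, ROIMask, TrialPattern, extract_roi, preprocess_run
from .registration import (
    CommonSpace,
    RegistrationConfig,
    build_common_space,
    jacobian_map,
    parcel_jacobian_features,
)
from .synthetic import LABEL_GM, SyntheticCohort

ROUTES = ("dti", "t1", "none")


def default_roi(cohort: SyntheticCohort) -> ROIMask:
    """Gray-matter band of the template as the decoding ROI.

    The common grid coincides with the template subject's grid (subject 0
    is undeformed), so the template's gray-matter band doubles as a
    common-space ROI — the synthetic stand-in for an anatomical atlas ROI.
    """
    return ROIMask(data=cohort.geometry.labels == LABEL_GM,
                   affine=cohort.template.affine, name="gm_band")


def build_cohort_common_space(cohort: SyntheticCohort, route: str = "dti",
                              reg_config: RegistrationConfig | None = None,
                              ) -> CommonSpace:
    """Common coordinates from the cohort's tensors (dti) or pseudo-T1 (t1)."""
    if route == "dti":
        vols = [s.tensors for s in cohort.subjects]
    elif route == "t1":
        vols = [s.pseudo_t1 for s in cohort.subjects]
    else:
        raise ValueError(f"unknown registration route {route!r}")
    return build_common_space(vols, template_id=0, config=reg_config)


def transfer_patterns(cohort: SyntheticCohort, registration: str = "dti",
                      reg_config: RegistrationConfig | None = None,
                      prep_config: PreprocessConfig | None = None,
                      roi: ROIMask | None = None,
                      common_space: CommonSpace | None = None,
                      ) -> tuple[list[TrialPattern], CommonSpace | None]:
    """ROI trial patterns of all analysis subjects in the common space.

    ``registration='none'`` skips the spatial normalization entirely — the
    unregistered baseline where the ROI is applied to each subject's native
    grid directly.
    """
    if registration not in ROUTES:
        raise ValueError(f"registration must be one of {ROUTES}")
    roi = roi or default_roi(cohort)
    cs = common_space
    if registration != "none" and cs is None:
        cs = build_cohort_common_space(cohort, registration, reg_config)
    patterns: list[TrialPattern] = []
    for sub in cohort.analysis_subjects:
        raw = [p for run in sub.runs
               for p in preprocess_run(run, prep_config)]
        phi = None if registration == "none" else cs.transforms[sub.subject_id]
        patterns.extend(extract_roi(raw, roi, phi))
    return patterns, cs


def transfer_decode(cohort: SyntheticCohort, scheme: str = "conjunction",
                    registration: str = "dti",
                    reg_config: RegistrationConfig | None = None,
                    prep_config: PreprocessConfig | None = None,
                    roi: ROIMask | None = None,
                    common_space: CommonSpace | None = None) -> DecodingResult:
    """Leave-one-subject-out transfer decoding over the analysis subjects."""
    patterns, _ = transfer_patterns(cohort, registration, reg_config,
                                    prep_config, roi, common_space)
    if scheme == "conjunction":
        return conjunction_decode(patterns)
    if scheme == "voting":
        return voting_decode(patterns)
    raise ValueError(f"unknown transfer scheme {scheme!r}")


def self_decode_cohort(cohort: SyntheticCohort,
                       prep_config: PreprocessConfig | None = None,
                       ) -> DecodingResult:
    """Within-subject leave-one-run-out decoding in native space.

    The per-subject ROI is the subject's own gray-matter band (from its
    warped tissue labels); no inter-subject registration is involved.
    """
    patterns: list[TrialPattern] = []
    for sub in cohort.analysis_subjects:
        roi = ROIMask(data=sub.labels == LABEL_GM,
                      affine=cohort.template.affine,
                      name=f"sub-{sub.subject_id}_gm")
        raw = [p for run in sub.runs for p in preprocess_run(run, prep_config)]
        patterns.extend(extract_roi(raw, roi, None))
    return self_decode(patterns)


# ---------------------------------------------------------------------------
# discordance between the two registration routes
# ---------------------------------------------------------------------------

@dataclass
class DiscordanceAnalysis:
    map: DiscordanceMap
    masks: TissueMasks
    summary: "object"  # pandas DataFrame


def discordance_analysis(cohort: SyntheticCohort,
                         reg_config: RegistrationConfig | None = None,
                         cs_dti: CommonSpace | None = None,
                         cs_t1: CommonSpace | None = None,
                         ) -> DiscordanceAnalysis:
    """Fig.-3-style comparison of the tensor and scalar registration routes."""
    cs_dti = cs_dti or build_cohort_common_space(cohort, "dti", reg_config)
    cs_t1 = cs_t1 or build_cohort_common_space(cohort, "t1", reg_config)
    grid = cs_dti.mean_template
    fa_dti, fa_t1 = [], []
    for sub in cohort.analysis_subjects:
        fa_dti.append(registered_fa(sub.tensors,
                                    cs_dti.transforms[sub.subject_id], grid))
        fa_t1.append(registered_fa(sub.tensors,
                                   cs_t1.transforms[sub.subject_id], grid))
    dmap = discordance_map(fa_dti, fa_t1)
    masks = tissue_masks(cohort.template)
    return DiscordanceAnalysis(map=dmap, masks=masks,
                               summary=stratified_summary(dmap, masks))


# ---------------------------------------------------------------------------
# deformation features
# ---------------------------------------------------------------------------

def synthetic_parcellation(cohort: SyntheticCohort,
                           splits: tuple[int, int, int] = (3, 3, 3)
                           ) -> np.ndarray:
    """Octant-style parcellation of the template brain into labelled areas."""
    shape = cohort.template.shape
    labels = np.zeros(shape, dtype=np.int32)
    idx = np.indices(shape)
    code = np.zeros(shape, dtype=np.int32)
    for k in range(3):
        band = np.minimum((idx[k] * splits[k]) // shape[k], splits[k] - 1)
        code = code * splits[k] + band
    labels[cohort.template.mask] = code[cohort.template.mask] + 1
    return labels


def deformation_features(common_space: CommonSpace, parcellation: np.ndarray,
                         subject_ids=None) -> np.ndarray:
    """Subject-by-parcel matrix of mean Jacobian determinants of phi_s."""
    grid = common_space.mean_template
    ids = sorted(common_space.transforms) if subject_ids is None \
        else list(subject_ids)
    rows = []
    for sid in ids:
        jac = jacobian_map(common_space.transforms[sid], grid)
        _, means = parcel_jacobian_features(jac, parcellation)
        rows.append(means)
    return np.array(rows)
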