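"""Trial-pattern preprocessing, ROI extraction and voxel selection."""

import numpy as np
import pandas as pd
import pytest

from tensorxfer.fmri_prep import (
    FunctionalRun,
    PreprocessConfig,
    ROIMask,
    TrialPattern,
    extract_roi,
    preprocess_run,
    select_voxels,
)
from tensorxfer.registration import PiecewiseAffineTransform, \
    apply_transform_scalar
from tensorxfer.tensor_core import ScalarVolume


def toy_run(n_trials=3, shape=(2, 2, 1), tr=2.0, drop=5, sides=None,
            signal=None, noise=None, seed=0):
    """A minimal run: `drop` dummy volumes, then rest(8)/control(4)/attention(8)."""
    sides = sides or ["left", "right", "left"][:n_trials]
    rows = []
    t = drop * tr
    for side in sides:
        rows.append((t, 8.0, "rest", ""))
        rows.append((t + 8.0, 4.0, "control", ""))
        rows.append((t + 12.0, 8.0, "attention", side))
        t += 20.0
    n_vol = int(t / tr) + 2  # room for the delayed response
    events = pd.DataFrame(rows, columns=["onset", "duration", "phase", "side"])
    rng = np.random.default_rng(seed)
    data = np.zeros((n_vol,) + shape, dtype=float)
    if noise:
        data += rng.normal(0, noise, data.shape)
    if signal is not None:
        signal(data, events, tr)
    return FunctionalRun(data=data, events=events, tr=tr)


def add_attention_boxcar(amplitude, voxel=(0, 0, 0), delay_trs=2):
    """Side-signed boxcar in the attention phase of every trial."""
    def _apply(data, events, tr):
        for _, row in events[events["phase"] == "attention"].iterrows():
            v0 = int(row["onset"] / tr) + delay_trs
            v1 = v0 + int(row["duration"] / tr)
            s = 1.0 if row["side"] == "left" else -1.0
            data[(slice(v0, v1), *voxel)] += s * amplitude
    return _apply


class TestPreprocessRun:
    def test_pure_trend_voxel_gives_zero_features(self):
        run = toy_run()
        run.data[:, 0, 0, 0] = 0.7 * np.arange(run.n_volumes) + 5.0
        pats = preprocess_run(run)
        feats = np.array([p.features for p in pats])
        assert np.allclose(feats, 0.0, atol=1e-10)

    def test_noiseless_boxcar_is_perfectly_separable(self):
        run = toy_run(n_trials=4, sides=["left", "right", "right", "left"],
                      signal=add_attention_boxcar(2.0))
        pats = preprocess_run(run)
        labels = np.array([p.label for p in pats])
        vals = np.array([p.features[0] for p in pats])
        assert np.all(vals[labels == 1] > 0)
        assert np.all(vals[labels == -1] < 0)

    def test_phase_means_match_hand_computed_oracle(self):
        """Steps 5-6 equal spreadsheet-style phase means on a tiny run."""
        run = toy_run(n_trials=3)
        rng = np.random.default_rng(3)
        run.data[:] = rng.normal(0, 1, run.data.shape)
        cfg = PreprocessConfig(detrend=False, winsorize_mads=0, zscore=False)
        pats = preprocess_run(run, cfg)
        tr, drop, delay = 2.0, 5, 2
        x = run.data[drop:].reshape(run.n_volumes - drop, -1)
        for i, p in enumerate(pats):
            onset_att = (8.0 + 4.0) + 20.0 * i  # after dropped volumes
            a0 = int(onset_att / tr) + delay
            c0 = int((onset_att - 4.0) / tr) + delay
            expected = x[a0:a0 + 4].mean(axis=0) - x[c0:c0 + 2].mean(axis=0)
            assert np.allclose(p.features, expected)

    def test_invariance_to_offset_and_trend(self):
        base = toy_run(n_trials=4, sides=["left", "right", "left", "right"],
                       signal=add_attention_boxcar(1.5), noise=0.3)
        shifted = toy_run(n_trials=4,
                          sides=["left", "right", "left", "right"],
                          signal=add_attention_boxcar(1.5), noise=0.3)
        t = np.arange(shifted.n_volumes, dtype=float)
        shifted.data += 11.0 + 0.25 * t[:, None, None, None]
        f_base = np.array([p.features for p in preprocess_run(base)])
        f_shift = np.array([p.features for p in preprocess_run(shifted)])
        assert np.allclose(f_base, f_shift, atol=1e-8)

    def test_zscore_moments(self):
        run = toy_run(n_trials=4, sides=["left", "right", "left", "right"],
                      noise=1.0)
        feats = np.array([p.features for p in preprocess_run(run)])
        mu = feats.mean(axis=0)
        sd = feats.std(axis=0)
        nz = sd > 0
        assert np.abs(mu[nz]).max() < 1e-10
        assert np.abs(sd[nz] - 1).max() < 1e-10

    def test_truncated_trial_dropped_with_warning(self):
        run = toy_run(n_trials=3)
        run.data = run.data[:-6]  # cut into the last attention phase
        with pytest.warns(RuntimeWarning, match="truncated"):
            pats = preprocess_run(run)
        assert len(pats) == 2

    def test_labels_follow_sides(self):
        run = toy_run(n_trials=3, sides=["right", "left", "right"])
        pats = preprocess_run(run)
        assert [p.label for p in pats] == [-1, 1, -1]


class TestExtractROI:
    def _patterns(self, rng, shape=(6, 6, 6), n=4):
        return [TrialPattern(features=rng.normal(size=np.prod(shape)),
                             label=1 if i % 2 == 0 else -1, subject_id=0,
                             run_id=0, grid_shape=shape, affine=np.eye(4))
                for i in range(n)]

    def test_full_mask_identity_is_unchanged(self, rng):
        pats = self._patterns(rng)
        mask = ROIMask(data=np.ones((6, 6, 6), bool))
        out = extract_roi(pats, mask, None)
        for p, q in zip(pats, out):
            assert np.allclose(q.features, p.features)

    def test_small_mask_keeps_fixed_ascending_order(self, rng):
        pats = self._patterns(rng)
        sel = np.zeros((6, 6, 6), bool)
        chosen = rng.choice(216, size=10, replace=False)
        sel.flat[np.sort(chosen)] = True
        out = extract_roi(pats, ROIMask(data=sel), None)
        assert out[0].features.shape == (10,)
        expected = pats[0].features[np.flatnonzero(sel.ravel())]
        assert np.allclose(out[0].features, expected)

    def test_warped_extraction_matches_volume_warp(self, rng):
        pats = self._patterns(rng)
        phi = PiecewiseAffineTransform((1, 1, 1), (-10, -10, -10),
                                       (10, 10, 10),
                                       a=np.eye(3)[None],
                                       t=np.array([[0.7, -0.4, 0.2]]))
        sel = np.zeros((6, 6, 6), bool)
        sel[2:4, 2:4, 2:4] = True
        mask = ROIMask(data=sel)
        out = extract_roi(pats, mask, phi)
        vol = ScalarVolume(data=pats[0].features.reshape(6, 6, 6),
                           affine=np.eye(4))
        warped = apply_transform_scalar(vol, phi, mask)
        assert np.allclose(out[0].features, warped.data[sel])

    def test_out_of_field_roi_errors(self, rng):
        pats = self._patterns(rng)
        phi = PiecewiseAffineTransform((1, 1, 1), (-100, -100, -100),
                                       (100, 100, 100),
                                       a=np.eye(3)[None],
                                       t=np.array([[50.0, 0, 0]]))
        sel = np.zeros((6, 6, 6), bool)
        sel[0, 0, 0] = True
        with pytest.raises(ValueError, match="empty intersection"):
            extract_roi(pats, ROIMask(data=sel), phi)


def _subject_patterns(rng, effect_voxel, n_voxels=30, n_trials=8, effect=3.0):
    pats = []
    for i in range(n_trials):
        label = 1 if i % 2 == 0 else -1
        f = rng.normal(size=n_voxels)
        f[effect_voxel] += label * effect
        pats.append(TrialPattern(features=f, label=label, subject_id=0,
                                 run_id=0))
    return pats


class TestSelectVoxels:
    def test_fraction_one_returns_mask_unchanged(self, rng):
        mask = ROIMask(data=np.ones((3, 2, 5), bool))
        refs = [_subject_patterns(rng, 4)]
        assert select_voxels(refs, mask, 1.0) is mask

    def test_strong_voxel_ranks_first(self):
        hits = 0
        for seed in range(100):
            rng = np.random.default_rng(seed)
            mask = ROIMask(data=np.ones((30, 1, 1), bool))
            refs = [_subject_patterns(rng, 7) for _ in range(3)]
            out = select_voxels(refs, mask, fraction=1 / 30)
            hits += bool(out.data.flat[7])
        assert hits >= 95

    def test_duplicating_a_reference_preserves_ranking(self, rng):
        mask = ROIMask(data=np.ones((30, 1, 1), bool))
        refs = [_subject_patterns(rng, 12)]
        single = select_voxels(refs, mask, 0.2)
        doubled = select_voxels(refs + refs, mask, 0.2)
        assert np.array_equal(single.data, doubled.data)

    def test_permutation_symmetry(self, rng):
        mask = ROIMask(data=np.ones((30, 1, 1), bool))
        refs = [_subject_patterns(np.random.default_rng(s), 3 + s)
                for s in range(3)]
        a = select_voxels(refs, mask, 0.3)
        b = select_voxels(refs[::-1], mask, 0.3)
        assert np.array_equal(a.data, b.data)

    def test_bad_fraction_rejected(self, rng):
        mask = ROIMask(data=np.ones((4, 1, 1), bool))
        refs = [_subject_patterns(rng, 0, n_voxels=4)]
        for frac in (0.0, -0.2, 1.5):
            with pytest.raises(ValueError):
                select_voxels(refs, mask, frac)


class TestPatternIO:
    def test_tsv_roundtrip(self, rng, tmp_path):
        from tensorxfer.fmri_prep import load_patterns, save_patterns
        pats = [TrialPattern(features=rng.normal(size=7),
                             label=1 if i % 2 == 0 else -1,
                             subject_id=i % 3, run_id=i % 2)
                for i in range(6)]
        save_patterns(pats, tmp_path / "pats.tsv")
        back = load_patterns(tmp_path / "pats.tsv")
        assert len(back) == 6
        for p, q in zip(pats, back):
            assert np.allclose(p.features, q.features)
            assert (p.label, p.subject_id, p.run_id) == \
                (q.label, q.subject_id, q.run_id)
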