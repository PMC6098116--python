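"""Linear-SVM decoders for attend-left vs attend-right trial patterns.

Three schemes:

* **conjunction** — one soft-margin linear SVM trained on all reference
  subjects' trials pooled in the common space, tested on the held-out target
  subject (leave-one-subject-out).
* **voting** — one SVM per reference subject; each casts a vote on every
  target trial and the majority wins.  An exact tie is scored as a
  mis-decoding regardless of the true label.
* **self** — a within-subject decoder evaluated by leave-one-run-out
  cross-validation.

All classifiers use a linear kernel with C = 1 and no feature scaling beyond
the per-run z-scores the preprocessing already applied.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.svm import SVC

from .fmri_prep import TrialPattern


@dataclass
class LinearClassifier:
    """Trained hyperplane: predicts sign(w . x + b)."""

    weights: np.ndarray
    bias: float
    training_set: str = ""

    def decision(self, x: np.ndarray) -> np.ndarray:
        return np.atleast_2d(x) @ self.weights + self.bias

    def predict(self, x: np.ndarray) -> np.ndarray:
        return np.where(self.decision(x) >= 0, 1, -1)


@dataclass
class DecodingResult:
    """Per-target accuracies (percent) plus per-trial records.

    ``trials`` columns: subject, fold, trial, true, predicted,
    decision_value.  ``predicted`` is 0 for an exact voting tie (always
    scored incorrect).
    """

    scheme: str
    per_subject: dict[int, float]
    trials: pd.DataFrame = field(default_factory=pd.DataFrame)

    @property
    def mean_accuracy(self) -> float:
        return float(np.mean(list(self.per_subject.values())))


def train_svm(x: np.ndarray, y: np.ndarray, c: float = 1.0) -> LinearClassifier:
    """Soft-margin linear SVM (hinge loss, L2 regularization)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=int)
    classes = np.unique(y)
    if classes.size < 2:
        raise ValueError("training labels contain a single class")
    svm = SVC(kernel="linear", C=c, tol=1e-6)
    svm.fit(x, y)
    w = svm.coef_.ravel()
    b = float(svm.intercept_[0])
    # sklearn orients the decision function toward the larger class label;
    # with labels {-1, +1} that is already "positive = attend-left"
    return LinearClassifier(weights=w, bias=b)


def _by_subject(patterns: Sequence[TrialPattern]) -> dict[int, list[TrialPattern]]:
    groups: dict[int, list[TrialPattern]] = {}
    for p in patterns:
        groups.setdefault(p.subject_id, []).append(p)
    return groups


def _xy(patterns: Sequence[TrialPattern]):
    return (np.array([p.features for p in patterns]),
            np.array([p.label for p in patterns]))


def _check_both_classes(groups: dict[int, list[TrialPattern]]) -> None:
    for sid, pats in groups.items():
        labs = {p.label for p in pats}
        if labs != {-1, 1}:
            raise ValueError(f"subject {sid} lacks one of the two classes")


def conjunction_decode(patterns: Sequence[TrialPattern],
                       target_subject: int | None = None,
                       c: float = 1.0) -> DecodingResult:
    """Pooled-training transfer decoder, leave-one-subject-out.

    With ``target_subject`` given, decodes that subject only; with ``None``
    every subject takes the target role in turn (the full LOSO table).
    """
    groups = _by_subject(patterns)
    _check_both_classes(groups)
    targets = sorted(groups) if target_subject is None else [target_subject]
    per_subject: dict[int, float] = {}
    rows = []
    for tgt in targets:
        if tgt not in groups:
            raise ValueError(f"no patterns for target subject {tgt}")
        refs = [p for sid, pats in groups.items() if sid != tgt for p in pats]
        if len({p.subject_id for p in refs}) < 2:
            raise ValueError("need >= 2 reference subjects")
        clf = train_svm(*_xy(refs), c=c)
        xt, yt = _xy(groups[tgt])
        dec = clf.decision(xt)
        pred = np.where(dec >= 0, 1, -1)
        per_subject[tgt] = float((pred == yt).mean() * 100)
        for i in range(len(yt)):
            rows.append((tgt, 0, i, int(yt[i]), int(pred[i]), float(dec[i])))
    trials = pd.DataFrame(rows, columns=["subject", "fold", "trial", "true",
                                         "predicted", "decision_value"])
    return DecodingResult(scheme="conjunction", per_subject=per_subject,
                          trials=trials)


def voting_decode(patterns: Sequence[TrialPattern],
                  target_subject: int | None = None,
                  c: float = 1.0) -> DecodingResult:
    """Majority vote of per-reference-subject SVMs; exact ties are misses."""
    groups = _by_subject(patterns)
    _check_both_classes(groups)
    # one classifier per subject, reused across target folds
    clfs = {sid: train_svm(*_xy(pats), c=c) for sid, pats in groups.items()}
    targets = sorted(groups) if target_subject is None else [target_subject]
    per_subject: dict[int, float] = {}
    rows = []
    for tgt in targets:
        if tgt not in groups:
            raise ValueError(f"no patterns for target subject {tgt}")
        ref_ids = [sid for sid in groups if sid != tgt]
        if len(ref_ids) < 2:
            raise ValueError("need >= 2 reference subjects")
        xt, yt = _xy(groups[tgt])
        votes = np.stack([clfs[sid].predict(xt) for sid in ref_ids])  # (R, n)
        tally = votes.sum(axis=0)
        pred = np.sign(tally).astype(int)  # 0 marks an exact tie
        correct = pred == yt  # a tie (0) never equals +/-1 -> incorrect
        per_subject[tgt] = float(correct.mean() * 100)
        for i in range(len(yt)):
            rows.append((tgt, 0, i, int(yt[i]), int(pred[i]),
                         float(tally[i])))
    trials = pd.DataFrame(rows, columns=["subject", "fold", "trial", "true",
                                         "predicted", "decision_value"])
    return DecodingResult(scheme="voting", per_subject=per_subject,
                          trials=trials)


def self_decode(patterns: Sequence[TrialPattern],
                c: float = 1.0) -> DecodingResult:
    """Within-subject leave-one-run-out cross-validation.

    Accuracy per subject is the mean over run folds; a fold whose training
    split lacks a class is skipped with a warning.
    """
    groups = _by_subject(patterns)
    per_subject: dict[int, float] = {}
    rows = []
    for sid, pats in sorted(groups.items()):
        runs = sorted({p.run_id for p in pats})
        if len(runs) < 2:
            raise ValueError(f"subject {sid} needs >= 2 runs for "
                             "leave-one-run-out")
        fold_accs = []
        for fold, run in enumerate(runs):
            train = [p for p in pats if p.run_id != run]
            test = [p for p in pats if p.run_id == run]
            ytr = {p.label for p in train}
            if ytr != {-1, 1}:
                warnings.warn(f"subject {sid}: fold holding out run {run} "
                              "has single-class training data; skipped",
                              RuntimeWarning, stacklevel=2)
                continue
            clf = train_svm(*_xy(train), c=c)
            xt, yt = _xy(test)
            dec = clf.decision(xt)
            pred = np.where(dec >= 0, 1, -1)
            fold_accs.append(float((pred == yt).mean() * 100))
            for i in range(len(yt)):
                rows.append((sid, fold, i, int(yt[i]), int(pred[i]),
                             float(dec[i])))
        if not fold_accs:
            raise ValueError(f"subject {sid}: no usable folds")
        per_subject[sid] = float(np.mean(fold_accs))
    trials = pd.DataFrame(rows, columns=["subject", "fold", "trial", "true",
                                         "predicted", "decision_value"])
    return DecodingResult(scheme="self", per_subject=per_subject, trials=trials)
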