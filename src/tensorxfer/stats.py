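"""Statistical comparisons for decoding accuracies and deformation features.

Contents: paired Wilcoxon signed-rank comparisons of decoder accuracies, a
jackknife test comparing the areas under two transfer-vs-self regression
lines, a surrogate (random-subset) test on mean pairwise distances between
subjects' deformation features, and a PCA embedding of those features.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as sps
from sklearn.decomposition import PCA


@dataclass
class PairedAccuracies:
    """Per-subject accuracy pairs (percent) for two methods."""

    method_a: np.ndarray
    method_b: np.ndarray
    subjects: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.method_a = np.asarray(self.method_a, dtype=float).ravel()
        self.method_b = np.asarray(self.method_b, dtype=float).ravel()
        if self.method_a.size != self.method_b.size:
            raise ValueError("paired accuracy arrays must have equal length")
        for arr in (self.method_a, self.method_b):
            if np.any((arr < 0) | (arr > 100)):
                raise ValueError("accuracies must lie in [0, 100]")


@dataclass
class ScatterData:
    """Per-subject (self-accuracy, transfer-accuracy) points for one method."""

    self_accuracy: np.ndarray
    transfer_accuracy: np.ndarray
    subjects: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.self_accuracy = np.asarray(self.self_accuracy, dtype=float).ravel()
        self.transfer_accuracy = np.asarray(self.transfer_accuracy,
                                            dtype=float).ravel()
        if self.self_accuracy.size != self.transfer_accuracy.size:
            raise ValueError("scatter arrays must have equal length")

    @property
    def n(self) -> int:
        return self.self_accuracy.size


@dataclass
class WilcoxonResult:
    p_two_sided: float
    p_greater: float
    n_nonzero: int
    all_zero: bool = False


@dataclass
class JackknifeAreaResult:
    """Signed leave-one-out area differences and the jackknife-t p-value."""

    estimate: float               # full-sample area difference (A - B)
    differences: np.ndarray       # leave-one-out area differences
    pseudovalues: np.ndarray
    t_statistic: float
    p_value: float                # one-sided: mean pseudovalue difference > 0


@dataclass
class SurrogateTestResult:
    observed: float
    surrogates: np.ndarray
    p_value: float
    n_surrogates: int


def wilcoxon_paired(pairs: PairedAccuracies) -> WilcoxonResult:
    """Paired Wilcoxon signed-rank test on accuracy differences.

    Zero differences are dropped; with n <= 25 remaining pairs the exact
    null distribution is used, the normal approximation above.  If every
    difference is zero the test is vacuous and p = 1 is returned with a
    flag.
    """
    d = pairs.method_a - pairs.method_b
    nz = d[d != 0]
    if nz.size == 0:
        return WilcoxonResult(p_two_sided=1.0, p_greater=1.0, n_nonzero=0,
                              all_zero=True)
    if nz.size < 6:
        raise ValueError("need >= 6 non-zero differences for the "
                         "signed-rank test")
    method = "exact" if nz.size <= 25 else "approx"
    p2 = sps.wilcoxon(nz, alternative="two-sided", method=method).pvalue
    pg = sps.wilcoxon(nz, alternative="greater", method=method).pvalue
    return WilcoxonResult(p_two_sided=float(p2), p_greater=float(pg),
                          n_nonzero=int(nz.size))


def _area_under_line(x: np.ndarray, y: np.ndarray) -> float:
    """Area under the OLS line of y on x over the observed x range."""
    if np.ptp(x) == 0:
        raise ValueError("degenerate x-range: all self-accuracies equal")
    slope, intercept = np.polyfit(x, y, 1)
    lo, hi = float(x.min()), float(x.max())
    return (intercept + slope * (lo + hi) / 2.0) * (hi - lo)


def jackknife_area_test(a: ScatterData, b: ScatterData) -> JackknifeAreaResult:
    """Jackknife comparison of areas under two transfer-vs-self regressions.

    For each left-out subject, OLS lines are fitted to the retained points
    of both datasets and integrated over each dataset's retained
    self-accuracy range; the statistic is the signed area difference
    (A - B).  The p-value is a one-sided t-test on the jackknife
    pseudovalues of the difference (mean > 0), with n - 1 degrees of
    freedom.  The raw leave-one-out differences are returned so other
    summaries can be applied.
    """
    n = a.n
    if b.n != n:
        raise ValueError("datasets must contain the same subjects")
    if n < 5:
        raise ValueError("need at least 5 subjects")
    full = (_area_under_line(a.self_accuracy, a.transfer_accuracy)
            - _area_under_line(b.self_accuracy, b.transfer_accuracy))
    keep = np.ones(n, dtype=bool)
    diffs = np.empty(n)
    for i in range(n):
        keep[i] = False
        diffs[i] = (_area_under_line(a.self_accuracy[keep],
                                     a.transfer_accuracy[keep])
                    - _area_under_line(b.self_accuracy[keep],
                                       b.transfer_accuracy[keep]))
        keep[i] = True
    pseudo = n * full - (n - 1) * diffs
    mean = pseudo.mean()
    sd = pseudo.std(ddof=1)
    if sd == 0:
        t = np.inf if mean > 0 else (-np.inf if mean < 0 else 0.0)
        p = 0.0 if mean > 0 else (1.0 if mean < 0 else 0.5)
    else:
        t = mean / (sd / np.sqrt(n))
        p = float(sps.t.sf(t, df=n - 1))
    return JackknifeAreaResult(estimate=float(full), differences=diffs,
                               pseudovalues=pseudo, t_statistic=float(t),
                               p_value=float(p))


def surrogate_distance_test(features: np.ndarray, selected,
                            n_surrogates: int = 10_000,
                            seed: int = 0) -> SurrogateTestResult:
    """Are the selected subjects unusually close in feature space?

    The statistic is the mean pairwise Euclidean distance among the
    selected subjects (in the original feature space); surrogates repeat it
    on uniformly drawn subsets of the same size.  Small distances are
    significant: p = (1 + #{surrogate <= observed}) / (1 + n_surrogates).
    """
    features = np.atleast_2d(np.asarray(features, dtype=float))
    selected = np.asarray(selected, dtype=int)
    n_subjects = features.shape[0]
    k = selected.size
    if k < 2:
        raise ValueError("need at least 2 selected subjects")
    if k > n_subjects:
        raise ValueError("subset size exceeds the number of subjects")
    if n_surrogates < 99:
        raise ValueError("need at least 99 surrogates")

    def mean_pairwise(idx: np.ndarray) -> float:
        sub = features[idx]
        d = np.sqrt(((sub[:, None, :] - sub[None, :, :]) ** 2).sum(-1))
        iu = np.triu_indices(len(idx), k=1)
        return float(d[iu].mean())

    observed = mean_pairwise(selected)
    rng = np.random.default_rng(seed)
    surr = np.array([mean_pairwise(rng.choice(n_subjects, size=k,
                                              replace=False))
                     for _ in range(n_surrogates)])
    p = (1 + int((surr <= observed).sum())) / (1 + n_surrogates)
    return SurrogateTestResult(observed=observed, surrogates=surr,
                               p_value=float(p), n_surrogates=n_surrogates)


def pca_embed(features: np.ndarray, k: int = 3):
    """Mean-centred PCA of subject-by-parcel features.

    Returns ``(coordinates, explained_variance_ratios)``; components are
    ordered by decreasing variance and each is signed so its
    largest-magnitude loading is positive.
    """
    features = np.atleast_2d(np.asarray(features, dtype=float))
    n = features.shape[0]
    if n < k + 1:
        raise ValueError("need at least k + 1 subjects")
    centered = features - features.mean(axis=0)
    if k > np.linalg.matrix_rank(centered):
        raise ValueError("k exceeds the rank of the centred feature matrix")
    pca = PCA(n_components=k, svd_solver="full")
    coords = pca.fit_transform(centered)
    comps = pca.components_
    for j in range(k):
        lead = comps[j, np.argmax(np.abs(comps[j]))]
        if lead < 0:
            comps[j] *= -1
            coords[:, j] *= -1
    return coords, pca.explained_variance_ratio_


def correlation(x: np.ndarray, y: np.ndarray):
    """Convenience Pearson r and two-sided p for scatter summaries."""
    r, p = sps.pearsonr(np.asarray(x, float).ravel(),
                        np.asarray(y, float).ravel())
    return float(r), float(p)
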