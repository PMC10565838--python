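"""Cross-validated decoding paradigms and accuracy-timecourse statistics.

Three per-timepoint paradigms share one protocol (stratified k-fold linear
maximum-margin classifier, per-fold feature standardisation, folds shared
across timepoints so timecourses are comparable):

* **instantaneous** — raw multichannel values at each timepoint (P features);
* **narrowband** — real STFT coefficients of one band (P features);
* **complex** — real and imaginary coefficients of one band (2P features).

An **aggregate** classifier stacks the per-band complex decoders' decision
values with a random-forest ensemble in a nested cross-validation, capturing
information that is complementary across frequency bands.

Spectral structure in accuracy timecourses (frequency doubling, aliasing) is
read off with :func:`accuracy_psd`; differences between paradigms across
subjects or seeds are tested with a sign-flip cluster permutation test.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from scipy.signal import periodogram
from sklearn.ensemble import RandomForestClassifier
from sklearn.model_selection import StratifiedKFold
from sklearn.preprocessing import StandardScaler
from sklearn.svm import LinearSVC

from .evoked_model import TrialDataset
from .spectral import (
    SpectralFeatures,
    band_complex_features,
    band_real_features,
    stft_epochs,
)

__all__ = [
    "DecodingResult",
    "PairwiseDecodingResult",
    "ClusterTestResult",
    "decode_instantaneous",
    "decode_narrowband",
    "decode_complex",
    "decode_aggregate",
    "pairwise_decode",
    "accuracy_psd",
    "cluster_permutation_test",
]

# fixed unit regularisation; the protocol deliberately does no tuning
_SVC_KWARGS = dict(C=1.0, dual="auto", max_iter=20_000, random_state=0)


@dataclass
class DecodingResult:
    """Cross-validated accuracy per timepoint with CV provenance."""

    accuracy: np.ndarray
    time_s: np.ndarray
    paradigm: str
    n_folds: int
    seed: int
    classifier: str
    per_fold: np.ndarray
    band_hz: float | None = None

    def __post_init__(self) -> None:
        self.accuracy = np.asarray(self.accuracy, dtype=float)
        if np.any(self.accuracy < 0) or np.any(self.accuracy > 1):
            raise ValueError("accuracies must lie in [0, 1]")

    @property
    def mean_accuracy(self) -> float:
        return float(self.accuracy.mean())


@dataclass
class PairwiseDecodingResult:
    """Per-pair results of a mass pairwise classification run."""

    pairs: dict[tuple, DecodingResult]
    skipped: list[tuple] = field(default_factory=list)

    @property
    def mean_accuracy(self) -> np.ndarray:
        """Mean accuracy timecourse over all decoded pairs."""
        return np.mean([r.accuracy for r in self.pairs.values()], axis=0)


@dataclass
class ClusterTestResult:
    cluster_spans: list[tuple[float, float]]
    cluster_masses: list[float]
    p_values: list[float]
    n_permutations: int
    threshold: float


def _check_labels(y: np.ndarray, n_folds: int) -> None:
    vals, counts = np.unique(y, return_counts=True)
    if len(vals) < 2:
        raise ValueError("decoding requires two classes in the labels")
    if counts.min() < n_folds:
        raise ValueError(
            f"need at least {n_folds} trials per class for {n_folds}-fold CV"
        )


def _cv_decode(X: np.ndarray, y: np.ndarray, n_folds: int, seed: int):
    """Shared protocol: per-timepoint accuracy for each stratified fold.

    X is (trials, features, time); the fold structure is computed once and
    reused at every timepoint.
    """
    _check_labels(y, n_folds)
    skf = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed)
    splits = list(skf.split(np.zeros(len(y)), y))
    n_time = X.shape[2]
    per_fold = np.zeros((n_folds, n_time))
    for k, (tr, te) in enumerate(splits):
        for ti in range(n_time):
            scaler = StandardScaler().fit(X[tr, :, ti])
            clf = LinearSVC(**_SVC_KWARGS).fit(scaler.transform(X[tr, :, ti]), y[tr])
            per_fold[k, ti] = clf.score(scaler.transform(X[te, :, ti]), y[te])
    return per_fold


def decode_instantaneous(
    dataset: TrialDataset, n_folds: int = 3, seed: int = 0
) -> DecodingResult:
    """Per-timepoint decoding of the raw broadband multichannel signal."""
    per_fold = _cv_decode(dataset.data, dataset.labels, n_folds, seed)
    return DecodingResult(
        accuracy=per_fold.mean(axis=0),
        time_s=dataset.time_s,
        paradigm="instantaneous",
        n_folds=n_folds,
        seed=seed,
        classifier="linear_svm",
        per_fold=per_fold,
    )


def decode_narrowband(
    features: SpectralFeatures, band_hz: float, n_folds: int = 3, seed: int = 0,
    labels: np.ndarray | None = None,
) -> DecodingResult:
    """Decoding on the real coefficients of one band (P features)."""
    y = _feature_labels(features, labels)
    per_fold = _cv_decode(band_real_features(features, band_hz), y, n_folds, seed)
    return DecodingResult(
        accuracy=per_fold.mean(axis=0), time_s=features.time_s,
        paradigm="narrowband", n_folds=n_folds, seed=seed,
        classifier="linear_svm", per_fold=per_fold, band_hz=float(band_hz),
    )


def decode_complex(
    features: SpectralFeatures, band_hz: float, n_folds: int = 3, seed: int = 0,
    labels: np.ndarray | None = None,
) -> DecodingResult:
    """Decoding on real and imaginary coefficients of one band (2P features)."""
    y = _feature_labels(features, labels)
    per_fold = _cv_decode(band_complex_features(features, band_hz), y, n_folds, seed)
    return DecodingResult(
        accuracy=per_fold.mean(axis=0), time_s=features.time_s,
        paradigm="complex", n_folds=n_folds, seed=seed,
        classifier="linear_svm", per_fold=per_fold, band_hz=float(band_hz),
    )


def _feature_labels(features: SpectralFeatures, labels) -> np.ndarray:
    if labels is None:
        raise ValueError(
            "labels must be supplied alongside SpectralFeatures for decoding"
        )
    y = np.asarray(labels)
    if y.shape != (features.n_trials,):
        raise ValueError("labels length does not match feature trials")
    return y


def _band_decision_values(
    X: np.ndarray, y: np.ndarray, tr: np.ndarray, te: np.ndarray,
    inner_folds: int, seed: int,
):
    """Out-of-sample decision values for the training set (inner CV) and for
    the test set (classifier trained on the full training set)."""
    dv_tr = np.zeros(len(tr))
    skf = StratifiedKFold(n_splits=inner_folds, shuffle=True, random_state=seed)
    for itr, ite in skf.split(np.zeros(len(tr)), y[tr]):
        scaler = StandardScaler().fit(X[tr[itr]])
        clf = LinearSVC(**_SVC_KWARGS).fit(scaler.transform(X[tr[itr]]), y[tr[itr]])
        dv_tr[ite] = clf.decision_function(scaler.transform(X[tr[ite]]))
    scaler = StandardScaler().fit(X[tr])
    clf = LinearSVC(**_SVC_KWARGS).fit(scaler.transform(X[tr]), y[tr])
    dv_te = clf.decision_function(scaler.transform(X[te]))
    return dv_tr, dv_te


def decode_aggregate(
    features: SpectralFeatures,
    labels: np.ndarray,
    n_folds_outer: int = 2,
    n_trees: int = 100,
    n_repeats: int = 10,
    seed: int = 0,
    inner_folds: int = 3,
    time_indices: np.ndarray | None = None,
) -> DecodingResult:
    """Aggregate cross-frequency classifier (nested cross-validation).

    Inner loop: per-band complex decoders produce per-trial decision values
    (signed distances to the hyperplane).  Outer loop: a random forest with
    ``n_trees`` trees predicts the label from the vector of band decision
    values, under ``n_folds_outer``-fold CV; the outer loop is repeated
    ``n_repeats`` times on bootstrap-resampled trial sets and accuracies are
    averaged.  ``time_indices`` restricts the (expensive) computation to a
    subset of timepoints.
    """
    y_all = _feature_labels(features, labels)
    t_idx = (np.arange(len(features.time_s)) if time_indices is None
             else np.asarray(time_indices, dtype=int))
    bands = features.band_hz
    rng = np.random.default_rng(seed)

    acc = np.zeros((n_repeats, len(t_idx)))
    n = features.n_trials
    for rep in range(n_repeats):
        boot = np.sort(rng.choice(n, size=n, replace=True))
        y = y_all[boot]
        if len(np.unique(y)) < 2:  # extremely unlikely; redraw deterministically
            boot = np.arange(n)
            y = y_all
        skf = StratifiedKFold(
            n_splits=n_folds_outer, shuffle=True, random_state=seed + rep
        )
        splits = list(skf.split(np.zeros(len(y)), y))
        for j, ti in enumerate(t_idx):
            fold_acc = []
            for tr, te in splits:
                meta_tr = np.zeros((len(tr), len(bands)))
                meta_te = np.zeros((len(te), len(bands)))
                for bi, b in enumerate(bands):
                    Xb = band_complex_features(features, b)[boot][:, :, ti]
                    meta_tr[:, bi], meta_te[:, bi] = _band_decision_values(
                        Xb, y, tr, te, inner_folds, seed + rep
                    )
                rf = RandomForestClassifier(
                    n_estimators=n_trees, random_state=seed + rep
                ).fit(meta_tr, y[tr])
                fold_acc.append(rf.score(meta_te, y[te]))
            acc[rep, j] = np.mean(fold_acc)

    return DecodingResult(
        accuracy=acc.mean(axis=0), time_s=features.time_s[t_idx],
        paradigm="aggregate", n_folds=n_folds_outer, seed=seed,
        classifier="complex_svm+random_forest", per_fold=acc,
    )


def pairwise_decode(
    data: np.ndarray,
    labels: np.ndarray,
    sample_rate_hz: float,
    time_s: np.ndarray,
    paradigm: str = "instantaneous",
    n_folds: int = 3,
    seed: int = 0,
    band_hz: float | None = None,
    window_ms: float = 100.0,
) -> PairwiseDecodingResult:
    """Mass pairwise classification over every pair of condition labels.

    ``labels`` may take any number of distinct values; each pair is mapped to
    a binary +1/-1 problem and decoded with the chosen paradigm.  Pairs with
    too few trials are skipped with a warning and recorded.
    """
    labels = np.asarray(labels)
    conds = sorted(np.unique(labels).tolist())
    if len(conds) < 2:
        raise ValueError("pairwise decoding requires at least two conditions")

    results: dict[tuple, DecodingResult] = {}
    skipped: list[tuple] = []
    for a, b in itertools.combinations(conds, 2):
        mask = np.isin(labels, (a, b))
        y = np.where(labels[mask] == a, 1, -1)
        if min((y == 1).sum(), (y == -1).sum()) < n_folds:
            warnings.warn(f"skipping pair {(a, b)}: insufficient trials")
            skipped.append((a, b))
            continue
        ds = TrialDataset(
            data=data[mask], labels=y, sample_rate_hz=sample_rate_hz, time_s=time_s
        )
        if paradigm == "instantaneous":
            results[(a, b)] = decode_instantaneous(ds, n_folds=n_folds, seed=seed)
        elif paradigm in ("narrowband", "complex"):
            if band_hz is None:
                raise ValueError(f"paradigm {paradigm!r} requires band_hz")
            feats = stft_epochs(ds, window_ms=window_ms)
            fn = decode_narrowband if paradigm == "narrowband" else decode_complex
            results[(a, b)] = fn(
                feats, band_hz, n_folds=n_folds, seed=seed, labels=y
            )
        else:
            raise ValueError(f"unknown paradigm {paradigm!r}")
    return PairwiseDecodingResult(pairs=results, skipped=skipped)


def accuracy_psd(result: DecodingResult):
    """Power spectral density of the mean-removed accuracy timecourse.

    Exposes frequency-doubled harmonics and representational-alias peaks.
    Returns ``(freqs_hz, power)``.
    """
    acc = np.asarray(result.accuracy, dtype=float)
    if acc.size < 8:
        raise ValueError("need at least 8 timepoints for a PSD")
    dt = np.diff(result.time_s)
    fs = 1.0 / float(np.mean(dt))
    return periodogram(acc, fs=fs, detrend="constant", window="boxcar")


# ---------------------------------------------------------------------------
# cluster-based permutation statistics

def _cluster_masses(t_vals: np.ndarray, threshold: float):
    """Contiguous runs of |t| > threshold with sign-consistent membership."""
    spans, masses = [], []
    for sign in (1.0, -1.0):
        mask = sign * t_vals > threshold
        if not mask.any():
            continue
        padded = np.concatenate([[False], mask, [False]])
        edges = np.flatnonzero(np.diff(padded))
        for start, stop in zip(edges[::2], edges[1::2]):
            spans.append((int(start), int(stop)))
            masses.append(float(t_vals[start:stop].sum()))
    return spans, masses


def cluster_permutation_test(
    cond_a: np.ndarray,
    cond_b: np.ndarray,
    n_permutations: int = 1000,
    cluster_alpha: float = 0.05,
    seed: int = 0,
    time_s: np.ndarray | None = None,
) -> ClusterTestResult:
    """Paired sign-flip cluster permutation test on per-unit timecourses.

    ``cond_a`` and ``cond_b`` are (units, time) arrays of paired measurements
    (units = subjects or simulation seeds).  A paired-difference t statistic
    is computed per timepoint; clusters are contiguous runs where |t| exceeds
    the two-sided t threshold at ``cluster_alpha``; cluster mass is the summed
    t.  The null distribution of the maximum |mass| is built by randomly
    flipping the sign of each unit's difference;
    ``p = (1 + #{perm >= observed}) / (n_permutations + 1)``.
    """
    a = np.atleast_2d(np.asarray(cond_a, dtype=float))
    b = np.atleast_2d(np.asarray(cond_b, dtype=float))
    if a.shape != b.shape:
        raise ValueError("condition arrays must have matching (units, time) shapes")
    n_units, n_time = a.shape
    if n_units < 5:
        raise ValueError("need at least 5 paired units")
    if n_permutations < 500:
        raise ValueError("need at least 500 permutations")

    d = a - b
    threshold = float(stats.t.ppf(1.0 - cluster_alpha / 2.0, df=n_units - 1))

    sumsq = (d ** 2).sum(axis=0)

    def t_stats(means: np.ndarray) -> np.ndarray:
        # means: (..., time); sum of squares is sign-flip invariant
        var = (sumsq - n_units * means ** 2) / (n_units - 1)
        var = np.maximum(var, 1e-300)
        return means / np.sqrt(var / n_units)

    t_obs = t_stats(d.mean(axis=0))
    spans, masses = _cluster_masses(t_obs, threshold)

    rng = np.random.default_rng(seed)
    signs = rng.choice((-1.0, 1.0), size=(n_permutations, n_units))
    perm_means = signs @ d / n_units
    perm_t = t_stats(perm_means)
    max_mass = np.zeros(n_permutations)
    for i in range(n_permutations):
        _, pm = _cluster_masses(perm_t[i], threshold)
        if pm:
            max_mass[i] = max(abs(m) for m in pm)

    p_values = [
        float((1 + np.sum(max_mass >= abs(m))) / (n_permutations + 1)) for m in masses
    ]
    if time_s is not None:
        time_s = np.asarray(time_s, dtype=float)
        spans_out = [(float(time_s[s]), float(time_s[e - 1])) for s, e in spans]
    else:
        spans_out = [(float(s), float(e)) for s, e in spans]
    return ClusterTestResult(
        cluster_spans=spans_out,
        cluster_masses=masses,
        p_values=p_values,
        n_permutations=int(n_permutations),
        threshold=threshold,
    )
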