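"""Decode lick phase (pre-sound vs post-sound) from population activity.

Features are the mean deconvolved rates in the 330 ms window starting
165 ms before each isolated lick, per cell (optionally restricted to one
functional group, optionally augmented with session-level behavioral
covariates).  Because post-sound licks outnumber pre-sound licks in trained
animals, the minority class is balanced by SMOTE-style oversampling
(synthetic samples on segments from minority points toward their nearest
minority neighbors).  Dimensionality is reduced to the principal components
explaining 80% of the variance, an RBF-kernel SVM is trained and accuracy
is estimated by stratified 10-fold cross-validation; a shuffled-label
control repeats the identical procedure.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from sklearn.decomposition import PCA
from sklearn.model_selection import StratifiedKFold
from sklearn.neighbors import NearestNeighbors
from sklearn.svm import SVC

from .core_io import POST_SOUND, PRE_SOUND, AnalysisWindows, SessionRecording
from .cell_classification import CellClassSet, LickAnchors, event_window_means

__all__ = ["DecodeDesign", "DecodeResult", "build_design",
           "oversample_minority", "decode", "group_comparison"]

ALL_CELLS = "ALL_CELLS"


@dataclass
class DecodeDesign:
    """Feature matrix (licks x features) with PRE/POST labels."""

    X: np.ndarray
    y: np.ndarray                  # PRE_SOUND / POST_SOUND per row
    feature_set: str = ALL_CELLS
    session_index: int = -1
    bin_index: int = 0

    @property
    def n(self) -> int:
        return len(self.y)

    def class_counts(self) -> dict[str, int]:
        vals, counts = np.unique(self.y, return_counts=True)
        return dict(zip(vals.tolist(), counts.tolist()))


@dataclass
class DecodeResult:
    """Cross-validated accuracy distribution with its shuffled control."""

    accuracy: np.ndarray
    shuffled: np.ndarray
    feature_set: str = ALL_CELLS
    bin_index: int = 0
    n_components: int = 0
    hyperparams: dict = field(default_factory=dict)

    @property
    def mean_accuracy(self) -> float:
        return float(np.mean(self.accuracy))


# ---------------------------------------------------------------------------
# Design construction
# ---------------------------------------------------------------------------

def build_design(
    session: SessionRecording,
    anchors: LickAnchors,
    classes: CellClassSet | None = None,
    feature_set: str = ALL_CELLS,
    windows: AnalysisWindows | None = None,
    covariates: dict[str, float] | None = None,
) -> DecodeDesign | None:
    """One row per isolated lick; features are during-window cell means.

    ``feature_set`` restricts columns to one functional group's cells
    (requires ``classes``); ``covariates`` are session-level scalars
    (e.g. lick probability, modulated-cell proportion) broadcast to every
    row.  Returns ``None`` when either phase has no anchors — such a
    session cannot contribute a within-session decoder.
    """
    w = windows or AnalysisWindows()
    times = anchors.times
    context = anchors.context
    if not (np.any(context == PRE_SOUND) and np.any(context == POST_SOUND)):
        return None
    means, used = event_window_means(session.activity, times, w.during,
                                     session.frame_rate)
    labels = context[used]
    if feature_set != ALL_CELLS:
        if classes is None:
            raise ValueError("feature_set restriction requires classes")
        mask = classes.mask(feature_set) & classes.included
        means = means[:, mask]
    elif classes is not None:
        means = means[:, classes.included]
    if means.shape[1] == 0:
        return None
    if covariates:
        extra = np.tile(np.array(list(covariates.values()), dtype=float),
                        (means.shape[0], 1))
        means = np.hstack([means, extra])
    if not (np.any(labels == PRE_SOUND) and np.any(labels == POST_SOUND)):
        return None
    return DecodeDesign(X=means, y=labels, feature_set=feature_set,
                        session_index=session.session_index,
                        bin_index=session.bin_index)


# ---------------------------------------------------------------------------
# Minority oversampling (SMOTE-style)
# ---------------------------------------------------------------------------

def oversample_minority(
    X: np.ndarray,
    y: np.ndarray,
    rng: np.random.Generator | None = None,
    k: int = 5,
) -> tuple[np.ndarray, np.ndarray]:
    """Balance classes by synthesizing minority samples.

    Each synthetic sample is ``x_i + u * (x_nn - x_i)`` with
    ``u ~ Uniform(0, 1)`` and ``x_nn`` one of the ``min(k, n_min - 1)``
    nearest minority neighbors of a random minority point.  Majority rows
    are never altered; originals are preserved.  A minority class of one
    falls back to duplication with small jitter.
    """
    rng = rng if rng is not None else np.random.default_rng(0)
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    vals, counts = np.unique(y, return_counts=True)
    if len(vals) != 2:
        raise ValueError("oversampling expects exactly two classes")
    order = np.argsort(counts)
    minority, majority = vals[order[0]], vals[order[1]]
    n_min, n_maj = counts[order[0]], counts[order[1]]
    deficit = int(n_maj - n_min)
    if deficit == 0:
        return X, y
    Xm = X[y == minority]
    if n_min == 1:
        scale = 1e-6 * (np.abs(Xm).max() + 1.0)
        synth = Xm[np.zeros(deficit, dtype=int)] + \
            scale * rng.standard_normal((deficit, X.shape[1]))
    else:
        k_eff = min(k, n_min - 1)
        nn = NearestNeighbors(n_neighbors=k_eff + 1).fit(Xm)
        _, idx = nn.kneighbors(Xm)
        base = rng.integers(0, n_min, size=deficit)
        pick = rng.integers(1, k_eff + 1, size=deficit)   # skip self (col 0)
        neigh = Xm[idx[base, pick]]
        u = rng.uniform(0.0, 1.0, size=(deficit, 1))
        synth = Xm[base] + u * (neigh - Xm[base])
    X_out = np.vstack([X, synth])
    y_out = np.concatenate([y, np.full(deficit, minority, dtype=y.dtype)])
    return X_out, y_out


# ---------------------------------------------------------------------------
# Decoding
# ---------------------------------------------------------------------------

def _fit_accuracy(
    X: np.ndarray, y: np.ndarray, folds: int, variance_frac: float,
    rng: np.random.Generator, per_fold: bool, oversample: bool,
) -> tuple[float, int]:
    """One stratified k-fold accuracy (= 1 - misclassification rate).

    With ``per_fold`` both the oversampling and the PCA are fit on each
    training fold only (leakage-safe) and the score is the balanced
    accuracy (mean per-class recall) over the held-out original rows, so
    class imbalance cannot recenter the chance level.  Without it, both
    steps were already applied to the full (balanced) design by the caller
    and the plain misclassification rate is used.
    """
    from sklearn.metrics import balanced_accuracy_score

    y_arr = np.asarray(y)
    y_bin = (y_arr == POST_SOUND).astype(int) if y_arr.dtype == object else y_arr
    n_splits = min(folds, int(np.bincount(y_bin).min()))
    if n_splits < 2:
        raise ValueError("not enough samples per class for cross-validation")
    skf = StratifiedKFold(n_splits=n_splits, shuffle=True,
                          random_state=int(rng.integers(2**31 - 1)))
    n_comp = 0
    if not per_fold:
        X, n_comp = _pca_reduce(X, variance_frac)
    preds = np.empty_like(y_bin)
    for train, test in skf.split(X, y_bin):
        Xtr, ytr = X[train], y_bin[train]
        Xte = X[test]
        if per_fold:
            if oversample and len(np.unique(ytr)) == 2:
                Xtr, ytr = oversample_minority(Xtr, ytr, rng)
            pca = PCA(n_components=_n_components(Xtr, variance_frac),
                      svd_solver="full").fit(Xtr)
            Xtr, Xte = pca.transform(Xtr), pca.transform(Xte)
            n_comp = max(n_comp, pca.n_components_)
        clf = SVC(kernel="rbf", C=1.0, gamma="scale")
        clf.fit(Xtr, ytr)
        preds[test] = clf.predict(Xte)
    if per_fold:
        return float(balanced_accuracy_score(y_bin, preds)), n_comp
    return float(np.mean(preds == y_bin)), n_comp


def _n_components(X: np.ndarray, variance_frac: float) -> int:
    full = PCA(svd_solver="full").fit(X)
    cum = np.cumsum(full.explained_variance_ratio_)
    return int(np.searchsorted(cum, variance_frac - 1e-12) + 1)


def _pca_reduce(X: np.ndarray, variance_frac: float) -> tuple[np.ndarray, int]:
    """Project onto the fewest leading PCs reaching the variance fraction."""
    k = _n_components(X, variance_frac)
    pca = PCA(n_components=k, svd_solver="full")
    return pca.fit_transform(X), k


def decode(
    design: DecodeDesign,
    reps: int = 1,
    folds: int = 10,
    variance_frac: float = 0.80,
    rng: np.random.Generator | None = None,
    oversample: bool = True,
    per_fold: bool = False,
    shuffled_reps: int | None = None,
) -> DecodeResult:
    """Cross-validated phase decoding with a shuffled-label control.

    The default order is — oversample, PCA on the full
    design, then stratified k-fold CV.  ``per_fold=True`` switches to a
    leakage-safe variant that refits the oversampler and PCA inside each
    training fold; the default order is optimistically biased at small
    sample sizes (synthetic minority points leak across folds), so
    calibration checks and cross-condition comparisons use the per-fold
    variant.  ``reps`` repeats the procedure with fresh CV splits (and
    oversampling draws) to build an accuracy distribution.
    """
    rng = rng if rng is not None else np.random.default_rng(0)
    shuffled_reps = reps if shuffled_reps is None else shuffled_reps
    acc, n_comp = [], 0
    for _ in range(reps):
        X, y = design.X, design.y
        if oversample and not per_fold:
            X, y = oversample_minority(X, y, rng)
        a, k = _fit_accuracy(X, y, folds, variance_frac, rng, per_fold,
                             oversample)
        acc.append(a)
        n_comp = max(n_comp, k)
    shuf = []
    for _ in range(shuffled_reps):
        X, y = design.X, rng.permutation(design.y)
        if oversample and not per_fold:
            X, y = oversample_minority(X, y, rng)
        a, _ = _fit_accuracy(X, y, folds, variance_frac, rng, per_fold,
                             oversample)
        shuf.append(a)
    return DecodeResult(
        accuracy=np.asarray(acc), shuffled=np.asarray(shuf),
        feature_set=design.feature_set, bin_index=design.bin_index,
        n_components=n_comp,
        hyperparams={"C": 1.0, "kernel": "rbf", "gamma": "scale",
                     "folds": folds, "variance_frac": variance_frac,
                     "oversample": oversample, "per_fold": per_fold},
    )


def group_comparison(
    result_a: DecodeResult,
    result_b: DecodeResult,
    n_permutations: int = 5000,
    rng: np.random.Generator | None = None,
) -> float:
    """Two-sample permutation p-value for mean accuracy difference (a > b).

    Unequal repetition counts are resampled down to the common count.
    """
    rng = rng if rng is not None else np.random.default_rng(0)
    a = np.asarray(result_a.accuracy, dtype=float)
    b = np.asarray(result_b.accuracy, dtype=float)
    n = min(len(a), len(b))
    if len(a) != len(b):
        a = rng.choice(a, size=n, replace=False)
        b = rng.choice(b, size=n, replace=False)
    obs = a.mean() - b.mean()
    pooled = np.concatenate([a, b])
    count = 0
    for _ in range(n_permutations):
        perm = rng.permutation(pooled)
        if perm[:n].mean() - perm[n:].mean() >= obs:
            count += 1
    return (1 + count) / (n_permutations + 1)
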