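"""Kernel-weight estimation by inner cross-validation.

Each channel kernel is scored on the training partition alone: a
single-kernel one-vs-one SVM is trained and tested across cvK folds, the K
test-fold predictions are pooled into one confusion matrix, and the channel's
score is its overall sensitivity times its aggregate multiclass MCC. The
scores, clamped at zero, normalize into the fusion weights. The scheme is
linear in the number of channels — one kernel in memory at a time — unlike
semidefinite-programming weight optimization.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from sklearn.svm import SVC

from gotlm.features import CHANNELS
from gotlm.kernels import KernelWeights
from gotlm.metrics import ConfusionMatrix, confusion_matrix, multiclass_mcc, overall_se


@dataclass(frozen=True)
class ChannelScore:
    """One channel's inner-CV sensitivity, MCC, and their (clamped) product."""

    channel: str
    se: float
    mcc: float

    @property
    def product(self) -> float:
        return max(0.0, self.se * self.mcc)


def kfold_split(n: int, K: int, seed: int) -> np.ndarray:
    """Fold index per example: K disjoint parts of equal size, remainder to the last.

    The examples are permuted by ``seed`` and cut into contiguous blocks of
    floor(n/K); the last fold absorbs the n mod K leftover examples (for
    K = 5 that is 1-4 extra). Deterministic given (n, K, seed).
    """
    if K < 2:
        raise ValueError(f"need at least 2 folds, got {K}")
    if n < K:
        raise ValueError(f"cannot split {n} examples into {K} folds")
    rng = np.random.default_rng(seed)
    order = rng.permutation(n)
    base = n // K
    folds = np.empty(n, dtype=int)
    for k in range(K):
        start = k * base
        stop = (k + 1) * base if k < K - 1 else n
        folds[order[start:stop]] = k
    return folds


def _fit_predict_fold(
    kernel: np.ndarray,
    y: np.ndarray,
    train_idx: np.ndarray,
    test_idx: np.ndarray,
    C: float,
) -> np.ndarray:
    """Train a precomputed-kernel one-vs-one SVM on one fold, predict the other."""
    y_train = y[train_idx]
    if len(np.unique(y_train)) < 2:
        # degenerate single-class training fold: predict the sole class
        return np.full(len(test_idx), y_train[0])
    svm = SVC(kernel="precomputed", C=C)
    svm.fit(kernel[np.ix_(train_idx, train_idx)], y_train)
    return svm.predict(kernel[np.ix_(test_idx, train_idx)])


def cv_confusion(
    kernel: np.ndarray,
    labels: Sequence[str],
    classes: Sequence[str],
    folds: np.ndarray,
    C: float,
) -> ConfusionMatrix:
    """Pooled confusion matrix over all test folds of one kernel's CV."""
    y = np.asarray(labels, dtype=object)
    n = len(y)
    if kernel.shape != (n, n):
        raise ValueError(f"kernel shape {kernel.shape} does not match {n} labels")
    y_pred = np.empty(n, dtype=object)
    for k in np.unique(folds):
        test_idx = np.flatnonzero(folds == k)
        train_idx = np.flatnonzero(folds != k)
        y_pred[test_idx] = _fit_predict_fold(kernel, y, train_idx, test_idx, C)
    return confusion_matrix(list(y), list(y_pred), classes)


def score_channel(
    kernel: np.ndarray,
    labels: Sequence[str],
    classes: Sequence[str],
    cvK: int,
    C: float,
    seed: int,
    channel: str = "fused",
) -> ChannelScore:
    """Score one channel kernel by cvK-fold CV: SE and aggregate MCC of the pooled confusion."""
    folds = kfold_split(len(labels), cvK, seed)
    M = cv_confusion(kernel, labels, classes, folds, C)
    return ChannelScore(channel=channel, se=overall_se(M), mcc=multiclass_mcc(M))


def estimate_weights(
    kernels: Mapping[str, np.ndarray],
    labels: Sequence[str],
    classes: Sequence[str],
    cvK: int,
    C: float,
    seed: int,
) -> tuple[KernelWeights, dict[str, ChannelScore]]:
    """Estimate fusion weights w_e = SE_e * MCC_e / sum_c SE_c * MCC_c.

    ``kernels`` maps channel names to square train kernels aligned with
    ``labels``; channels absent from the map receive weight 0 (ablation).
    All channels share the same fold assignment, so identical kernels get
    identical scores. Returns the weights and the per-channel scores.
    """
    scores: dict[str, ChannelScore] = {}
    for name in CHANNELS:
        if name not in kernels:
            continue
        scores[name] = score_channel(
            kernels[name], labels, classes, cvK, C, seed, channel=name
        )
    if not scores:
        raise ValueError("no channel kernels provided")
    weights = KernelWeights.from_products(
        {name: sc.product for name, sc in scores.items()}
    )
    return weights, scores
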