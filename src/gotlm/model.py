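"""End-to-end training, prediction, and the outer evaluation protocols.

Training grid-searches (cvK, gamma, C) over the canonical grids — cvK in
{3, 5, 10}, gamma in {2^-1 .. 2^-4}, C in {2^1 .. 2^11} — selecting the
combination with the best internal-CV overall accuracy of the fused-kernel
SVM. For every grid point the five channel weights are re-estimated on the
training data alone (never on test folds), so the outer protocols are
leak-free: vocabularies, weights and SVM state all derive from the training
partition.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.svm import SVC

from gotlm.features import CHANNELS, FeatureChannel, FeatureVocabulary, build_channels
from gotlm.io import Dataset, GoAnnotation, ProteinRecord
from gotlm.kernels import KernelWeights, channel_kernels, fuse_kernels
from gotlm.metrics import (
    ConfusionMatrix,
    confusion_matrix,
    multiclass_mcc,
    overall_se,
    per_class_metrics,
)
from gotlm.weighting import ChannelScore, cv_confusion, estimate_weights, kfold_split

logger = logging.getLogger(__name__)

#: canonical hyper-parameter grids
CVK_GRID = (3, 5, 10)
GAMMA_GRID = (2.0**-1, 2.0**-2, 2.0**-3, 2.0**-4)
C_GRID = tuple(2.0**k for k in range(1, 12))


@dataclass(frozen=True)
class ModelConfig:
    """Hyper-parameter grids, outer-CV fold count, channel mask and seed.

    Grids must be non-empty subsets of the canonical grids; the defaults are
    the full canonical grids. ``channels`` masks which of the five kernels
    participate (an ablated model zeroes the missing channels' weights).
    """

    cvk_grid: tuple[int, ...] = CVK_GRID
    gamma_grid: tuple[float, ...] = GAMMA_GRID
    c_grid: tuple[float, ...] = C_GRID
    outer_folds: int = 5
    seed: int = 0
    channels: tuple[str, ...] = CHANNELS

    def __post_init__(self) -> None:
        for name, grid, full in (
            ("cvk_grid", self.cvk_grid, CVK_GRID),
            ("gamma_grid", self.gamma_grid, GAMMA_GRID),
            ("c_grid", self.c_grid, C_GRID),
        ):
            if not grid:
                raise ValueError(f"{name} must be non-empty")
            bad = [v for v in grid if v not in full]
            if bad:
                raise ValueError(f"{name} values {bad} outside the canonical grid {full}")
        if not self.channels or any(c not in CHANNELS for c in self.channels):
            raise ValueError(f"channels must be a non-empty subset of {CHANNELS}")
        if self.outer_folds < 2:
            raise ValueError("outer_folds must be >= 2")


@dataclass
class GridResult:
    """Internal-CV accuracy of one (cvK, gamma, C) grid point."""

    cvk: int
    gamma: float
    C: float
    accuracy: float


@dataclass
class TrainedModel:
    """A fitted fused-kernel predictor with everything needed to score new proteins."""

    classes: tuple[str, ...]
    vocabularies: dict[str, FeatureVocabulary]
    train_channels: dict[str, FeatureChannel]
    train_ids: tuple[str, ...]
    weights: KernelWeights
    channel_scores: dict[str, ChannelScore]
    cvk: int
    gamma: float
    C: float
    svm: SVC
    config: ModelConfig
    internal_cv_accuracy: float
    grid_results: list[GridResult] = field(default_factory=list)


@dataclass
class EvaluationReport:
    """Pooled evaluation: confusion matrix, per-class table, and per-fold weights."""

    confusion: ConfusionMatrix
    fold_weights: list[KernelWeights]
    fold_params: list[tuple[int, float, float]]
    predictions: pd.DataFrame
    channels: tuple[str, ...] = CHANNELS

    @property
    def overall_accuracy(self) -> float:
        return overall_se(self.confusion)

    @property
    def overall_mcc(self) -> float:
        return multiclass_mcc(self.confusion)

    @property
    def per_class(self) -> pd.DataFrame:
        return per_class_metrics(self.confusion)

    def to_tsv(self, path) -> None:
        with open(path, "w") as fh:
            if set(self.channels) != set(CHANNELS):
                fh.write(f"# ablated_model\tchannels={','.join(self.channels)}\n")
            self.per_class.to_csv(fh, sep="\t", index=False, float_format="%.4f")
            fh.write(f"# overall_accuracy\t{self.overall_accuracy:.4f}\n")
            fh.write(f"# overall_mcc\t{self.overall_mcc:.4f}\n")
            for k, w in enumerate(self.fold_weights):
                ws = "\t".join(f"{c}={w[c]:.4f}" for c in CHANNELS)
                fh.write(f"# fold_{k}_weights\t{ws}\n")
            for k, (cvk, gamma, C) in enumerate(self.fold_params):
                fh.write(f"# fold_{k}_params\tcvK={cvk}\tgamma={gamma:g}\tC={C:g}\n")


def _check_classes(labels: Sequence[str | None], context: str) -> list[str]:
    if any(l is None for l in labels):
        raise ValueError(f"{context}: every protein must carry a location label")
    classes = sorted(set(labels))  # type: ignore[arg-type]
    if len(classes) < 2:
        raise ValueError(f"{context}: need at least 2 location classes")
    return classes  # type: ignore[return-value]


def train(dataset: Dataset, config: ModelConfig) -> TrainedModel:
    """Fit a fused-kernel model: grid search, weight estimation, final refit.

    For each (cvK, gamma, C) the channel weights are estimated on the full
    training set by cvK-fold CV and the fused SVM is scored by internal CV
    overall accuracy over the same folds. The best combination wins; ties
    break toward smallest C, then largest gamma, then smallest cvK. Weights
    and the SVM are then refit on all data with the winning parameters.
    """
    labels = dataset.labels
    classes = tuple(_check_classes(labels, "train"))
    y = [str(l) for l in labels]
    n = len(y)
    max_cvk = max(config.cvk_grid)
    smallest = min(np.unique(y, return_counts=True)[1])
    if n < max_cvk:
        raise ValueError(
            f"{n} examples cannot be split into {max_cvk} folds; use fewer folds"
        )
    if smallest < 2:
        logger.warning("a class has a single member; CV estimates will be unstable")

    all_channels = build_channels(dataset.records, dataset.annotations)
    channels = {c: all_channels[c] for c in config.channels}
    vocabularies = {
        a: all_channels[a].vocabulary for a in ("P", "F", "C")
    }

    best: tuple[float, float, float, int] | None = None  # (-acc, C, -gamma, cvK)
    best_acc = -np.inf
    grid_results: list[GridResult] = []
    best_combo: tuple[int, float, float] | None = None
    kernels_by_gamma: dict[float, dict[str, np.ndarray]] = {}

    for gamma in config.gamma_grid:
        kernels = channel_kernels(channels, None, gamma)
        kernels_by_gamma[gamma] = kernels
        for cvk in config.cvk_grid:
            folds = kfold_split(n, cvk, config.seed)
            for C in config.c_grid:
                weights, _ = estimate_weights(
                    kernels, y, classes, cvk, C, config.seed
                )
                fused = fuse_kernels(kernels, weights)
                acc = overall_se(cv_confusion(fused, y, classes, folds, C))
                grid_results.append(GridResult(cvk, gamma, C, acc))
                key = (-acc, C, -gamma, cvk)
                if best is None or key < best:
                    best = key
                    best_acc = acc
                    best_combo = (cvk, gamma, C)

    assert best_combo is not None
    cvk, gamma, C = best_combo
    logger.info(
        "selected cvK=%d gamma=%g C=%g (internal CV accuracy %.4f)",
        cvk, gamma, C, best_acc,
    )
    kernels = kernels_by_gamma[gamma]
    weights, scores = estimate_weights(kernels, y, classes, cvk, C, config.seed)
    fused = fuse_kernels(kernels, weights)
    svm = SVC(kernel="precomputed", C=C)
    svm.fit(fused, y)
    return TrainedModel(
        classes=classes,
        vocabularies=vocabularies,
        train_channels=channels,
        train_ids=tuple(dataset.ids),
        weights=weights,
        channel_scores=scores,
        cvk=cvk,
        gamma=gamma,
        C=C,
        svm=svm,
        config=config,
        internal_cv_accuracy=best_acc,
        grid_results=grid_results,
    )


def predict(
    model: TrainedModel,
    records: Sequence[ProteinRecord],
    annotations: Sequence[GoAnnotation] = (),
) -> pd.DataFrame:
    """Predict a location for each protein.

    Test features are built against the stored training vocabularies
    (out-of-vocabulary GO terms drop), rectangular channel kernels against
    the training rows are fused with the stored weights, and the one-vs-one
    SVM votes. Proteins with no annotations (all-zero GO rows) are legal and
    classified from whatever channels carry signal. Returns a frame with
    protein_id, predicted_location and the aggregated decision score of the
    winning class.
    """
    if not records:
        raise ValueError("no proteins to predict")
    test_all = build_channels(records, annotations, vocabularies=model.vocabularies)
    test_channels = {c: test_all[c] for c in model.train_channels}
    kernels = channel_kernels(test_channels, model.train_channels, model.gamma)
    fused = fuse_kernels(kernels, model.weights)
    pred = model.svm.predict(fused)
    dec = model.svm.decision_function(fused)
    if dec.ndim == 1:  # binary: signed distance to the separating plane
        score = np.abs(dec)
    else:
        score = dec.max(axis=1)
    return pd.DataFrame(
        {
            "protein_id": [r.id for r in records],
            "predicted_location": pred,
            "decision_score": score,
        }
    )


def cross_validate(dataset: Dataset, config: ModelConfig) -> EvaluationReport:
    """Outer K-fold cross-validation with a full leak-free train() per fold.

    Folds follow the equal-size rule with the remainder in the last fold.
    Inside each training partition the vocabulary construction, weight
    estimation and grid search are re-run from scratch; the held-out fold is
    only ever touched for prediction. The K test-fold predictions pool into
    one confusion matrix.
    """
    labels = dataset.labels
    classes = tuple(_check_classes(labels, "cross_validate"))
    counts = pd.Series([str(l) for l in labels]).value_counts()
    if counts.min() < config.outer_folds:
        raise ValueError(
            f"class {counts.idxmin()!r} has {counts.min()} members, fewer than "
            f"{config.outer_folds} folds; use fewer folds"
        )
    n = len(dataset.records)
    folds = kfold_split(n, config.outer_folds, config.seed)
    fold_weights: list[KernelWeights] = []
    fold_params: list[tuple[int, float, float]] = []
    frames: list[pd.DataFrame] = []
    for k in range(config.outer_folds):
        test_idx = np.flatnonzero(folds == k)
        train_idx = np.flatnonzero(folds != k)
        model = train(dataset.subset(train_idx), config)
        test_records = [dataset.records[i] for i in test_idx]
        test_ids = {r.id for r in test_records}
        test_anns = [a for a in dataset.annotations if a.protein_id in test_ids]
        preds = predict(model, test_records, test_anns)
        preds["true_location"] = [r.label for r in test_records]
        preds["fold"] = k
        frames.append(preds)
        fold_weights.append(model.weights)
        fold_params.append((model.cvk, model.gamma, model.C))
    predictions = pd.concat(frames, ignore_index=True)
    M = confusion_matrix(
        predictions["true_location"], predictions["predicted_location"], classes
    )
    return EvaluationReport(
        confusion=M,
        fold_weights=fold_weights,
        fold_params=fold_params,
        predictions=predictions,
        channels=config.channels,
    )


def holdout_evaluate(
    train_dataset: Dataset, test_dataset: Dataset, config: ModelConfig
) -> EvaluationReport:
    """Single fixed train/test partition: fit on the training set, score the test set."""
    if not test_dataset.records:
        raise ValueError("empty test set")
    overlap = set(train_dataset.ids) & set(test_dataset.ids)
    if overlap:
        raise ValueError(
            f"train and test sets share protein ids: {sorted(overlap)[:5]}"
        )
    if any(l is None for l in test_dataset.labels):
        raise ValueError("holdout_evaluate: every test protein must carry a label")
    model = train(train_dataset, config)
    unknown = sorted(set(test_dataset.labels) - set(model.classes))
    if unknown:
        raise ValueError(f"test set contains unseen classes: {unknown}")
    preds = predict(model, test_dataset.records, test_dataset.annotations)
    preds["true_location"] = test_dataset.labels
    preds["fold"] = 0
    M = confusion_matrix(
        preds["true_location"], preds["predicted_location"], model.classes
    )
    return EvaluationReport(
        confusion=M,
        fold_weights=[model.weights],
        fold_params=[(model.cvk, model.gamma, model.C)],
        predictions=preds,
        channels=config.channels,
    )
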