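"""Stacked ensemble classification: per-band polynomial SVMs blended by a
logistic-regression meta-classifier.

Each band's SVM (poly kernel, C=0.001, gamma=10) is trained on the
target-domain training features plus the (adapted) source features.  The
meta-classifier is fitted on the 6-vector of band-wise predicted labels
over a held-out validation split (blending), encoded as {0, 1} with
classes in lexicographic order, and maps it to the final label.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.linear_model import LogisticRegression
from sklearn.svm import SVC

__all__ = [
    "EnsembleModel",
    "make_svm",
    "train_band_svms",
    "band_predictions",
    "train_meta",
    "train_ensemble",
    "predict_ensemble",
    "accuracy",
]

SVM_C = 0.001
SVM_GAMMA = 10.0


def make_svm(kernel: str = "poly", c: float = SVM_C, gamma: float = SVM_GAMMA) -> SVC:
    return SVC(kernel=kernel, C=c, gamma=gamma)


@dataclass
class EnsembleModel:
    svms: dict  # band index -> fitted SVC
    meta: LogisticRegression
    classes: np.ndarray  # lexicographically sorted label alphabet

    def __post_init__(self) -> None:
        if self.meta is not None and len(self.svms) < 1:
            raise ValueError("ensemble needs at least one band classifier")


def _check_two_classes(labels: np.ndarray) -> np.ndarray:
    classes = np.unique(labels)
    if len(classes) < 2:
        raise ValueError("training labels contain a single class")
    return classes


def train_band_svms(features: dict[int, np.ndarray], labels: np.ndarray,
                    kernel: str = "poly", c: float = SVM_C,
                    gamma: float = SVM_GAMMA) -> dict[int, SVC]:
    """One independent SVM per band, identical hyperparameters."""
    _check_two_classes(labels)
    svms = {}
    for band in sorted(features):
        svms[band] = make_svm(kernel, c, gamma).fit(features[band], labels)
    return svms


def band_predictions(svms: dict[int, SVC], features: dict[int, np.ndarray],
                     classes: np.ndarray) -> np.ndarray:
    """(n, n_bands) matrix of band-wise predicted labels encoded {0, 1}."""
    cols = []
    for band in sorted(svms):
        if band not in features:
            raise ValueError(f"missing features for band {band}")
        pred = svms[band].predict(features[band])
        cols.append(np.searchsorted(classes, pred))
    return np.column_stack(cols).astype(float)


def train_meta(band_pred_matrix: np.ndarray, labels: np.ndarray) -> LogisticRegression:
    """Logistic-regression blender over encoded band predictions."""
    if len(band_pred_matrix) < 2:
        raise ValueError("need at least 2 validation samples")
    _check_two_classes(labels)
    return LogisticRegression().fit(band_pred_matrix, labels)


def train_ensemble(train_features: dict[int, np.ndarray], train_labels: np.ndarray,
                   val_features: dict[int, np.ndarray], val_labels: np.ndarray,
                   kernel: str = "poly", c: float = SVM_C,
                   gamma: float = SVM_GAMMA) -> EnsembleModel:
    """Fit band SVMs on training data and blend them on validation data."""
    classes = np.sort(np.unique(train_labels))
    svms = train_band_svms(train_features, train_labels, kernel, c, gamma)
    val_preds = band_predictions(svms, val_features, classes)
    meta = train_meta(val_preds, val_labels)
    return EnsembleModel(svms=svms, meta=meta, classes=classes)


def predict_ensemble(model: EnsembleModel, features: dict[int, np.ndarray]) -> np.ndarray:
    """Final labels: band SVM predictions fed through the meta-classifier."""
    preds = band_predictions(model.svms, features, model.classes)
    return model.meta.predict(preds)


def accuracy(predictions, truths) -> float:
    """Fraction of correct predictions, (TP+TN)/(TP+FN+TN+FP)."""
    predictions = np.asarray(predictions)
    truths = np.asarray(truths)
    if predictions.shape != truths.shape:
        raise ValueError("predictions and truths must align")
    if predictions.size == 0:
        raise ValueError("empty input")
    return float(np.mean(predictions == truths))
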