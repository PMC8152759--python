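"""Sample splitting, object-based classification and accuracy assessment.

Confusion matrices are oriented with predicted classes on rows and
reference classes on columns, so user's accuracy (UA) sits on row totals
and producer's accuracy (PA) on column totals.  Overall accuracy is
reported in percent, Cohen's kappa on [.., 1].
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.pipeline import make_pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from .types import ValidationError

logger = logging.getLogger(__name__)


def split_samples(table: pd.DataFrame, ratio: float = 1 / 5, seed: int = 0,
                  label_col: str = "label") -> tuple[pd.DataFrame, pd.DataFrame]:
    """Stratified random train/test split with train:test = ``ratio`` per class.

    The default 1:5 ratio assigns 1/6 of each class to training (rounded,
    but at least 1 training object per class).  The split is disjoint and
    exhaustive; classes with fewer than 2 objects are rejected.
    """
    rng = np.random.default_rng(seed)
    train_parts, test_parts = [], []
    frac = ratio / (1.0 + ratio)
    for cls, group in table.groupby(label_col, sort=True):
        n = len(group)
        if n < 2:
            raise ValidationError(f"class {cls!r} has fewer than 2 objects")
        n_train = max(1, int(round(n * frac)))
        n_train = min(n_train, n - 1)
        perm = rng.permutation(n)
        train_parts.append(group.iloc[perm[:n_train]])
        test_parts.append(group.iloc[perm[n_train:]])
    train = pd.concat(train_parts).sort_index()
    test = pd.concat(test_parts).sort_index()
    return train, test


def classify(model, table: pd.DataFrame, feature_names: list[str],
             labels_raster: np.ndarray | None = None):
    """Predict a class for every object; optionally paint a label raster.

    ``model`` must have been trained on exactly ``feature_names``.  When
    ``labels_raster`` (segment ids, as produced by the segmenter) is given,
    returns (predictions, predicted_label_raster); otherwise predictions.
    """
    missing = [f for f in feature_names if f not in table.columns]
    if missing:
        raise ValidationError(f"object table lacks feature columns {missing}")
    n_expected = getattr(model, "n_features_in_", len(feature_names))
    if n_expected != len(feature_names):
        raise ValidationError(
            f"model expects {n_expected} features, got {len(feature_names)}")
    x = table.loc[:, feature_names].to_numpy(dtype=float)
    pred = pd.Series(model.predict(x), index=table.index, name="predicted")
    if labels_raster is None:
        return pred
    lut = dict(zip(table["id"], pred))
    flat = np.asarray(labels_raster).ravel()
    painted = np.array([lut.get(i) for i in flat], dtype=object)
    return pred, painted.reshape(np.asarray(labels_raster).shape)


#: Recorded SVM baseline hyperparameters (standardized RBF kernel).
SVM_PARAMS = {"kernel": "rbf", "C": 10.0, "gamma": "scale"}


def svm_baseline(train: pd.DataFrame, test: pd.DataFrame,
                 feature_names: list[str], label_col: str = "label",
                 seed: int = 0) -> pd.Series:
    """Kernel-SVM comparison arm: fit on train, predict the test objects.

    Features are standardized internally; hyperparameters are fixed and
    recorded in :data:`SVM_PARAMS` (logged per run).
    """
    logger.info("SVM baseline hyperparameters: %s", SVM_PARAMS)
    clf = make_pipeline(StandardScaler(),
                        SVC(random_state=seed, **SVM_PARAMS))
    clf.fit(train.loc[:, feature_names].to_numpy(dtype=float),
            train[label_col].to_numpy())
    pred = clf.predict(test.loc[:, feature_names].to_numpy(dtype=float))
    return pd.Series(pred, index=test.index, name="predicted")


@dataclass
class ConfusionMatrix:
    """K x K counts; rows are predicted classes, columns reference classes."""

    counts: np.ndarray
    classes: tuple[str, ...]

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        k = len(self.classes)
        if self.counts.shape != (k, k):
            raise ValidationError("counts must be K x K for K classes")
        if np.any(self.counts < 0):
            raise ValidationError("confusion counts must be non-negative")
        if self.counts.sum() <= 0:
            raise ValidationError("confusion matrix is empty")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=list(self.classes),
                            columns=list(self.classes))


def confusion(pred, truth, classes: tuple[str, ...] | None = None) -> ConfusionMatrix:
    """Count (predicted, reference) pairs into a confusion matrix."""
    pred = np.asarray(pred, dtype=object)
    truth = np.asarray(truth, dtype=object)
    if pred.shape != truth.shape:
        raise ValidationError("prediction and truth lengths differ")
    if classes is None:
        classes = tuple(sorted(set(pred.tolist()) | set(truth.tolist())))
    index = {c: i for i, c in enumerate(classes)}
    k = len(classes)
    counts = np.zeros((k, k), dtype=np.int64)
    for p, t in zip(pred.ravel(), truth.ravel()):
        if p not in index or t not in index:
            raise ValidationError(f"label outside vocabulary: {p!r} / {t!r}")
        counts[index[p], index[t]] += 1
    return ConfusionMatrix(counts, tuple(classes))


@dataclass
class AccuracyReport:
    """Overall accuracy (%), Cohen's kappa and per-class UA/PA (%)."""

    overall_accuracy: float
    kappa: float
    user_accuracy: pd.Series      # per predicted-class row; NaN when undefined
    producer_accuracy: pd.Series  # per reference-class column
    n: int = 0
    extras: dict = field(default_factory=dict)


def accuracy_report(matrix: ConfusionMatrix) -> AccuracyReport:
    """Confusion-matrix statistics.

    OA = 100 * sum(diagonal) / N; kappa = (po - pe) / (1 - pe) with
    pe = sum_k row_k * col_k / N^2; UA_k = 100 * diag_k / row_k;
    PA_k = 100 * diag_k / col_k.  A zero row or column total leaves the
    corresponding UA/PA undefined (NaN).
    """
    m = matrix.counts.astype(float)
    n = m.sum()
    diag = np.diag(m)
    row = m.sum(axis=1)
    col = m.sum(axis=0)
    po = diag.sum() / n
    pe = (row * col).sum() / n ** 2
    kappa = 1.0 if pe == 1.0 else (po - pe) / (1.0 - pe)
    with np.errstate(invalid="ignore", divide="ignore"):
        ua = np.where(row > 0, 100.0 * diag / np.where(row > 0, row, 1.0), np.nan)
        pa = np.where(col > 0, 100.0 * diag / np.where(col > 0, col, 1.0), np.nan)
    cls = list(matrix.classes)
    return AccuracyReport(
        overall_accuracy=100.0 * po,
        kappa=float(kappa),
        user_accuracy=pd.Series(ua, index=cls, name="UA"),
        producer_accuracy=pd.Series(pa, index=cls, name="PA"),
        n=int(n),
    )
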