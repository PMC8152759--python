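"""Random-forest permutation importance and sequential backward selection.

Importance is the mean decrease in accuracy (MDA): for each tree the
out-of-bag (OOB) misclassification error is computed before and after
permuting one feature within that tree's OOB subset, and the differences
are averaged over trees with a plain (unweighted) mean.  An OOB-size
weighted variant is available behind a flag.  Per-class importances use the
same per-tree errors restricted to the samples of one class.

Sequential backward selection ranks the features once by full-model MDA,
then removes the lowest-ranked remaining feature one at a time, scoring
each subset by stratified 10-fold cross-validated accuracy of a freshly
trained forest; the selected subset maximizes the accuracy, ties going to
the smaller subset.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier
from sklearn.model_selection import StratifiedKFold

from .types import ValidationError


@dataclass
class FittedForest:
    """A bagged tree ensemble with per-tree in-bag/out-of-bag records."""

    model: RandomForestClassifier
    feature_names: list[str]
    oob_indices: list[np.ndarray]   # per tree, indices never drawn in-bag
    n_samples: int
    seed: int


@dataclass
class ImportanceReport:
    """MDA per feature, optionally per (feature, class)."""

    mda: pd.Series                      # index: feature name
    per_class: pd.DataFrame | None      # rows: feature, cols: class
    n_trees: int
    seed: int


@dataclass
class SelectionTrace:
    """Backward-elimination record: one row per subset size."""

    steps: pd.DataFrame        # columns: removed, subset, cv_accuracy
    selected: list[str] = field(default_factory=list)


def train_forest(table: pd.DataFrame, feature_names: list[str],
                 label_col: str = "label", n_trees: int = 800,
                 seed: int = 0) -> FittedForest:
    """Fit a bagged decision-tree ensemble, retaining per-tree OOB indices.

    Deterministic under ``seed``.  Raises on single-class input.
    """
    x = table.loc[:, feature_names].to_numpy(dtype=float)
    y = table[label_col].to_numpy()
    if len(np.unique(y)) < 2:
        raise ValidationError("training table must contain at least 2 classes")
    if not np.all(np.isfinite(x)):
        raise ValidationError("training features contain missing values")
    model = RandomForestClassifier(
        n_estimators=n_trees, bootstrap=True, random_state=seed, n_jobs=1,
    )
    model.fit(x, y)
    n = len(y)
    oob = []
    for inbag in model.estimators_samples_:
        mask = np.ones(n, dtype=bool)
        mask[inbag] = False
        oob.append(np.flatnonzero(mask))
    return FittedForest(model, list(feature_names), oob, n, seed)


def _tree_error(tree, x: np.ndarray, y_codes: np.ndarray,
                classes: np.ndarray) -> np.ndarray:
    """Per-sample 0/1 loss of one tree (predictions via class codes)."""
    pred = tree.predict(x)
    return (pred.astype(y_codes.dtype) != y_codes).astype(float)


def mda_importance(forest: FittedForest, table: pd.DataFrame,
                   seed: int = 0, label_col: str = "label",
                   per_class: bool = False, weighted: bool = False,
                   permutations: dict[tuple[int, str], np.ndarray] | None = None,
                   ) -> ImportanceReport:
    """Mean-decrease-accuracy importance of every feature.

    For tree i, errOOB1(i) is its OOB misclassification rate; errOOB2(i) is
    the rate after permuting feature f within the OOB subset; MDA(f) is the
    plain mean of errOOB2(i) - errOOB1(i) over trees with non-empty OOB
    sets (``weighted=True`` switches to an OOB-size weighted mean).

    ``permutations`` maps (tree_index, feature_name) to an explicit index
    permutation of that tree's OOB subset, overriding the seeded random
    shuffles — used for exact oracle checks.
    """
    rng = np.random.default_rng(seed)
    x = table.loc[:, forest.feature_names].to_numpy(dtype=float)
    y = table[label_col].to_numpy()
    model = forest.model
    classes = model.classes_
    class_code = {c: k for k, c in enumerate(classes)}
    y_codes = np.array([class_code[v] for v in y])

    n_feat = len(forest.feature_names)
    diffs = np.zeros((0, n_feat))
    rows = []
    class_rows: dict[str, list[np.ndarray]] = {c: [] for c in classes}
    sizes = []
    for i, tree in enumerate(model.estimators_):
        oob = forest.oob_indices[i]
        if oob.size == 0:
            continue
        x_oob = x[oob]
        y_oob = y_codes[oob]
        loss1 = _tree_error(tree, x_oob, y_oob, classes)
        err1 = loss1.mean()
        row = np.empty(n_feat)
        cls_row = np.empty((len(classes), n_feat))
        for j, fname in enumerate(forest.feature_names):
            if permutations is not None and (i, fname) in permutations:
                perm = np.asarray(permutations[(i, fname)])
            else:
                perm = rng.permutation(oob.size)
            x_perm = x_oob.copy()
            x_perm[:, j] = x_oob[perm, j]
            loss2 = _tree_error(tree, x_perm, y_oob, classes)
            row[j] = loss2.mean() - err1
            if per_class:
                for k in range(len(classes)):
                    m = y_oob == k
                    cls_row[k, j] = (loss2[m].mean() - loss1[m].mean()) if m.any() else np.nan
        rows.append(row)
        sizes.append(oob.size)
        if per_class:
            for k, c in enumerate(classes):
                class_rows[c].append(cls_row[k])

    if not rows:
        raise ValidationError("no tree has a non-empty OOB set")
    diffs = np.vstack(rows)
    if weighted:
        w = np.asarray(sizes, dtype=float)
        mda = (diffs * w[:, None]).sum(axis=0) / w.sum()
    else:
        mda = diffs.mean(axis=0)
    mda_s = pd.Series(mda, index=forest.feature_names, name="MDA")

    per_class_df = None
    if per_class:
        per_class_df = pd.DataFrame(
            {c: np.nanmean(np.vstack(v), axis=0) for c, v in class_rows.items()},
            index=forest.feature_names,
        )
    return ImportanceReport(mda_s, per_class_df, len(model.estimators_), seed)


def _cv_accuracy(x: np.ndarray, y: np.ndarray, n_trees: int, folds: int,
                 seed: int) -> float:
    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    correct = 0
    for k, (tr, te) in enumerate(skf.split(x, y)):
        clf = RandomForestClassifier(n_estimators=n_trees, random_state=seed + k,
                                     n_jobs=1)
        clf.fit(x[tr], y[tr])
        correct += int((clf.predict(x[te]) == y[te]).sum())
    return correct / len(y)


def sbs_optimize(table: pd.DataFrame, feature_names: list[str],
                 label_col: str = "label", n_trees: int = 800,
                 folds: int = 10, seed: int = 0,
                 cv_trees: int | None = None,
                 rerank: bool = False) -> SelectionTrace:
    """Sequential backward selection over an MDA ranking.

    Features are ranked once by MDA from the full model (``rerank=True``
    re-estimates the ranking after every removal); the lowest-ranked
    remaining feature is dropped at each step and every subset is scored by
    stratified ``folds``-fold cross-validated accuracy of a fresh forest
    (``cv_trees`` trees, defaulting to ``n_trees``).  The selected subset
    maximizes CV accuracy; ties favor the smaller subset.
    """
    if not feature_names:
        raise ValidationError("at least one feature is required")
    cv_trees = n_trees if cv_trees is None else cv_trees
    y = table[label_col].to_numpy()

    current = list(feature_names)
    forest = train_forest(table, current, label_col, n_trees=n_trees, seed=seed)
    ranking = mda_importance(forest, table, seed=seed, label_col=label_col).mda

    records = []
    best_acc, best_subset = -1.0, list(current)
    removed: str | None = None
    while current:
        x = table.loc[:, current].to_numpy(dtype=float)
        acc = _cv_accuracy(x, y, cv_trees, folds, seed)
        records.append({"removed": removed, "subset": tuple(current),
                        "cv_accuracy": acc})
        if acc >= best_acc:     # later records have fewer features: ties -> smaller
            best_acc, best_subset = acc, list(current)
        if len(current) == 1:
            break
        if rerank:
            forest = train_forest(table, current, label_col,
                                  n_trees=n_trees, seed=seed)
            ranking = mda_importance(forest, table, seed=seed,
                                     label_col=label_col).mda
        removed = min(current, key=lambda f: (ranking[f], f))
        current = [f for f in current if f != removed]

    return SelectionTrace(pd.DataFrame.from_records(records), best_subset)
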