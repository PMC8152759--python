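"""End-to-end object-based classification workflow on a synthetic scene.

Mirrors the full processing chain: simulate a speckled multilook scene with
known class structure, extract the 16-feature stack, segment the dB-scaled
Pauli RGB, aggregate features per object, split the labeled objects 1:5
into training and testing sets, rank features and optimize the subset, then
train tree ensembles (plus an SVM comparison arm) and evaluate with
confusion-matrix statistics.

A 256x256 scene yields a few dozen objects — far too few to train on
object units directly — so labeled sample points (pixels) are drawn from
the training objects for model fitting, importance ranking and the
cross-validated subset search, mirroring how training points are collected
inside ground-truth polygons; test objects are then classified from their
mean feature vectors.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .decomposition import FEATURE_SETS, extract_feature_stack
from .evaluation import (
    AccuracyReport,
    accuracy_report,
    confusion,
    split_samples,
    svm_baseline,
)
from .preprocess import pauli_rgb
from .segmentation import aggregate_objects, multiresolution_segment
from .selection import SelectionTrace, mda_importance, sbs_optimize, train_forest
from .synthetic import default_scene
from .types import CLASS_NAMES, FEATURE_NAMES


@dataclass
class WorkflowResult:
    """Everything the synthetic rehearsal produces."""

    objects: pd.DataFrame
    n_segments: int
    importance: pd.Series
    trace: SelectionTrace
    reports: dict[str, AccuracyReport] = field(default_factory=dict)


def sample_points(labels: np.ndarray, feats, truth: np.ndarray,
                  object_ids: set, per_object: int, seed: int) -> pd.DataFrame:
    """Draw labeled per-pixel feature samples from the given objects.

    At most ``per_object`` valid pixels are sampled (without replacement,
    seeded) from every object; each point carries the truth label of its
    pixel.
    """
    rng = np.random.default_rng(seed)
    flat_labels = labels.ravel()
    flat_feats = feats.data.reshape(-1, len(FEATURE_NAMES))
    flat_truth = np.asarray(truth).ravel()
    flat_ok = feats.mask.ravel()
    rows = []
    for sid in sorted(object_ids):
        idx = np.flatnonzero((flat_labels == sid) & flat_ok)
        if idx.size == 0:
            continue
        take = rng.choice(idx, size=min(per_object, idx.size), replace=False)
        block = pd.DataFrame(flat_feats[take], columns=list(FEATURE_NAMES))
        block["label"] = flat_truth[take]
        block["id"] = sid
        rows.append(block)
    return pd.concat(rows, ignore_index=True)


def run_synthetic_workflow(rows: int = 256, cols: int = 256, tile: int = 32,
                           looks: int = 16, seed: int = 0,
                           scale: float = 28.0, shape_weight: float = 0.3,
                           compactness_weight: float = 0.5,
                           n_trees: int = 800, cv_trees: int = 200,
                           points_per_object: int = 40,
                           run_sbs: bool = True,
                           run_svm: bool = False) -> WorkflowResult:
    """Run the whole chain on a simulated seven-class scene.

    Returns per-feature-set accuracy reports keyed ``all`` (16 features),
    ``selected`` (the SBS optimum, when ``run_sbs``) and ``svm_all``
    (when ``run_svm``).  ``cv_trees`` sizes the forests used inside the
    cross-validated subset search; the final classifiers use ``n_trees``.
    Accuracy is object-based (each test object counts once, reference =
    its majority truth label); the pixel-level accuracy of the painted map
    against the raw truth raster is reported under ``extras``.
    """
    scene, truth = default_scene(rows, cols, tile=tile, looks=looks, seed=seed)
    feats = extract_feature_stack(scene)
    # segment the dB-scaled Pauli image (the conventional display scaling;
    # makes speckle additive with class-independent variance)
    rgb_db = 10.0 * np.log10(np.maximum(pauli_rgb(scene).bands, 1e-12))
    labels = multiresolution_segment(rgb_db, scale=scale,
                                     shape_weight=shape_weight,
                                     compactness_weight=compactness_weight)
    objects = aggregate_objects(labels, feats, truth=truth)
    objects = objects.dropna(subset=list(FEATURE_NAMES))

    train_obj, test_obj = split_samples(objects, ratio=1 / 5, seed=seed + 1)
    feature_names = list(FEATURE_NAMES)
    train_pts = sample_points(labels, feats, truth, set(train_obj["id"]),
                              per_object=points_per_object, seed=seed + 2)

    forest_all = train_forest(train_pts, feature_names, n_trees=n_trees,
                              seed=seed + 3)
    importance = mda_importance(forest_all, train_pts, seed=seed + 4).mda

    reports: dict[str, AccuracyReport] = {}
    test_ids = set(test_obj["id"])
    test_px = np.isin(labels, list(test_ids))
    truth_arr = np.asarray(truth)

    def evaluate(predict, names: list[str]) -> AccuracyReport:
        pred = predict(test_obj.loc[:, names].to_numpy(dtype=float))
        cm = confusion(pred, test_obj["label"].to_numpy(), classes=CLASS_NAMES)
        rep = accuracy_report(cm)
        lut = dict(zip(test_obj["id"], pred))
        painted = np.empty(labels.shape, dtype=object)
        for sid, cls in lut.items():
            painted[labels == sid] = cls
        rep.extras["pixel_accuracy"] = float(
            (painted[test_px] == truth_arr[test_px]).mean() * 100.0)
        return rep

    reports["all"] = evaluate(forest_all.model.predict, feature_names)

    trace = SelectionTrace(pd.DataFrame(), list(feature_names))
    if run_sbs:
        trace = sbs_optimize(train_pts, feature_names, n_trees=n_trees,
                             folds=10, seed=seed + 5, cv_trees=cv_trees)
        forest_sel = train_forest(train_pts, trace.selected, n_trees=n_trees,
                                  seed=seed + 6)
        reports["selected"] = evaluate(forest_sel.model.predict, trace.selected)

    if run_svm:
        def svm_predict(x: np.ndarray) -> np.ndarray:
            frame = pd.DataFrame(x, columns=feature_names)
            return svm_baseline(train_pts, frame, feature_names,
                                seed=seed + 7).to_numpy()

        reports["svm_all"] = evaluate(svm_predict, feature_names)

    return WorkflowResult(objects=objects, n_segments=int(labels.max()),
                          importance=importance, trace=trace, reports=reports)


__all__ = ["WorkflowResult", "run_synthetic_workflow", "sample_points",
           "FEATURE_SETS"]
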