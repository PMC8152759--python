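"""Bundled reference confusion matrices for a seven-class coastal wetland
GF-3 classification experiment.

These published tables serve as fixed inputs for validating the
confusion-matrix arithmetic (overall accuracy, Cohen's kappa, user's and
producer's accuracy): the counts are re-entered verbatim and all statistics
are recomputed from them.  Rows are predicted classes, columns reference
classes, in the order beach, Suaeda salsa, Spartina alterniflora, road,
water, irrigable land, rice paddy.

Keys name the feature set and classifier that produced each matrix:
``fs_rf`` (optimized 7-feature subset, random forest), ``ha_span_rf``
(H/A/Span), ``neumann_span_rf`` (Neu_tau/Neu_pha/Span), ``y4_rf``
(Yamaguchi powers), ``all_rf`` (all 16 features) and ``all_svm`` (all 16
features, SVM).
"""

from __future__ import annotations

import numpy as np

from .evaluation import ConfusionMatrix

TABLE_CLASSES = (
    "beach",
    "Suaeda salsa",
    "Spartina alterniflora",
    "road",
    "water",
    "irrigable land",
    "rice paddy",
)

_COUNTS = {
    "fs_rf": [
        [7682, 0, 0, 3, 1, 0, 0],
        [0, 3277, 0, 0, 0, 319, 196],
        [40, 0, 9306, 29, 10, 56, 454],
        [87, 0, 64, 1285, 253, 0, 5],
        [264, 0, 0, 5, 5551, 0, 0],
        [0, 112, 108, 0, 0, 8228, 238],
        [0, 76, 855, 2, 0, 114, 7437],
    ],
    "ha_span_rf": [
        [7257, 0, 0, 235, 28, 0, 0],
        [0, 1753, 0, 0, 0, 87, 108],
        [27, 0, 7102, 17, 9, 226, 2208],
        [600, 0, 194, 1055, 279, 0, 192],
        [189, 0, 0, 17, 5498, 0, 0],
        [0, 1650, 86, 0, 0, 8333, 982],
        [0, 62, 2951, 0, 1, 71, 4840],
    ],
    "neumann_span_rf": [
        [7165, 0, 0, 5, 1, 0, 0],
        [0, 3116, 0, 1, 0, 409, 453],
        [61, 0, 6523, 123, 1, 144, 435],
        [579, 0, 881, 1097, 483, 14, 112],
        [268, 0, 0, 28, 5330, 0, 0],
        [0, 94, 27, 0, 0, 8022, 387],
        [0, 255, 2902, 70, 0, 128, 6943],
    ],
    "y4_rf": [
        [7804, 0, 0, 87, 13, 0, 0],
        [0, 3113, 0, 0, 239, 210, 219],
        [53, 0, 7942, 13, 4, 124, 682],
        [7, 0, 1125, 1214, 288, 0, 97],
        [209, 0, 0, 10, 5271, 0, 0],
        [0, 99, 29, 0, 0, 8199, 369],
        [0, 253, 1237, 0, 0, 184, 6963],
    ],
    "all_rf": [
        [7661, 0, 0, 38, 19, 0, 0],
        [0, 2764, 0, 0, 0, 50, 60],
        [53, 0, 9018, 8, 9, 106, 1504],
        [88, 0, 151, 1264, 104, 0, 52],
        [272, 0, 0, 14, 5682, 0, 0],
        [0, 576, 112, 0, 0, 8487, 481],
        [0, 125, 1053, 0, 0, 74, 6232],
    ],
    "all_svm": [
        [7065, 0, 0, 0, 0, 0, 0],
        [0, 3231, 0, 0, 0, 156, 466],
        [48, 0, 7542, 17, 18, 207, 732],
        [380, 0, 2, 1286, 611, 0, 0],
        [581, 0, 0, 20, 5185, 0, 0],
        [0, 154, 24, 0, 0, 8283, 313],
        [0, 80, 2766, 1, 0, 71, 6819],
    ],
}


def reference_confusion_matrices() -> dict[str, ConfusionMatrix]:
    """The six bundled confusion matrices as ConfusionMatrix objects."""
    return {
        name: ConfusionMatrix(np.array(counts, dtype=np.int64), TABLE_CLASSES)
        for name, counts in _COUNTS.items()
    }
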