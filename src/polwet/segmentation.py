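"""Multiresolution region-merging segmentation and object aggregation.

The segmenter follows the classic multiresolution (bottom-up pairwise
region-merging) formulation: starting from single-pixel regions, the pair
with the globally lowest fusion cost is merged while the cost stays below
scale^2.  The fusion cost is

    f = (1 - shape_weight) * dh_color + shape_weight * dh_shape

where dh_color is the area-weighted increase in per-band standard deviation
summed over bands, and dh_shape mixes a compactness term (perimeter /
sqrt(area)) and a smoothness term (perimeter / bounding-box perimeter) by
``compactness_weight``.  Input bands are standardized to zero mean and unit
variance so the scale parameter is comparable across scenes.  Merging the
globally cheapest pair makes every merge mutually best-fitting; ties break
deterministically on the lower region id.  Regions are 4-connected
throughout, and final ids are canonicalized by raster scan order starting
at 1.
"""

from __future__ import annotations

import heapq
import logging
import math

import numpy as np
import pandas as pd

from .types import CLASS_NAMES, FEATURE_NAMES, FeatureRaster, PauliRGB, ValidationError

logger = logging.getLogger(__name__)


def multiresolution_segment(image: PauliRGB | np.ndarray,
                            scale: float = 28.0,
                            shape_weight: float = 0.3,
                            compactness_weight: float = 0.5) -> np.ndarray:
    """Segment a multiband image into 4-connected regions.

    Returns an int32 label raster with ids contiguous from 1 in raster scan
    order.  ``scale`` controls the maximum admissible fusion cost
    (scale^2); ``shape_weight`` trades color homogeneity against shape, and
    ``compactness_weight`` trades compactness against smoothness.
    """
    bands = image.bands if isinstance(image, PauliRGB) else np.asarray(image, float)
    if bands.ndim == 2:
        bands = bands[..., None]
    rows, cols, nb = bands.shape
    if rows == 0 or cols == 0:
        raise ValidationError("empty image")
    if not (0.0 <= shape_weight <= 1.0 and 0.0 <= compactness_weight <= 1.0):
        raise ValidationError("weights must lie in [0, 1]")
    if scale <= 0:
        raise ValidationError("scale must be positive")

    # standardize bands
    flat = bands.reshape(-1, nb).astype(float)
    mu = flat.mean(axis=0)
    sd = flat.std(axis=0)
    sd[sd == 0] = 1.0
    flat = (flat - mu) / sd

    n_px = rows * cols
    color_w = 1.0 - shape_weight
    cmp_w = compactness_weight
    threshold = float(scale) * float(scale)

    # per-region stats as plain python lists (fast scalar access)
    cnt = [1] * n_px
    sums = [list(flat[i]) for i in range(n_px)]
    sqs = [list(flat[i] ** 2) for i in range(n_px)]
    perim = [4.0] * n_px
    bbox = [(i // cols, i // cols, i % cols, i % cols) for i in range(n_px)]
    nbrs: list[dict[int, float]] = [dict() for _ in range(n_px)]
    for i in range(n_px):
        y, x = divmod(i, cols)
        if x + 1 < cols:
            nbrs[i][i + 1] = 1.0
            nbrs[i + 1][i] = 1.0
        if y + 1 < rows:
            nbrs[i][i + cols] = 1.0
            nbrs[i + cols][i] = 1.0

    version = [0] * n_px
    parent = list(range(n_px))

    def find(r: int) -> int:
        while parent[r] != r:
            parent[r] = parent[parent[r]]
            r = parent[r]
        return r

    sqrt = math.sqrt

    def h_color(r: int) -> float:
        n = cnt[r]
        total = 0.0
        sr, qr = sums[r], sqs[r]
        for b in range(nb):
            var = qr[b] / n - (sr[b] / n) ** 2
            if var > 0:
                total += n * sqrt(var)
        return total

    def h_shape(r: int) -> float:
        n = cnt[r]
        l = perim[r]
        y0, y1, x0, x1 = bbox[r]
        bb = 2.0 * ((y1 - y0 + 1) + (x1 - x0 + 1))
        return cmp_w * sqrt(n) * l + (1.0 - cmp_w) * n * l / bb

    hc = [0.0] * n_px           # color h is 0 for single pixels
    hs = [h_shape(i) for i in range(n_px)]

    def merge_cost(r1: int, r2: int) -> float:
        n1, n2 = cnt[r1], cnt[r2]
        n = n1 + n2
        s1, s2, q1, q2 = sums[r1], sums[r2], sqs[r1], sqs[r2]
        color = 0.0
        for b in range(nb):
            s = s1[b] + s2[b]
            q = q1[b] + q2[b]
            var = q / n - (s / n) ** 2
            if var > 0:
                color += n * sqrt(var)
        d_color = color - hc[r1] - hc[r2]
        l = perim[r1] + perim[r2] - 2.0 * nbrs[r1][r2]
        a0, a1, b0, b1 = bbox[r1]
        c0, c1, d0, d1 = bbox[r2]
        y0 = a0 if a0 < c0 else c0
        y1 = a1 if a1 > c1 else c1
        x0 = b0 if b0 < d0 else d0
        x1 = b1 if b1 > d1 else d1
        bb = 2.0 * ((y1 - y0 + 1) + (x1 - x0 + 1))
        shape = cmp_w * sqrt(n) * l + (1.0 - cmp_w) * n * l / bb
        d_shape = shape - hs[r1] - hs[r2]
        return color_w * d_color + shape_weight * d_shape

    heap: list[tuple[float, int, int, int, int]] = []
    for i in range(n_px):
        for j in nbrs[i]:
            if j > i:
                cost = merge_cost(i, j)
                if cost < threshold:
                    heap.append((cost, i, j, 0, 0))
    heapq.heapify(heap)

    while heap:
        cost, r1, r2, v1, v2 = heapq.heappop(heap)
        if version[r1] != v1 or version[r2] != v2:
            continue
        if cost >= threshold:
            break
        # merge r2 into r1 (r1 < r2 by construction of pushes)
        parent[r2] = r1
        shared = nbrs[r1].pop(r2)
        nbrs[r2].pop(r1)
        cnt[r1] += cnt[r2]
        for b in range(nb):
            sums[r1][b] += sums[r2][b]
            sqs[r1][b] += sqs[r2][b]
        perim[r1] = perim[r1] + perim[r2] - 2.0 * shared
        a0, a1, b0, b1 = bbox[r1]
        c0, c1, d0, d1 = bbox[r2]
        bbox[r1] = (min(a0, c0), max(a1, c1), min(b0, d0), max(b1, d1))
        hc[r1] = h_color(r1)
        hs[r1] = h_shape(r1)
        for x, length in nbrs[r2].items():
            nbrs[x].pop(r2)
            nbrs[r1][x] = nbrs[r1].get(x, 0.0) + length
            nbrs[x][r1] = nbrs[r1][x]
        nbrs[r2].clear()
        version[r1] += 1
        version[r2] += 1
        vr1 = version[r1]
        for x in nbrs[r1]:
            cost = merge_cost(r1, x) if r1 < x else merge_cost(x, r1)
            if cost < threshold:
                if r1 < x:
                    heapq.heappush(heap, (cost, r1, x, vr1, version[x]))
                else:
                    heapq.heappush(heap, (cost, x, r1, version[x], vr1))

    roots = np.fromiter((find(i) for i in range(n_px)), dtype=np.int64, count=n_px)
    _, canonical = np.unique(roots, return_inverse=True)
    # np.unique sorts roots; re-map so ids follow first appearance in scan order
    order = np.zeros(canonical.max() + 1, dtype=np.int64)
    seen: dict[int, int] = {}
    next_id = 1
    for cid in canonical:
        c = int(cid)
        if c not in seen:
            seen[c] = next_id
            next_id += 1
    for c, lab in seen.items():
        order[c] = lab
    labels = order[canonical].reshape(rows, cols).astype(np.int32)
    logger.debug("segmentation produced %d regions", next_id - 1)
    return labels


def aggregate_objects(labels: np.ndarray,
                      features: FeatureRaster,
                      truth: np.ndarray | None = None) -> pd.DataFrame:
    """Per-segment unweighted mean of each unmasked feature band.

    Returns a table with one row per segment: id, pixel count, the 16
    feature means and (when ``truth`` is given) the majority truth label,
    ties broken by the lowest class index (logged).
    """
    labels = np.asarray(labels)
    if labels.shape != features.data.shape[:2]:
        raise ValidationError("label raster and feature raster shapes differ")
    if truth is not None and np.asarray(truth).shape != labels.shape:
        raise ValidationError("truth raster shape mismatch")

    flat_labels = labels.ravel()
    flat_feats = features.data.reshape(-1, len(FEATURE_NAMES))
    flat_mask = features.mask.ravel()

    df = pd.DataFrame(flat_feats, columns=list(FEATURE_NAMES))
    df["id"] = flat_labels
    counts = df.groupby("id").size().rename("n_pixels")
    means = df[flat_mask].groupby(df.loc[flat_mask, "id"]).mean(numeric_only=True)
    means = means.drop(columns=["id"], errors="ignore")
    out = pd.concat([counts, means.reindex(counts.index)], axis=1).reset_index()

    if truth is not None:
        truth_flat = pd.Series(np.asarray(truth).ravel(), name="label")
        rank = {c: i for i, c in enumerate(CLASS_NAMES)}

        def majority(s: pd.Series) -> str:
            vc = s.value_counts()
            top = vc[vc == vc.max()].index.tolist()
            if len(top) > 1:
                logger.debug("majority tie in segment -> lowest class index")
                top.sort(key=lambda c: rank.get(c, len(rank)))
            return top[0]

        maj = truth_flat.groupby(flat_labels).agg(majority)
        out["label"] = out["id"].map(maj)
    return out
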