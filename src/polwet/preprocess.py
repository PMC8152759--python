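"""Multilooking, speckle filtering and Pauli RGB construction.

Filters operate jointly on all T3 elements, with local statistics estimated
from the Span channel.  Border handling: filters replicate edges; the
multilook operator drops trailing partial windows.  Filtered matrices are
projected back to the PSD cone if numerical noise produces a slightly
negative eigenvalue; the number of projected pixels is logged.
"""

from __future__ import annotations

import logging

import numpy as np
from scipy import ndimage

from .types import CoherencyRaster, PauliRGB, ScatteringImage, ValidationError

logger = logging.getLogger(__name__)


def pauli_vector(image: ScatteringImage) -> np.ndarray:
    """Per-pixel Pauli scattering vector k = (SHH+SVV, SHH-SVV, 2 SHV)/sqrt(2)."""
    k = np.stack(
        [image.shh + image.svv, image.shh - image.svv, 2.0 * image.shv],
        axis=-1,
    )
    return k / np.sqrt(2.0)


def multilook(image: ScatteringImage, looks_az: int, looks_rg: int) -> CoherencyRaster:
    """Average Pauli outer products over looks_az x looks_rg windows.

    The output look count is looks_az * looks_rg; trailing rows/columns that
    do not fill a window are dropped.
    """
    if looks_az < 1 or looks_rg < 1:
        raise ValidationError("look factors must be >= 1")
    if looks_az > image.rows or looks_rg > image.cols:
        raise ValidationError("multilook window larger than image")
    k = pauli_vector(image)
    outer = k[..., :, None] * np.conj(k[..., None, :])
    r = (image.rows // looks_az) * looks_az
    c = (image.cols // looks_rg) * looks_rg
    outer = outer[:r, :c]
    blocks = outer.reshape(r // looks_az, looks_az, c // looks_rg, looks_rg, 3, 3)
    t = blocks.mean(axis=(1, 3))
    return CoherencyRaster(t, looks=looks_az * looks_rg,
                           metadata=dict(image.metadata))


def _project_psd(t: np.ndarray) -> np.ndarray:
    """Clamp negative eigenvalues to zero, preserving Hermitian structure."""
    herm = 0.5 * (t + np.conj(np.swapaxes(t, -1, -2)))
    w, v = np.linalg.eigh(herm)
    n_bad = int(np.count_nonzero(w[..., 0] < 0))
    if n_bad:
        logger.info("projected %d pixels back to the PSD cone", n_bad)
        w = np.clip(w, 0.0, None)
        herm = np.einsum("...ij,...j,...kj->...ik", v, w, np.conj(v))
    return herm


def boxcar(raster: CoherencyRaster, window: int = 3) -> CoherencyRaster:
    """Sliding-window mean of every T3 element (edge-replicated borders)."""
    if window < 1:
        raise ValidationError("window must be >= 1")
    t = raster.data
    out = np.empty_like(t)
    for i in range(3):
        for j in range(3):
            out[..., i, j] = (
                ndimage.uniform_filter(t[..., i, j].real, size=window,
                                       mode="nearest")
                + 1j * ndimage.uniform_filter(t[..., i, j].imag, size=window,
                                              mode="nearest")
            )
    out = _project_psd(out)
    return CoherencyRaster(out, looks=raster.looks, metadata=dict(raster.metadata))


def _directional_kernels(window: int) -> np.ndarray:
    """Eight edge-aligned half-window masks of Lee's refined filter.

    Each mask keeps the half plane (including the central row/column/diagonal)
    on one side of one of four edge orientations.
    """
    half = window // 2
    yy, xx = np.mgrid[-half:half + 1, -half:half + 1]
    masks = [
        xx >= 0, xx <= 0,          # vertical edge, keep right / left
        yy >= 0, yy <= 0,          # horizontal edge, keep lower / upper
        yy >= xx, yy <= xx,        # 45-degree diagonal halves
        yy >= -xx, yy <= -xx,      # 135-degree diagonal halves
    ]
    return np.stack([m.astype(float) for m in masks])


def refined_lee(raster: CoherencyRaster, window: int = 7) -> CoherencyRaster:
    """Edge-aligned directional-window minimum-mean-square speckle filter.

    For each pixel the directional half-window with the lowest local Span
    variance is selected; within it the MMSE weight
    b = max(0, var(Span) - mean(Span)^2 sigma_v^2) / ((1 + sigma_v^2) var)
    (sigma_v^2 = 1/looks) scales the deviation of every T3 element from its
    local mean.  Spatially constant regions pass through unchanged.
    """
    if window < 3 or window % 2 == 0:
        raise ValidationError("window must be an odd integer >= 3")
    t = raster.data
    span = np.einsum("...ii", t).real
    kernels = _directional_kernels(window)
    n_dir = kernels.shape[0]
    counts = kernels.sum(axis=(1, 2))

    def dir_mean(img: np.ndarray, d: int) -> np.ndarray:
        return ndimage.correlate(img, kernels[d], mode="nearest") / counts[d]

    mean_s = np.stack([dir_mean(span, d) for d in range(n_dir)])
    mean_s2 = np.stack([dir_mean(span ** 2, d) for d in range(n_dir)])
    var_s = np.clip(mean_s2 - mean_s ** 2, 0.0, None)
    best = np.argmin(var_s, axis=0)
    sel = np.take_along_axis(var_s, best[None], axis=0)[0]
    mu = np.take_along_axis(mean_s, best[None], axis=0)[0]

    sigma_v2 = 1.0 / raster.looks
    num = np.clip(sel - mu ** 2 * sigma_v2, 0.0, None)
    den = (1.0 + sigma_v2) * sel
    with np.errstate(invalid="ignore", divide="ignore"):
        b = np.where(den > 0, num / den, 0.0)

    out = np.empty_like(t)
    for i in range(3):
        for j in range(3):
            ch = t[..., i, j]
            means = np.empty((n_dir,) + ch.shape, dtype=np.complex128)
            for d in range(n_dir):
                means[d] = (dir_mean(ch.real, d) + 1j * dir_mean(ch.imag, d))
            mu_ch = np.take_along_axis(means, best[None], axis=0)[0]
            out[..., i, j] = mu_ch + b * (ch - mu_ch)
    out = _project_psd(out)
    return CoherencyRaster(out, looks=raster.looks, metadata=dict(raster.metadata))


def pauli_rgb(raster: CoherencyRaster) -> PauliRGB:
    """Pauli power bands (T11, T22, T33); their sum equals the Span."""
    t = raster.data
    bands = np.stack([t[..., 0, 0].real, t[..., 1, 1].real, t[..., 2, 2].real],
                     axis=-1)
    return PauliRGB(np.clip(bands, 0.0, None), metadata=dict(raster.metadata))
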