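"""Polarimetric target decompositions: the 16-feature stack.

Every operation accepts either a single 3x3 coherency matrix or an array of
matrices with shape (..., 3, 3) and is vectorized over the leading axes.
Features and conventions:

* Cloude-Pottier H/A/alpha from the eigen-decomposition of T3.  Entropy uses
  base-3 logarithms so H is in [0, 1]; alpha angles are reported in degrees
  in [0, 90], with the mean alpha weighted by the pseudo-probabilities.
* RVI = 4 lambda_3 / (lambda_1 + lambda_2 + lambda_3) from the same
  eigenvalues.
* SERD/DERD from the co-polar eigenvalues under reflection symmetry: the
  single-bounce eigenvalue is the co-pol eigenvalue whose eigenvector alpha
  angle is <= 45 degrees.
* Yamaguchi four-component powers (2005 variant, helix from Im T23, volume
  branch chosen by the 10 log10(|SVV|^2/|SHH|^2) ratio at +-2 dB), with
  negative intermediate powers clamped and the deficit redistributed so the
  four powers sum exactly to the trace.
* Shannon entropy SE = ln(pi^3 e^3 det T3) with a determinant floor.
* Neumann parameters: particle anisotropy magnitude sqrt((T22+T33)/T11) and
  phase Arg(T12), orientation randomness tau = 1 - |T12|/(|delta| T11)
  clamped to [0, 1], and mean orientation psi from the circular-polarization
  estimator (1/4) atan2(2 Re T23, T22 - T33).
"""

from __future__ import annotations

import logging

import numpy as np

from .types import (
    FEATURE_NAMES,
    CoherencyRaster,
    FeatureRaster,
    UndefinedFeatureError,
)

logger = logging.getLogger(__name__)

#: Named feature subsets used in the feature-set comparison design.
FEATURE_SETS: dict[str, tuple[str, ...]] = {
    "all": FEATURE_NAMES,
    "fs": ("SE", "Y4_Vol", "Span", "Neu_tau", "Y4_Dbl", "Y4_Odd", "Y4_Hlx"),
    "ha-span": ("H", "A", "Span"),
    "neumann-span": ("Neu_tau", "Neu_pha", "Span"),
    "y4": ("Y4_Dbl", "Y4_Vol", "Y4_Odd", "Y4_Hlx"),
}

_DEG = 180.0 / np.pi


def _as_batch(t: np.ndarray) -> tuple[np.ndarray, tuple[int, ...], bool]:
    t = np.asarray(t, dtype=np.complex128)
    if t.shape[-2:] != (3, 3):
        raise ValueError("expected shape (..., 3, 3)")
    scalar = t.ndim == 2
    batch = t.reshape((-1, 3, 3))
    return batch, t.shape[:-2], scalar


def _unbatch(x: np.ndarray, shape: tuple[int, ...], scalar: bool):
    if scalar:
        return x[0] if x.ndim == 1 else x[0, ...]
    return x.reshape(shape + x.shape[1:])


def span(t: np.ndarray) -> np.ndarray | float:
    """Total power: trace of T3 (equal to the eigenvalue sum and to the
    Yamaguchi power sum by conservation)."""
    batch, shape, scalar = _as_batch(t)
    s = np.einsum("nii->n", batch).real
    out = _unbatch(s, shape, scalar)
    return float(out) if scalar else out


def _eigen(batch: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Eigenvalues descending (clamped >= 0) and matching alpha angles (deg)."""
    herm = 0.5 * (batch + np.conj(np.swapaxes(batch, -1, -2)))
    w, v = np.linalg.eigh(herm)
    w = np.clip(w[:, ::-1], 0.0, None)           # descending
    first = np.abs(v[:, 0, ::-1])                # |first component| per vector
    alpha = np.degrees(np.arccos(np.clip(first, 0.0, 1.0)))
    return w, alpha


def cloude_pottier(t: np.ndarray):
    """Entropy H (base-3), anisotropy A and mean alpha angle (degrees).

    Raises UndefinedFeatureError for a zero-trace matrix (scalar input);
    batched callers should mask such pixels instead.
    """
    batch, shape, scalar = _as_batch(t)
    w, alpha = _eigen(batch)
    total = w.sum(axis=1)
    if scalar and total[0] <= 0:
        raise UndefinedFeatureError("zero-trace matrix: H/A/alpha undefined")
    safe = np.maximum(total, np.finfo(float).tiny)
    p = w / safe[:, None]
    with np.errstate(divide="ignore", invalid="ignore"):
        logs = np.where(p > 0, np.log(np.maximum(p, np.finfo(float).tiny)), 0.0)
    h = -(p * logs).sum(axis=1) / np.log(3.0)
    h = np.clip(h, 0.0, 1.0)
    denom = w[:, 1] + w[:, 2]
    a = np.where(denom > 1e-15 * safe, (w[:, 1] - w[:, 2]) / np.maximum(denom, 1e-300), 0.0)
    mean_alpha = (p * alpha).sum(axis=1)
    out = tuple(_unbatch(x, shape, scalar) for x in (h, a, mean_alpha))
    return tuple(float(x) for x in out) if scalar else out


def rvi(t: np.ndarray):
    """Radar vegetation index 4 lambda_3 / (lambda_1+lambda_2+lambda_3)."""
    batch, shape, scalar = _as_batch(t)
    w, _ = _eigen(batch)
    total = w.sum(axis=1)
    if scalar and total[0] <= 0:
        raise UndefinedFeatureError("zero total power: RVI undefined")
    r = 4.0 * w[:, 2] / np.maximum(total, np.finfo(float).tiny)
    out = _unbatch(np.clip(r, 0.0, 4.0 / 3.0), shape, scalar)
    return float(out) if scalar else out


def copol_eigen(t: np.ndarray):
    """Co-polar eigenvalues (lam1' >= lam2', lam3' = 2<|SHV|^2>) and the
    alpha angles of the two co-pol eigenvectors, under reflection symmetry.

    Returns (lam1p, lam2p, lam3p, alpha1_deg, alpha2_deg).
    """
    batch, shape, scalar = _as_batch(t)
    t11 = batch[:, 0, 0].real
    t22 = batch[:, 1, 1].real
    t12 = batch[:, 0, 1]
    chh = 0.5 * (t11 + t22) + t12.real          # <|SHH|^2>
    cvv = 0.5 * (t11 + t22) - t12.real          # <|SVV|^2>
    cx = 0.5 * (t11 - t22) - 1j * t12.imag      # <SHH SVV*>
    tr2 = chh + cvv
    disc = np.sqrt((chh - cvv) ** 2 + 4.0 * np.abs(cx) ** 2)
    lam1 = np.clip(0.5 * (tr2 + disc), 0.0, None)
    lam2 = np.clip(0.5 * (tr2 - disc), 0.0, None)
    lam3 = np.clip(batch[:, 2, 2].real, 0.0, None)

    def copol_alpha(lam: np.ndarray) -> np.ndarray:
        # eigenvector of [[chh, cx], [cx*, cvv]] for eigenvalue lam
        u1 = np.where(np.abs(cx) > 0, cx, np.where(lam - cvv >= lam - chh, 1.0, 0.0))
        u2 = np.where(np.abs(cx) > 0, lam - chh,
                      np.where(lam - cvv >= lam - chh, 0.0, 1.0))
        norm = np.sqrt(np.abs(u1) ** 2 + np.abs(u2) ** 2)
        norm = np.maximum(norm, np.finfo(float).tiny)
        cosa = np.abs(u1 + u2) / (np.sqrt(2.0) * norm)
        return np.degrees(np.arccos(np.clip(cosa, 0.0, 1.0)))

    a1 = copol_alpha(lam1)
    a2 = copol_alpha(lam2)
    out = tuple(_unbatch(x, shape, scalar) for x in (lam1, lam2, lam3, a1, a2))
    return tuple(float(x) for x in out) if scalar else out


def serd_derd(t: np.ndarray):
    """Single- and double-bounce eigenvalue relative differences.

    The single-bounce co-pol eigenvalue lam_s is whichever of lam1', lam2'
    has eigenvector alpha <= 45 degrees (surface-like); the other is lam_d.
    SERD = (lam_s - lam3')/(lam_s + lam3'), DERD likewise for lam_d; a 0/0
    denominator yields 0 (logged).
    """
    batch, shape, scalar = _as_batch(t)
    lam1, lam2, lam3, a1, a2 = (np.atleast_1d(x) for x in copol_eigen(batch))

    single_is_1 = a1 <= 45.0 + 1e-12
    lam_s = np.where(single_is_1, lam1, lam2)
    lam_d = np.where(single_is_1, lam2, lam1)

    def ratio(num: np.ndarray) -> np.ndarray:
        den = num + lam3
        zero = den <= 0
        if np.any(zero):
            logger.debug("SERD/DERD 0/0 at %d pixels -> 0", int(zero.sum()))
        return np.where(zero, 0.0, (num - lam3) / np.where(zero, 1.0, den))

    serd = np.clip(ratio(lam_s), -1.0, 1.0)
    derd = np.clip(ratio(lam_d), -1.0, 1.0)
    out = tuple(_unbatch(x, shape, scalar) for x in (serd, derd))
    return tuple(float(x) for x in out) if scalar else out


# Unit-trace volume templates in the Pauli basis: balanced and the two
# skewed branches (|SHH| dominant / |SVV| dominant).
_TV_BAL = (0.5, 0.25, 0.25, 0.0)            # (T11, T22, T33, T12)
_TV_HH = (0.5, 7.0 / 30.0, 4.0 / 15.0, 1.0 / 6.0)
_TV_VV = (0.5, 7.0 / 30.0, 4.0 / 15.0, -1.0 / 6.0)


def yamaguchi4(t: np.ndarray):
    """Four-component powers (ps, pd, pv, ph): surface, double-bounce,
    volume and helix.

    Helix power ph = 2|Im T23|; the volume branch is selected by the co-pol
    ratio 10 log10(<|SVV|^2>/<|SHH|^2>) at +-2 dB; surface and double powers
    solve the residual co-pol system (Freeman-style dominant-mechanism
    split).  Negative intermediates are clamped to zero with the deficit
    redistributed, so ps+pd+pv+ph equals trace(T) exactly.
    """
    batch, shape, scalar = _as_batch(t)
    t11 = batch[:, 0, 0].real
    t22 = batch[:, 1, 1].real
    t33 = batch[:, 2, 2].real
    t12 = batch[:, 0, 1]
    t23 = batch[:, 1, 2]
    tp = t11 + t22 + t33

    # helix power cannot exceed the cross-pol power or the total power
    ph = 2.0 * np.abs(t23.imag)
    ph = np.minimum(np.minimum(ph, 2.0 * np.clip(t33, 0.0, None)), tp)

    chh = 0.5 * (t11 + t22) + t12.real
    cvv = 0.5 * (t11 + t22) - t12.real
    tiny = np.finfo(float).tiny
    ratio_db = 10.0 * (np.log10(np.maximum(cvv, tiny))
                       - np.log10(np.maximum(chh, tiny)))
    both_zero = (chh <= 0) & (cvv <= 0)
    ratio_db = np.where(both_zero, 0.0, ratio_db)

    branch = np.where(ratio_db < -2.0, 0, np.where(ratio_db > 2.0, 2, 1))
    tv = np.array([_TV_HH, _TV_BAL, _TV_VV])   # indexed by branch 0/1/2
    tv11, tv22, tv33, tv12 = (tv[branch, k] for k in range(4))

    pv = np.where(tv33 > 0, (t33 - 0.5 * ph) / tv33, 0.0)
    pv = np.clip(pv, 0.0, np.maximum(tp - ph, 0.0))

    s = t11 - pv * tv11
    d = t22 - pv * tv22 - 0.5 * ph
    c = t12 - pv * tv12

    # surface + double share the exact remaining power budget
    rem = np.clip(tp - ph - pv, 0.0, None)
    c2 = np.abs(c) ** 2
    surface_dom = c.real >= 0.0
    with np.errstate(divide="ignore", invalid="ignore"):
        ps_raw = np.where(
            surface_dom,
            np.where(s > 0, s + c2 / np.where(s > 0, s, 1.0), s),
            np.where(d > 0, s - c2 / np.where(d > 0, d, 1.0), s),
        )
    ps = np.clip(ps_raw, 0.0, rem)
    pd = rem - ps

    out = tuple(_unbatch(x, shape, scalar) for x in (ps, pd, pv, ph))
    return tuple(float(x) for x in out) if scalar else out


def shannon_entropy(t: np.ndarray):
    """SE = ln(pi^3 e^3 det T3), with det floored at 1e-30 trace^3 so the
    value stays finite for singular matrices (floor events logged)."""
    batch, shape, scalar = _as_batch(t)
    herm = 0.5 * (batch + np.conj(np.swapaxes(batch, -1, -2)))
    det = np.linalg.det(herm).real
    tr = np.einsum("nii->n", herm).real
    floor = 1e-30 * np.maximum(tr, np.finfo(float).tiny) ** 3
    n_floored = int(np.count_nonzero(det < floor))
    if n_floored:
        logger.debug("SE determinant floored at %d pixels", n_floored)
    det = np.maximum(det, floor)
    se = 3.0 * (1.0 + np.log(np.pi)) + np.log(det)
    out = _unbatch(se, shape, scalar)
    return float(out) if scalar else out


def neumann(t: np.ndarray, sqrt_delta: bool = True):
    """Neumann particle-cloud parameters (delta_mod, delta_pha, tau, psi).

    delta_mod = sqrt((T22+T33)/T11) (set ``sqrt_delta=False`` for the plain
    ratio reading, kept for sensitivity checks); delta_pha = Arg(T12);
    tau = 1 - |T12| / (delta_mod * T11) clamped to [0, 1]; psi is the
    circular-polarization orientation-angle estimate from T23.  A zero T11
    yields all-zero parameters (logged).
    """
    batch, shape, scalar = _as_batch(t)
    t11 = batch[:, 0, 0].real
    t22 = batch[:, 1, 1].real
    t33 = batch[:, 2, 2].real
    t12 = batch[:, 0, 1]
    t23 = batch[:, 1, 2]

    zero = t11 <= 0
    if np.any(zero):
        logger.debug("Neumann parameters zeroed at %d pixels (T11=0)",
                     int(zero.sum()))
    safe_t11 = np.where(zero, 1.0, t11)
    ratio = np.clip((t22 + t33), 0.0, None) / safe_t11
    dmod = np.sqrt(ratio) if sqrt_delta else ratio
    dpha = np.angle(t12)
    den = dmod * safe_t11
    tau = np.where(den > 0, 1.0 - np.abs(t12) / np.where(den > 0, den, 1.0), 0.0)
    tau = np.clip(tau, 0.0, 1.0)
    psi = 0.25 * np.arctan2(2.0 * t23.real, t22 - t33)
    for arr in (dmod, dpha, tau, psi):
        arr[zero] = 0.0
    out = tuple(_unbatch(x, shape, scalar) for x in (dmod, dpha, tau, psi))
    return tuple(float(x) for x in out) if scalar else out


def extract_feature_stack(raster: CoherencyRaster) -> FeatureRaster:
    """Compute all 16 features per pixel.

    Pixels where the features are undefined (zero trace) are masked and take
    the fill value (NaN); errors never abort the raster.
    """
    t = raster.data.reshape(-1, 3, 3)
    n = t.shape[0]
    tr = np.einsum("nii->n", t).real
    ok = tr > 0

    feats = np.full((n, len(FEATURE_NAMES)), np.nan)
    if np.any(ok):
        sub = t[ok]
        h, a, alpha = cloude_pottier(sub)
        ps, pd, pv, ph = yamaguchi4(sub)
        dmod, dpha, tau, psi = neumann(sub)
        serd, derd = serd_derd(sub)
        se = shannon_entropy(sub)
        sp = np.einsum("nii->n", sub).real
        r = rvi(sub)
        cols = {
            "H": h, "A": a, "a": alpha,
            "Y4_Dbl": pd, "Y4_Vol": pv, "Y4_Odd": ps, "Y4_Hlx": ph,
            "Neu_tau": tau, "Neu_psi": psi, "Neu_mod": dmod, "Neu_pha": dpha,
            "SERD": serd, "DERD": derd, "SE": se, "Span": sp, "RVI": r,
        }
        block = np.column_stack([cols[name] for name in FEATURE_NAMES])
        feats[ok] = block

    shape = raster.data.shape[:2]
    return FeatureRaster(feats.reshape(shape + (len(FEATURE_NAMES),)),
                         mask=ok.reshape(shape),
                         metadata=dict(raster.metadata))
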