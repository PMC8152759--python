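"""Polarimetric feature extraction: canonical targets, algebraic
identities, and an independent characteristic-polynomial eigensolver."""

from __future__ import annotations

import numpy as np
import pytest

from polwet.decomposition import (
    FEATURE_SETS,
    cloude_pottier,
    copol_eigen,
    extract_feature_stack,
    neumann,
    rvi,
    serd_derd,
    shannon_entropy,
    span,
    yamaguchi4,
)
from polwet.synthetic import ClassSpec, SceneLayout, generate_scene, sample_wishart
from polwet.types import FEATURE_NAMES, FEATURE_RANGES, UndefinedFeatureError
from conftest import random_psd

SURFACE = np.diag([1.0, 0.0, 0.0]).astype(complex)
DOUBLE = np.diag([0.0, 1.0, 0.0]).astype(complex)
VOLUME = np.diag([2.0, 1.0, 1.0]).astype(complex) / 4.0

H_VOLUME = -(0.5 * np.log(0.5) + 2 * 0.25 * np.log(0.25)) / np.log(3.0)


def cardano_eigvals(a: np.ndarray) -> np.ndarray:
    """Closed-form eigenvalues of a 3x3 Hermitian matrix (descending)."""
    p1 = abs(a[0, 1]) ** 2 + abs(a[0, 2]) ** 2 + abs(a[1, 2]) ** 2
    q = np.trace(a).real / 3.0
    if p1 == 0.0:
        return np.sort(np.diag(a).real)[::-1]
    p2 = sum((a[i, i].real - q) ** 2 for i in range(3)) + 2.0 * p1
    p = np.sqrt(p2 / 6.0)
    b = (a - q * np.eye(3)) / p
    r = np.clip(np.linalg.det(b).real / 2.0, -1.0, 1.0)
    phi = np.arccos(r) / 3.0
    e1 = q + 2.0 * p * np.cos(phi)
    e3 = q + 2.0 * p * np.cos(phi + 2.0 * np.pi / 3.0)
    return np.array([e1, 3.0 * q - e1 - e3, e3])


def null_vector(a: np.ndarray) -> np.ndarray:
    """A vector annihilated by the rank-deficient matrix ``a``."""
    best, bestn = None, -1.0
    for i, j in ((0, 1), (0, 2), (1, 2)):
        v = np.cross(a[i], a[j])
        n = np.linalg.norm(v)
        if n > bestn:
            best, bestn = v, n
    return best / bestn


class TestCanonicalTargets:
    def test_entropy_alpha_on_pure_mechanisms(self):
        h, a, alpha = cloude_pottier(SURFACE)
        assert abs(h) <= 1e-12 and abs(alpha) <= 1e-8
        h, a, alpha = cloude_pottier(DOUBLE)
        assert abs(h) <= 1e-12 and abs(alpha - 90.0) <= 1e-8

    def test_volume_entropy_anisotropy_alpha(self):
        h, a, alpha = cloude_pottier(VOLUME)
        np.testing.assert_allclose(h, H_VOLUME, atol=1e-12)
        np.testing.assert_allclose(h, 0.9464, atol=1e-4)
        assert a == 0.0
        np.testing.assert_allclose(alpha, 45.0, atol=1e-8)

    @pytest.mark.parametrize("t,expected", [
        (SURFACE, 0.0), (VOLUME, 1.0),
        (np.diag([1.0, 1.0, 1.0]).astype(complex), 4.0 / 3.0),
    ])
    def test_rvi(self, t, expected):
        np.testing.assert_allclose(rvi(t), expected, atol=1e-12)

    @pytest.mark.parametrize("t,expected", [
        (SURFACE, (1.0, 0.0, 0.0, 0.0)),
        (DOUBLE, (0.0, 1.0, 0.0, 0.0)),
        (4.0 * VOLUME, (0.0, 0.0, 4.0, 0.0)),
    ])
    def test_yamaguchi_pure_mechanisms(self, t, expected):
        np.testing.assert_allclose(yamaguchi4(t), expected, atol=1e-12)

    def test_shannon_entropy_closed_forms(self):
        np.testing.assert_allclose(shannon_entropy(np.eye(3, dtype=complex)),
                                   3.0 * (1.0 + np.log(np.pi)), rtol=1e-12)
        np.testing.assert_allclose(shannon_entropy(VOLUME),
                                   np.log(np.pi ** 3 * np.e ** 3 / 32.0),
                                   rtol=1e-12)

    def test_shannon_entropy_floor_is_finite(self):
        assert np.isfinite(shannon_entropy(SURFACE))

    def test_serd_derd_canon(self):
        # surface: single-bounce dominant, cross-pol zero; DERD hits 0/0 -> 0
        np.testing.assert_allclose(serd_derd(2.0 * SURFACE), (1.0, 0.0),
                                   atol=1e-12)
        # equal co- and cross-pol eigenvalues
        np.testing.assert_allclose(
            serd_derd(np.eye(3, dtype=complex)), (0.0, 0.0), atol=1e-12)
        # volume template: lam' = (1/2, 1/4), lam3' = 1/4
        np.testing.assert_allclose(serd_derd(VOLUME), (1.0 / 3.0, 0.0),
                                   atol=1e-12)

    def test_neumann_canon(self):
        d = 0.5
        dipole = np.array([[1, d, 0], [d, d * d, 0], [0, 0, 0]], dtype=complex)
        dmod, dpha, tau, _ = neumann(dipole)
        np.testing.assert_allclose((dmod, tau), (0.5, 0.0), atol=1e-12)
        dmod, _, tau, _ = neumann(VOLUME)
        np.testing.assert_allclose((dmod, tau), (1.0, 1.0), atol=1e-12)

    def test_neumann_phase(self):
        t = np.array([[1.0, 0.3j, 0], [-0.3j, 0.5, 0], [0, 0, 0.1]],
                     dtype=complex)
        assert np.isclose(neumann(t)[1], np.pi / 2)

    def test_neumann_non_sqrt_variant(self):
        dmod_sqrt = neumann(VOLUME, sqrt_delta=True)[0]
        dmod_plain = neumann(VOLUME, sqrt_delta=False)[0]
        assert np.isclose(dmod_sqrt ** 2, dmod_plain)


class TestCopolEigen:
    def test_trihedral(self):
        # SHH = SVV deterministic: co-pol matrix [[1,1],[1,1]]
        t = np.zeros((3, 3), dtype=complex)
        t[0, 0] = 2.0
        lam1, lam2, lam3, a1, a2 = copol_eigen(t)
        np.testing.assert_allclose((lam1, lam2, lam3), (2.0, 0.0, 0.0),
                                   atol=1e-12)
        assert a1 < 1e-3  # surface-like eigenvector

    def test_cross_pol_only(self):
        t = np.diag([0.0, 0.0, 0.8]).astype(complex)
        lam1, lam2, lam3, _, _ = copol_eigen(t)
        np.testing.assert_allclose((lam1, lam2, lam3), (0.0, 0.0, 0.8),
                                   atol=1e-12)

    def test_copol_eigenvalue_sum_is_span(self, rng):
        t = random_psd(rng, 500)
        lam1, lam2, lam3, _, _ = copol_eigen(t)
        np.testing.assert_allclose(lam1 + lam2 + lam3, span(t), rtol=1e-9)

    def test_serd_derd_bounded(self, rng):
        t = random_psd(rng, 1000)
        serd, derd = serd_derd(t)
        assert np.all((serd >= -1) & (serd <= 1))
        assert np.all((derd >= -1) & (derd <= 1))


class TestAlgebraicInvariants:
    def test_eigensolver_against_characteristic_polynomial(self, rng):
        """H/A/alpha computed via the generic eigensolver must agree with a
        closed-form Cardano solver plus explicit null-space eigenvectors."""
        t = random_psd(rng, 1000)
        h_impl, a_impl, alpha_impl = cloude_pottier(t)
        for k in range(t.shape[0]):
            w = cardano_eigvals(t[k])
            p = w / w.sum()
            h = -(p * np.log(np.maximum(p, 1e-300))).sum() / np.log(3.0)
            a = (w[1] - w[2]) / (w[1] + w[2]) if w[1] + w[2] > 0 else 0.0
            alphas = []
            for lam in w:
                v = null_vector(t[k] - lam * np.eye(3))
                alphas.append(np.degrees(np.arccos(min(abs(v[0]), 1.0))))
            alpha = float(np.dot(p, alphas))
            assert abs(h - h_impl[k]) < 1e-8
            assert abs(a - a_impl[k]) < 1e-8
            assert abs(alpha - alpha_impl[k]) < 1e-6

    def test_power_conservation(self, rng):
        t = random_psd(rng, 2000)
        ps, pd, pv, ph = yamaguchi4(t)
        total = span(t)
        np.testing.assert_allclose(ps + pd + pv + ph, total, rtol=1e-9)
        w = np.linalg.eigvalsh(t)
        np.testing.assert_allclose(w.sum(axis=1), total, rtol=1e-9)

    def test_rotation_invariance(self, rng):
        """H, A, alpha, Span, SE and RVI are invariant under an antenna-axis
        rotation of the coherency matrix."""
        t = random_psd(rng, 100)
        psi = 0.3
        c, s = np.cos(2 * psi), np.sin(2 * psi)
        r = np.array([[1, 0, 0], [0, c, -s], [0, s, c]], dtype=complex)
        t_rot = np.einsum("ij,njk,lk->nil", r, t, r.conj())
        for f in (lambda x: np.column_stack(cloude_pottier(x)),
                  lambda x: span(x)[:, None],
                  lambda x: np.asarray(shannon_entropy(x))[:, None],
                  lambda x: np.asarray(rvi(x))[:, None]):
            np.testing.assert_allclose(f(t_rot), f(t), atol=1e-8)

    def test_entropy_increases_with_mechanism_mixing(self):
        hs = []
        for w in np.linspace(0.0, 0.5, 11):
            h, _, _ = cloude_pottier((1 - w) * SURFACE + w * DOUBLE)
            hs.append(h)
        assert all(b > a for a, b in zip(hs, hs[1:]))

    def test_zero_trace_raises(self):
        with pytest.raises(UndefinedFeatureError):
            cloude_pottier(np.zeros((3, 3), dtype=complex))


class TestFeatureStack:
    def test_band_names_and_sets(self):
        assert len(FEATURE_NAMES) == 16
        assert set(FEATURE_SETS["fs"]) == {
            "SE", "Y4_Vol", "Span", "Neu_tau", "Y4_Dbl", "Y4_Odd", "Y4_Hlx"}
        for names in FEATURE_SETS.values():
            assert set(names) <= set(FEATURE_NAMES)

    def test_surface_patch_statistics(self):
        labels = np.full((24, 24), "beach")
        spec = {"beach": ClassSpec("beach", {"surface": 1.0}, power=2.0)}
        scene, _ = generate_scene(SceneLayout(labels), spec, looks=64, seed=9)
        stack = extract_feature_stack(scene)
        assert stack.band("H").mean() < 0.3
        assert stack.band("a").mean() < 15.0
        np.testing.assert_allclose(stack.band("Y4_Odd").mean(),
                                   stack.band("Span").mean(), rtol=0.05)
        assert stack.band("Neu_tau").mean() < 0.3

    def test_ranges_hold_on_random_speckle(self, rng):
        sigma = random_psd(rng, 1)[0]
        t = sample_wishart(sigma, looks=2, n=400, seed=11).reshape(20, 20, 3, 3)
        from polwet.types import CoherencyRaster
        stack = extract_feature_stack(CoherencyRaster(t, looks=2))
        for name, (lo, hi) in FEATURE_RANGES.items():
            band = stack.band(name)[stack.mask]
            assert band.min() >= lo - 1e-9, name
            assert band.max() <= hi + 1e-9, name

    def test_degenerate_pixels_masked(self):
        t = np.tile(np.diag([1.0, 0.5, 0.2]).astype(complex), (2, 2, 1, 1))
        t[0, 0] = 0.0
        from polwet.types import CoherencyRaster
        stack = extract_feature_stack(CoherencyRaster(t))
        assert not stack.mask[0, 0]
        assert np.isnan(stack.data[0, 0]).all()
        assert stack.mask[1, 1]
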