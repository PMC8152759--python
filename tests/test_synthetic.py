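"""Scene simulator: mechanism templates, particle-cloud volume model,
Wishart speckle statistics."""

from __future__ import annotations

import numpy as np
import pytest
from scipy.special import i0

from polwet.synthetic import (
    ClassSpec,
    SceneLayout,
    default_class_specs,
    default_scene,
    generate_scene,
    kappa_to_tau,
    mechanism_covariance,
    neumann_volume_covariance,
    sample_wishart,
)
from polwet.types import CLASS_NAMES, ValidationError


class TestMechanismTemplates:
    def test_surface_and_double_axes(self):
        np.testing.assert_array_equal(mechanism_covariance("surface"),
                                      np.diag([1, 0, 0]))
        np.testing.assert_array_equal(mechanism_covariance("double"),
                                      np.diag([0, 1, 0]))

    def test_all_templates_unit_trace_psd(self):
        for kind in ("surface", "double", "volume", "helix"):
            t = mechanism_covariance(kind)
            assert np.isclose(np.trace(t).real, 1.0)
            assert np.linalg.eigvalsh(t).min() >= -1e-12

    def test_helix_is_rank_one(self):
        w = np.linalg.eigvalsh(mechanism_covariance("helix"))
        np.testing.assert_allclose(sorted(w), [0.0, 0.0, 1.0], atol=1e-12)

    def test_unknown_kind(self):
        with pytest.raises(ValueError):
            mechanism_covariance("sphere")


class TestNeumannVolume:
    def test_aligned_dipole_cloud(self):
        # tau=0, delta=1: coherent dipole, rank-1 in the co-pol subspace
        expected = 0.5 * np.array([[1, 1, 0], [1, 1, 0], [0, 0, 0]])
        np.testing.assert_allclose(neumann_volume_covariance(1.0, 0.0),
                                   expected, atol=1e-15)

    @pytest.mark.parametrize("delta", [0.5, 1.0, 2.0 + 1.0j])
    def test_fully_random_orientation_kills_correlation(self, delta):
        t = neumann_volume_covariance(delta, 1.0)
        assert abs(t[0, 1]) == 0.0

    @pytest.mark.parametrize("tau", [0.0, 0.3, 0.7, 1.0])
    def test_isotropic_particle_is_pure_surface(self, tau):
        np.testing.assert_allclose(neumann_volume_covariance(0.0, tau),
                                   np.diag([1.0, 0.0, 0.0]), atol=1e-15)

    @pytest.mark.parametrize("tau", [0.1, 0.5, 0.9])
    def test_unit_trace_hermitian_psd(self, tau):
        t = neumann_volume_covariance(0.7 + 0.2j, tau)
        np.testing.assert_allclose(t, t.conj().T, atol=1e-15)
        assert np.isclose(np.trace(t).real, 1.0)
        assert np.linalg.eigvalsh(t).min() >= -1e-12

    def test_tau_out_of_range(self):
        with pytest.raises(ValidationError):
            neumann_volume_covariance(1.0, 1.5)


class TestKappaToTau:
    def test_limits_and_value(self):
        assert kappa_to_tau(0.0) == 1.0
        assert kappa_to_tau(50.0) < 0.06
        np.testing.assert_allclose(kappa_to_tau(1.0), i0(1.0) * np.exp(-1.0),
                                   rtol=1e-12)
        np.testing.assert_allclose(kappa_to_tau(1.0), 0.4658, atol=5e-5)

    def test_strictly_decreasing(self):
        grid = np.linspace(0.0, 10.0, 101)
        vals = [kappa_to_tau(k) for k in grid]
        assert all(a > b for a, b in zip(vals, vals[1:]))

    def test_negative_kappa(self):
        with pytest.raises(ValidationError):
            kappa_to_tau(-0.1)


class TestWishart:
    SIGMA = np.array([[2.0, 0.4 + 0.1j, 0.0],
                      [0.4 - 0.1j, 1.0, 0.2j],
                      [0.0, -0.2j, 0.5]])

    def test_single_look_rank_one(self):
        s = sample_wishart(self.SIGMA, looks=1, n=50, seed=0)
        ranks = np.linalg.matrix_rank(s, tol=1e-10)
        assert np.all(ranks == 1)

    def test_mean_converges_to_sigma(self):
        n, looks = 10_000, 4
        s = sample_wishart(self.SIGMA, looks=looks, n=n, seed=1)
        mean = s.mean(axis=0)
        # element std err ~ sigma_ii / sqrt(n * looks); 3-sigma band
        se = np.sqrt(np.outer(np.diag(self.SIGMA).real,
                              np.diag(self.SIGMA).real) / (n * looks))
        assert np.all(np.abs(mean - self.SIGMA) <= 3.0 * se + 1e-12)

    def test_determinism(self):
        a = sample_wishart(self.SIGMA, looks=4, n=10, seed=42)
        b = sample_wishart(self.SIGMA, looks=4, n=10, seed=42)
        np.testing.assert_array_equal(a, b)

    def test_samples_hermitian_psd(self):
        s = sample_wishart(self.SIGMA, looks=3, n=200, seed=2)
        np.testing.assert_allclose(s, np.conj(np.swapaxes(s, -1, -2)),
                                   atol=1e-12)
        assert np.linalg.eigvalsh(s).min() >= -1e-10

    def test_non_psd_sigma_rejected(self):
        with pytest.raises(ValidationError):
            sample_wishart(np.diag([1.0, -1.0, 1.0]).astype(complex),
                           looks=4, n=1, seed=0)


class TestSceneGeneration:
    def test_two_patch_means_recover_covariances(self, two_patch_scene):
        scene, truth = two_patch_scene
        surf = scene.data[np.asarray(truth) == "beach"].mean(axis=0)
        dbl = scene.data[np.asarray(truth) == "road"].mean(axis=0)
        np.testing.assert_allclose(surf, np.diag([2.0, 0, 0]), atol=0.1)
        np.testing.assert_allclose(dbl, np.diag([0, 2.0, 0]), atol=0.1)

    def test_variance_shrinks_with_looks(self):
        labels = np.full((40, 40), "beach")
        layout = SceneLayout(labels)
        spec = {"beach": ClassSpec("beach", {"surface": 1.0}, power=1.0)}
        variances = []
        for looks in (4, 16, 64):
            scene, _ = generate_scene(layout, spec, looks=looks, seed=3)
            variances.append(scene.span().var())
        assert variances[0] > variances[1] > variances[2]

    def test_truth_partitions_grid(self):
        scene, truth = default_scene(48, 48, tile=16, looks=4, seed=0)
        assert truth.shape == (48, 48)
        assert set(np.unique(truth)) <= set(CLASS_NAMES)
        assert scene.looks == 4

    def test_missing_class_spec_rejected(self):
        layout = SceneLayout(np.full((4, 4), "beach"))
        with pytest.raises(ValidationError, match="beach"):
            generate_scene(layout, {}, looks=4, seed=0)

    def test_default_specs_cover_all_classes(self):
        specs = default_class_specs()
        assert set(specs) == set(CLASS_NAMES)
        for spec in specs.values():
            t = spec.covariance()
            np.testing.assert_allclose(np.trace(t).real, spec.power, rtol=1e-12)
            assert np.linalg.eigvalsh(t).min() >= -1e-12
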