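"""Shared fixtures: random PSD coherency matrices and small scenes."""

from __future__ import annotations

import numpy as np
import pytest

from polwet.synthetic import ClassSpec, SceneLayout, generate_scene


def random_psd(rng: np.random.Generator, n: int = 1,
               scale: float = 1.0) -> np.ndarray:
    """Random 3x3 Hermitian PSD matrices of shape (n, 3, 3)."""
    a = rng.standard_normal((n, 3, 3)) + 1j * rng.standard_normal((n, 3, 3))
    return scale * np.einsum("nij,nkj->nik", a, np.conj(a)) / 3.0


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)


@pytest.fixture
def two_patch_scene():
    """64x64 scene: left surface-dominated, right double-bounce, L=16."""
    labels = np.empty((64, 64), dtype=object)
    labels[:, :32] = "beach"
    labels[:, 32:] = "road"
    layout = SceneLayout(labels.astype(str))
    specs = {
        "beach": ClassSpec("beach", {"surface": 1.0}, power=2.0),
        "road": ClassSpec("road", {"double": 1.0}, power=2.0),
    }
    return generate_scene(layout, specs, looks=16, seed=7)
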