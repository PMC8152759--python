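"""Core data model shared by every stage of the pipeline.

All rasters are stored row-major with the origin at the top-left pixel;
coordinates are 0-based and windows are half-open.  Coherency matrices are
kept in double precision in memory (on disk they are 32-bit float per band).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any

import numpy as np
import pandas as pd

#: Band names of the 16-feature stack, in canonical order.
FEATURE_NAMES: tuple[str, ...] = (
    "H", "A", "a",
    "Y4_Dbl", "Y4_Vol", "Y4_Odd", "Y4_Hlx",
    "Neu_tau", "Neu_psi", "Neu_mod", "Neu_pha",
    "SERD", "DERD", "SE", "Span", "RVI",
)

#: The seven-class coastal wetland scheme, in confusion-table order.
CLASS_NAMES: tuple[str, ...] = (
    "beach",
    "Suaeda salsa",
    "Spartina alterniflora",
    "road",
    "water",
    "irrigable land",
    "rice paddy",
)

HERMITIAN_RTOL = 1e-9
PSD_RTOL = 1e-9


class ValidationError(ValueError):
    """An input violates a structural invariant of the data model."""


class FormatError(IOError):
    """An on-disk artifact is missing a part or is malformed."""


class UndefinedFeatureError(ValueError):
    """A polarimetric feature is undefined for the given matrix (zero power)."""


@dataclass
class ScatteringImage:
    """Single-look complex scattering vectors (SHH, SHV, SVV) per pixel.

    Monostatic reciprocity (SHV = SVH) is assumed, so only one cross-pol
    channel is stored.  Amplitudes are in linear units.
    """

    shh: np.ndarray
    shv: np.ndarray
    svv: np.ndarray
    metadata: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.shh = np.asarray(self.shh, dtype=np.complex128)
        self.shv = np.asarray(self.shv, dtype=np.complex128)
        self.svv = np.asarray(self.svv, dtype=np.complex128)
        if not (self.shh.shape == self.shv.shape == self.svv.shape):
            raise ValidationError("SHH, SHV, SVV must share one shape")
        if self.shh.ndim != 2:
            raise ValidationError("scattering channels must be 2-D rasters")
        for name, ch in (("SHH", self.shh), ("SHV", self.shv), ("SVV", self.svv)):
            if not np.all(np.isfinite(ch)):
                raise ValidationError(f"non-finite values in {name}")

    @property
    def rows(self) -> int:
        return self.shh.shape[0]

    @property
    def cols(self) -> int:
        return self.shh.shape[1]


@dataclass
class CoherencyRaster:
    """Per-pixel 3x3 Hermitian PSD coherency matrix T3 in the Pauli basis.

    ``data`` has shape (rows, cols, 3, 3), complex128, linear power units.
    ``looks`` is the number of independent looks averaged into each matrix.
    """

    data: np.ndarray
    looks: int = 1
    metadata: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.data = np.ascontiguousarray(self.data, dtype=np.complex128)
        if self.data.ndim != 4 or self.data.shape[2:] != (3, 3):
            raise ValidationError("coherency data must have shape (rows, cols, 3, 3)")
        if int(self.looks) < 1:
            raise ValidationError("looks must be a positive integer")
        self.looks = int(self.looks)
        self.validate()

    @property
    def rows(self) -> int:
        return self.data.shape[0]

    @property
    def cols(self) -> int:
        return self.data.shape[1]

    def validate(self) -> None:
        """Check Hermitian symmetry and numerical positive semidefiniteness.

        Violations are rejected, never silently repaired.
        """
        t = self.data
        if not np.all(np.isfinite(t.view(np.float64))):
            raise ValidationError("non-finite coherency values")
        tr = np.einsum("...ii", t).real
        if np.any(tr < -PSD_RTOL * np.maximum(tr.max(initial=0.0), 1.0)):
            idx = tuple(int(i) for i in np.unravel_index(int(np.argmin(tr)), tr.shape))
            raise ValidationError(f"negative trace at pixel {idx}")
        scale = np.maximum(tr, np.finfo(float).tiny)
        asym = np.abs(t - np.conj(np.swapaxes(t, -1, -2))).max(axis=(-1, -2))
        bad = asym > HERMITIAN_RTOL * scale
        if np.any(bad):
            idx = tuple(int(i) for i in np.unravel_index(int(np.argmax(asym / scale)), asym.shape))
            raise ValidationError(f"non-Hermitian matrix at pixel {idx}")
        herm = 0.5 * (t + np.conj(np.swapaxes(t, -1, -2)))
        ev = np.linalg.eigvalsh(herm)
        if np.any(ev[..., 0] < -PSD_RTOL * scale):
            rel = ev[..., 0] / scale
            idx = tuple(int(i) for i in np.unravel_index(int(np.argmin(rel)), rel.shape))
            raise ValidationError(f"matrix not positive semidefinite at pixel {idx}")

    def span(self) -> np.ndarray:
        """Total power (trace of T3) per pixel."""
        return np.einsum("...ii", self.data).real


@dataclass
class PauliRGB:
    """The three Pauli powers |a|^2 = T11, |b|^2 = T22, |c|^2 = T33."""

    bands: np.ndarray  # (rows, cols, 3), non-negative
    metadata: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.bands = np.asarray(self.bands, dtype=np.float64)
        if self.bands.ndim != 3 or self.bands.shape[2] != 3:
            raise ValidationError("Pauli RGB must have shape (rows, cols, 3)")
        if np.any(self.bands < -1e-12 * max(self.bands.max(initial=0.0), 1.0)):
            raise ValidationError("Pauli bands must be non-negative")

    @property
    def rows(self) -> int:
        return self.bands.shape[0]

    @property
    def cols(self) -> int:
        return self.bands.shape[1]


#: Hard range constraints checked for every unmasked feature pixel.
FEATURE_RANGES: dict[str, tuple[float, float]] = {
    "H": (0.0, 1.0),
    "A": (0.0, 1.0),
    "a": (0.0, 90.0),
    "Y4_Dbl": (0.0, np.inf),
    "Y4_Vol": (0.0, np.inf),
    "Y4_Odd": (0.0, np.inf),
    "Y4_Hlx": (0.0, np.inf),
    "Neu_tau": (0.0, 1.0),
    "SERD": (-1.0, 1.0),
    "DERD": (-1.0, 1.0),
    "Span": (0.0, np.inf),
    "RVI": (0.0, 4.0 / 3.0),
}


@dataclass
class FeatureRaster:
    """Stack of the 16 polarimetric features, plus a validity mask.

    ``data`` has shape (rows, cols, 16) in FEATURE_NAMES order; ``mask`` is
    True where all features are defined.  Masked pixels hold ``fill``.
    """

    data: np.ndarray
    mask: np.ndarray | None = None
    fill: float = np.nan
    metadata: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        if self.data.ndim != 3 or self.data.shape[2] != len(FEATURE_NAMES):
            raise ValidationError(
                f"feature stack must have {len(FEATURE_NAMES)} bands"
            )
        if self.mask is None:
            self.mask = np.ones(self.data.shape[:2], dtype=bool)
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.mask.shape != self.data.shape[:2]:
            raise ValidationError("mask shape must match raster shape")

    @property
    def rows(self) -> int:
        return self.data.shape[0]

    @property
    def cols(self) -> int:
        return self.data.shape[1]

    @property
    def band_names(self) -> tuple[str, ...]:
        return FEATURE_NAMES

    def band(self, name: str) -> np.ndarray:
        return self.data[..., FEATURE_NAMES.index(name)]


SAMPLE_COLUMNS = ("id",) + FEATURE_NAMES + ("label", "split")


def validate_sample_table(df: pd.DataFrame) -> pd.DataFrame:
    """Normalize a sample table to canonical column order and validate it.

    Raises ValidationError on unknown class labels, missing columns or
    missing feature values.
    """
    missing = [c for c in SAMPLE_COLUMNS if c not in df.columns]
    if missing:
        raise ValidationError(f"sample table missing columns: {missing}")
    df = df.loc[:, list(SAMPLE_COLUMNS)].copy()
    bad = set(df["label"].unique()) - set(CLASS_NAMES)
    if bad:
        raise ValidationError(
            f"unknown class labels {sorted(bad)}; allowed: {list(CLASS_NAMES)}"
        )
    bad_split = set(df["split"].unique()) - {"train", "test"}
    if bad_split:
        raise ValidationError(f"unknown split tags {sorted(bad_split)}")
    feats = df.loc[:, list(FEATURE_NAMES)].to_numpy(dtype=float)
    if not np.all(np.isfinite(feats)):
        raise ValidationError("sample table contains missing feature values")
    return df
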