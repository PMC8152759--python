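"""Readers and writers for coherency rasters and labeled sample tables.

Two raster dialects are supported:

``envi-t3``
    A PolSARpro-style T3 directory: nine flat little-endian float32 binaries
    (``T11.bin``, ``T12_real.bin``, ``T12_imag.bin``, ``T13_real.bin``,
    ``T13_imag.bin``, ``T22.bin``, ``T23_real.bin``, ``T23_imag.bin``,
    ``T33.bin``), one ENVI ``.hdr`` per band, and a ``config.txt`` holding
    the raster dimensions and look count.

``multiband-tiff``
    A single 9-band float32 TIFF in the band order
    T11, T12_real, T12_imag, T13_real, T13_imag, T22, T23_real, T23_imag,
    T33, with looks and pass-through metadata in the ImageDescription tag.

Only the six independent elements of the Hermitian T3 are stored; the lower
triangle is reconstructed on read.  Sample tables are plain CSV.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from .types import (
    SAMPLE_COLUMNS,
    CoherencyRaster,
    FormatError,
    validate_sample_table,
)

T3_ELEMENTS = (
    "T11", "T12_real", "T12_imag", "T13_real", "T13_imag",
    "T22", "T23_real", "T23_imag", "T33",
)

DIALECTS = ("envi-t3", "multiband-tiff")


def _t3_to_bands(raster: CoherencyRaster) -> np.ndarray:
    t = raster.data
    bands = np.stack(
        [
            t[..., 0, 0].real, t[..., 0, 1].real, t[..., 0, 1].imag,
            t[..., 0, 2].real, t[..., 0, 2].imag,
            t[..., 1, 1].real, t[..., 1, 2].real, t[..., 1, 2].imag,
            t[..., 2, 2].real,
        ]
    )
    return bands.astype(np.float32)


def _bands_to_t3(bands: np.ndarray, looks: int, metadata: dict) -> CoherencyRaster:
    b = bands.astype(np.float64)
    rows, cols = b.shape[1:]
    t = np.zeros((rows, cols, 3, 3), dtype=np.complex128)
    t[..., 0, 0] = b[0]
    t[..., 0, 1] = b[1] + 1j * b[2]
    t[..., 0, 2] = b[3] + 1j * b[4]
    t[..., 1, 1] = b[5]
    t[..., 1, 2] = b[6] + 1j * b[7]
    t[..., 2, 2] = b[8]
    t[..., 1, 0] = np.conj(t[..., 0, 1])
    t[..., 2, 0] = np.conj(t[..., 0, 2])
    t[..., 2, 1] = np.conj(t[..., 1, 2])
    return CoherencyRaster(t, looks=looks, metadata=metadata)


def _write_envi_header(path: Path, rows: int, cols: int) -> None:
    path.write_text(
        "ENVI\n"
        f"samples = {cols}\n"
        f"lines = {rows}\n"
        "bands = 1\n"
        "data type = 4\n"
        "interleave = bsq\n"
        "byte order = 0\n"
    )


def _read_envi_header(path: Path) -> tuple[int, int]:
    rows = cols = None
    for line in path.read_text().splitlines():
        if "=" in line:
            key, _, val = line.partition("=")
            key = key.strip().lower()
            if key == "samples":
                cols = int(val)
            elif key == "lines":
                rows = int(val)
    if rows is None or cols is None:
        raise FormatError(f"ENVI header {path} lacks samples/lines")
    return rows, cols


def write_t3_raster(raster: CoherencyRaster, path: str | Path,
                    dialect: str = "envi-t3") -> Path:
    """Write a coherency raster; returns the path written.

    The on-disk representation round-trips through :func:`read_t3_raster`
    for the same dialect (band values are stored as float32).
    """
    path = Path(path)
    bands = _t3_to_bands(raster)
    if dialect == "envi-t3":
        path.mkdir(parents=True, exist_ok=True)
        for name, band in zip(T3_ELEMENTS, bands):
            (path / f"{name}.bin").write_bytes(band.tobytes())
            _write_envi_header(path / f"{name}.bin.hdr", raster.rows, raster.cols)
        config = (
            "Nrow\n"
            f"{raster.rows}\n"
            "---------\n"
            "Ncol\n"
            f"{raster.cols}\n"
            "---------\n"
            "PolarCase\n"
            "monostatic\n"
            "---------\n"
            "PolarType\n"
            "full\n"
            "---------\n"
            "Nlook\n"
            f"{raster.looks}\n"
        )
        (path / "config.txt").write_text(config)
        if raster.metadata:
            (path / "metadata.json").write_text(
                json.dumps(raster.metadata, default=str)
            )
        return path
    if dialect == "multiband-tiff":
        desc = json.dumps({"looks": raster.looks, "metadata": raster.metadata},
                          default=str)
        path.parent.mkdir(parents=True, exist_ok=True)
        tifffile.imwrite(path, bands, description=desc)
        return path
    raise ValueError(f"unknown dialect {dialect!r}; expected one of {DIALECTS}")


def read_t3_raster(path: str | Path, dialect: str = "envi-t3") -> CoherencyRaster:
    """Read a coherency raster written by :func:`write_t3_raster`.

    Hermitian symmetry is reconstructed from the six independent elements;
    the CoherencyRaster invariants (Hermitian, PSD, trace >= 0) are enforced
    on the result.
    """
    path = Path(path)
    if dialect == "envi-t3":
        if not path.is_dir():
            raise FormatError(f"{path} is not a T3 directory")
        config = path / "config.txt"
        if not config.exists():
            raise FormatError(f"missing config.txt in {path}")
        fields = _parse_config(config.read_text())
        rows, cols = int(fields["Nrow"]), int(fields["Ncol"])
        looks = int(fields.get("Nlook", 1))
        bands = np.empty((9, rows, cols), dtype=np.float32)
        for i, name in enumerate(T3_ELEMENTS):
            binpath = path / f"{name}.bin"
            if not binpath.exists():
                raise FormatError(f"missing T3 element {name.split('_')[0]} "
                                  f"({binpath.name})")
            hdr = path / f"{name}.bin.hdr"
            if hdr.exists():
                hrows, hcols = _read_envi_header(hdr)
                if (hrows, hcols) != (rows, cols):
                    raise FormatError(f"header/config size mismatch for {name}")
            raw = np.frombuffer(binpath.read_bytes(), dtype=np.float32)
            if raw.size != rows * cols:
                raise FormatError(f"{name}.bin has {raw.size} values, "
                                  f"expected {rows * cols}")
            bands[i] = raw.reshape(rows, cols)
        meta_path = path / "metadata.json"
        metadata = json.loads(meta_path.read_text()) if meta_path.exists() else {}
        return _bands_to_t3(bands, looks, metadata)
    if dialect == "multiband-tiff":
        if not path.exists():
            raise FormatError(f"missing raster file {path}")
        with tifffile.TiffFile(path) as tif:
            bands = tif.asarray()
            desc = tif.pages[0].description
        if bands.ndim != 3 or bands.shape[0] != 9:
            raise FormatError(f"{path} must have 9 bands, got shape {bands.shape}")
        looks, metadata = 1, {}
        if desc:
            try:
                info = json.loads(desc)
                looks = int(info.get("looks", 1))
                metadata = info.get("metadata", {})
            except (json.JSONDecodeError, TypeError, ValueError):
                pass
        return _bands_to_t3(bands, looks, metadata)
    raise ValueError(f"unknown dialect {dialect!r}; expected one of {DIALECTS}")


def _parse_config(text: str) -> dict[str, str]:
    fields: dict[str, str] = {}
    lines = [ln.strip() for ln in text.splitlines()
             if ln.strip() and not set(ln.strip()) <= {"-"}]
    for key, val in zip(lines[::2], lines[1::2]):
        fields[key] = val
    return fields


def write_samples(table: pd.DataFrame, path: str | Path) -> Path:
    """Write a labeled sample table as CSV (canonical column order)."""
    table = validate_sample_table(table)
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    table.to_csv(path, index=False)
    return path


def read_samples(path: str | Path) -> pd.DataFrame:
    """Read a labeled sample table, validating labels and completeness."""
    path = Path(path)
    if not path.exists():
        raise FormatError(f"missing sample table {path}")
    df = pd.read_csv(path)
    missing = [c for c in SAMPLE_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"sample CSV missing columns: {missing}")
    return validate_sample_table(df)
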