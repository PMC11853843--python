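"""Minimal ENVI-compatible raster I/O for spectral cubes.

Implements the small interoperable subset of the ENVI format used throughout
this package: a plain-text ``.hdr`` key-value header next to a raw binary
payload of little-endian float32 samples, in any of the three standard
interleaves (BSQ: band-sequential, BIL: band-interleaved-by-line, BIP:
band-interleaved-by-pixel).  Required header keys are ``samples``, ``lines``,
``bands``, ``interleave``, ``data type`` (must be 4 = float32), ``byte order``
(must be 0 = little-endian) and ``wavelength``.

Writes are atomic (temp file + rename) and refuse non-finite or negative
reflectance.  A write/read round trip is bit-exact for every interleave.
"""

from __future__ import annotations

import os
import re
from pathlib import Path

import numpy as np

from .cube import SpectralCube
from .errors import (
    DimensionMismatchError,
    HeaderError,
    NonFiniteError,
    UnsupportedInterleaveError,
    WavelengthMismatchError,
)

_INTERLEAVES = ("bsq", "bil", "bip")
_REQUIRED_KEYS = ("samples", "lines", "bands", "interleave", "data type", "byte order", "wavelength")

# axis order of the on-disk array for each interleave, in (row, col, band) labels
_AXIS_ORDER = {
    "bsq": (2, 0, 1),  # (bands, lines, samples)
    "bil": (0, 2, 1),  # (lines, bands, samples)
    "bip": (0, 1, 2),  # (lines, samples, bands)
}


def header_path(path: str | os.PathLike) -> Path:
    return Path(str(path) + ".hdr") if not str(path).endswith(".hdr") else Path(path)


def _data_path(path: str | os.PathLike) -> Path:
    p = str(path)
    return Path(p[: -len(".hdr")]) if p.endswith(".hdr") else Path(p)


def write_cube(cube: SpectralCube, path: str | os.PathLike, interleave: str = "bsq") -> Path:
    """Write ``cube`` to ``path`` (raw payload) + ``path``.hdr (text header).

    Returns the payload path.  Refuses cubes with non-finite or negative
    values: a reflectance cube that fails those checks is corrupt and should
    never reach disk silently.
    """
    interleave = interleave.lower()
    if interleave not in _INTERLEAVES:
        raise UnsupportedInterleaveError(f"unknown interleave {interleave!r}")
    if not np.all(np.isfinite(cube.data)):
        raise NonFiniteError("refusing to write cube with non-finite values")
    if np.any(cube.data < 0):
        raise NonFiniteError("refusing to write cube with negative reflectance")

    h, w, b = cube.shape
    payload = np.transpose(cube.data, _AXIS_ORDER[interleave])
    payload = np.ascontiguousarray(payload, dtype="<f4")

    data_path = _data_path(path)
    wl = ", ".join(repr(float(x)) for x in cube.wavelengths)  # shortest exact repr
    header = (
        "ENVI\n"
        f"samples = {w}\n"
        f"lines = {h}\n"
        f"bands = {b}\n"
        "data type = 4\n"
        f"interleave = {interleave}\n"
        "byte order = 0\n"
        "wavelength units = Nanometers\n"
        f"wavelength = {{ {wl} }}\n"
    )

    tmp_data = data_path.with_name(data_path.name + ".tmp")
    tmp_hdr = data_path.with_name(data_path.name + ".hdr.tmp")
    tmp_data.write_bytes(payload.tobytes())
    tmp_hdr.write_text(header)
    os.replace(tmp_data, data_path)
    os.replace(tmp_hdr, header_path(data_path))
    return data_path


def _parse_header(text: str) -> dict[str, str]:
    """Parse ENVI ``key = value`` pairs; brace-delimited values may span lines."""
    fields: dict[str, str] = {}
    # collapse multi-line { ... } blocks before splitting into lines
    text = re.sub(r"\{[^}]*\}", lambda m: m.group(0).replace("\n", " "), text)
    for line in text.splitlines():
        if "=" not in line:
            continue
        key, _, value = line.partition("=")
        fields[key.strip().lower()] = value.strip()
    return fields


def read_header(path: str | os.PathLike) -> dict[str, str]:
    hdr = header_path(path)
    if not hdr.exists():
        raise HeaderError(f"header file not found: {hdr}")
    return _parse_header(hdr.read_text())


def read_cube(path: str | os.PathLike) -> SpectralCube:
    """Read an ENVI raster (payload path or header path) into a SpectralCube."""
    fields = read_header(path)
    missing = [k for k in _REQUIRED_KEYS if k not in fields]
    if missing:
        raise HeaderError(f"header missing required field(s): {', '.join(missing)}")

    try:
        w = int(fields["samples"])
        h = int(fields["lines"])
        b = int(fields["bands"])
        dtype_code = int(fields["data type"])
        byte_order = int(fields["byte order"])
    except ValueError as exc:
        raise HeaderError(f"malformed numeric header field: {exc}") from exc

    if dtype_code != 4:
        raise HeaderError(f"unsupported data type {dtype_code} (only 4 = float32)")
    if byte_order != 0:
        raise HeaderError(f"unsupported byte order {byte_order} (only 0 = little-endian)")
    interleave = fields["interleave"].lower()
    if interleave not in _INTERLEAVES:
        raise UnsupportedInterleaveError(f"unknown interleave {fields['interleave']!r}")

    wl_text = fields["wavelength"].strip().strip("{}").strip()
    wavelengths = np.array([float(x) for x in wl_text.split(",") if x.strip()])
    if len(wavelengths) != b:
        raise WavelengthMismatchError(
            f"header declares {b} bands but lists {len(wavelengths)} wavelengths"
        )

    data_path = _data_path(path)
    raw = np.frombuffer(data_path.read_bytes(), dtype="<f4")
    if raw.size != h * w * b:
        raise DimensionMismatchError(
            f"payload has {raw.size} samples, header implies {h * w * b}"
        )

    order = _AXIS_ORDER[interleave]
    disk_shape = tuple((h, w, b)[ax] for ax in order)
    arr = raw.reshape(disk_shape)
    # invert the write-time transpose
    inverse = tuple(order.index(ax) for ax in range(3))
    data = np.transpose(arr, inverse)
    return SpectralCube(data=data.copy(), wavelengths=wavelengths)


def write_mask(mask: np.ndarray, path: str | os.PathLike) -> Path:
    """Write a boolean mask as a single-band ENVI raster of 0/1 floats."""
    cube = SpectralCube(data=mask.astype(np.float32)[:, :, None], wavelengths=np.array([0.0]))
    return write_cube(cube, path, interleave="bsq")


def read_mask(path: str | os.PathLike) -> np.ndarray:
    """Read a single-band ENVI raster back as a boolean mask."""
    cube = read_cube(path)
    if cube.n_bands != 1:
        raise DimensionMismatchError(f"mask raster must have one band, found {cube.n_bands}")
    return cube.data[:, :, 0] > 0.5
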