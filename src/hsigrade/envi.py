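"""Minimal ENVI raster I/O for hyperspectral cubes.

Supports the plain uncompressed ENVI layout: a text ``.hdr`` header next to a
binary payload, band-interleaved-by-line (BIL) or band-sequential (BSQ),
little-endian, with data types 4 (float32), 5 (float64) and 12 (uint16).
The header must carry a ``wavelength`` list; it becomes the cube axis.
"""

from __future__ import annotations

import os
import re

import numpy as np

from .cube import SpectralCube

__all__ = [
    "read_envi",
    "write_envi",
    "EnviFormatError",
    "MissingWavelengthError",
    "DimensionMismatchError",
    "UnknownInterleaveError",
]

_DTYPES = {4: np.float32, 5: np.float64, 12: np.uint16}
_DTYPE_CODES = {np.dtype(v): k for k, v in _DTYPES.items()}


class EnviFormatError(ValueError):
    """Header/payload inconsistency in an ENVI file pair."""


class MissingWavelengthError(EnviFormatError):
    """Header carries no wavelength list."""


class DimensionMismatchError(EnviFormatError):
    """Payload size disagrees with header dimensions."""


class UnknownInterleaveError(EnviFormatError):
    """Interleave is not BIL or BSQ."""


def _parse_header(text: str) -> dict:
    if not text.lstrip().upper().startswith("ENVI"):
        raise EnviFormatError("not an ENVI header (missing magic line)")
    # fold { ... } blocks (possibly multi-line) onto one line
    text = re.sub(r"\{[^}]*\}", lambda m: m.group(0).replace("\n", " "), text)
    fields: dict = {}
    for line in text.splitlines()[1:]:
        if "=" not in line:
            continue
        key, _, value = line.partition("=")
        fields[key.strip().lower()] = value.strip()
    return fields


def read_envi(path: str | os.PathLike) -> SpectralCube:
    """Read an ENVI ``.hdr``/payload pair into a :class:`SpectralCube`.

    ``path`` may point at the header or at the payload; the sibling file is
    located by swapping/adding the ``.hdr`` suffix.
    """
    path = os.fspath(path)
    if path.endswith(".hdr"):
        hdr_path, img_path = path, path[:-4]
        if not os.path.exists(img_path):
            img_path = path[:-4] + ".img"
    else:
        hdr_path, img_path = path + ".hdr", path
        if not os.path.exists(hdr_path):
            base, _ = os.path.splitext(path)
            hdr_path = base + ".hdr"
    with open(hdr_path) as fh:
        fields = _parse_header(fh.read())

    try:
        lines = int(fields["lines"])
        samples = int(fields["samples"])
        bands = int(fields["bands"])
        dtype_code = int(fields["data type"])
    except KeyError as exc:
        raise EnviFormatError(f"header missing required field: {exc}") from exc
    if dtype_code not in _DTYPES:
        raise EnviFormatError(f"unsupported ENVI data type {dtype_code}")
    interleave = fields.get("interleave", "bsq").lower()
    if interleave not in ("bil", "bsq"):
        raise UnknownInterleaveError(f"unsupported interleave {interleave!r}")
    if "wavelength" not in fields:
        raise MissingWavelengthError(f"{hdr_path} has no wavelength list")
    wl_text = fields["wavelength"].strip().lstrip("{").rstrip("}")
    wavelengths = np.array([float(v) for v in wl_text.split(",") if v.strip()])
    if wavelengths.size != bands:
        raise DimensionMismatchError(
            f"wavelength list length {wavelengths.size} != bands {bands}"
        )

    dtype = np.dtype(_DTYPES[dtype_code]).newbyteorder("<")
    flat = np.fromfile(img_path, dtype=dtype)
    expected = lines * samples * bands
    if flat.size != expected:
        raise DimensionMismatchError(
            f"payload holds {flat.size} values, header implies {expected}"
        )
    if interleave == "bil":
        data = flat.reshape(lines, bands, samples).transpose(0, 2, 1)
    else:  # bsq
        data = flat.reshape(bands, lines, samples).transpose(1, 2, 0)
    kind = fields.get("hsigrade kind", "raw").strip()
    if kind not in ("raw", "reflectance"):
        kind = "raw"
    return SpectralCube(np.ascontiguousarray(data), wavelengths, kind=kind)


def write_envi(
    cube: SpectralCube, path: str | os.PathLike, *, interleave: str = "bil"
) -> None:
    """Write a cube as an ENVI pair ``path`` + ``path.hdr``.

    The payload dtype follows ``cube.data.dtype`` (uint16, float32 or
    float64); raw DN cubes are conventionally uint16 and reflectance cubes
    float32.
    """
    path = os.fspath(path)
    interleave = interleave.lower()
    if interleave not in ("bil", "bsq"):
        raise UnknownInterleaveError(f"unsupported interleave {interleave!r}")
    dtype = np.dtype(cube.data.dtype)
    if dtype not in _DTYPE_CODES:
        raise EnviFormatError(f"unsupported payload dtype {dtype}")
    rows, cols, bands = cube.data.shape
    if interleave == "bil":
        payload = cube.data.transpose(0, 2, 1)  # lines, bands, samples
    else:
        payload = cube.data.transpose(2, 0, 1)  # bands, lines, samples
    np.ascontiguousarray(payload).astype(dtype.newbyteorder("<")).tofile(path)
    wl = ", ".join(f"{v:.6f}" for v in cube.wavelengths)
    header = (
        "ENVI\n"
        f"samples = {cols}\n"
        f"lines = {rows}\n"
        f"bands = {bands}\n"
        "header offset = 0\n"
        "file type = ENVI Standard\n"
        f"data type = {_DTYPE_CODES[dtype]}\n"
        f"interleave = {interleave}\n"
        "byte order = 0\n"
        f"hsigrade kind = {cube.kind}\n"
        f"wavelength = {{ {wl} }}\n"
    )
    with open(path + ".hdr", "w") as fh:
        fh.write(header)
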