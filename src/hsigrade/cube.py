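"""Hyperspectral cube container, reflectance calibration and band subsetting.

A line-scan NIR camera records raw digital numbers (DN).  Converting them to
relative reflectance requires a white reference frame (near-perfect diffuse
reflector, e.g. Teflon) and a dark reference frame (shutter closed)::

    R = (I_raw - I_dark) / (I_white - I_dark)

applied element-wise.  The correction is invariant to affine re-scalings of
the sensor response, which is what makes it an instrument calibration.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "SpectralCube",
    "ReferenceFrames",
    "correct_reflectance",
    "subset_bands",
]

#: absolute tolerance (nm) used when comparing wavelengths to interval
#: endpoints; guards against float rounding in axis construction
WAVELENGTH_ATOL = 1e-6


@dataclass
class SpectralCube:
    """A (rows, cols, bands) intensity grid with its wavelength axis.

    Parameters
    ----------
    data : ndarray of shape (rows, cols, bands)
        Raw DN or reflectance values.
    wavelengths : ndarray of shape (bands,)
        Band-center wavelengths in nm, strictly increasing.
    kind : {"raw", "reflectance"}
        Whether ``data`` holds uncalibrated DN or calibrated reflectance.
    """

    data: np.ndarray
    wavelengths: np.ndarray
    kind: str = "raw"

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        self.wavelengths = np.asarray(self.wavelengths, dtype=float)
        if self.data.ndim != 3:
            raise ValueError(f"cube data must be 3-D, got shape {self.data.shape}")
        if self.wavelengths.ndim != 1 or len(self.wavelengths) != self.data.shape[2]:
            raise ValueError(
                f"wavelength axis length {self.wavelengths.size} does not match "
                f"band count {self.data.shape[2]}"
            )
        if self.wavelengths.size > 1 and not np.all(np.diff(self.wavelengths) > 0):
            raise ValueError("wavelength axis must be strictly increasing")
        if self.kind not in ("raw", "reflectance"):
            raise ValueError(f"kind must be 'raw' or 'reflectance', got {self.kind!r}")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    @property
    def n_bands(self) -> int:
        return self.data.shape[2]

    def band_nearest(self, nm: float) -> int:
        """Index of the band whose center wavelength is closest to ``nm``."""
        return int(np.argmin(np.abs(self.wavelengths - nm)))


@dataclass
class ReferenceFrames:
    """White and dark reference frames for reflectance calibration.

    Both frames share the cube's (rows, cols, bands) shape; the white frame
    must exceed the dark frame at every element, otherwise the calibration
    denominator vanishes or flips sign.
    """

    white: np.ndarray
    dark: np.ndarray

    def __post_init__(self) -> None:
        self.white = np.asarray(self.white, dtype=float)
        self.dark = np.asarray(self.dark, dtype=float)
        if self.white.shape != self.dark.shape:
            raise ValueError(
                f"white shape {self.white.shape} != dark shape {self.dark.shape}"
            )
        bad = self.white <= self.dark
        if np.any(bad):
            pos = np.argwhere(bad)
            head = ", ".join(str(tuple(int(v) for v in p)) for p in pos[:5])
            raise ValueError(
                f"white frame must exceed dark frame everywhere; "
                f"{pos.shape[0]} offending positions, first: {head}"
            )


def correct_reflectance(
    raw: SpectralCube,
    refs: ReferenceFrames,
    *,
    column_average: bool = False,
    clip: bool = False,
) -> SpectralCube:
    """Calibrate a raw cube to relative reflectance.

    Computes ``(raw - dark) / (white - dark)`` element-wise.

    Parameters
    ----------
    raw : SpectralCube
        Cube of raw DN with ``kind == "raw"``.
    refs : ReferenceFrames
        White/dark frames matching the cube shape.
    column_average : bool
        If True, average the reference frames along the scan (row) axis
        first, applying one reference line per column — the line-scan
        convention for instruments whose illumination is row-stationary.
        Default is full per-pixel correction.
    clip : bool
        If True, clip the output into [0, 1].  Off by default: values
        slightly outside the unit interval (specular pixels, noise) carry
        information and downstream ROI averaging is robust to them.
    """
    if refs.white.shape != raw.data.shape:
        raise ValueError(
            f"reference shape {refs.white.shape} does not match cube {raw.data.shape}"
        )
    white, dark = refs.white, refs.dark
    if column_average:
        white = np.broadcast_to(white.mean(axis=0, keepdims=True), raw.data.shape)
        dark = np.broadcast_to(dark.mean(axis=0, keepdims=True), raw.data.shape)
    denom = white - dark
    out = (raw.data.astype(float) - dark) / denom
    if clip:
        out = np.clip(out, 0.0, 1.0)
    return SpectralCube(out, raw.wavelengths.copy(), kind="reflectance")


def subset_bands(cube: SpectralCube, lo_nm: float, hi_nm: float) -> SpectralCube:
    """Retain exactly the bands with ``lo_nm <= wavelength <= hi_nm``.

    The interval is closed on both ends (reported retained-range endpoints
    are themselves retained).  Raises ``ValueError`` when no band falls in
    the interval.
    """
    if lo_nm >= hi_nm:
        raise ValueError(f"need lo < hi, got [{lo_nm}, {hi_nm}]")
    keep = (cube.wavelengths >= lo_nm - WAVELENGTH_ATOL) & (
        cube.wavelengths <= hi_nm + WAVELENGTH_ATOL
    )
    if not keep.any():
        raise ValueError(f"no bands inside [{lo_nm}, {hi_nm}] nm")
    return SpectralCube(cube.data[:, :, keep], cube.wavelengths[keep], kind=cube.kind)
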