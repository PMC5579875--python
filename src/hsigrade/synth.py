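"""Synthetic NIR hyperspectral cubes of three-grade sausage samples.

The generator emulates a line-scan NIR imaging study of a semi-dry sausage
sold in three quality grades that differ chiefly in their lean/fat meat
proportion: the top grade is leanest, the second grade fattiest.  Each pixel
spectrum is a linear mixture of endmember reflectances (lean meat, fat,
binder, belt background), where endmembers are smooth baselines minus
Gaussian absorption features placed at NIR overtone positions (N-H second
overtone near 995 and 1056-1099 nm, C-H second overtone near 1160 and
1210 nm, amide combination bands at 1254-1348 nm, O-H near 1402/1450 nm).

Variability has four levels, mirroring how real spectra vary:

* between-sample lean-fraction draws (Beta around the grade mean),
* extra slice-level fraction variance for sliced samples (slices cut from a
  sausage expose a less representative cross-section than its whole surface),
* per-pixel fraction jitter (visible lean/fat marbling),
* a smooth per-sample baseline "scatter" term (additive low-order polynomial
  in wavelength) standing in for surface/scattering effects — this is what
  makes grade mean+/-SD envelopes overlap even when grades remain separable
  multivariately.

Raw digital numbers are produced by inverting the white/dark reflectance
calibration: ``raw = dark + R * (white - dark) + noise``, so applying the
calibration to a noise-free cube recovers the simulated reflectance exactly.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .cube import ReferenceFrames, SpectralCube
from .envi import write_envi

__all__ = [
    "Endmember",
    "SyntheticConfig",
    "GroundTruth",
    "default_endmembers",
    "make_wavelength_axis",
    "endmember_reflectance",
    "simulate_sample",
    "simulate_dataset",
    "read_manifest",
]

COMPONENTS = ("lean", "fat", "binder", "background")


@dataclass(frozen=True)
class Endmember:
    """A pure-component reflectance model: baseline minus Gaussian dips.

    ``features`` is a list of ``(center_nm, width_nm, depth)`` tuples; the
    reflectance is ``baseline - sum(depth * exp(-(lam-center)^2/(2 width^2)))``.
    """

    name: str
    baseline: float
    features: tuple[tuple[float, float, float], ...] = ()

    def __post_init__(self) -> None:
        for center, width, depth in self.features:
            if not (874.0 <= center <= 1734.0):
                raise ValueError(f"{self.name}: center {center} nm outside 874-1734")
            if width <= 0 or not (0.0 <= depth <= 1.0):
                raise ValueError(f"{self.name}: bad feature ({center}, {width}, {depth})")


def default_endmembers() -> dict[str, Endmember]:
    """Endmembers with absorption features at standard NIR overtone positions.

    Lean meat carries protein/water features (N-H second overtone at 995 nm
    and the 1056-1099 nm cluster, amide combinations at 1254-1348 nm, strong
    water O-H near 1450 nm); fat carries C-H second overtones (1160, 1210 nm)
    and a weaker O-H feature near 1402 nm; the binder is nearly featureless;
    the background is a dark matte belt.
    """
    return {
        "lean": Endmember(
            "lean",
            0.58,
            (
                (995.0, 14.0, 0.05),
                (1075.0, 26.0, 0.09),
                (1300.0, 40.0, 0.10),
                (1450.0, 34.0, 0.22),
            ),
        ),
        "fat": Endmember(
            "fat",
            0.68,
            (
                (1160.0, 18.0, 0.07),
                (1210.0, 16.0, 0.13),
                (1402.0, 22.0, 0.10),
            ),
        ),
        "binder": Endmember("binder", 0.50, ((1450.0, 40.0, 0.08),)),
        "background": Endmember("background", 0.05),
    }


def make_wavelength_axis(
    n_bands: int, lo_nm: float, hi_nm: float, n_in_range: int
) -> np.ndarray:
    """Uniform wavelength axis with exactly ``n_in_range`` bands in [lo, hi].

    The in-range block has ``lo_nm`` and ``hi_nm`` as its first and last
    band centers; the remaining ``n_bands - n_in_range`` bands pad the axis
    outside the interval, split as evenly as possible between the two sides.
    """
    if n_in_range < 2 or n_in_range > n_bands:
        raise ValueError(f"need 2 <= n_in_range <= n_bands, got {n_in_range}/{n_bands}")
    if lo_nm >= hi_nm:
        raise ValueError(f"need lo < hi, got [{lo_nm}, {hi_nm}]")
    spacing = (hi_nm - lo_nm) / (n_in_range - 1)
    n_pad = n_bands - n_in_range
    pad_lo = n_pad // 2
    return lo_nm + (np.arange(n_bands) - pad_lo) * spacing


def endmember_reflectance(endmember: Endmember, axis: np.ndarray) -> np.ndarray:
    """Evaluate an endmember's Gaussian-absorption reflectance on an axis."""
    axis = np.asarray(axis, dtype=float)
    if axis.size == 0:
        raise ValueError("wavelength axis is empty")
    refl = np.full(axis.shape, endmember.baseline)
    for center, width, depth in endmember.features:
        refl -= depth * np.exp(-((axis - center) ** 2) / (2.0 * width**2))
    return refl


@dataclass
class SyntheticConfig:
    """Everything the simulator needs; defaults reproduce the study layout.

    50 intact sausages per grade, 3 slices cut from each (150 slices per
    grade); grade lean-fraction means strictly decreasing from top (1) to
    second (3) grade; sliced samples draw their fractions with a variance
    ``slice_variance_multiplier**2`` times the intact between-sample
    variance.  Concentrations are Beta concentration parameters (higher =
    tighter); ``np.inf`` switches a level of variability off.
    """

    n_intact_per_grade: int = 50
    slices_per_sausage: int = 3
    grade_lean_means: tuple[float, float, float] = (0.75, 0.60, 0.45)
    fraction_concentration: float = 260.0  # between-sausage Beta concentration
    pixel_concentration: float = 80.0  # within-sample (marbling) concentration
    slice_variance_multiplier: float = 2.5
    scatter_sd: float = 0.03  # per-sample smooth baseline SD (reflectance)
    noise_sd: float = 5.0  # sensor noise SD in DN
    binder_fraction: float = 0.10
    n_bands: int = 256
    range_lo_nm: float = 975.01
    range_hi_nm: float = 1645.82
    n_in_range: int = 200
    rows: int = 50
    cols: int = 30
    dn_dark: float = 100.0
    dn_gain: float = 2500.0
    seed: int = 0
    endmembers: dict[str, Endmember] = field(default_factory=default_endmembers)

    def __post_init__(self) -> None:
        m = self.grade_lean_means
        if not (m[0] > m[1] > m[2]):
            raise ValueError(f"grade lean means must strictly decrease, got {m}")
        if not all(0.0 < v < 1.0 for v in m):
            raise ValueError(f"lean-fraction means must lie in (0,1), got {m}")
        if self.slice_variance_multiplier <= 1.0:
            raise ValueError("slice_variance_multiplier must exceed 1")
        if set(self.endmembers) != set(COMPONENTS):
            raise ValueError(f"endmembers must be exactly {COMPONENTS}")
        axis = self.wavelength_axis()
        for em in self.endmembers.values():
            refl = endmember_reflectance(em, axis)
            if refl.min() < 0.01 or refl.max() > 0.99:
                raise ValueError(
                    f"endmember {em.name!r} reflectance leaves [0.01, 0.99]"
                )

    def wavelength_axis(self) -> np.ndarray:
        return make_wavelength_axis(
            self.n_bands, self.range_lo_nm, self.range_hi_nm, self.n_in_range
        )

    def endmember_matrix(self, axis: np.ndarray | None = None) -> np.ndarray:
        """(4, n_bands) reflectance rows in :data:`COMPONENTS` order."""
        if axis is None:
            axis = self.wavelength_axis()
        return np.stack(
            [endmember_reflectance(self.endmembers[c], axis) for c in COMPONENTS]
        )


@dataclass
class GroundTruth:
    """Per-pixel composition truth for one simulated sample."""

    fractions: np.ndarray  # (rows, cols, 4) in COMPONENTS order, rows sum to 1
    mask: np.ndarray  # (rows, cols) bool, True on the sample
    grade: int
    form: str  # "intact" | "sliced"
    lean_fraction: float  # sample-level lean share of the meat mix


def _draw_beta(mean: float, concentration: float, rng: np.random.Generator, size=None):
    """Beta draw parameterized by mean and concentration; inf = point mass."""
    mean = float(np.clip(mean, 1e-3, 1.0 - 1e-3))
    if not np.isfinite(concentration):
        return np.full(size, mean) if size is not None else mean
    a = mean * concentration
    b = (1.0 - mean) * concentration
    draw = rng.beta(a, b, size=size)
    return np.clip(draw, 1e-3, 1.0 - 1e-3)


def _sample_mask(config: SyntheticConfig, form: str) -> np.ndarray:
    rr, cc = np.mgrid[0 : config.rows, 0 : config.cols]
    r0, c0 = (config.rows - 1) / 2.0, (config.cols - 1) / 2.0
    if form == "intact":
        a, b = 0.42 * config.rows, 0.30 * config.cols  # elongated ellipse
    elif form == "sliced":
        a = b = 0.36 * min(config.rows, config.cols)  # disc
    else:
        raise ValueError(f"form must be 'intact' or 'sliced', got {form!r}")
    return ((rr - r0) / a) ** 2 + ((cc - c0) / b) ** 2 <= 1.0


def _reference_frames(config: SyntheticConfig) -> ReferenceFrames:
    """Deterministic white/dark frames shared by a dataset.

    Dark current has a slight along-scan gradient; illumination has a smooth
    spectral profile.  Frames are noise-free so that calibration inverts the
    simulation exactly when sensor noise is off.
    """
    axis = config.wavelength_axis()
    t = (axis - axis[0]) / (axis[-1] - axis[0])
    gain = config.dn_gain * (0.75 + 0.25 * np.sin(np.pi * t))
    rows_grad = np.linspace(0.0, 2.0, config.rows)[:, None, None]
    dark = config.dn_dark + rows_grad + np.zeros((config.rows, config.cols, config.n_bands))
    white = dark + gain[None, None, :]
    return ReferenceFrames(white=white, dark=dark)


def simulate_sample(
    config: SyntheticConfig,
    grade: int,
    form: str,
    rng: np.random.Generator,
    *,
    lean_fraction: float | None = None,
) -> tuple[SpectralCube, ReferenceFrames, GroundTruth]:
    """Simulate one raw cube with its reference frames and ground truth.

    ``lean_fraction`` overrides the sample-level draw; :func:`simulate_dataset`
    uses it to make slices vary around their parent sausage's composition.
    """
    if grade not in (1, 2, 3):
        raise ValueError(f"grade must be 1, 2 or 3, got {grade}")
    axis = config.wavelength_axis()
    E = config.endmember_matrix(axis)  # (4, bands)
    mask = _sample_mask(config, form)
    n_px = int(mask.sum())

    if lean_fraction is None:
        mean = config.grade_lean_means[grade - 1]
        kappa = config.fraction_concentration
        if form == "sliced" and np.isfinite(kappa):
            kappa = kappa_for_multiplier(mean, kappa, config.slice_variance_multiplier)
        lean_fraction = float(_draw_beta(mean, kappa, rng))

    # per-pixel marbling around the sample-level fraction
    f_px = _draw_beta(lean_fraction, config.pixel_concentration, rng, size=n_px)

    fractions = np.zeros((config.rows, config.cols, 4))
    fractions[..., 3][~mask] = 1.0
    meat = 1.0 - config.binder_fraction
    fractions[..., 0][mask] = f_px * meat
    fractions[..., 1][mask] = (1.0 - f_px) * meat
    fractions[..., 2][mask] = config.binder_fraction

    refl = fractions.reshape(-1, 4) @ E  # (pixels, bands)
    refl = refl.reshape(config.rows, config.cols, config.n_bands)

    scatter_sd = config.scatter_sd
    if form == "sliced":
        # cut surfaces are rougher and wetter than casings: the slice
        # heterogeneity multiplier scales the scatter term too
        scatter_sd *= config.slice_variance_multiplier
    if scatter_sd > 0:
        t = 2.0 * (axis - axis[0]) / (axis[-1] - axis[0]) - 1.0
        coef = rng.normal(0.0, scatter_sd * np.array([1.0, 0.6, 0.4]))
        baseline = coef[0] + coef[1] * t + coef[2] * (2.0 * t**2 - 1.0)
        refl[mask] += baseline
    np.clip(refl, 0.005, 0.995, out=refl)

    refs = _reference_frames(config)
    raw = refs.dark + refl * (refs.white - refs.dark)
    if config.noise_sd > 0:
        raw = raw + rng.normal(0.0, config.noise_sd, size=raw.shape)

    truth = GroundTruth(
        fractions=fractions, mask=mask, grade=grade, form=form,
        lean_fraction=float(lean_fraction),
    )
    return SpectralCube(raw, axis, kind="raw"), refs, truth


def kappa_for_multiplier(mean: float, kappa: float, multiplier: float) -> float:
    """Beta concentration whose variance is ``multiplier**2`` times Beta(mean, kappa)'s."""
    return max((kappa + 1.0) / multiplier**2 - 1.0, 2.0)


def slice_concentration(config: SyntheticConfig, mean: float) -> float:
    """Concentration for the slice-around-parent draw.

    Chosen so total slice variance (parent between-sausage variance plus the
    slice-level stage) is ``slice_variance_multiplier**2`` times the intact
    between-sample variance.
    """
    kappa = config.fraction_concentration
    if not np.isfinite(kappa):
        return np.inf
    var_base = mean * (1.0 - mean) / (kappa + 1.0)
    var_extra = (config.slice_variance_multiplier**2 - 1.0) * var_base
    return max(mean * (1.0 - mean) / var_extra - 1.0, 2.0)


def iter_dataset(config: SyntheticConfig):
    """Yield every sample record of a dataset in deterministic order.

    Yields ``(record, cube, refs, truth)`` where ``record`` is a dict with
    id, grade, form and parent_id.  Slices are drawn around their parent
    sausage's lean fraction so siblings are correlated, with slice-level
    variance sized by ``slice_variance_multiplier``.
    """
    rng = np.random.default_rng(config.seed)
    for grade in (1, 2, 3):
        mean = config.grade_lean_means[grade - 1]
        for i in range(config.n_intact_per_grade):
            sid = f"g{grade}_s{i:03d}"
            parent_fraction = float(_draw_beta(mean, config.fraction_concentration, rng))
            cube, refs, truth = simulate_sample(
                config, grade, "intact", rng, lean_fraction=parent_fraction
            )
            yield {"id": sid, "grade": grade, "form": "intact", "parent_id": ""}, cube, refs, truth
            kappa_slice = slice_concentration(config, mean)
            for j in range(config.slices_per_sausage):
                frac = float(_draw_beta(parent_fraction, kappa_slice, rng))
                cube, refs, truth = simulate_sample(
                    config, grade, "sliced", rng, lean_fraction=frac
                )
                yield {
                    "id": f"{sid}_c{j}", "grade": grade, "form": "sliced",
                    "parent_id": sid,
                }, cube, refs, truth


def simulate_dataset(config: SyntheticConfig, out_dir: str | os.PathLike) -> pd.DataFrame:
    """Write a full synthetic dataset as ENVI cubes plus a CSV manifest.

    Layout: ``white``/``dark`` reference cubes at the root (shared), one
    uint16 raw cube per sample, and ``manifest.csv`` with columns
    id, path, grade, form, parent_id (seed recorded in the header comment).
    Returns the manifest as a DataFrame.
    """
    out_dir = os.fspath(out_dir)
    try:
        os.makedirs(out_dir, exist_ok=True)
        probe = os.path.join(out_dir, ".write_probe")
        with open(probe, "w"):
            pass
        os.remove(probe)
    except OSError as exc:
        raise OSError(f"output path {out_dir!r} is not writable: {exc}") from exc

    axis = config.wavelength_axis()
    refs = _reference_frames(config)
    write_envi(SpectralCube(refs.white.astype(np.float32), axis), os.path.join(out_dir, "white.img"))
    write_envi(SpectralCube(refs.dark.astype(np.float32), axis), os.path.join(out_dir, "dark.img"))

    records = []
    for record, cube, _, truth in iter_dataset(config):
        path = f"{record['id']}.img"
        dn = np.clip(np.rint(cube.data), 0, 65535).astype(np.uint16)
        write_envi(SpectralCube(dn, axis, kind="raw"), os.path.join(out_dir, path))
        np.save(os.path.join(out_dir, f"{record['id']}_mask.npy"), truth.mask)
        records.append({**record, "path": path})
    manifest = pd.DataFrame(records, columns=["id", "grade", "form", "parent_id", "path"])
    manifest_path = os.path.join(out_dir, "manifest.csv")
    with open(manifest_path, "w") as fh:
        fh.write(f"# seed = {config.seed}\n")
        manifest.to_csv(fh, index=False)
    return manifest


def read_manifest(path: str | os.PathLike) -> pd.DataFrame:
    """Read a dataset manifest written by :func:`simulate_dataset`."""
    return pd.read_csv(path, comment="#")
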