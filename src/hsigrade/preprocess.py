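"""Exploratory decomposition and derivative preprocessing of spectra."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.signal import savgol_filter
from sklearn.decomposition import PCA

__all__ = ["PCAResult", "pca_scores", "second_derivative"]


@dataclass
class PCAResult:
    """Principal-component scores of mean-centered spectra."""

    scores: np.ndarray  # (n_samples, n_components)
    explained_variance_ratio: np.ndarray
    loadings: np.ndarray  # (n_components, n_bands)


def pca_scores(X: np.ndarray, n_components: int) -> PCAResult:
    """PCA scores of mean-centered rows of ``X`` (no autoscaling).

    Sign convention: each component is oriented so its largest-magnitude
    loading is positive, making score plots reproducible across runs.
    """
    X = np.asarray(X, dtype=float)
    limit = min(X.shape[0] - 1, X.shape[1])
    if not 1 <= n_components <= limit:
        raise ValueError(f"need 1 <= n_components <= {limit}, got {n_components}")
    pca = PCA(n_components=n_components, svd_solver="full")
    scores = pca.fit_transform(X)
    loadings = pca.components_.copy()
    for k in range(n_components):
        peak = np.argmax(np.abs(loadings[k]))
        if loadings[k, peak] < 0:
            loadings[k] = -loadings[k]
            scores[:, k] = -scores[:, k]
    return PCAResult(
        scores=scores,
        explained_variance_ratio=pca.explained_variance_ratio_.copy(),
        loadings=loadings,
    )


def second_derivative(
    X: np.ndarray,
    wavelengths: np.ndarray,
    *,
    window: int = 7,
    polyorder: int = 3,
) -> np.ndarray:
    """Savitzky-Golay second derivative of each row, in reflectance / nm^2.

    The wavelength axis must be uniformly spaced (its mean spacing is used
    as the sampling step).  Edges are handled by the boundary polynomial
    fit ("interp" mode), so output rows keep the input length.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    wavelengths = np.asarray(wavelengths, dtype=float)
    if wavelengths.size != X.shape[1]:
        raise ValueError("wavelength axis does not match spectra width")
    if window % 2 == 0 or not (window > polyorder >= 2):
        raise ValueError(
            f"need odd window > polyorder >= 2, got window={window}, polyorder={polyorder}"
        )
    if window > X.shape[1]:
        raise ValueError(f"window {window} exceeds band count {X.shape[1]}")
    steps = np.diff(wavelengths)
    # 1% jitter is tolerated so axes round-tripped through fixed-precision
    # file headers still count as uniform
    if steps.size and np.any(np.abs(steps - steps.mean()) > 1e-2 * abs(steps.mean())):
        raise ValueError("second_derivative requires a uniformly spaced axis")
    delta = float(steps.mean()) if steps.size else 1.0
    return savgol_filter(
        X, window_length=window, polyorder=polyorder, deriv=2, delta=delta,
        axis=1, mode="interp",
    )
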