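"""Optimal-wavelength selection by second-derivative peaks and by RF elimination.

Two selectors, both returning a :class:`WavelengthSubset`:

* **Second-derivative peak picking** — candidate bands are local extrema of
  the pooled mean Savitzky-Golay second-derivative spectrum; candidates are
  ranked by the between-grade range (max minus min of the grade-mean second
  derivatives at that band) and the top-k kept greedily subject to a
  minimum band separation.

* **RF recursive elimination with an OOB curve** — repeatedly train an
  ensemble of R seeded forests, average the impurity importances, drop the
  fixed number of lowest-importance bands, until a predefined count N
  remains; rank the survivors by importance, then for k = 1..N train R
  forests on the top-k bands and keep the k minimizing mean OOB error.

Both are sklearn-compatible transformers (``fit``/``transform``/
``get_support``), so they drop into sklearn pipelines.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.signal import find_peaks
from sklearn.base import BaseEstimator
from sklearn.feature_selection import SelectorMixin
from sklearn.utils.validation import check_is_fitted

from ._forest import derive_seed, fit_forest, forest_oob_error
from .preprocess import second_derivative

__all__ = [
    "WavelengthSubset",
    "SelectionConfig",
    "optimal_k",
    "D2WavelengthSelector",
    "RFWavelengthSelector",
    "select_by_d2",
    "select_by_rf",
]


@dataclass
class WavelengthSubset:
    """A selected band subset with its selection trace.

    ``indices`` are original band indices: sorted ascending for the
    second-derivative method, in decreasing-importance order for RF.
    ``trace`` holds per-round (surviving indices, mean importances) for RF;
    ``oob_curve`` the mean OOB error for k = 1..N.
    """

    indices: np.ndarray
    wavelengths: np.ndarray
    method: str  # "d2" | "rf"
    trace: list = field(default_factory=list)
    oob_curve: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.indices = np.asarray(self.indices, dtype=int)
        if len(np.unique(self.indices)) != self.indices.size:
            raise ValueError("selected band indices must be unique")

    @property
    def n_selected(self) -> int:
        return self.indices.size


@dataclass
class SelectionConfig:
    """Parameters of the RF recursive-elimination selector."""

    models_per_round: int = 100
    eliminate_per_round: int = 20
    stop_at: int = 20
    n_trees: int = 50
    max_features: int = 50
    seed: int = 0


def optimal_k(oob_curve: np.ndarray) -> int:
    """Model size minimizing the OOB curve; ties go to the smallest k."""
    oob_curve = np.asarray(oob_curve, dtype=float)
    if oob_curve.size == 0:
        raise ValueError("empty OOB curve")
    return int(np.argmin(oob_curve)) + 1


def _rank_candidates(
    d2: np.ndarray, grades: np.ndarray, min_separation: int
) -> tuple[np.ndarray, np.ndarray]:
    """Candidate extrema of the pooled mean D2 spectrum with their scores."""
    pooled = d2.mean(axis=0)
    peaks, _ = find_peaks(pooled)
    valleys, _ = find_peaks(-pooled)
    candidates = np.sort(np.concatenate([peaks, valleys]))
    if candidates.size == 0:
        # monotone pooled spectrum: fall back to every band
        candidates = np.arange(d2.shape[1])
    grade_means = np.stack([d2[grades == g].mean(axis=0) for g in np.unique(grades)])
    scores = grade_means.max(axis=0) - grade_means.min(axis=0)
    if np.all(scores[candidates] == 0.0):
        warnings.warn(
            "grade means identical at every candidate band; "
            "ranking by extremum magnitude instead",
            stacklevel=3,
        )
        return candidates, np.abs(pooled)[candidates]
    return candidates, scores[candidates]


def select_by_d2(
    d2: np.ndarray,
    grades: np.ndarray,
    *,
    k: int = 14,
    min_separation: int = 5,
    wavelengths: np.ndarray | None = None,
) -> WavelengthSubset:
    """Pick the top-k second-derivative extrema with largest grade contrast.

    ``d2`` is the per-sample second-derivative matrix.  Candidates closer
    than ``min_separation`` bands to an already-kept candidate are skipped.
    Returns the selection sorted by wavelength; warns (and returns fewer)
    when candidates run out before k.
    """
    d2 = np.atleast_2d(np.asarray(d2, dtype=float))
    grades = np.asarray(grades)
    if k < 1:
        raise ValueError(f"k must be >= 1, got {k}")
    if np.unique(grades).size < 2:
        raise ValueError("need at least two grades to rank contrast")
    candidates, scores = _rank_candidates(d2, grades, min_separation)
    # stable sort: equal scores break toward the lower band index
    order = candidates[np.argsort(-scores, kind="stable")]
    kept: list[int] = []
    for band in order:
        if all(abs(band - b) >= min_separation for b in kept):
            kept.append(int(band))
        if len(kept) == k:
            break
    if len(kept) < k:
        warnings.warn(
            f"only {len(kept)} candidate bands available, requested {k}",
            stacklevel=2,
        )
    indices = np.sort(np.array(kept, dtype=int))
    wl = wavelengths[indices] if wavelengths is not None else indices.astype(float)
    return WavelengthSubset(indices=indices, wavelengths=np.asarray(wl), method="d2")


def select_by_rf(
    X: np.ndarray,
    y: np.ndarray,
    config: SelectionConfig | None = None,
    *,
    wavelengths: np.ndarray | None = None,
) -> WavelengthSubset:
    """RF recursive wavelength elimination with OOB-curve model sizing.

    See the module docstring for the procedure.  ``X`` should be the
    calibration set only, so the OOB curve is an internal generalization
    estimate.  The eliminated count per round must divide
    ``n_bands - stop_at`` exactly.
    """
    cfg = config or SelectionConfig()
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    n_bands = X.shape[1]
    if np.unique(y).size < 2:
        raise ValueError("need at least two classes")
    if n_bands <= cfg.stop_at:
        raise ValueError(f"n_bands {n_bands} must exceed stop_at {cfg.stop_at}")
    if (n_bands - cfg.stop_at) % cfg.eliminate_per_round != 0:
        raise ValueError(
            f"eliminate_per_round {cfg.eliminate_per_round} must divide "
            f"n_bands - stop_at = {n_bands - cfg.stop_at}"
        )
    if cfg.max_features > n_bands:
        warnings.warn(
            f"max_features {cfg.max_features} exceeds band count {n_bands}; clamped",
            stacklevel=2,
        )

    def mean_importance(bands: np.ndarray, round_no: int) -> np.ndarray:
        imp = np.zeros(bands.size)
        for j in range(cfg.models_per_round):
            clf = fit_forest(
                X[:, bands], y,
                n_trees=cfg.n_trees, max_features=cfg.max_features,
                seed=derive_seed(cfg.seed, round_no, j),
            )
            imp += clf.feature_importances_
        return imp / cfg.models_per_round

    remaining = np.arange(n_bands)
    trace: list[tuple[np.ndarray, np.ndarray]] = []
    round_no = 0
    while remaining.size > cfg.stop_at:
        imp = mean_importance(remaining, round_no)
        trace.append((remaining.copy(), imp))
        # stable argsort: importance ties eliminate the lower band index first
        order = np.argsort(imp, kind="stable")
        remaining = np.sort(remaining[order[cfg.eliminate_per_round :]])
        round_no += 1

    final_imp = mean_importance(remaining, round_no)
    trace.append((remaining.copy(), final_imp))
    ranked = remaining[np.argsort(-final_imp, kind="stable")]

    oob_curve = np.empty(cfg.stop_at)
    for k in range(1, cfg.stop_at + 1):
        errs = [
            forest_oob_error(
                X[:, ranked[:k]], y,
                n_trees=cfg.n_trees, max_features=cfg.max_features,
                seed=derive_seed(cfg.seed, round_no + k, j),
            )
            for j in range(cfg.models_per_round)
        ]
        oob_curve[k - 1] = float(np.mean(errs))
    k_star = optimal_k(oob_curve)

    indices = ranked[:k_star]
    wl = wavelengths[indices] if wavelengths is not None else indices.astype(float)
    return WavelengthSubset(
        indices=indices, wavelengths=np.asarray(wl), method="rf",
        trace=trace, oob_curve=oob_curve,
    )


class D2WavelengthSelector(SelectorMixin, BaseEstimator):
    """sklearn transformer wrapping :func:`select_by_d2`.

    Computes the Savitzky-Golay second derivative internally; pass the
    wavelength axis so the subset reports physical wavelengths (band-index
    units are used otherwise).
    """

    def __init__(
        self,
        k: int = 14,
        min_separation: int = 5,
        window: int = 7,
        polyorder: int = 3,
        wavelengths: np.ndarray | None = None,
    ):
        self.k = k
        self.min_separation = min_separation
        self.window = window
        self.polyorder = polyorder
        self.wavelengths = wavelengths

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        wl = (
            np.asarray(self.wavelengths, dtype=float)
            if self.wavelengths is not None
            else np.arange(X.shape[1], dtype=float)
        )
        d2 = second_derivative(X, wl, window=self.window, polyorder=self.polyorder)
        self.subset_ = select_by_d2(
            d2, np.asarray(y), k=self.k,
            min_separation=self.min_separation, wavelengths=wl,
        )
        self.n_features_in_ = X.shape[1]
        return self

    def _get_support_mask(self):
        check_is_fitted(self, "subset_")
        mask = np.zeros(self.n_features_in_, dtype=bool)
        mask[self.subset_.indices] = True
        return mask


class RFWavelengthSelector(SelectorMixin, BaseEstimator):
    """sklearn transformer wrapping :func:`select_by_rf`."""

    def __init__(
        self,
        models_per_round: int = 100,
        eliminate_per_round: int = 20,
        stop_at: int = 20,
        n_trees: int = 50,
        max_features: int = 50,
        random_state: int = 0,
        wavelengths: np.ndarray | None = None,
    ):
        self.models_per_round = models_per_round
        self.eliminate_per_round = eliminate_per_round
        self.stop_at = stop_at
        self.n_trees = n_trees
        self.max_features = max_features
        self.random_state = random_state
        self.wavelengths = wavelengths

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        cfg = SelectionConfig(
            models_per_round=self.models_per_round,
            eliminate_per_round=self.eliminate_per_round,
            stop_at=self.stop_at,
            n_trees=self.n_trees,
            max_features=self.max_features,
            seed=self.random_state,
        )
        wl = (
            np.asarray(self.wavelengths, dtype=float)
            if self.wavelengths is not None
            else None
        )
        self.subset_ = select_by_rf(X, np.asarray(y), cfg, wavelengths=wl)
        self.n_features_in_ = X.shape[1]
        return self

    def _get_support_mask(self):
        check_is_fitted(self, "subset_")
        mask = np.zeros(self.n_features_in_, dtype=bool)
        mask[self.subset_.indices] = True
        return mask
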