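"""Grid-searched SVM and random-forest graders, and accuracy evaluation.

The SVM is an RBF-kernel classifier with (C, gamma) chosen from the
dyadic-exponent grid ``2**e, e = -8, -7.2, ..., 8`` by stratified
cross-validated accuracy (features z-scored on the calibration set, since an
RBF kernel on raw reflectance scales is degenerate).  The random forest is
chosen from trees {50..500 step 50} x features-per-split {10..100 step 10}
by mean out-of-bag error over seeded repetitions.  All tie-breaks are
deterministic: smaller C then smaller gamma; fewer trees then fewer
features-per-split.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.ensemble import RandomForestClassifier
from sklearn.metrics import confusion_matrix
from sklearn.model_selection import GridSearchCV, StratifiedKFold
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC
from sklearn.utils.validation import check_is_fitted

from ._forest import accumulate_oob_votes, derive_seed, oob_error_from_votes

__all__ = [
    "ModelSpec",
    "ModelResult",
    "GridSVC",
    "GridRFC",
    "train_svm_grid",
    "train_rf_grid",
    "evaluate",
    "accuracy_from_confusion",
    "round_half_up",
]

GRADES = (1, 2, 3)


@dataclass
class ModelSpec:
    """Family and winning hyperparameters of a fitted grader."""

    family: str  # "svm" | "rf"
    params: dict


@dataclass
class ModelResult:
    """Confusion matrices and accuracies on calibration and prediction sets."""

    spec: ModelSpec
    confusion: dict[str, np.ndarray] = field(default_factory=dict)
    accuracy: dict[str, float] = field(default_factory=dict)


def round_half_up(value: float, ndigits: int = 2) -> float:
    """Round with ties away from zero (the convention of reported accuracies)."""
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(value)).quantize(q, rounding=ROUND_HALF_UP))


def accuracy_from_confusion(matrix: np.ndarray) -> float:
    """Overall accuracy 100*trace/total, half-up rounded to 2 decimals."""
    matrix = np.asarray(matrix)
    total = int(matrix.sum())
    if total == 0:
        raise ValueError("empty confusion matrix")
    acc = Decimal(100 * int(np.trace(matrix))) / Decimal(total)
    return float(acc.quantize(Decimal("0.01"), rounding=ROUND_HALF_UP))


def evaluate(model, X: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, float]:
    """Confusion matrix (rows = true grade 1..3) and overall accuracy (%).

    Raises when labels fall outside the grade coding {1, 2, 3}.
    """
    y = np.asarray(y)
    unseen = set(np.unique(y)) - set(GRADES)
    if unseen:
        raise ValueError(f"labels outside grade coding {GRADES}: {sorted(unseen)}")
    pred = model.predict(np.asarray(X, dtype=float))
    matrix = confusion_matrix(y, pred, labels=list(GRADES))
    return matrix, accuracy_from_confusion(matrix)


def _exponent_grid(lo: float, hi: float, step: float) -> np.ndarray:
    n = int(round((hi - lo) / step))
    if n < 0 or lo > hi:
        raise ValueError(f"empty exponent grid [{lo}, {hi}] step {step}")
    return lo + step * np.arange(n + 1)


class GridSVC(ClassifierMixin, BaseEstimator):
    """RBF SVM with (C, gamma) grid-searched on the dyadic exponent lattice.

    The winner is the highest mean stratified-CV accuracy; exact score ties
    resolve to the smaller C, then the smaller gamma.  The final model is
    refit on the full calibration set inside a standardizing pipeline.
    """

    def __init__(
        self,
        exp_lo: float = -8.0,
        exp_hi: float = 8.0,
        exp_step: float = 0.8,
        cv: int = 5,
        random_state: int = 0,
    ):
        self.exp_lo = exp_lo
        self.exp_hi = exp_hi
        self.exp_step = exp_step
        self.cv = cv
        self.random_state = random_state

    @property
    def grid_values(self) -> np.ndarray:
        return 2.0 ** _exponent_grid(self.exp_lo, self.exp_hi, self.exp_step)

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y)
        if np.unique(y).size < 2:
            raise ValueError("need at least two classes")
        values = self.grid_values
        pipe = Pipeline([("scale", StandardScaler()), ("svc", SVC(kernel="rbf"))])
        folds = StratifiedKFold(
            n_splits=self.cv, shuffle=True, random_state=self.random_state
        )
        # ParameterGrid iterates C ascending (outer) then gamma ascending
        # (inner); GridSearchCV keeps the first best index, which realizes
        # the smaller-C-then-smaller-gamma tie-break.
        search = GridSearchCV(
            pipe,
            {"svc__C": list(values), "svc__gamma": list(values)},
            scoring="accuracy",
            cv=folds,
            n_jobs=1,
            refit=True,
        )
        search.fit(X, y)
        self.C_ = float(search.best_params_["svc__C"])
        self.gamma_ = float(search.best_params_["svc__gamma"])
        self.cv_accuracy_ = float(search.best_score_)
        self.model_ = search.best_estimator_
        self.classes_ = self.model_.classes_
        self.n_features_in_ = X.shape[1]
        return self

    def predict(self, X):
        check_is_fitted(self, "model_")
        return self.model_.predict(np.asarray(X, dtype=float))

    def spec(self) -> ModelSpec:
        check_is_fitted(self, "model_")
        return ModelSpec("svm", {"C": self.C_, "gamma": self.gamma_})


class GridRFC(ClassifierMixin, BaseEstimator):
    """Random forest with (trees, features-per-split) chosen by mean OOB error.

    For each features-per-split value (clamped to the band count and
    deduplicated) and each seeded repetition, one forest is grown
    incrementally with ``warm_start`` and its OOB error snapshotted at every
    tree-count checkpoint — the first T trees of a grown sklearn forest are
    identical to a forest fit directly with T trees and the same seed, so
    each snapshot is exact.  OOB votes follow the package convention
    (vote-less samples count as errors).
    """

    def __init__(
        self,
        trees_grid: tuple = tuple(range(50, 501, 50)),
        mtry_grid: tuple = tuple(range(10, 101, 10)),
        n_repeats: int = 10,
        random_state: int = 0,
    ):
        self.trees_grid = trees_grid
        self.mtry_grid = mtry_grid
        self.n_repeats = n_repeats
        self.random_state = random_state

    def _effective_mtry(self, n_features: int) -> list[int]:
        clamped = [min(int(m), n_features) for m in self.mtry_grid]
        if any(int(m) > n_features for m in self.mtry_grid):
            warnings.warn(
                f"features-per-split values above the band count {n_features} "
                "were clamped",
                stacklevel=2,
            )
        out: list[int] = []
        for m in clamped:
            if m not in out:
                out.append(m)
        return sorted(out)

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y)
        if np.unique(y).size < 2:
            raise ValueError("need at least two classes")
        trees = sorted(int(t) for t in self.trees_grid)
        mtrys = self._effective_mtry(X.shape[1])
        if not trees or not mtrys:
            raise ValueError("empty hyperparameter grid")
        classes = np.unique(y)
        errors = np.zeros((len(trees), len(mtrys)))
        for mi, mtry in enumerate(mtrys):
            for rep in range(self.n_repeats):
                seed = derive_seed(self.random_state, mi, rep)
                forest = RandomForestClassifier(
                    n_estimators=trees[0], max_features=mtry,
                    bootstrap=True, warm_start=True,
                    random_state=seed, n_jobs=1,
                )
                votes = np.zeros((X.shape[0], classes.size))
                grown = 0
                for ti, n_trees in enumerate(trees):
                    forest.set_params(n_estimators=n_trees)
                    forest.fit(X, y)
                    accumulate_oob_votes(forest.estimators_[grown:], X, votes)
                    grown = n_trees
                    errors[ti, mi] += oob_error_from_votes(votes, y, classes)
        errors /= self.n_repeats

        best = None  # (error, ti, mi); iteration order realizes the tie-break
        for ti in range(len(trees)):
            for mi in range(len(mtrys)):
                if best is None or errors[ti, mi] < best[0]:
                    best = (errors[ti, mi], ti, mi)
        self.oob_errors_ = errors
        self.oob_error_ = float(best[0])
        self.n_trees_ = trees[best[1]]
        self.max_features_ = mtrys[best[2]]
        self.trees_grid_ = trees
        self.mtry_grid_ = mtrys
        self.model_ = RandomForestClassifier(
            n_estimators=self.n_trees_, max_features=self.max_features_,
            bootstrap=True, random_state=derive_seed(self.random_state, 9999),
            n_jobs=1,
        ).fit(X, y)
        self.classes_ = self.model_.classes_
        self.n_features_in_ = X.shape[1]
        return self

    def predict(self, X):
        check_is_fitted(self, "model_")
        return self.model_.predict(np.asarray(X, dtype=float))

    def spec(self) -> ModelSpec:
        check_is_fitted(self, "model_")
        return ModelSpec(
            "rf", {"n_trees": self.n_trees_, "max_features": self.max_features_}
        )


def train_svm_grid(
    X: np.ndarray, y: np.ndarray, *, cv: int = 5, random_state: int = 0, **grid
) -> GridSVC:
    """Fit a :class:`GridSVC` on the calibration set."""
    return GridSVC(cv=cv, random_state=random_state, **grid).fit(X, y)


def train_rf_grid(
    X: np.ndarray, y: np.ndarray, *, n_repeats: int = 10, random_state: int = 0, **grid
) -> GridRFC:
    """Fit a :class:`GridRFC` on the calibration set."""
    return GridRFC(n_repeats=n_repeats, random_state=random_state, **grid).fit(X, y)
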