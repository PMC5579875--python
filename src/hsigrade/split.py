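"""Kennard-Stone calibration/prediction sample-set partitioning.

Kennard-Stone is deterministic farthest-point sampling: seed the calibration
set with the two most mutually distant samples (Euclidean distance on the
spectra), then repeatedly add the sample whose minimum distance to the
already-chosen set is largest.  Applied independently within each grade so
the calibration set is grade-balanced.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import squareform, pdist

from .spectra import SpectrumTable

__all__ = ["SplitAssignment", "kennard_stone", "kennard_stone_split"]


@dataclass
class SplitAssignment:
    """Row indices of the calibration and prediction sets."""

    calibration: np.ndarray
    prediction: np.ndarray
    per_grade_calibration: dict[int, int]
    per_grade_prediction: dict[int, int]


def kennard_stone(X: np.ndarray, n_select: int) -> np.ndarray:
    """Classic Kennard-Stone selection of ``n_select`` rows of ``X``.

    Ties (equal distances) break toward the lower row index, making the
    selection fully deterministic.  Returns indices in selection order.
    """
    X = np.asarray(X, dtype=float)
    n = X.shape[0]
    if not 2 <= n_select <= n:
        raise ValueError(f"need 2 <= n_select <= {n}, got {n_select}")
    D = squareform(pdist(X))
    if np.all(D <= 0):
        warnings.warn(
            "all samples identical; Kennard-Stone falls back to index order",
            stacklevel=2,
        )
        return np.arange(n_select)
    # farthest pair; argmax on the flattened matrix is the deterministic
    # lowest-(i,j) tie-break
    i, j = np.unravel_index(np.argmax(D), D.shape)
    chosen = [min(i, j), max(i, j)]
    remaining = np.ones(n, dtype=bool)
    remaining[chosen] = False
    min_dist = np.minimum(D[chosen[0]], D[chosen[1]])
    while len(chosen) < n_select:
        cand = np.where(remaining)[0]
        nxt = cand[np.argmax(min_dist[cand])]
        chosen.append(int(nxt))
        remaining[nxt] = False
        min_dist = np.minimum(min_dist, D[nxt])
    return np.array(chosen)


def kennard_stone_split(table: SpectrumTable, cal_fraction: float) -> SplitAssignment:
    """Grade-wise Kennard-Stone split into calibration/prediction sets.

    Within each grade, ``round(cal_fraction * n_grade)`` samples enter the
    calibration set (0.74 reproduces 37/13 of 50 and 111/39 of 150).  Raises
    if any grade would leave an empty prediction set or has fewer than two
    samples.
    """
    if not 0.0 < cal_fraction < 1.0:
        raise ValueError(f"cal_fraction must be in (0,1), got {cal_fraction}")
    cal_idx, pred_idx = [], []
    per_cal, per_pred = {}, {}
    for g in np.unique(table.grades):
        rows = np.where(table.grades == g)[0]
        n = rows.size
        if n < 2:
            raise ValueError(f"grade {g} has fewer than 2 samples")
        n_cal = int(np.floor(cal_fraction * n + 0.5))  # round half up
        if n_cal >= n:
            raise ValueError(
                f"cal_fraction {cal_fraction} leaves no prediction samples for grade {g}"
            )
        n_cal = max(n_cal, 2)
        sel = kennard_stone(table.spectra[rows], n_cal)
        chosen = rows[sel]
        cal_idx.append(np.sort(chosen))
        pred_idx.append(np.setdiff1d(rows, chosen))
        per_cal[int(g)] = n_cal
        per_pred[int(g)] = n - n_cal
    return SplitAssignment(
        calibration=np.concatenate(cal_idx),
        prediction=np.concatenate(pred_idx),
        per_grade_calibration=per_cal,
        per_grade_prediction=per_pred,
    )
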