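"""Internal random-forest OOB bookkeeping shared by selection and models.

Out-of-bag error here is the fraction of training samples misclassified by
the majority vote of the trees whose bootstrap excluded them; samples that
ended up in every bootstrap (no OOB vote) count as errors.  Vote ties break
toward the lowest class label.  sklearn's own ``oob_score_`` silently scores
vote-less samples, hence the custom accounting.
"""

from __future__ import annotations

import numpy as np
from sklearn.ensemble import RandomForestClassifier
from sklearn.ensemble._forest import _generate_unsampled_indices


def derive_seed(master: int, *key: int) -> int:
    """Deterministic child seed (< 2**31) from a master seed and a key path."""
    ss = np.random.SeedSequence(entropy=int(master) % (2**31), spawn_key=tuple(key))
    return int(ss.generate_state(1)[0] % (2**31))


def accumulate_oob_votes(trees, X: np.ndarray, votes: np.ndarray) -> None:
    """Add each tree's OOB predictions into the per-sample vote counts.

    Sub-trees of a fitted forest predict *encoded* class indices (positions
    into the forest's sorted ``classes_``), which is exactly the vote column.
    """
    n = X.shape[0]
    for tree in trees:
        oob = _generate_unsampled_indices(tree.random_state, n, n, None)
        if oob.size == 0:
            continue
        pred = tree.predict(X[oob]).astype(int)
        np.add.at(votes, (oob, pred), 1)


def oob_error_from_votes(votes: np.ndarray, y: np.ndarray, classes: np.ndarray) -> float:
    """Misclassification rate of the OOB vote; vote-less samples are errors."""
    has_vote = votes.sum(axis=1) > 0
    pred = classes[np.argmax(votes, axis=1)]  # argmax tie -> lowest class
    correct = has_vote & (pred == y)
    return float(1.0 - correct.mean())


def forest_oob_error(
    X: np.ndarray,
    y: np.ndarray,
    *,
    n_trees: int,
    max_features: int,
    seed: int,
) -> float:
    """OOB error of one seeded forest (mtry clamped to the feature count)."""
    clf = fit_forest(X, y, n_trees=n_trees, max_features=max_features, seed=seed)
    classes = clf.classes_
    votes = np.zeros((X.shape[0], classes.size))
    accumulate_oob_votes(clf.estimators_, X, votes)
    return oob_error_from_votes(votes, y, classes)


def fit_forest(
    X: np.ndarray, y: np.ndarray, *, n_trees: int, max_features: int, seed: int
) -> RandomForestClassifier:
    clf = RandomForestClassifier(
        n_estimators=n_trees,
        max_features=min(int(max_features), X.shape[1]),
        bootstrap=True,
        random_state=seed,
        n_jobs=1,
    )
    return clf.fit(X, y)
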