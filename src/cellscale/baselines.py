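"""Random Forest baselines and the random-guessing reference.

The Random Forest learns S/M/L from either the five segmentation
features or the top PCA scores (100 trees, fixed seed, otherwise
default hyperparameters; no feature scaling — trees are
scale-invariant).

Random guessing is the floor every model must beat: predictions drawn
uniformly over the three classes, evaluated against a truth vector
whose class proportions follow the test cohort. Its expected weighted
F1 has a closed form — with truth fractions q_c, each class has
expected recall 1/3 and precision q_c, so

    E[weighted F1] ~= sum_c q_c * 2 q_c (1/3) / (q_c + 1/3)

which the Monte-Carlo mean approaches as the item count grows.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier

from .metrics import CLASSES, EvalReport, PredictionSet, evaluate


class ForestModel:
    """A fitted Random Forest with named feature columns."""

    def __init__(self, clf: RandomForestClassifier, feature_names: list[str]):
        self.clf = clf
        self.feature_names = list(feature_names)

    def predict(self, features) -> list[str]:
        x = self._matrix(features)
        return [str(c) for c in self.clf.predict(x)]

    def _matrix(self, features) -> np.ndarray:
        if isinstance(features, pd.DataFrame):
            return features[self.feature_names].to_numpy(dtype=float)
        return np.asarray(features, dtype=float)


def train_random_forest(features, labels, n_estimators: int = 100,
                        seed: int = 2022) -> ForestModel:
    """Fit the forest; deterministic for a fixed seed.

    ``features`` may be a DataFrame (columns are matched by name at
    prediction time, so column order cannot matter) or a plain matrix.
    """
    labels = list(labels)
    if len(set(labels)) < 2:
        raise ValueError("training labels must contain at least 2 classes")
    if isinstance(features, pd.DataFrame):
        names = list(features.columns)
        x = features.to_numpy(dtype=float)
    else:
        x = np.asarray(features, dtype=float)
        names = [f"f{i}" for i in range(x.shape[1])]
    clf = RandomForestClassifier(n_estimators=n_estimators, random_state=seed)
    clf.fit(x, labels)
    return ForestModel(clf, names)


def evaluate_forest(model: ForestModel, features, labels,
                    ids: list[str] | None = None) -> EvalReport:
    preds = model.predict(features)
    labels = list(labels)
    ids = ids or [str(i) for i in range(len(labels))]
    return evaluate(PredictionSet(ids, labels, preds))


def random_guess_baseline(test_truth, n_seeds: int, seed: int = 2022) -> float:
    """Mean weighted F1 of uniform random guessing over ``n_seeds`` draws.

    The truth vector is fixed (it carries the cohort's class ratios);
    only the predictions are random, drawn uniformly over S/M/L with an
    independent seed per repeat.
    """
    truth = list(test_truth)
    if not truth:
        raise ValueError("test_truth must be nonempty")
    root = np.random.default_rng(seed)
    scores = []
    classes = np.array(CLASSES, dtype=object)
    ids = [str(i) for i in range(len(truth))]
    for _ in range(n_seeds):
        rng = np.random.default_rng(int(root.integers(0, 2**31 - 1)))
        preds = classes[rng.integers(0, 3, size=len(truth))]
        scores.append(evaluate(PredictionSet(ids, truth, list(preds))).weighted_f1)
    return float(np.mean(scores))


def expected_random_guess_weighted_f1(class_fractions) -> float:
    """Closed-form large-N expectation of the random-guess weighted F1."""
    q = np.asarray(class_fractions, dtype=float)
    if abs(q.sum() - 1.0) > 1e-9 or (q < 0).any():
        raise ValueError("class_fractions must be nonnegative and sum to 1")
    with np.errstate(invalid="ignore"):
        f1 = np.where(q > 0, 2.0 * q * (1.0 / 3.0) / (q + 1.0 / 3.0), 0.0)
    return float((q * f1).sum())


def proportional_truth(class_counts, n_items: int) -> list[str]:
    """A truth vector of ``n_items`` labels in the given class ratio,
    apportioned by largest remainder (ties to the earlier class)."""
    counts = np.asarray(class_counts, dtype=float)
    exact = counts / counts.sum() * n_items
    base = np.floor(exact).astype(int)
    order = np.argsort(-(exact - base), kind="stable")
    base[order[: n_items - base.sum()]] += 1
    out: list[str] = []
    for c, k in zip(CLASSES, base):
        out.extend([c] * int(k))
    return out
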