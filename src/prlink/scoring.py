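"""Match-probability classification (pipeline step 4).

A classifier is trained on labeled comparison vectors by exhaustive grid
search with stratified cross-validated accuracy, refit on all data, and
then used to assign each candidate pair a match probability.  Thresholding
the probabilities yields the linkage; several scorers' probabilities can
be combined into an ensemble by averaging or majority vote.

`MatchScorer` is a scikit-learn style estimator (get_params/set_params,
fit, predict, predict_proba, trailing-underscore fitted attributes) and
composes with sklearn tooling; the module-level functions are thin
wrappers matching the pipeline vocabulary.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClassifierMixin, clone
from sklearn.ensemble import RandomForestClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import ParameterGrid, StratifiedKFold
from sklearn.neural_network import MLPClassifier
from xgboost import XGBClassifier

from .features import FEATURE_COLUMNS, FeatureMatrix, registry_hash

ALGORITHMS = (
    "gradient_boosted_trees",
    "logistic_regression",
    "random_forest",
    "neural_network",
)

# Default hyperparameter grids.  The boosted-tree grid is the benchmark
# 3 x 3 x 4 = 36-point grid; the others are small sensible defaults.
DEFAULT_GRIDS: dict[str, dict[str, list]] = {
    "gradient_boosted_trees": {
        "learning_rate": [0.01, 0.10, 0.25],
        "max_depth": [5, 10, 15],
        "n_estimators": [250, 500, 1000, 2000],
    },
    "logistic_regression": {"C": [0.01, 0.1, 1.0, 10.0]},
    "random_forest": {"n_estimators": [100, 250, 500], "max_depth": [5, 10, None]},
    "neural_network": {
        "hidden_layer_sizes": [(16,), (32,), (32, 16)],
        "alpha": [1e-4, 1e-3],
    },
}

# Per-algorithm default decision thresholds.
DEFAULT_THRESHOLDS = {
    "gradient_boosted_trees": 0.80,
    "logistic_regression": 0.80,
    "neural_network": 0.75,
    "random_forest": 0.40,
}

# Parsimony order used to break cross-validation ties: smallest model
# first (fewest estimators, then shallowest, then slowest learning rate).
_TIE_BREAK_ORDER: dict[str, tuple[str, ...]] = {
    "gradient_boosted_trees": ("n_estimators", "max_depth", "learning_rate"),
    "random_forest": ("n_estimators", "max_depth"),
    "logistic_regression": ("C",),
    "neural_network": ("hidden_layer_sizes", "alpha"),
}


def _make_estimator(algorithm: str, params: Mapping, seed: int):
    if algorithm == "gradient_boosted_trees":
        return XGBClassifier(
            tree_method="hist",
            n_jobs=1,
            random_state=seed,
            eval_metric="logloss",
            **params,
        )
    if algorithm == "logistic_regression":
        return LogisticRegression(max_iter=5000, **params)
    if algorithm == "random_forest":
        return RandomForestClassifier(n_jobs=1, random_state=seed, **params)
    if algorithm == "neural_network":
        return MLPClassifier(max_iter=800, random_state=seed, **params)
    raise ValueError(f"unknown algorithm {algorithm!r}; expected one of {ALGORITHMS}")


def _tie_key(algorithm: str, params: Mapping) -> tuple:
    def size(v):
        if v is None:
            return (1, 0)
        if isinstance(v, tuple):
            return (0, sum(v))
        return (0, v)

    order = _TIE_BREAK_ORDER.get(algorithm, tuple(sorted(params)))
    return tuple(size(params[k]) for k in order if k in params)


@dataclass(frozen=True)
class ModelSpec:
    """Algorithm choice plus its hyperparameter grid and CV protocol."""

    algorithm: str = "gradient_boosted_trees"
    grid: Mapping[str, Sequence] | None = None
    cv_folds: int = 5
    seed: int = 0

    def resolved_grid(self) -> dict[str, list]:
        grid = dict(self.grid) if self.grid else dict(DEFAULT_GRIDS[self.algorithm])
        if not grid:
            raise ValueError("hyperparameter grid must be non-empty")
        return grid


@dataclass
class ScoredPairs:
    """Candidate pairs with one match probability per pair."""

    frame: pd.DataFrame  # columns id_a, id_b, probability

    @property
    def probabilities(self) -> np.ndarray:
        return self.frame["probability"].to_numpy()

    def __len__(self) -> int:
        return len(self.frame)


@dataclass
class LinkageResult:
    """Pairs declared matches at a probability threshold.

    One-to-many links are permitted: no deduplication of multiple matches
    per record is performed.
    """

    threshold: float
    matched: set[tuple[str, str]] = field(default_factory=set)

    def __len__(self) -> int:
        return len(self.matched)


def _as_xy(matrix, labels=None):
    if isinstance(matrix, FeatureMatrix):
        X = matrix.X
        cols = list(matrix.columns)
    elif isinstance(matrix, pd.DataFrame):
        cols = [c for c in matrix.columns if c not in ("id_a", "id_b")]
        X = matrix[cols].to_numpy()
    else:
        X = np.asarray(matrix)
        cols = [f"f{i}" for i in range(X.shape[1])]
    if labels is None:
        return X, None, cols
    y = np.asarray(
        [l == "match" if isinstance(l, str) else bool(l) for l in np.asarray(labels).ravel()]
    )
    return X, y.astype(int), cols


class MatchScorer(BaseEstimator, ClassifierMixin):
    """Grid-searched match-probability classifier over comparison vectors.

    Parameters
    ----------
    algorithm : one of `ALGORITHMS`.
    param_grid : mapping of hyperparameter name to value list; defaults
        to the algorithm's entry in `DEFAULT_GRIDS`.
    cv_folds : stratified CV folds used to score each grid point by mean
        accuracy (default 5).
    threshold : default decision threshold; defaults per algorithm.
    random_state : seed controlling fold shuffling and the estimator.

    Fitted attributes
    -----------------
    best_params_, best_score_, cv_results_, model_, classes_,
    feature_names_in_, registry_hash_.
    """

    def __init__(
        self,
        algorithm: str = "gradient_boosted_trees",
        param_grid: Mapping[str, Sequence] | None = None,
        cv_folds: int = 5,
        threshold: float | None = None,
        random_state: int = 0,
    ):
        self.algorithm = algorithm
        self.param_grid = param_grid
        self.cv_folds = cv_folds
        self.threshold = threshold
        self.random_state = random_state

    # -- fitting ------------------------------------------------------

    def fit(self, X, y=None) -> "MatchScorer":
        X, y, cols = _as_xy(X, y)
        if y is None:
            raise ValueError("labels are required to fit a MatchScorer")
        classes, counts = np.unique(y, return_counts=True)
        if len(classes) < 2:
            raise ValueError("training labels contain a single class; need matches and nonmatches")
        if counts.min() < 2:
            raise ValueError("need at least 2 examples of each label")
        self._warn_conflicting_duplicates(X, y)

        spec = ModelSpec(self.algorithm, self.param_grid, self.cv_folds, self.random_state)
        grid = spec.resolved_grid()
        n_splits = min(self.cv_folds, int(counts.min()))
        cv = StratifiedKFold(n_splits=n_splits, shuffle=True, random_state=self.random_state)
        folds = list(cv.split(X, y))

        results = []
        for params in ParameterGrid(grid):
            accs = []
            for tr, te in folds:
                est = _make_estimator(self.algorithm, params, self.random_state)
                est.fit(X[tr], y[tr])
                accs.append(float(np.mean(est.predict(X[te]) == y[te])))
            results.append({"params": params, "mean_accuracy": float(np.mean(accs)),
                            "fold_accuracies": accs})
        best = min(
            results,
            key=lambda r: (-r["mean_accuracy"], _tie_key(self.algorithm, r["params"])),
        )

        self.cv_results_ = results
        self.best_params_ = dict(best["params"])
        self.best_score_ = best["mean_accuracy"]
        self.model_ = _make_estimator(self.algorithm, self.best_params_, self.random_state)
        self.model_.fit(X, y)
        self.classes_ = np.array([0, 1])
        self.feature_names_in_ = np.array(cols, dtype=object)
        self.registry_hash_ = registry_hash(cols)
        return self

    @staticmethod
    def _warn_conflicting_duplicates(X: np.ndarray, y: np.ndarray) -> None:
        df = pd.DataFrame(X)
        df["_y"] = y
        n_conflict = (df.groupby(list(df.columns[:-1]), sort=False)["_y"].nunique() > 1).sum()
        if n_conflict:
            warnings.warn(
                f"{int(n_conflict)} identical comparison vector(s) carry conflicting labels; "
                "training proceeds",
                stacklevel=3,
            )

    # -- prediction ---------------------------------------------------

    def _check_matrix(self, X):
        if isinstance(X, FeatureMatrix):
            h = X.hash
            if h != self.registry_hash_:
                ours, theirs = set(self.feature_names_in_), set(X.columns)
                raise ValueError(
                    "feature registry mismatch: "
                    f"missing columns {sorted(ours - theirs)}, extra columns {sorted(theirs - ours)}"
                )
        X_arr, _, _ = _as_xy(X)
        return X_arr

    def predict_proba(self, X) -> np.ndarray:
        X_arr = self._check_matrix(X)
        return self.model_.predict_proba(X_arr)

    def predict(self, X) -> np.ndarray:
        thr = self.threshold if self.threshold is not None else DEFAULT_THRESHOLDS[self.algorithm]
        return (self.predict_proba(X)[:, 1] >= thr).astype(int)

    def score_pairs(self, matrix: FeatureMatrix, chunk_size: int | None = None) -> ScoredPairs:
        """Match probabilities for every row of a feature matrix, row
        order preserved; chunked scoring equals one-shot scoring."""
        X_arr = self._check_matrix(matrix)
        if chunk_size is None or chunk_size >= len(X_arr):
            probs = self.model_.predict_proba(X_arr)[:, 1] if len(X_arr) else np.array([])
        else:
            probs = np.concatenate(
                [
                    self.model_.predict_proba(X_arr[i : i + int(chunk_size)])[:, 1]
                    for i in range(0, len(X_arr), int(chunk_size))
                ]
            )
        frame = matrix.pair_frame.copy()
        frame["probability"] = probs
        return ScoredPairs(frame)

    # -- persistence --------------------------------------------------

    def save(self, path: str | Path) -> None:
        """Persist the fitted scorer (joblib) with a JSON metadata sidecar."""
        import joblib

        path = Path(path)
        joblib.dump(self, path)
        meta = {
            "algorithm": self.algorithm,
            "best_params": {k: (list(v) if isinstance(v, tuple) else v)
                            for k, v in self.best_params_.items()},
            "best_cv_accuracy": self.best_score_,
            "registry_hash": self.registry_hash_,
            "feature_columns": list(self.feature_names_in_),
        }
        path.with_suffix(path.suffix + ".json").write_text(json.dumps(meta, indent=2))

    @staticmethod
    def load(path: str | Path) -> "MatchScorer":
        import joblib

        return joblib.load(path)


# ---------------------------------------------------------------------------
# functional wrappers


def grid_search_train(matrix, labels, spec: ModelSpec = ModelSpec()) -> MatchScorer:
    """Train a MatchScorer per `spec` on a labeled feature matrix."""
    scorer = MatchScorer(
        algorithm=spec.algorithm,
        param_grid=spec.grid,
        cv_folds=spec.cv_folds,
        random_state=spec.seed,
    )
    return scorer.fit(matrix, labels)


def score_pairs(scorer: MatchScorer, matrix: FeatureMatrix, chunk_size: int | None = None) -> ScoredPairs:
    return scorer.score_pairs(matrix, chunk_size=chunk_size)


def classify(scored: ScoredPairs, threshold: float = 0.80) -> LinkageResult:
    """Threshold scored pairs into a linkage (probability >= threshold)."""
    if not 0.0 < threshold <= 1.0:
        raise ValueError(f"threshold must be in (0, 1], got {threshold!r}")
    keep = scored.frame["probability"] >= threshold
    matched = set(zip(scored.frame.loc[keep, "id_a"], scored.frame.loc[keep, "id_b"]))
    return LinkageResult(threshold=threshold, matched=matched)


def ensemble(
    score_sets: Sequence[ScoredPairs],
    method: str = "mean",
    threshold: float = 0.80,
):
    """Combine several scorers' probabilities over the same pair list.

    mean -> a ScoredPairs with the per-pair arithmetic mean probability;
    majority_vote -> a LinkageResult containing pairs matched by more
    than half of the thresholded members (ties are nonmatches).
    """
    if not score_sets:
        raise ValueError("ensemble requires at least one ScoredPairs")
    base = score_sets[0].frame[["id_a", "id_b"]]
    for s in score_sets[1:]:
        if not base.equals(s.frame[["id_a", "id_b"]]):
            raise ValueError("all ensemble members must score the identical pair list")
    probs = np.column_stack([s.probabilities for s in score_sets])
    if method == "mean":
        frame = base.copy()
        frame["probability"] = probs.mean(axis=1)
        return ScoredPairs(frame)
    if method == "majority_vote":
        votes = (probs >= threshold).sum(axis=1)
        keep = votes > len(score_sets) / 2
        matched = set(zip(base.loc[keep, "id_a"], base.loc[keep, "id_b"]))
        return LinkageResult(threshold=threshold, matched=matched)
    raise ValueError(f"unknown ensemble method {method!r}")
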