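"""Scoring: grid search with parsimony tie-breaks, probability scoring,
thresholding, and ensembles."""

import numpy as np
import pandas as pd
import pytest
from sklearn.model_selection import ParameterGrid

from prlink.features import FEATURE_COLUMNS, FeatureMatrix
from prlink.scoring import (
    DEFAULT_GRIDS,
    LinkageResult,
    MatchScorer,
    ModelSpec,
    ScoredPairs,
    classify,
    ensemble,
    grid_search_train,
)


def _toy_matrix(n_match=12, n_nonmatch=12):
    """Perfectly separable toy set: matches agree on everything,
    nonmatches on nothing."""
    rows = []
    for i in range(n_match):
        rows.append({"id_a": f"A{i:03d}", "id_b": f"B{i:03d}",
                     **{c: 1 for c in FEATURE_COLUMNS}})
    for i in range(n_nonmatch):
        rows.append({"id_a": f"A{i + 500:03d}", "id_b": f"B{i + 500:03d}",
                     **{c: 0 for c in FEATURE_COLUMNS}})
    frame = pd.DataFrame(rows)
    labels = ["match"] * n_match + ["nonmatch"] * n_nonmatch
    return FeatureMatrix(frame), labels


def test_default_boosted_grid_has_36_points():
    assert len(ParameterGrid(DEFAULT_GRIDS["gradient_boosted_trees"])) == 36
    assert len(ParameterGrid(ModelSpec().resolved_grid())) == 36


def test_separable_data_ties_break_to_smallest_model():
    """Every grid point reaches CV accuracy 1.0 on separable data, so the
    parsimony tie-break must pick the fewest estimators, then the
    smallest depth, then the smallest learning rate."""
    matrix, labels = _toy_matrix()
    grid = {"learning_rate": [0.01, 0.25], "max_depth": [5, 15], "n_estimators": [50, 100]}
    scorer = MatchScorer(param_grid=grid, cv_folds=3, random_state=0).fit(matrix, labels)
    assert all(r["mean_accuracy"] == 1.0 for r in scorer.cv_results_)
    assert scorer.best_params_ == {"learning_rate": 0.01, "max_depth": 5, "n_estimators": 50}
    probs = scorer.score_pairs(matrix).probabilities
    assert probs[0] > 0.5 > probs[-1]


def test_separable_data_scores_saturate():
    matrix, labels = _toy_matrix(150, 150)
    grid = {"learning_rate": [0.25], "max_depth": [5], "n_estimators": [200]}
    scorer = MatchScorer(param_grid=grid, cv_folds=3, random_state=0).fit(matrix, labels)
    probs = scorer.score_pairs(matrix).probabilities
    assert probs[0] > 0.99 and probs[-1] < 0.01


def test_single_class_labels_rejected():
    matrix, _ = _toy_matrix(6, 6)
    with pytest.raises(ValueError, match="single class"):
        MatchScorer(param_grid={"n_estimators": [10]}).fit(matrix, ["match"] * 12)


def test_conflicting_duplicate_rows_warn_but_train():
    matrix, labels = _toy_matrix(6, 6)
    labels = list(labels)
    labels[0] = "nonmatch"  # an all-ones row labeled nonmatch conflicts
    with pytest.warns(UserWarning, match="conflicting"):
        scorer = MatchScorer(param_grid={"n_estimators": [10]}, cv_folds=2).fit(matrix, labels)
    assert hasattr(scorer, "model_")


def test_scoring_reproduces_training_predictions(quick_scorer, small_std, small_candidates):
    from prlink.features import build_matrix

    matrix = build_matrix(small_candidates, *small_std)
    p1 = quick_scorer.score_pairs(matrix).probabilities
    p2 = quick_scorer.predict_proba(matrix)[:, 1]
    np.testing.assert_array_equal(p1, p2)
    assert np.isfinite(p1).all() and (0 <= p1).all() and (p1 <= 1).all()


def test_chunked_scoring_equals_one_shot(quick_scorer, small_std, small_candidates):
    from prlink.features import build_matrix

    matrix = build_matrix(small_candidates, *small_std)
    one = quick_scorer.score_pairs(matrix).probabilities
    chunked = quick_scorer.score_pairs(matrix, chunk_size=29).probabilities
    np.testing.assert_array_equal(one, chunked)


def test_registry_mismatch_is_named():
    matrix, labels = _toy_matrix()
    scorer = MatchScorer(param_grid={"n_estimators": [10]}, cv_folds=2).fit(matrix, labels)
    wrong = FeatureMatrix(
        matrix.frame.drop(columns=["exact_zip"]),
        columns=tuple(c for c in FEATURE_COLUMNS if c != "exact_zip"),
    )
    with pytest.raises(ValueError, match="exact_zip"):
        scorer.score_pairs(wrong)


def test_refit_is_deterministic():
    matrix, labels = _toy_matrix()
    grid = {"learning_rate": [0.1], "max_depth": [3, 5], "n_estimators": [25]}
    s1 = MatchScorer(param_grid=grid, cv_folds=2, random_state=11).fit(matrix, labels)
    s2 = MatchScorer(param_grid=grid, cv_folds=2, random_state=11).fit(matrix, labels)
    assert s1.best_params_ == s2.best_params_
    np.testing.assert_array_equal(
        s1.score_pairs(matrix).probabilities, s2.score_pairs(matrix).probabilities
    )


def test_grid_search_train_wrapper():
    matrix, labels = _toy_matrix()
    spec = ModelSpec(grid={"n_estimators": [10]}, cv_folds=2, seed=0)
    scorer = grid_search_train(matrix, labels, spec)
    assert scorer.best_score_ == 1.0


class TestClassify:
    def _scored(self, probs):
        frame = pd.DataFrame(
            {"id_a": [f"A{i}" for i in range(len(probs))],
             "id_b": [f"B{i}" for i in range(len(probs))],
             "probability": probs}
        )
        return ScoredPairs(frame)

    def test_threshold_one_with_lower_probs_is_empty(self):
        assert len(classify(self._scored([0.2, 0.99]), 1.0)) == 0

    def test_monotone_thresholding(self, rng):
        scored = self._scored(rng.random(200))
        for lo, hi in [(0.4, 0.9), (0.5, 0.6), (0.05, 1.0)]:
            assert classify(scored, hi).matched <= classify(scored, lo).matched

    def test_counts_non_increasing_across_sweep_grid(self, rng):
        scored = self._scored(rng.random(500))
        counts = [len(classify(scored, t)) for t in np.arange(0.40, 0.951, 0.05)]
        assert counts == sorted(counts, reverse=True)

    def test_invalid_threshold(self):
        with pytest.raises(ValueError):
            classify(self._scored([0.5]), 0.0)


class TestEnsemble:
    def _scored(self, probs):
        frame = pd.DataFrame(
            {"id_a": [f"A{i}" for i in range(len(probs))],
             "id_b": [f"B{i}" for i in range(len(probs))],
             "probability": probs}
        )
        return ScoredPairs(frame)

    def test_single_member_identity(self):
        s = self._scored([0.3, 0.9])
        out = ensemble([s], method="mean")
        np.testing.assert_array_equal(out.probabilities, s.probabilities)

    def test_mean_arithmetic(self):
        members = [self._scored([p]) for p in (0.9, 0.6, 0.6)]
        assert ensemble(members, "mean").probabilities[0] == pytest.approx(0.7)

    def test_idempotent_on_identical_members(self):
        s = self._scored([0.25, 0.75])
        out = ensemble([s, s, s], "mean")
        np.testing.assert_allclose(out.probabilities, s.probabilities)

    def test_majority_vote(self):
        members = [self._scored([0.9]), self._scored([0.1]), self._scored([0.85])]
        result = ensemble(members, "majority_vote", threshold=0.8)
        assert result.matched == {("A0", "B0")}
        # 1-of-2 is a tie -> nonmatch
        tie = ensemble(members[:2], "majority_vote", threshold=0.8)
        assert tie.matched == set()

    def test_mismatched_pair_lists_rejected(self):
        a = self._scored([0.5, 0.5])
        b = ScoredPairs(a.frame.iloc[::-1].reset_index(drop=True))
        with pytest.raises(ValueError, match="identical pair list"):
            ensemble([a, b], "mean")
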