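"""Stage classifier, coefficient standardization, selection, Jaccard, null."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from stagesig import DegenerateDataError, PipelineError, ValidationError
from stagesig.signature import (
    SELECT_ALL,
    evaluate,
    random_signature_null,
    select_features,
    standardize_coefficients,
    train_classifier,
    two_round_reduction,
)


class TestTrainClassifier:
    def test_separable_two_class_perfect_training_accuracy(self):
        X = np.array([[0.0], [0.1], [0.2], [5.0], [5.1], [5.2]])
        y = np.array(["a", "a", "a", "b", "b", "b"])
        model = train_classifier(X, y, seed=0)
        assert (model.predict(X) == y).all()

    def test_strong_regularization_collapses_to_majority(self, rng):
        X = rng.normal(size=(40, 30))
        y = np.array(["a"] * 25 + ["b"] * 15)
        model = train_classifier(X, y, l2_strength=1e7, seed=0)
        pred = model.predict(X)
        assert (pred == "a").mean() >= 0.95  # majority class dominates

    def test_deterministic_coefficients(self, rng):
        X = rng.normal(size=(30, 10))
        y = np.array(["a", "b", "c"] * 10)
        b1 = train_classifier(X, y, seed=1).beta
        b2 = train_classifier(X, y, seed=1).beta
        assert np.allclose(b1, b2, atol=1e-8)

    def test_validation(self, rng):
        X = rng.normal(size=(6, 3))
        with pytest.raises(DegenerateDataError, match="2 classes"):
            train_classifier(X, np.array(["a"] * 6))
        with pytest.raises(DegenerateDataError, match="< 2 samples"):
            train_classifier(X, np.array(["a", "a", "a", "a", "a", "b"]))
        X[0, 0] = np.nan
        with pytest.raises(ValidationError):
            train_classifier(X, np.array(["a", "a", "a", "b", "b", "b"]))


class TestStandardizeCoefficients:
    def test_hand_computed(self):
        z = standardize_coefficients(np.array([[1.0, 2.0, 3.0, 4.0]]))
        assert np.allclose(z, [[-1.342, -0.447, 0.447, 1.342]], atol=1e-3)

    def test_zero_mean_unit_sd(self, rng):
        z = standardize_coefficients(rng.normal(2, 3, size=(8, 50)))
        assert abs(z.mean()) < 1e-9
        assert abs(z.std(ddof=0) - 1) < 1e-9

    def test_symmetry(self):
        z = standardize_coefficients(np.array([[-1.0, 0.0, 1.0] * 4]))
        vals = sorted(set(np.round(z.ravel(), 12)))
        assert vals[1] == 0.0 and vals[0] == -vals[2]

    def test_single_spike_has_max_z(self):
        beta = np.zeros((3, 10))
        beta[1, 4] = 2.0
        z = standardize_coefficients(beta)
        assert np.unravel_index(np.argmax(np.abs(z)), z.shape) == (1, 4)

    def test_degenerate(self):
        with pytest.raises(DegenerateDataError):
            standardize_coefficients(np.full((2, 3), 1.5))


class TestSelectFeatures:
    def test_strict_inequality_at_threshold(self):
        z = np.array([[0.5, 0.78, 0.9]])
        mask, score = select_features(z, threshold=0.78)
        assert mask.tolist() == [False, False, True]
        assert np.allclose(score, [0.5, 0.78, 0.9])

    def test_all_zero_selects_nothing(self):
        mask, _ = select_features(np.zeros((4, 6)), threshold=0.0)
        assert not mask.any()

    def test_select_all_sentinel(self):
        mask, _ = select_features(np.zeros((2, 5)), threshold=SELECT_ALL)
        assert mask.all()

    def test_max_over_classes(self):
        z = np.array([[0.1, 2.0], [1.5, 0.1]])
        mask, score = select_features(z, threshold=1.0)
        assert mask.tolist() == [True, True]
        assert np.allclose(score, [1.5, 2.0])

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(
        st.lists(st.floats(-5, 5), min_size=4, max_size=24),
        st.floats(0, 2),
        st.floats(0, 2),
    )
    def test_monotone_in_threshold(self, flat, t1, t2):
        z = np.asarray(flat).reshape(2, -1) if len(flat) % 2 == 0 else np.asarray(flat[:-1]).reshape(2, -1)
        lo, hi = min(t1, t2), max(t1, t2)
        m_lo, _ = select_features(z, lo)
        m_hi, _ = select_features(z, hi)
        assert not np.any(m_hi & ~m_lo)


class TestTwoRoundReduction:
    def test_select_all_sentinel_is_identity(self, rng):
        X = rng.normal(size=(24, 6))
        y = np.array(["a", "b", "c"] * 8)
        res = two_round_reduction(X, y, threshold=SELECT_ALL, seed=0)
        assert res.round1 == res.round2 == list(range(6))

    def test_deterministic(self, rng):
        X = rng.normal(size=(40, 30))
        y = np.array(["a", "b", "c", "d"] * 10)
        r1 = two_round_reduction(X, y, seed=3)
        r2 = two_round_reduction(X, y, seed=3)
        assert r1.round1 == r2.round1 and r1.round2 == r2.round2

    def test_round2_subset_of_round1(self, rng):
        X = rng.normal(size=(40, 30))
        y = np.array(["a", "b", "c", "d"] * 10)
        res = two_round_reduction(X, y, seed=0)
        assert set(res.round2) <= set(res.round1)

    def test_empty_round1_raises(self, rng):
        X = rng.normal(size=(24, 6))
        y = np.array(["a", "b", "c"] * 8)
        with pytest.raises(PipelineError, match="threshold"):
            two_round_reduction(X, y, threshold=1e9, seed=0)


class TestEvaluate:
    def test_identity(self):
        rep = evaluate(["a", "b", "a"], ["a", "b", "a"])
        assert rep.accuracy == 1.0 and rep.macro_jaccard == 1.0

    def test_hand_computed_macro_jaccard(self):
        # truth (a,a,b,b) vs pred (a,b,b,b): J_a = 1/2, J_b = 2/3.
        rep = evaluate(["a", "a", "b", "b"], ["a", "b", "b", "b"])
        assert rep.accuracy == pytest.approx(0.75)
        assert rep.per_class_jaccard["a"] == pytest.approx(1 / 2)
        assert rep.per_class_jaccard["b"] == pytest.approx(2 / 3)
        assert rep.macro_jaccard == pytest.approx(7 / 12)

    def test_single_wrong_class_counts_false_positives(self):
        rep = evaluate(["a", "a", "b", "b"], ["b", "b", "b", "b"])
        assert rep.accuracy == 0.5
        assert rep.per_class_jaccard["a"] == 0.0
        assert rep.per_class_jaccard["b"] == pytest.approx(2 / 4)

    def test_confusion_axes_and_conservation(self, rng):
        y_true = rng.choice(list("abcd"), size=100)
        y_pred = rng.choice(list("abcd"), size=100)
        rep = evaluate(y_true, y_pred)
        assert rep.confusion.to_numpy().sum() == 100
        for label in "abcd":
            assert rep.confusion.loc[label].sum() == (y_true == label).sum()

    def test_unknown_label_rejected(self):
        with pytest.raises(ValidationError, match="unknown"):
            evaluate(["a"], ["z"], class_labels=["a", "b"])


class TestRandomSignatureNull:
    def test_single_set_deterministic(self, rng):
        X = rng.normal(size=(30, 20))
        y = np.array(["a", "b", "c"] * 10)
        n1 = random_signature_null(X, y, observed=0.5, k=5, n_sets=1, seed=9)
        n2 = random_signature_null(X, y, observed=0.5, k=5, n_sets=1, seed=9)
        assert n1.jaccard_values[0] == n2.jaccard_values[0]

    def test_empirical_p_floor_when_observed_dominates(self, rng):
        X = rng.normal(size=(30, 20))
        y = np.array(["a", "b", "c"] * 10)
        null = random_signature_null(X, y, observed=2.0, k=5, n_sets=19, seed=0)
        assert null.empirical_p == pytest.approx(1 / 20)
        assert np.all(null.jaccard_values <= 1.0) and np.all(null.jaccard_values >= 0.0)

    def test_k_larger_than_features_rejected(self, rng):
        X = rng.normal(size=(30, 4))
        y = np.array(["a", "b", "c"] * 10)
        with pytest.raises(ValidationError, match="exceeds"):
            random_signature_null(X, y, observed=0.5, k=10, n_sets=2, seed=0)


def test_dataframe_features_keep_gene_ids(rng):
    X = pd.DataFrame(rng.normal(size=(24, 6)), columns=[f"g{i}" for i in range(6)])
    y = np.array(["a", "b", "c"] * 8)
    res = two_round_reduction(X, y, threshold=SELECT_ALL, seed=0)
    assert res.round1 == [f"g{i}" for i in range(6)]
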