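import numpy as np
import pytest

from nirsbci.classifier import (
    BaggedEnsemble,
    BinaryUnit,
    ClassifierError,
    LinearDiscriminant,
    MulticlassModel,
    binary_vote,
    ovo_tally,
)


def two_gaussians(n=50, sep=5.0, sd=0.5, seed=0, p=3):
    rng = np.random.default_rng(seed)
    X = np.vstack([
        rng.normal(-sep, sd, size=(n, p)),
        rng.normal(sep, sd, size=(n, p)),
    ])
    y = np.array(["A"] * n + ["B"] * n)
    return X, y


class TestLinearDiscriminant:
    def test_separable_classes_fit_perfectly(self):
        X, y = two_gaussians()
        lda = LinearDiscriminant().fit(X, y)
        assert np.mean(lda.predict(X) == y) == 1.0

    def test_identical_distributions_near_chance(self):
        rng = np.random.default_rng(1)
        X = rng.normal(size=(400, 3))
        y = np.array(["A", "B"] * 200)
        lda = LinearDiscriminant().fit(X, y)
        fresh = rng.normal(size=(2000, 3))
        frac = np.mean(lda.predict(fresh) == "A")
        assert 0.4 < frac < 0.6  # binomial CI at n=2000

    def test_duplicating_training_points_leaves_discriminant_unchanged(self):
        X, y = two_gaussians(seed=2)
        a = LinearDiscriminant().fit(X, y)
        b = LinearDiscriminant().fit(np.vstack([X, X]), np.concatenate([y, y]))
        np.testing.assert_allclose(a.coef_, b.coef_, rtol=1e-6)
        assert a.intercept_ == pytest.approx(b.intercept_, rel=1e-6)

    def test_single_class_rejected(self):
        X = np.zeros((5, 2))
        with pytest.raises(ClassifierError):
            LinearDiscriminant().fit(X, np.array(["A"] * 5))

    def test_agrees_with_sklearn_lda(self):
        # independent cross-check of the pooled-covariance solution
        from sklearn.discriminant_analysis import LinearDiscriminantAnalysis

        X, y = two_gaussians(sep=1.0, sd=1.0, seed=3, p=4)
        ours = LinearDiscriminant(gamma=0.0).fit(X, y)
        ref = LinearDiscriminantAnalysis(solver="svd").fit(X, y)
        grid = np.random.default_rng(4).normal(size=(500, 4)) * 2
        agree = np.mean(ours.predict(grid) == ref.predict(grid))
        assert agree > 0.99


class TestBaggedEnsemble:
    def test_ten_members(self):
        X, y = two_gaussians()
        ens = BaggedEnsemble().fit(X, y, np.random.default_rng(0))
        assert len(ens.members) == 10

    def test_same_seed_identical_predictions(self):
        X, y = two_gaussians(sep=0.5, sd=1.0, seed=5)
        preds = [
            BaggedEnsemble().fit(X, y, np.random.default_rng(7)).predict(X)
            for _ in range(2)
        ]
        np.testing.assert_array_equal(preds[0], preds[1])

    def test_separable_data_trains_to_perfect_accuracy(self):
        X, y = two_gaussians(seed=6)
        ens = BaggedEnsemble().fit(X, y, np.random.default_rng(1))
        assert np.mean(ens.predict(X) == y) == 1.0


class TestBinaryVote:
    @pytest.mark.parametrize(
        "votes,winner",
        [
            (("A", "A", "B"), "A"),
            (("B", "B", "B"), "B"),
            (("B", "A", "B"), "B"),
        ],
    )
    def test_majority_of_three(self, votes, winner):
        preds = np.array([[v] for v in votes])
        assert binary_vote(preds, ("A", "B"))[0] == winner

    def test_flipping_dissenter_never_changes_unanimous_outcome(self):
        preds = np.array([["A"], ["A"], ["A"]])
        base = binary_vote(preds, ("A", "B"))[0]
        for i in range(3):
            flipped = preds.copy()
            flipped[i] = "B"
            assert binary_vote(flipped, ("A", "B"))[0] == base == "A"


class TestOVO:
    @pytest.mark.parametrize("n,m", [(2, 1), (3, 3), (4, 6), (5, 10)])
    def test_unit_counts(self, n, m):
        tasks = tuple("ABCDE"[:n])
        assert MulticlassModel(tasks=tasks).n_units == m

    def test_tally_majority(self):
        winner = ovo_tally(("A", "B", "C"), {
            ("A", "B"): "A", ("A", "C"): "A", ("B", "C"): "B",
        })
        assert winner == "A"

    def test_cyclic_tie_returns_lowest_indexed_task(self):
        winner = ovo_tally(("A", "B", "C"), {
            ("A", "B"): "A", ("B", "C"): "B", ("A", "C"): "C",
        })
        assert winner == "A"

    def test_untrained_model_rejected(self):
        model = MulticlassModel(tasks=("A", "B"))
        with pytest.raises(ClassifierError):
            model.predict({"temporal": np.zeros((1, 4))})


def _featured_gaussians(tasks, n=30, seed=0, p=6, sep=4.0):
    rng = np.random.default_rng(seed)
    centers = {t: rng.normal(0, sep, size=p) for t in tasks}
    X = np.vstack([centers[t] + rng.normal(0, 1, size=(n, p)) for t in tasks])
    y = np.concatenate([[t] * n for t in tasks])
    return {"temporal": X, "spatial": X.copy(), "combined": X.copy()}, y


class TestMulticlassModel:
    def test_end_to_end_determinism(self):
        Xd, y = _featured_gaussians(("A", "B", "C"), seed=1)
        preds = [
            MulticlassModel(tasks=("A", "B", "C")).fit(Xd, y, seed=9).predict(Xd)
            for _ in range(2)
        ]
        np.testing.assert_array_equal(preds[0], preds[1])

    def test_relabeling_permutes_predictions(self):
        Xd, y = _featured_gaussians(("A", "B", "C"), seed=2)
        mapping = {"A": "C", "B": "A", "C": "B"}
        y2 = np.array([mapping[t] for t in y])
        p1 = MulticlassModel(tasks=("A", "B", "C")).fit(Xd, y, seed=3).predict(Xd)
        p2 = MulticlassModel(tasks=("A", "B", "C")).fit(Xd, y2, seed=3).predict(Xd)
        assert np.mean(np.array([mapping[t] for t in p1]) == p2) > 0.95

    def test_two_class_model_equals_binary_unit(self):
        Xd, y = _featured_gaussians(("A", "B"), seed=4)
        model = MulticlassModel(tasks=("A", "B")).fit(Xd, y, seed=5)
        unit = BinaryUnit(pair=("A", "B")).fit(Xd, y, seed=5)
        np.testing.assert_array_equal(model.predict(Xd), unit.predict(Xd))

    def test_well_separated_three_class_problem_solved(self):
        Xd, y = _featured_gaussians(("A", "B", "C"), seed=6)
        model = MulticlassModel(tasks=("A", "B", "C")).fit(Xd, y, seed=7)
        assert np.mean(model.predict(Xd) == y) > 0.95
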