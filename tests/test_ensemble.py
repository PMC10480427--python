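"""Instance ensemble: correct-set union, correlation contract, routing,
self-augmentation."""

import itertools

import numpy as np
import pytest
import scipy.sparse as sp

from epigram import (
    CorrelationRoutedEnsemble,
    SyntheticSpec,
    build_feature_table,
    correlation,
    generate,
)

from conftest import random_peptides


def _separable_tables(seed=0, n=40):
    seqs = generate(
        SyntheticSpec(
            n_pos=n, n_neg=n, length_range=(10, 25),
            signal_kmers=[("WY", 1, 3.0)], seed=seed,
        )
    )
    cut = int(0.7 * len(seqs))
    order = np.random.default_rng(seed).permutation(len(seqs))
    train = [seqs[i] for i in order[:cut]]
    test = [seqs[i] for i in order[cut:]]
    return build_feature_table(train), build_feature_table(test)


class TestCorrelation:
    def test_identical_vectors_are_one_in_both_modes(self):
        v = np.array([1.0, 2.0, 3.0])
        assert correlation(v, v, "as_printed") == 1.0
        assert correlation(v, v, "pearson") == 1.0

    def test_printed_hand_example(self):
        """(1,0) vs (0,1): (1-0 + 0-1)/sqrt(2) = 0."""
        assert correlation([1.0, 0.0], [0.0, 1.0], "as_printed") == pytest.approx(0.0)

    def test_printed_bounded_by_sqrt_n(self, rng):
        """Cauchy-Schwarz: |sum(d)/sqrt(sum(d^2))| <= sqrt(n)."""
        for _ in range(500):
            n = int(rng.integers(1, 20))
            u, v = rng.normal(size=n), rng.normal(size=n)
            c = correlation(u, v, "as_printed")
            assert abs(c) <= np.sqrt(n) + 1e-12

    def test_pearson_constant_vector(self):
        assert correlation([1.0, 1.0], [0.0, 2.0], "pearson") == 0.0
        assert correlation([1.0, 1.0], [1.0, 1.0], "pearson") == 1.0

    def test_pearson_matches_numpy(self, rng):
        u, v = rng.normal(size=30), rng.normal(size=30)
        assert correlation(u, v, "pearson") == pytest.approx(np.corrcoef(u, v)[0, 1])

    def test_length_mismatch_errors(self):
        with pytest.raises(ValueError, match="length"):
            correlation([1.0], [1.0, 2.0])


class TestUnion:
    def test_set_arithmetic_example(self):
        """C_knn={1,2}, C_RF={2,3}, C_LR={}, C_SVM={3} on 4 rows -> 0.75."""
        union = np.unique(np.concatenate([[1, 2], [2, 3], [], [3]]).astype(int))
        np.testing.assert_array_equal(union, [1, 2, 3])
        assert union.size / 4 == 0.75

    def test_union_dominance_exhaustive_small(self):
        """Union accuracy >= each individual accuracy for every possible
        correctness pattern of 4 classifiers on 3 test rows."""
        n = 3
        patterns = itertools.product(range(16), repeat=n)
        for pat in patterns:
            sets = [
                {i for i in range(n) if pat[i] >> j & 1} for j in range(4)
            ]
            union = set().union(*sets)
            assert len(union) >= max(len(s) for s in sets)

    def test_union_dominance_random_patterns(self, rng):
        for _ in range(200):
            n = int(rng.integers(1, 13))
            correct = rng.integers(0, 2, size=(4, n)).astype(bool)
            union = correct.any(axis=0)
            assert union.sum() >= correct.sum(axis=1).max()

    def test_union_on_fitted_model(self):
        tr, te = _separable_tables(seed=1)
        model = CorrelationRoutedEnsemble(seed=1).fit(tr.X, tr.y)
        model.calibrate(te.X, te.y)
        union = model.union_indices_
        for name, s in model.correct_sets_.items():
            assert set(s) <= set(union)
            assert model.union_accuracy_ >= model.individual_accuracy_[name]
        assert model.union_accuracy_ == len(union) / te.n
        # separable data: all four classifiers beat chance
        assert all(a > 0.5 for a in model.individual_accuracy_.values())

    def test_empty_calibration_errors(self):
        tr, _ = _separable_tables(seed=2)
        model = CorrelationRoutedEnsemble(seed=2).fit(tr.X, tr.y)
        with pytest.raises(ValueError, match="empty"):
            model.calibrate(sp.csr_matrix((0, tr.X.shape[1])), np.array([]))


class TestFitAndRouting:
    def test_single_class_train_errors(self, rng):
        tab = build_feature_table(random_peptides(rng, 6, label=1))
        with pytest.raises(ValueError, match="single class"):
            CorrelationRoutedEnsemble().fit(tab.X, tab.y)

    def test_one_nn_memorizes_training_point(self):
        tr, _ = _separable_tables(seed=3)
        model = CorrelationRoutedEnsemble(seed=3).fit(tr.X, tr.y)
        preds = model.classifiers_["knn"].predict(tr.X)
        np.testing.assert_array_equal(preds, tr.y)

    def test_rf_seed_determinism(self):
        tr, te = _separable_tables(seed=4)
        a = CorrelationRoutedEnsemble(seed=9).fit(tr.X, tr.y)
        b = CorrelationRoutedEnsemble(seed=9).fit(tr.X, tr.y)
        np.testing.assert_array_equal(
            a.classifiers_["rf"].predict(te.X), b.classifiers_["rf"].predict(te.X)
        )

    def test_exact_match_routes_to_correct_classifier(self):
        """An input identical to a stored correct instance gets correlation
        1.0 and is routed to a classifier that got that instance right."""
        tr, te = _separable_tables(seed=5)
        model = CorrelationRoutedEnsemble(seed=5).fit(tr.X, tr.y)
        model.calibrate(te.X, te.y)
        i = model.correct_sets_["knn"][0]
        preds, chosen, mc = model.route(te.X[[i]])
        assert mc[0] == pytest.approx(1.0)
        assert i in model.correct_sets_[chosen[0]]

    def test_tie_break_prefers_knn(self):
        """With every classifier holding the same stored instance, an exact
        match ties at 1.0 everywhere and resolves to knn."""
        tr, te = _separable_tables(seed=6)
        model = CorrelationRoutedEnsemble(seed=6).fit(tr.X, tr.y)
        model.calibrate(te.X, te.y)
        common = set.intersection(
            *(set(s) for s in model.correct_sets_.values())
        )
        assert common  # separable data: some instance everyone gets right
        i = sorted(common)[0]
        _, chosen, _ = model.route(te.X[[i]])
        assert chosen[0] == "knn"

    def test_predictions_binary_and_deterministic(self):
        tr, te = _separable_tables(seed=7)
        model = CorrelationRoutedEnsemble(seed=7).fit(tr.X, tr.y)
        model.calibrate(te.X, te.y)
        p1 = model.predict(te.X)
        p2 = model.predict(te.X)
        np.testing.assert_array_equal(p1, p2)
        assert set(np.unique(p1)) <= {0, 1}

    def test_empty_classifier_never_chosen(self):
        tr, te = _separable_tables(seed=8)
        model = CorrelationRoutedEnsemble(seed=8).fit(tr.X, tr.y)
        model.calibrate(te.X, te.y)
        # artificially empty three classifiers; routing must use the fourth
        for name in ("knn", "rf", "lr"):
            model.correct_sets_[name] = np.array([], dtype=np.intp)
            model._stored_[name] = model._stored_[name][:0]
        _, chosen, _ = model.route(te.X[:5])
        assert set(chosen) == {"svm"}
        for name in ("knn", "rf", "lr", "svm"):
            model.correct_sets_[name] = np.array([], dtype=np.intp)
            model._stored_[name] = model._stored_[name][:0]
        with pytest.raises(ValueError, match="correctly classified"):
            model.route(te.X[:5])


class TestAugmentation:
    def test_threshold_is_strict(self):
        tr, te = _separable_tables(seed=9)
        model = CorrelationRoutedEnsemble(seed=9).fit(tr.X, tr.y)
        x = te.X[0].toarray().ravel()
        n0 = model.X_pool_.shape[0]
        assert model.maybe_augment(x, 1, 1.0) is True
        assert model.X_pool_.shape[0] == n0 + 1
        assert model.stale_ is True
        assert model.maybe_augment(x, 1, 0.5) is False
        assert model.maybe_augment(x, 1, 0.999) is False  # strictly above
        assert model.X_pool_.shape[0] == n0 + 1

    def test_pool_never_shrinks_and_refit_clears_stale(self):
        tr, te = _separable_tables(seed=10)
        model = CorrelationRoutedEnsemble(seed=10).fit(tr.X, tr.y)
        sizes = [model.X_pool_.shape[0]]
        for i in range(5):
            model.maybe_augment(
                te.X[i].toarray().ravel(), int(te.y[i]), 1.0 if i % 2 else 0.0
            )
            sizes.append(model.X_pool_.shape[0])
        assert all(b >= a for a, b in zip(sizes, sizes[1:]))
        model.refit()
        assert model.stale_ is False


def test_save_load_roundtrip(tmp_path):
    tr, te = _separable_tables(seed=11)
    model = CorrelationRoutedEnsemble(seed=11).fit(tr.X, tr.y)
    model.calibrate(te.X, te.y)
    p1, c1, m1 = model.route(te.X)
    model.save(tmp_path / "bundle")
    back = CorrelationRoutedEnsemble.load(tmp_path / "bundle")
    p2, c2, m2 = back.route(te.X)
    np.testing.assert_array_equal(p1, p2)
    assert c1 == c2
    np.testing.assert_allclose(m1, m2)
    assert back.union_accuracy_ == model.union_accuracy_
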