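import numpy as np
import pytest

from conftest import random_dataset
from oracles import one_nn_oracle

from wlmgs import (
    ExpressionMatrix,
    LabeledDataset,
    SelectionConfig,
    accuracy_curve,
    cross_validated_selection,
    kmeans_objective,
    one_nn_classify,
    stratified_folds,
    svm_classify,
)
from wlmgs.synthetic import SyntheticSpec, generate


class TestStratifiedFolds:
    def test_balanced_two_class_ten_folds(self):
        labels = ("A",) * 10 + ("B",) * 10
        folds = stratified_folds(labels, 10, seed=0)
        for _, test in folds:
            y = np.asarray(labels)[test]
            assert sorted(y) == ["A", "B"]

    def test_same_seed_identical(self):
        labels = tuple("AB" * 10)
        a = stratified_folds(labels, 5, seed=3)
        b = stratified_folds(labels, 5, seed=3)
        for (tr1, te1), (tr2, te2) in zip(a, b):
            np.testing.assert_array_equal(te1, te2)
            np.testing.assert_array_equal(tr1, tr2)

    def test_partition_cover_and_disjoint(self, rng):
        for _ in range(10):
            m = int(rng.integers(12, 30))
            labels = tuple(
                rng.choice(["A", "B", "C"]) for _ in range(m)
            )
            if min(labels.count(c) for c in set(labels)) < 2:
                continue
            folds = stratified_folds(labels, 3, seed=1)
            seen = np.concatenate([te for _, te in folds])
            assert sorted(seen) == list(range(m))
            for tr, te in folds:
                assert set(tr) & set(te) == set()

    def test_tiny_class_falls_back_with_warning(self):
        labels = ("A",) * 10 + ("B",) * 2
        with pytest.warns(UserWarning, match="unstratified"):
            folds = stratified_folds(labels, 5, seed=0)
        assert len(folds) == 5


class TestOneNN:
    def test_exact_training_point(self):
        pred = one_nn_classify(np.array([[0.0], [10.0]]), ["A", "B"], np.array([[10.0]]))
        assert pred[0] == "B"

    def test_nearest_by_inspection(self):
        pred = one_nn_classify(np.array([[0.0], [10.0]]), ["A", "B"], np.array([[2.0]]))
        assert pred[0] == "A"

    def test_matches_exhaustive_oracle(self, rng):
        for _ in range(30):
            n_tr, n_te, d = rng.integers(2, 10), rng.integers(1, 6), rng.integers(1, 4)
            train = rng.normal(size=(n_tr, d))
            test = rng.normal(size=(n_te, d))
            y = np.asarray([f"c{i % 3}" for i in range(n_tr)], dtype=object)
            np.testing.assert_array_equal(
                one_nn_classify(train, y, test), one_nn_oracle(train, y, test)
            )


class TestSVM:
    def test_separable_blobs_perfect(self, rng):
        train = np.vstack([rng.normal(0, 0.1, (10, 2)), rng.normal(20, 0.1, (10, 2))])
        y = ["A"] * 10 + ["B"] * 10
        test = np.vstack([rng.normal(0, 0.1, (5, 2)), rng.normal(20, 0.1, (5, 2))])
        pred = svm_classify(train, y, test)
        assert list(pred) == ["A"] * 5 + ["B"] * 5

    def test_deterministic(self, rng):
        train = rng.normal(size=(12, 3))
        y = [f"c{i % 2}" for i in range(12)]
        test = rng.normal(size=(4, 3))
        np.testing.assert_array_equal(
            svm_classify(train, y, test), svm_classify(train, y, test)
        )

    def test_single_class_fold_predicts_it(self, rng):
        with pytest.warns(UserWarning, match="single-class"):
            pred = svm_classify(rng.normal(size=(5, 2)), ["A"] * 5, rng.normal(size=(3, 2)))
        assert list(pred) == ["A"] * 3

    def test_label_permutation_null(self):
        """Shuffled labels on balanced data give chance-level accuracy."""
        accs = []
        for seed in range(20):
            rng = np.random.default_rng(seed)
            x = rng.normal(size=(40, 5))
            y = np.asarray(["A"] * 20 + ["B"] * 20, dtype=object)
            rng.shuffle(y)
            train, test = x[:30], x[30:]
            pred = svm_classify(train, y[:30], test)
            accs.append(np.mean(pred == y[30:]))
        assert 0.35 <= np.mean(accs) <= 0.65


@pytest.fixture(scope="module")
def strong_dataset():
    ds, truth = generate(SyntheticSpec(effect_size=3.0, n_noise=45, seed=5))
    return ds, truth


class TestCrossValidatedSelection:
    def test_perfectly_separable_reaches_full_accuracy(self, strong_dataset):
        ds, _ = strong_dataset
        rep = cross_validated_selection(
            ds, SelectionConfig(), n_folds=10, seed=1, classifiers=("1nn",)
        )
        assert rep.mean_accuracy["1nn"] == pytest.approx(1.0)

    def test_mean_is_grand_mean_and_in_unit_interval(self, strong_dataset):
        ds, _ = strong_dataset
        rep = cross_validated_selection(
            ds, SelectionConfig(), n_folds=5, seed=2, classifiers=("1nn",)
        )
        accs = [f.accuracy["1nn"] for f in rep.folds]
        assert all(0.0 <= a <= 1.0 for a in accs)
        assert rep.mean_accuracy["1nn"] == pytest.approx(np.mean(accs))

    def test_repeats_accumulate_folds(self, strong_dataset):
        ds, _ = strong_dataset
        rep = cross_validated_selection(
            ds, SelectionConfig(), n_folds=3, repeats=2, seed=0, classifiers=("1nn",)
        )
        assert len(rep.folds) == 6

    def test_consensus_frequency_counts_folds(self, strong_dataset):
        ds, _ = strong_dataset
        rep = cross_validated_selection(
            ds, SelectionConfig(), n_folds=5, seed=3, classifiers=("1nn",)
        )
        assert max(rep.frequencies.values()) <= 5
        top = rep.consensus_genes[0]
        assert rep.frequencies[top] == max(rep.frequencies.values())
        assert len(rep.consensus_subset) <= len(rep.consensus_genes)

    def test_no_test_fold_leakage(self, strong_dataset):
        """Perturbing held-out values must not change the selected subsets."""
        ds, _ = strong_dataset
        rep = cross_validated_selection(
            ds, SelectionConfig(), n_folds=5, seed=7, classifiers=("1nn",)
        )
        test_idx = list(rep.folds[0].test_indices)
        tampered = ds.matrix.values.copy()
        tampered[test_idx, :] += 500.0
        ds2 = LabeledDataset(
            ExpressionMatrix(tampered, ds.matrix.sample_ids, ds.matrix.gene_ids),
            ds.labels,
        )
        rep2 = cross_validated_selection(
            ds2, SelectionConfig(), n_folds=5, seed=7, classifiers=("1nn",)
        )
        assert rep.folds[0].selection.genes == rep2.folds[0].selection.genes

    def test_determinism_bit_for_bit(self, strong_dataset):
        ds, _ = strong_dataset
        kw = dict(n_folds=4, seed=11, classifiers=("1nn",))
        a = cross_validated_selection(ds, SelectionConfig(), **kw)
        b = cross_validated_selection(ds, SelectionConfig(), **kw)
        assert a.to_dict() == b.to_dict()


class TestAccuracyCurve:
    def test_bookkeeping_and_bounds(self):
        ds, truth = generate(SyntheticSpec(effect_size=3.0, n_noise=20, seed=2))
        ranked = list(truth.informative) + list(truth.noise)[:3]
        curve = accuracy_curve(ds, ranked, classifier="1nn", n_folds=5, seed=0)
        assert len(curve) == len(ranked)
        assert all(0.0 <= a <= 1.0 for a in curve)
        # full informative prefix separates the classes perfectly
        assert curve[len(truth.informative) - 1] == pytest.approx(1.0)
        # appended noise cannot push accuracy above 1
        assert max(curve) <= 1.0

    def test_empty_ranking_rejected(self, separable_1d):
        with pytest.raises(ValueError, match="non-empty"):
            accuracy_curve(separable_1d, [], n_folds=2)


class TestKmeansObjective:
    def test_hand_values(self):
        assert kmeans_objective(np.array([[0.0], [2.0]]), ["A", "A"]) == 2.0
        x = np.array([[0.0], [2.0], [3.0], [5.0]])
        assert kmeans_objective(x, ["A", "A", "B", "B"]) == 4.0

    def test_zero_at_class_means(self):
        x = np.array([[1.0, 2.0], [1.0, 2.0], [5.0, 5.0]])
        assert kmeans_objective(x, ["A", "A", "B"]) == 0.0

    def test_unsquared_variant(self):
        x = np.array([[0.0], [2.0]])
        assert kmeans_objective(x, ["A", "A"], squared=False) == 2.0

    def test_wlms_tracks_negative_objective(self, rng):
        """Single-gene WLM^s correlates positively with -J across genes."""
        from scipy.stats import spearmanr

        from wlmgs import wlms_for_subset, zscore_normalize

        ds, _ = generate(
            SyntheticSpec(
                n_informative=20, n_noise=40, effect_size=1.5, seed=6
            )
        )
        norm, _ = zscore_normalize(ds.matrix)
        nds = LabeledDataset(norm, ds.labels)
        scores = [wlms_for_subset(nds, (g,), 7) for g in range(60)]
        js = [kmeans_objective(norm.values[:, [g]], nds.labels) for g in range(60)]
        rho = spearmanr(scores, [-j for j in js]).statistic
        assert rho > 0.5
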