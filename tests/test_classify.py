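"""SVM training, stratified CV, AUC metrics and F-score ranking."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from sklearn.metrics.pairwise import rbf_kernel

from pombeori.classify import (
    SVMConfig,
    feature_fscore,
    pr_auc,
    repeated_cv,
    roc_auc,
    score_heldout,
    stratified_kfold,
    train_svm,
)
from pombeori.features import Dataset


def _blobs(rng, n_per_class=60, sep=6.0, d=3):
    X = np.vstack([
        rng.normal(0, 1, size=(n_per_class, d)),
        rng.normal(sep, 1, size=(n_per_class, d)),
    ])
    y = np.concatenate([np.zeros(n_per_class, int), np.ones(n_per_class, int)])
    return X, y


def _dataset(X, y):
    cols = [f"f{j}" for j in range(X.shape[1])]
    return Dataset(pd.DataFrame(X, columns=cols), y,
                   pd.DataFrame({"i": np.arange(len(y))}))


class TestTrainSvm:
    def test_kernel_convention_sigma_is_gamma(self):
        # k(x, z) = exp(-sigma * ||x - z||^2); k(x, x) = 1
        x = np.array([[1.0, 2.0, 3.0]])
        z = np.array([[2.0, 0.0, 3.0]])
        k = rbf_kernel(x, z, gamma=0.01)
        assert k[0, 0] == pytest.approx(np.exp(-0.01 * 5.0))
        assert rbf_kernel(x, x, gamma=0.01)[0, 0] == pytest.approx(1.0)

    def test_separable_blobs_perfect_training_auc(self, rng):
        X, y = _blobs(rng)
        model = train_svm(X, y, SVMConfig(), seed=0)
        assert model.svc.gamma == 0.01 and model.svc.C == 10
        assert roc_auc(model.decision(X), y) == 1.0

    def test_single_class_error(self, rng):
        X = rng.normal(size=(10, 2))
        with pytest.raises(ValueError, match="class"):
            train_svm(X, np.ones(10, int))

    def test_platt_probabilities_valid_and_monotone(self, rng):
        X, y = _blobs(rng, sep=3.0)
        model = train_svm(X, y, seed=0, fit_platt=True)
        dec = model.decision(X)
        probs = model.predict_proba(X)
        assert ((probs > 0) & (probs < 1)).all()
        order = np.argsort(dec)
        assert (np.diff(probs[order]) >= -1e-12).all()
        # higher decision value -> higher origin probability
        assert probs[order[-1]] > probs[order[0]]


class TestStratifiedKfold:
    def test_paper_sized_dataset_forces_fold_sizes(self):
        y = np.concatenate([np.ones(276, int), np.zeros(3036, int)])
        folds = stratified_kfold(y, k=4, seed=1)
        for fold in range(4):
            assert (y[folds == fold] == 1).sum() == 69
            assert (y[folds == fold] == 0).sum() == 759

    def test_pigeonhole_with_five_positives(self):
        y = np.concatenate([np.ones(5, int), np.zeros(40, int)])
        folds = stratified_kfold(y, k=4, seed=0)
        pos_counts = sorted((y[folds == f] == 1).sum() for f in range(4))
        assert pos_counts == [1, 1, 1, 2]

    def test_partition(self):
        y = np.concatenate([np.ones(20, int), np.zeros(80, int)])
        folds = stratified_kfold(y, k=4, seed=3)
        assert set(folds) == {0, 1, 2, 3}
        assert len(folds) == 100


class TestRocAuc:
    def test_separated_and_constant(self):
        assert roc_auc([3, 4, 1, 2], [1, 1, 0, 0]) == 1.0
        assert roc_auc([1, 1, 1, 1], [1, 1, 0, 0]) == 0.5

    def test_four_point_hand_example(self):
        # pairs: (4>3? no label mix) positives {4,2}, negatives {3,1}
        # wins: 4>3, 4>1, 2>1 = 3; losses: 2<3 = 1 -> AUC 3/4
        assert roc_auc([4, 3, 2, 1], [1, 0, 1, 0]) == 0.75

    @settings(deadline=None, max_examples=60, derandomize=True)
    @given(
        st.lists(st.integers(0, 5), min_size=2, max_size=40),
        st.data(),
    )
    def test_matches_exhaustive_pair_counting(self, scores, data):
        labels = data.draw(
            st.lists(st.integers(0, 1), min_size=len(scores), max_size=len(scores))
        )
        labels = np.asarray(labels)
        if labels.sum() in (0, len(labels)):
            labels[0] = 1 - labels[0]
        scores = np.asarray(scores, dtype=float)
        pos = scores[labels == 1]
        neg = scores[labels == 0]
        wins = sum((p > n) + 0.5 * (p == n) for p in pos for n in neg)
        assert roc_auc(scores, labels) == pytest.approx(
            wins / (len(pos) * len(neg))
        )

    def test_invariant_under_monotone_transform(self, rng):
        scores = rng.normal(size=50)
        labels = (rng.random(50) < 0.4).astype(int)
        labels[0], labels[1] = 0, 1
        assert roc_auc(np.exp(scores), labels) == pytest.approx(
            roc_auc(scores, labels)
        )


class TestPrAuc:
    def test_perfect_ranking(self):
        assert pr_auc([4, 3, 2, 1], [1, 1, 0, 0]) == pytest.approx(1.0)
        assert pr_auc([4, 3, 2, 1], [1, 1, 0, 0], interpolation="trapezoid") == \
            pytest.approx(1.0)

    def test_matches_fine_numerical_integration(self, rng):
        """Continuous PR-AUC equals numerically integrating precision over
        recall with linear TP/FP accrual between thresholds."""
        scores = rng.normal(size=40)
        labels = (rng.random(40) < 0.3).astype(int)
        labels[:2] = [0, 1]
        order = np.argsort(-scores)
        y = labels[order]
        n_pos = y.sum()
        grid = 200_000
        tp = fp = 0.0
        area = 0.0
        for yi in y:
            d_tp, d_fp = (1.0, 0.0) if yi else (0.0, 1.0)
            if d_tp:
                for s in (np.arange(grid) + 0.5) / grid:
                    prec = (tp + s * d_tp) / (tp + s * d_tp + fp + s * d_fp)
                    area += prec * d_tp / grid
            tp += d_tp
            fp += d_fp
        assert pr_auc(scores, labels) == pytest.approx(area / n_pos, abs=1e-4)

    def test_constant_scores_equal_prevalence(self):
        labels = np.array([1, 0, 0, 0, 1, 0, 0, 0, 0, 0])
        assert pr_auc(np.ones(10), labels) == pytest.approx(0.2)


class TestFeatureFscore:
    def test_hand_value(self):
        X = pd.DataFrame({"f": [2.0, 4.0, 0.0, 2.0]})
        y = np.array([1, 1, 0, 0])
        assert feature_fscore(X, y)["f"] == pytest.approx(0.5)

    def test_identical_distributions_near_zero(self, rng):
        v = rng.normal(size=200)
        X = pd.DataFrame({"f": np.concatenate([v, v])})
        y = np.concatenate([np.ones(200, int), np.zeros(200, int)])
        assert feature_fscore(X, y)["f"] == pytest.approx(0.0, abs=1e-12)

    def test_scale_invariance(self, rng):
        x = rng.normal(size=100)
        y = (rng.random(100) < 0.5).astype(int)
        y[:2] = [0, 1]
        f1 = feature_fscore(pd.DataFrame({"f": x}), y)["f"]
        f2 = feature_fscore(pd.DataFrame({"f": 17.0 * x}), y)["f"]
        assert f1 == pytest.approx(f2)


class TestRepeatedCv:
    def test_separable_dataset_perfect_auc(self, rng):
        X, y = _blobs(rng, n_per_class=40)
        report = repeated_cv(_dataset(X, y), rounds=2, seed=0)
        assert report.mean_roc == 1.0
        assert report.mean_pr == pytest.approx(1.0)

    def test_label_permutation_is_null(self, rng):
        X = rng.normal(size=(400, 3))
        y = np.zeros(400, int)
        y[:40] = 1
        rng.shuffle(y)
        report = repeated_cv(_dataset(X, y), rounds=3, seed=1)
        # null SE of AUC with 40 pos / 360 neg is ~0.05; stay within 3 SE
        assert 0.35 <= report.mean_roc <= 0.65

    def test_deterministic_given_seed(self, rng):
        X, y = _blobs(rng, n_per_class=20, sep=2.0)
        r1 = repeated_cv(_dataset(X, y), rounds=2, seed=7)
        r2 = repeated_cv(_dataset(X, y), rounds=2, seed=7)
        pd.testing.assert_frame_equal(r1.table, r2.table)
        assert r1.roc_ci == r2.roc_ci

    def test_report_structure(self, rng):
        X, y = _blobs(rng, n_per_class=20)
        report = repeated_cv(_dataset(X, y), k=4, rounds=3, seed=2)
        assert len(report.table) == 12
        assert report.roc_ci[0] <= report.mean_roc <= report.roc_ci[1]
        assert len(report.models) == 12


class TestScoreHeldout:
    def test_empty_input(self, rng):
        X, y = _blobs(rng, n_per_class=20)
        report = repeated_cv(_dataset(X, y), rounds=1, seed=0, fit_platt=True)
        assert score_heldout(report.models, np.zeros((0, 3))).shape == (0,)

    def test_deterministic_and_ordered(self, rng):
        X, y = _blobs(rng, n_per_class=30, sep=4.0)
        report = repeated_cv(_dataset(X, y), rounds=1, seed=0, fit_platt=True)
        new = np.vstack([np.full(3, -1.0), np.full(3, 4.0)])
        p1 = score_heldout(report.models, new)
        p2 = score_heldout(report.models, new)
        assert np.array_equal(p1, p2)
        assert p1[1] > p1[0]  # closer to the positive blob
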