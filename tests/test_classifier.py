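import numpy as np
import pytest

from glomclass.classifier import (
    NetworkConfig,
    ROCCurve,
    ShallowEnsembleClassifier,
    predict,
    roc_curve,
    select_hidden_size,
    threshold_approach_a,
    threshold_approach_b,
    train_ensemble,
)
from glomclass.metrics import confusion_matrix, mcc_score
from glomclass.network import EarlyStopping, train_network
from oracles import brute_force_corner_distance_threshold


def blobs(rng, n0=80, n1=40, sep=2.0, scale=0.5):
    X0 = rng.normal([-sep, -sep], scale, (n0, 2))
    X1 = rng.normal([sep, sep], scale, (n1, 2))
    X = np.vstack([X0, X1])
    y = np.r_[np.zeros(n0, int), np.ones(n1, int)]
    idx = rng.permutation(len(y))
    return X[idx], y[idx]


class TestTrainNetwork:
    def test_separable_data_reaches_perfect_training_mcc(self):
        rng = np.random.default_rng(0)
        X, y = blobs(rng)
        net, _ = train_network(
            X[:90], y[:90], X[90:], y[90:], hidden_size=2,
            rng=np.random.default_rng(1),
        )
        pred = (net.predict_proba(X[:90])[:, 1] >= 0.5).astype(int)
        assert mcc_score(confusion_matrix(y[:90], pred)) == 1.0

    def test_deterministic_for_fixed_seed(self):
        rng = np.random.default_rng(2)
        X, y = blobs(rng)
        nets = [
            train_network(
                X[:90], y[:90], X[90:], y[90:], hidden_size=3,
                rng=np.random.default_rng(7),
            )[0]
            for _ in range(2)
        ]
        assert np.array_equal(nets[0].get_weights(), nets[1].get_weights())

    def test_single_class_targets_rejected(self):
        X = np.zeros((10, 2))
        with pytest.raises(ValueError, match="single class"):
            train_network(X, np.zeros(10), X, np.zeros(10), 2, np.random.default_rng(0))

    def test_flipped_validation_stops_early(self):
        # validation labels inverted: validation loss rises as training fits
        rng = np.random.default_rng(3)
        X, y = blobs(rng, n0=60, n1=60)
        _, hist = train_network(
            X[:80], y[:80], X[80:], 1 - y[80:], hidden_size=2,
            rng=np.random.default_rng(4), max_epochs=1000,
        )
        assert hist.stopped_epoch < 1000


class TestEarlyStopping:
    def test_strictly_worsening_loss_stops_within_window(self):
        stopper = EarlyStopping(window=6)
        stopped_at = None
        for epoch, loss in enumerate([1.0, 1.1, 1.2, 1.3, 1.4, 1.5, 1.6, 1.7], 1):
            if stopper.update(loss, epoch):
                stopped_at = epoch
                break
        assert stopped_at is not None and stopped_at <= 7  # window + 1
        assert stopper.best_epoch == 1

    def test_improvement_resets_the_window(self):
        stopper = EarlyStopping(window=3)
        losses = [1.0, 1.1, 1.2, 0.9, 1.0, 1.1, 1.2]
        fired = [stopper.update(l, e) for e, l in enumerate(losses, 1)]
        assert fired == [False] * 6 + [True]
        assert stopper.best_epoch == 4


class TestROCCurve:
    def test_separated_scores_contain_perfect_point(self):
        roc = roc_curve(np.array([0.9, 0.8, 0.2, 0.1]), np.array([1, 1, 0, 0]))
        assert ((roc.sensitivity == 1) & (roc.specificity == 1)).any()

    def test_constant_scores_degenerate_endpoints(self):
        roc = roc_curve(np.full(6, 0.5), np.array([1, 0, 1, 0, 1, 0]))
        pts = set(zip(roc.sensitivity, roc.specificity))
        assert pts == {(0.0, 1.0), (1.0, 0.0)}

    def test_single_class_rejected(self):
        with pytest.raises(ValueError, match="both classes"):
            roc_curve(np.array([0.1, 0.9]), np.array([1, 1]))

    def test_counting_oracle_agreement(self):
        rng = np.random.default_rng(11)
        scores = rng.random(60)
        labels = rng.integers(0, 2, 60)
        if labels.min() == labels.max():
            labels[0] = 1 - labels[0]
        roc = roc_curve(scores, labels)
        n_pos, n_neg = (labels == 1).sum(), (labels == 0).sum()
        for t, sens, spec in zip(roc.thresholds, roc.sensitivity, roc.specificity):
            pred = scores >= t
            assert sens == pytest.approx((pred & (labels == 1)).sum() / n_pos)
            assert spec == pytest.approx((~pred & (labels == 0)).sum() / n_neg)
        # monotone: sensitivity falls as the threshold rises
        assert (np.diff(roc.sensitivity) >= 0).all()  # thresholds decrease along array


class TestThresholdApproaches:
    def two_point_curve(self):
        return ROCCurve(
            thresholds=np.array([0.7, 0.4]),
            sensitivity=np.array([0.9, 0.95]),
            specificity=np.array([0.9, 0.7]),
        )

    def test_approach_a_balanced_slope_objective(self):
        roc = ROCCurve(
            thresholds=np.array([0.8, 0.5]),
            sensitivity=np.array([0.9, 0.95]),
            specificity=np.array([0.9, 0.7]),
        )
        # objectives: 0.9-0.1 = 0.8 vs 0.95-0.3 = 0.65
        assert threshold_approach_a(roc, 10, 10) == 0.8

    def test_approach_a_perfect_classifier(self):
        roc = roc_curve(np.array([0.9, 0.8, 0.2]), np.array([1, 1, 0]))
        t = threshold_approach_a(roc, 1, 2)
        pred = np.array([0.9, 0.8, 0.2]) >= t
        assert pred.tolist() == [True, True, False]

    def test_approach_a_extreme_imbalance_forces_zero_fpr(self):
        rng = np.random.default_rng(13)
        scores = rng.random(50)
        labels = rng.integers(0, 2, 50)
        labels[:2] = [0, 1]
        roc = roc_curve(scores, labels)
        t = threshold_approach_a(roc, n_negative=10**9, n_positive=1)
        idx = int(np.argmin(np.abs(roc.thresholds - t)))
        assert roc.fpr[idx] == 0.0

    def test_approach_b_direct_evaluation(self):
        roc = ROCCurve(
            thresholds=np.array([0.6, 0.3]),
            sensitivity=np.array([0.9, 0.7]),
            specificity=np.array([0.8, 0.95]),
        )
        # distances ~0.2236 vs ~0.3041
        assert threshold_approach_b(roc) == 0.6

    def test_approach_b_matches_brute_force_on_random_scores(self):
        rng = np.random.default_rng(17)
        for _ in range(100):
            n = int(rng.integers(6, 40))
            scores = np.round(rng.random(n), 2)  # force ties
            labels = rng.integers(0, 2, n)
            if labels.min() == labels.max():
                labels[0] = 1 - labels[0]
            ours = threshold_approach_b(roc_curve(scores, labels))
            oracle = brute_force_corner_distance_threshold(scores, labels)
            assert ours == pytest.approx(oracle)

    def test_approaches_agree_on_symmetric_balanced_curve(self):
        scores = np.array([0.9, 0.8, 0.7, 0.3, 0.2, 0.1])
        labels = np.array([1, 1, 1, 0, 0, 0])
        roc = roc_curve(scores, labels)
        assert threshold_approach_a(roc, 3, 3) == threshold_approach_b(roc)


@pytest.fixture(scope="module")
def fitted():
    rng = np.random.default_rng(21)
    X, y = blobs(rng, n0=160, n1=60)
    clf = ShallowEnsembleClassifier(
        hidden_size=3, k=10, inits_per_fold=2, random_state=0
    ).fit(X, y)
    return clf, X, y


class TestEnsemble:
    def test_structure_k_models_with_unit_interval_thresholds(self, fitted):
        clf, _, _ = fitted
        assert len(clf.fold_models_) == 10
        assert all(0 <= fm.threshold <= 1 for fm in clf.fold_models_)

    def test_separable_data_high_fold_validation_mcc(self, fitted):
        clf, _, _ = fitted
        assert all(fm.validation_mcc >= 0.9 for fm in clf.fold_models_)

    def test_deterministic_refit(self, fitted):
        clf, X, y = fitted
        clf2 = ShallowEnsembleClassifier(
            hidden_size=3, k=10, inits_per_fold=2, random_state=0
        ).fit(X, y)
        for a, b in zip(clf.fold_models_, clf2.fold_models_):
            assert np.array_equal(a.network.get_weights(), b.network.get_weights())
            assert a.threshold == b.threshold

    def test_prediction_invariant_to_fold_order(self, fitted):
        clf, X, _ = fitted
        pred = clf.predict(X[:20])
        clf.fold_models_ = list(reversed(clf.fold_models_))
        assert np.array_equal(clf.predict(X[:20]), pred)

    def test_width_mismatch_rejected(self, fitted):
        clf, _, _ = fitted
        with pytest.raises(ValueError, match="width"):
            clf.predict(np.zeros((2, 5)))

    def test_functional_wrappers_match_estimator(self, fitted):
        clf, X, y = fitted
        wrapped = train_ensemble(
            X, y, k=10,
            config=NetworkConfig(hidden_size=3, inits_per_fold=2),
            random_state=0,
        )
        labels, votes = predict(wrapped, X[:15])
        assert votes.shape == (15, 10)
        assert np.array_equal(labels, clf.predict(X[:15]))


class TestHardVoting:
    def make_clf(self, thresholds):
        """Ensemble with stub fold networks voting by fixed thresholds."""
        clf = ShallowEnsembleClassifier(k=len(thresholds))
        clf.classes_ = np.array([0, 1])
        clf.pos_label_ = 1
        clf.n_features_in_ = 1

        class Stub:
            def predict_proba(self, X):
                p = np.asarray(X, float)[:, 0]
                return np.column_stack([1 - p, p])

        from glomclass.classifier import FoldModel

        clf.fold_models_ = [
            FoldModel(Stub(), t, i, 1.0) for i, t in enumerate(thresholds)
        ]
        return clf

    def test_unanimous_positive(self):
        clf = self.make_clf([0.5] * 10)
        assert clf.predict([[0.9]]) == [1]

    def test_tie_goes_to_positive(self):
        clf = self.make_clf([0.2] * 5 + [0.8] * 5)
        assert clf.predict([[0.5]]) == [1]  # 5 vs 5

    def test_minority_positive_vote_loses_then_flips(self):
        clf = self.make_clf([0.2] * 4 + [0.8] * 6)
        assert clf.predict([[0.5]]) == [0]  # 4 vs 6
        clf2 = self.make_clf([0.2] * 6 + [0.8] * 4)
        assert clf2.predict([[0.5]]) == [1]  # two votes flipped


class TestHiddenSizeSelection:
    def test_singleton_candidate_returned(self):
        rng = np.random.default_rng(31)
        X, y = blobs(rng, n0=60, n1=40)
        size, trace = select_hidden_size(X, y, [5], k=4)
        assert size == 5 and len(trace) == 1

    def test_tie_broken_toward_smaller(self):
        rng = np.random.default_rng(32)
        X, y = blobs(rng, n0=60, n1=40, sep=3.0)  # easy: every size is perfect
        size, trace = select_hidden_size(X, y, [2, 4], k=4)
        assert trace["mean_mcc"].nunique() == 1
        assert size == 2

    def test_xor_needs_at_least_two_hidden_units(self):
        rng = np.random.default_rng(33)
        centers = np.array([[-2, -2], [2, 2], [-2, 2], [2, -2]])
        labels = np.array([0, 0, 1, 1])
        X = np.vstack([
            rng.normal(c, 0.4, (40, 2)) for c in centers
        ])
        y = np.repeat(labels, 40)
        idx = rng.permutation(len(y))
        size, trace = select_hidden_size(
            X[idx], y[idx], [1, 4], k=4, inits_per_fold=2, random_state=1
        )
        trace = trace.set_index("size")
        assert size >= 2
        assert trace.loc[4, "mean_mcc"] > trace.loc[1, "mean_mcc"]
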