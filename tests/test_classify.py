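import numpy as np
import pytest

from pdglove import (
    BPNNClassifier,
    bpnn_predict,
    bpnn_train,
    cross_validate,
    evaluate,
    report_from_confusion,
)
from pdglove.classify import _sigmoid, _softmax


def test_separable_data_trains_to_full_accuracy(separable_features):
    X, y = separable_features
    model = bpnn_train(X, y, seed=0)
    assert np.mean(model.predict(X) == y) == 1.0


def test_shuffled_labels_score_near_chance(separable_features):
    from sklearn.model_selection import train_test_split

    X, y = separable_features
    rng = np.random.default_rng(0)
    accs = []
    for trial in range(3):
        y_perm = rng.permutation(y)
        Xtr, Xte, ytr, yte = train_test_split(
            X, y_perm, test_size=0.25, stratify=y_perm, random_state=trial
        )
        model = BPNNClassifier(random_state=trial).fit(Xtr, ytr)
        accs.append(np.mean(model.predict(Xte) == yte))
    assert abs(np.mean(accs) - 1 / 3) <= 0.15 + 1e-9


def test_same_seed_bitwise_identical(separable_features):
    X, y = separable_features
    a = BPNNClassifier(random_state=3).fit(X, y)
    b = BPNNClassifier(random_state=3).fit(X, y)
    for name in ("W1_", "b1_", "W2_", "b2_"):
        np.testing.assert_array_equal(getattr(a, name), getattr(b, name))
    assert a.loss_curve_ == b.loss_curve_


def test_loss_curve_decreases(separable_features):
    X, y = separable_features
    model = bpnn_train(X, y, seed=1)
    assert model.loss_curve_[-1] < model.loss_curve_[0]


def test_training_rejects_missing_class(separable_features):
    X, y = separable_features
    mask = y != 2
    with pytest.raises(ValueError):
        bpnn_train(X[mask], y[mask])


def test_training_rejects_nonfinite_features():
    X = np.full((12, 9), np.nan)
    with pytest.raises(ValueError):
        BPNNClassifier().fit(X, np.repeat([0, 1, 2], 4))


def test_probabilities_sum_to_one(separable_features):
    X, y = separable_features
    model = bpnn_train(X, y, seed=0)
    rng = np.random.default_rng(5)
    _, proba = bpnn_predict(model, rng.normal(size=(20, 9)))
    np.testing.assert_allclose(proba.sum(axis=1), 1.0, atol=1e-12)
    assert proba.min() >= 0.0


def test_prediction_invariant_to_row_duplication(separable_features):
    X, y = separable_features
    model = bpnn_train(X, y, seed=0)
    single = model.predict_proba(X[:1])
    doubled = model.predict_proba(np.vstack([X[:1], X[:1]]))
    np.testing.assert_array_equal(doubled[0], doubled[1])
    np.testing.assert_allclose(doubled[0], single[0], atol=1e-15)


def test_predict_rejects_wrong_feature_count(separable_features):
    X, y = separable_features
    model = bpnn_train(X, y, seed=0)
    with pytest.raises(ValueError):
        model.predict(np.zeros((3, 5)))


def test_forward_pass_matches_hand_arithmetic():
    # one-sample fixture with hand-set weights: the network must equal
    # softmax(W2' sigmoid(W1' x + b1) + b2) computed longhand
    model = BPNNClassifier(n_hidden=2)
    model.classes_ = np.array([0, 1, 2])
    model.mean_ = np.zeros(3)
    model.scale_ = np.ones(3)
    model.W1_ = np.array([[1.0, 0.0], [0.0, 1.0], [0.5, -0.5]])
    model.b1_ = np.array([0.1, -0.1])
    model.W2_ = np.array([[1.0, -1.0, 0.0], [0.0, 1.0, -1.0]])
    model.b2_ = np.array([0.0, 0.1, 0.2])
    x = np.array([0.2, -0.4, 0.6])
    h1 = 1 / (1 + np.exp(-(0.2 * 1.0 + (-0.4) * 0.0 + 0.6 * 0.5 + 0.1)))
    h2 = 1 / (1 + np.exp(-(0.2 * 0.0 + (-0.4) * 1.0 + 0.6 * (-0.5) - 0.1)))
    logits = np.array([h1 * 1.0, -h1 + h2 + 0.1, -h2 + 0.2])
    expected = np.exp(logits) / np.exp(logits).sum()
    np.testing.assert_allclose(model.predict_proba(x)[0], expected, atol=1e-12)


def test_softmax_sigmoid_stable_at_extremes():
    assert np.isfinite(_softmax(np.array([[1e4, -1e4, 0.0]]))).all()
    assert _sigmoid(np.array([-1e4]))[0] < 1e-200


# -- cross-validation --------------------------------------------------

def test_cv_folds_stratified_and_disjoint(tremor_dataset):
    from sklearn.model_selection import StratifiedKFold

    X, y = tremor_dataset
    folds = 5
    splitter = StratifiedKFold(n_splits=folds, shuffle=True, random_state=0)
    seen = []
    sizes = []
    for _, test_idx in splitter.split(X, y):
        seen.extend(test_idx)
        sizes.append(len(test_idx))
        counts = np.bincount(y[test_idx], minlength=3)
        assert counts.max() - counts.min() <= 1
    assert sorted(seen) == list(range(len(y)))
    assert max(sizes) - min(sizes) <= 1


def test_cv_selects_good_model_on_separable_data(separable_features):
    X, y = separable_features
    best, best_acc, results = cross_validate(
        X, y, folds=5, seed=0, epochs=150,
        hyper_grid=[{"n_hidden": 3, "learning_rate": 0.05},
                    {"n_hidden": 6, "learning_rate": 0.05}],
    )
    assert best_acc >= 0.95
    assert set(best) == {"n_hidden", "learning_rate"}


def test_cv_reduces_folds_with_rare_class(separable_features):
    X, y = separable_features
    idx = np.concatenate([np.where(y == 0)[0], np.where(y == 1)[0],
                          np.where(y == 2)[0][:3]])
    with pytest.warns(UserWarning, match="reducing folds"):
        cross_validate(X[idx], y[idx], folds=10, seed=0, epochs=20)


# -- evaluation --------------------------------------------------------

def test_micro_recall_equals_accuracy():
    rng = np.random.default_rng(4)
    conf = rng.integers(0, 20, size=(3, 3))
    report = report_from_confusion(conf)
    micro_recall = np.trace(conf) / conf.sum()
    assert report.accuracy == pytest.approx(micro_recall)


def test_f1_fixed_point_when_precision_equals_recall():
    report = report_from_confusion([[6, 2, 0], [2, 6, 0], [0, 0, 8]])
    name = report.class_names[0]
    assert report.precision[name] == report.recall[name]
    assert report.f1[name] == pytest.approx(report.precision[name])


def test_perfect_predictions_all_metrics_one(separable_features):
    X, y = separable_features
    model = bpnn_train(X, y, seed=0)
    report = evaluate(model, X, y)
    assert report.accuracy == 1.0
    assert np.all(np.diag(report.confusion) > 0)
    assert report.confusion.sum() == np.trace(report.confusion)
    for name in report.class_names:
        assert report.precision[name] == report.recall[name] == report.f1[name] == 1.0
        assert report.auc[name] == pytest.approx(1.0)


def test_evaluate_rejects_empty_test_set(separable_features):
    X, y = separable_features
    model = bpnn_train(X, y, seed=0)
    with pytest.raises(ValueError):
        evaluate(model, np.zeros((0, 9)), np.array([]))
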