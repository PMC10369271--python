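"""Tremor-severity classification with a from-scratch 9-6-3 network.

A single-hidden-layer back-propagation neural network (BPNN) maps the
9-element tremor feature vector to the three severity classes 0 = no
tremor, 1 = mild, 2 = severe (the UPDRS static-tremor item 0 regrouped
as class 0, items 1-2 as class 1, items 3-4 as class 2).  Features are
standardized, the hidden layer is sigmoid, the output softmax, and the
cross-entropy loss is minimized by seeded mini-batch gradient descent.
Stratified ten-fold cross-validation selects hyperparameters, and the
evaluation report carries the confusion matrix, per-class
precision/recall/F1 and one-vs-rest ROC AUC.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import StratifiedKFold

CLASS_NAMES = ("No tremor", "Mild tremor", "Severe tremor")


def _softmax(z: np.ndarray) -> np.ndarray:
    z = z - z.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


def _sigmoid(z: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-np.clip(z, -500, 500)))


class BPNNClassifier(BaseEstimator, ClassifierMixin):
    """Single-hidden-layer softmax classifier trained by back-propagation.

    Parameters
    ----------
    n_hidden : int
        Hidden-layer width (six in the default architecture).
    learning_rate, epochs, batch_size : training schedule of the
        mini-batch gradient descent.
    random_state : seed controlling weight init and batch shuffling;
        two fits with the same seed and data are bitwise identical.

    Attributes (after :meth:`fit`)
    ------------------------------
    W1_, b1_, W2_, b2_ : network weights/biases
    mean_, scale_ : per-feature standardization parameters
    classes_ : sorted unique labels
    loss_curve_ : mean cross-entropy per epoch
    """

    def __init__(self, n_hidden: int = 6, learning_rate: float = 0.05,
                 epochs: int = 500, batch_size: int = 16, random_state: int = 0):
        self.n_hidden = n_hidden
        self.learning_rate = learning_rate
        self.epochs = epochs
        self.batch_size = batch_size
        self.random_state = random_state

    def fit(self, X, y) -> "BPNNClassifier":
        X = np.asarray(X, dtype=float)
        y = np.asarray(y)
        if X.ndim != 2 or X.shape[0] != y.shape[0]:
            raise ValueError("X must be (n_samples, n_features) aligned with y")
        if not np.all(np.isfinite(X)):
            raise ValueError("features must be finite")
        if X.shape[0] < 10:
            raise ValueError("need at least 10 training samples")
        self.classes_ = np.unique(y)
        if self.classes_.size < 2:
            raise ValueError("need at least two classes present in y")
        n, d = X.shape
        k = self.classes_.size
        y_idx = np.searchsorted(self.classes_, y)

        self.mean_ = X.mean(axis=0)
        self.scale_ = X.std(axis=0)
        self.scale_[self.scale_ == 0] = 1.0
        Xs = (X - self.mean_) / self.scale_

        rng = np.random.default_rng(self.random_state)
        W1 = rng.normal(0.0, 1.0 / np.sqrt(d), size=(d, self.n_hidden))
        b1 = np.zeros(self.n_hidden)
        W2 = rng.normal(0.0, 1.0 / np.sqrt(self.n_hidden), size=(self.n_hidden, k))
        b2 = np.zeros(k)
        onehot = np.eye(k)[y_idx]

        self.loss_curve_ = []
        lr = self.learning_rate
        for _ in range(self.epochs):
            order = rng.permutation(n)
            for start in range(0, n, self.batch_size):
                idx = order[start:start + self.batch_size]
                xb, tb = Xs[idx], onehot[idx]
                h = _sigmoid(xb @ W1 + b1)
                p = _softmax(h @ W2 + b2)
                # gradient of mean cross-entropy wrt pre-softmax logits
                g_out = (p - tb) / len(idx)
                g_h = (g_out @ W2.T) * h * (1 - h)
                W2 -= lr * (h.T @ g_out)
                b2 -= lr * g_out.sum(axis=0)
                W1 -= lr * (xb.T @ g_h)
                b1 -= lr * g_h.sum(axis=0)
            p_all = _softmax(_sigmoid(Xs @ W1 + b1) @ W2 + b2)
            loss = -float(np.mean(np.log(p_all[np.arange(n), y_idx] + 1e-12)))
            self.loss_curve_.append(loss)
        self.W1_, self.b1_, self.W2_, self.b2_ = W1, b1, W2, b2
        return self

    def predict_proba(self, X) -> np.ndarray:
        if not hasattr(self, "W1_"):
            raise RuntimeError("model is not fitted")
        X = np.asarray(X, dtype=float)
        if X.ndim == 1:
            X = X[None, :]
        if X.shape[1] != self.W1_.shape[0]:
            raise ValueError(
                f"expected {self.W1_.shape[0]} features, got {X.shape[1]}"
            )
        Xs = (X - self.mean_) / self.scale_
        return _softmax(_sigmoid(Xs @ self.W1_ + self.b1_) @ self.W2_ + self.b2_)

    def predict(self, X) -> np.ndarray:
        return self.classes_[np.argmax(self.predict_proba(X), axis=1)]


@dataclass
class EvalReport:
    """Multiclass evaluation summary (rows of ``confusion`` = true label)."""

    confusion: np.ndarray
    accuracy: float
    precision: dict[str, float]
    recall: dict[str, float]
    f1: dict[str, float]
    auc: dict[str, float] = field(default_factory=dict)
    class_names: tuple[str, ...] = CLASS_NAMES

    def to_dict(self) -> dict:
        return {
            "confusion": self.confusion.tolist(),
            "accuracy": self.accuracy,
            "precision": self.precision,
            "recall": self.recall,
            "f1": self.f1,
            "auc": self.auc,
            "class_names": list(self.class_names),
        }


def report_from_confusion(confusion, class_names=CLASS_NAMES) -> EvalReport:
    """Accuracy and per-class precision/recall/F1 from a confusion matrix.

    Conventions: precision_c = conf[c,c] / column-sum (0 if the class is
    never predicted), recall_c = conf[c,c] / row-sum, F1 the harmonic
    mean (0 when precision + recall = 0).
    """
    conf = np.asarray(confusion, dtype=int)
    if conf.ndim != 2 or conf.shape[0] != conf.shape[1]:
        raise ValueError("confusion matrix must be square")
    if (conf < 0).any() or conf.sum() == 0:
        raise ValueError("confusion entries must be non-negative with a positive total")
    total = conf.sum()
    precision, recall, f1 = {}, {}, {}
    for c, name in enumerate(class_names):
        col = conf[:, c].sum()
        row = conf[c, :].sum()
        p = conf[c, c] / col if col else 0.0
        r = conf[c, c] / row if row else 0.0
        precision[name] = float(p)
        recall[name] = float(r)
        f1[name] = float(2 * p * r / (p + r)) if (p + r) else 0.0
    return EvalReport(
        confusion=conf,
        accuracy=float(np.trace(conf) / total),
        precision=precision,
        recall=recall,
        f1=f1,
        class_names=tuple(class_names),
    )


def evaluate(model: BPNNClassifier, X, y, class_names=CLASS_NAMES) -> EvalReport:
    """Confusion matrix, per-class metrics and one-vs-rest ROC AUC on a test set."""
    y = np.asarray(y)
    if y.size == 0:
        raise ValueError("empty test set")
    proba = model.predict_proba(X)
    pred = model.classes_[np.argmax(proba, axis=1)]
    k = len(class_names)
    conf = np.zeros((k, k), dtype=int)
    label_pos = {label: i for i, label in enumerate(model.classes_)}
    for yt, yp in zip(y, pred):
        conf[label_pos[yt], label_pos[yp]] += 1
    report = report_from_confusion(conf, class_names)
    for i, name in enumerate(class_names):
        mask = (y == model.classes_[i]).astype(int)
        if 0 < mask.sum() < mask.size:
            report.auc[name] = float(roc_auc_score(mask, proba[:, i]))
        else:
            report.auc[name] = float("nan")
    return report


def cross_validate(
    X, y,
    folds: int = 10,
    hyper_grid: list[dict] | None = None,
    seed: int = 0,
    epochs: int = 300,
):
    """Stratified k-fold grid search for the network hyperparameters.

    Every sample is tested exactly once per grid point.  Ties on mean
    validation accuracy go to fewer hidden nodes, then lower learning
    rate.  If the rarest class has fewer members than ``folds``, folds
    are reduced to that count with a warning.

    Returns ``(best_params, best_mean_accuracy, results)`` where
    ``results`` maps each grid point (as a tuple of sorted items) to its
    mean validation accuracy.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    if hyper_grid is None:
        hyper_grid = [
            {"n_hidden": h, "learning_rate": lr}
            for h in (3, 6) for lr in (0.05, 0.1)
        ]
    min_class = np.bincount(np.searchsorted(np.unique(y), y)).min()
    if min_class < folds:
        warnings.warn(
            f"rarest class has {min_class} members; reducing folds from {folds}"
        )
        folds = int(min_class)
    if folds < 2:
        raise ValueError("need at least 2 usable folds")
    splitter = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    results: dict[tuple, float] = {}
    for params in hyper_grid:
        accs = []
        for train_idx, test_idx in splitter.split(X, y):
            model = BPNNClassifier(epochs=epochs, random_state=seed, **params)
            model.fit(X[train_idx], y[train_idx])
            accs.append(float(np.mean(model.predict(X[test_idx]) == y[test_idx])))
        results[tuple(sorted(params.items()))] = float(np.mean(accs))
    best_key = min(
        results,
        key=lambda key: (
            -results[key],
            dict(key).get("n_hidden", 0),
            dict(key).get("learning_rate", 0.0),
        ),
    )
    return dict(best_key), results[best_key], results


def bpnn_train(features, labels, n_hidden: int = 6, learning_rate: float = 0.05,
               epochs: int = 500, batch_size: int = 16, seed: int = 0) -> BPNNClassifier:
    """Train the severity classifier; requires all three classes present."""
    labels = np.asarray(labels)
    if np.unique(labels).size != 3:
        raise ValueError("training labels must contain all three severity classes")
    return BPNNClassifier(
        n_hidden=n_hidden, learning_rate=learning_rate, epochs=epochs,
        batch_size=batch_size, random_state=seed,
    ).fit(features, labels)


def bpnn_predict(model: BPNNClassifier, features):
    """Predicted labels and per-class probabilities."""
    proba = model.predict_proba(features)
    return model.classes_[np.argmax(proba, axis=1)], proba
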