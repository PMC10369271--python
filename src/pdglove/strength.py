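"""Muscle-strength grading (Lovett M0-M5) by 1-D k-means interval partitioning.

A population of maximum grip/pinch force values is clustered with
Lloyd's algorithm into k=6 groups; the midpoints between adjacent sorted
cluster centers partition the force axis into six intervals which map
one-to-one onto the Lovett grades (M0 = weakest interval).  A subject's
grade is the interval containing their maximum force over the four test
actions.

The k-means loop is written out explicitly: assignment of each sample
x(i) to the nearest center mu(j) by squared distance, then update of
each center to the mean of its cluster, iterated to convergence.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.base import BaseEstimator

from .config import RunConfig
from .io import Recording
from .preprocess import ewa_filter

ACTIONS = (
    "Grasp the cylinder",
    "Pinch objects with fingertip",
    "Grasp the ball",
    "Click objects with finger",
)

M_GRADES = ("M0", "M1", "M2", "M3", "M4", "M5")


class IntervalKMeans(BaseEstimator):
    """1-D k-means that exposes its Voronoi interval boundaries.

    Lloyd iterations (nearest-center assignment, cluster-mean update)
    run until the assignment is stable or ``max_iter`` is hit; the best
    of ``n_restarts`` k-means++ seedings by within-cluster sum of
    squares (WCSS) is kept.  Centers are sorted ascending after fitting,
    so cluster index equals interval rank.

    Attributes (after :meth:`fit`)
    ------------------------------
    centers_ : ndarray (k,), sorted ascending
    boundaries_ : ndarray (k-1,), midpoints of adjacent centers
    labels_ : ndarray (n,), interval index per training sample
    n_per_cluster_ : ndarray (k,)
    inertia_ : float, final WCSS
    inertia_path_ : list of float, WCSS after each Lloyd iteration of
        the winning restart (non-increasing)
    """

    def __init__(self, k: int = 6, n_restarts: int = 10, max_iter: int = 300,
                 random_state: int = 0):
        self.k = k
        self.n_restarts = n_restarts
        self.max_iter = max_iter
        self.random_state = random_state

    # -- internals -----------------------------------------------------
    @staticmethod
    def _assign(x: np.ndarray, centers: np.ndarray) -> np.ndarray:
        return np.argmin(np.abs(x[:, None] - centers[None, :]), axis=1)

    @staticmethod
    def _wcss(x: np.ndarray, centers: np.ndarray, labels: np.ndarray) -> float:
        return float(np.sum((x - centers[labels]) ** 2))

    def _init_plus_plus(self, x: np.ndarray, rng: np.random.Generator) -> np.ndarray:
        centers = [x[rng.integers(x.size)]]
        for _ in range(1, self.k):
            d2 = np.min((x[:, None] - np.array(centers)[None, :]) ** 2, axis=1)
            total = d2.sum()
            if total == 0:
                centers.append(x[rng.integers(x.size)])
            else:
                centers.append(x[rng.choice(x.size, p=d2 / total)])
        return np.array(centers, dtype=float)

    def _lloyd(self, x: np.ndarray, centers: np.ndarray, rng: np.random.Generator):
        labels = self._assign(x, centers)
        path = [self._wcss(x, centers, labels)]
        for _ in range(self.max_iter):
            new_centers = centers.copy()
            for j in range(self.k):
                members = x[labels == j]
                if members.size:
                    new_centers[j] = members.mean()
                else:
                    # re-seed an empty cluster at the point farthest
                    # from its current center
                    new_centers[j] = x[np.argmax(np.abs(x - centers[j]))]
            new_labels = self._assign(x, new_centers)
            centers = new_centers
            path.append(self._wcss(x, centers, new_labels))
            if np.array_equal(new_labels, labels):
                labels = new_labels
                break
            labels = new_labels
        return centers, labels, path

    # -- sklearn surface -----------------------------------------------
    def fit(self, X, y=None) -> "IntervalKMeans":
        x = np.asarray(X, dtype=float).ravel()
        if not np.all(np.isfinite(x)):
            raise ValueError("values must be finite")
        if x.size < self.k:
            raise ValueError(f"need at least k={self.k} samples, got {x.size}")
        if self.k < 1:
            raise ValueError("k must be >= 1")
        if self.k > 1 and np.ptp(x) == 0:
            raise ValueError(
                "all values identical: cannot partition into k > 1 intervals"
            )
        rng = np.random.default_rng(self.random_state)
        best = None
        for _ in range(self.n_restarts):
            centers0 = self._init_plus_plus(x, rng)
            centers, labels, path = self._lloyd(x, centers0, rng)
            wcss = path[-1]
            if best is None or wcss < best[0] - 1e-12:
                best = (wcss, centers, labels, path)
        _, centers, _, path = best
        order = np.argsort(centers)
        self.centers_ = centers[order]
        self.boundaries_ = (self.centers_[:-1] + self.centers_[1:]) / 2.0
        self.labels_ = self.predict(x)
        self.n_per_cluster_ = np.bincount(self.labels_, minlength=self.k)
        self.inertia_ = self._wcss(x, self.centers_, self.labels_)
        self.inertia_path_ = path
        return self

    def predict(self, X) -> np.ndarray:
        """Interval index of each value; a value exactly on a boundary
        goes to the upper interval (half-open convention)."""
        if not hasattr(self, "centers_"):
            raise RuntimeError("model is not fitted")
        x = np.asarray(X, dtype=float).ravel()
        return np.searchsorted(self.boundaries_, x, side="right")


# -- thin functional wrappers ------------------------------------------

def kmeans_fit(values, k: int = 6, seed: int = 0, n_restarts: int = 10) -> IntervalKMeans:
    return IntervalKMeans(k=k, n_restarts=n_restarts, random_state=seed).fit(values)


def interval_boundaries(model: IntervalKMeans) -> np.ndarray:
    if not hasattr(model, "boundaries_"):
        raise RuntimeError("model is not fitted")
    return model.boundaries_


def grade_strength(overall_max: float, model: IntervalKMeans) -> str:
    """Map a maximum force value to its Lovett grade under the fitted partition."""
    if model.k != 6:
        raise ValueError(f"Lovett grading needs a k=6 model, got k={model.k}")
    return M_GRADES[int(model.predict([overall_max])[0])]


@dataclass
class StrengthResult:
    per_action_max: dict[str, float]
    overall_max: float
    grade: str


def assess_strength(
    recordings: list[Recording],
    model: IntervalKMeans,
    config: RunConfig | None = None,
) -> StrengthResult:
    """Grade muscle strength from pressure recordings of the four actions.

    Each pressure channel is EWA-smoothed; the per-action maximum is the
    peak over channels and time, and the grade comes from the overall
    maximum across actions.
    """
    config = config or RunConfig()
    if not recordings:
        raise ValueError("assess_strength needs at least one pressure recording")
    per_action: dict[str, float] = {}
    for rec in recordings:
        if rec.kind != "pressure":
            raise ValueError(f"expected pressure recordings, got kind={rec.kind!r}")
        action = rec.meta.get("action", "<unknown>")
        peak = max(
            float(ewa_filter(rec.data[:, i], config.ewa_alpha).max())
            for i in range(rec.n_channels)
        )
        per_action[action] = max(per_action.get(action, -np.inf), peak)
    overall = max(per_action.values())
    return StrengthResult(
        per_action_max=per_action,
        overall_max=overall,
        grade=grade_strength(overall, model),
    )
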