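"""Instance-based transfer learning: TrAdaBoost over weighted linear SVMs.

The ensemble trains on pooled source- and target-domain rows.  Each round
fits a linear SVM whose per-sample misclassification penalties are the
current instance weights, measures the weighted 0/1 error on the target rows
only, and then reweights: misclassified source rows are discounted by the
fixed factor ``beta = 1 / (1 + sqrt(2 ln n_source / N))`` while misclassified
target rows are boosted by ``1 / beta_t`` with ``beta_t = eps_t / (1 -
eps_t)`` — source instances inconsistent with the target concept fade away,
hard target instances gain influence.  Prediction is a plurality vote with
weight ``ln(1/beta_t)`` over the second half of the rounds, which in the
binary case reduces exactly to the classical product-form final hypothesis.

The multiclass behaviour (0/1 disagreement in the updates, vote over class
labels) is the SAMME-style generalisation of that binary rule.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from sklearn.svm import SVC

__all__ = [
    "DegenerateFitError",
    "WeightedDataset",
    "TrAdaBoostModel",
    "fit_weighted_svm",
    "source_discount",
    "tradaboost_fit",
    "tradaboost_predict",
    "evaluate_accuracy",
]

#: Clipping band for the per-round target error (keeps beta_t inside (0, 1)).
EPS_MIN = 1e-10
EPS_MAX = 0.499

#: Rounds with raw target error >= 0.5 tolerated before stopping early.
MAX_BAD_ROUNDS = 5


class DegenerateFitError(ValueError):
    """Raised when a base fit is impossible (e.g. one effective class)."""


@dataclass(eq=False)
class WeightedDataset:
    """Pooled training rows with origin flags and instance weights."""

    X: np.ndarray
    y: np.ndarray
    origin: np.ndarray  # per-row flag, "source" or "target"
    w: np.ndarray

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=float)
        self.y = np.asarray(self.y)
        self.origin = np.asarray(self.origin)
        self.w = np.asarray(self.w, dtype=float)
        n = self.X.shape[0]
        if not (len(self.y) == len(self.origin) == len(self.w) == n):
            raise ValueError("X, y, origin and w must agree in row count")
        if np.any(~np.isfinite(self.w)) or np.any(self.w < 0):
            raise ValueError("weights must be finite and non-negative")
        if self.w.sum() <= 0:
            raise ValueError("total weight must be positive")


def fit_weighted_svm(data: WeightedDataset, C: float = 1.0) -> SVC:
    """Linear-kernel SVM with per-sample penalty weights.

    Weights are normalised to mean 1 over the retained rows, so scaling all
    weights by a common factor leaves the fit unchanged at fixed C.
    Zero-weight rows are dropped outright (a zero penalty row cannot
    constrain the margin).
    """
    keep = data.w > 0
    X, y, w = data.X[keep], data.y[keep], data.w[keep]
    classes = np.unique(y)
    if len(classes) < 2:
        raise DegenerateFitError(
            f"need >= 2 classes with positive weight, got {classes.tolist()}"
        )
    w = w * (len(w) / w.sum())
    clf = SVC(kernel="linear", C=C)
    clf.fit(X, y, sample_weight=w)
    return clf


def source_discount(n_source: int, N: int) -> float:
    """The fixed source down-weighting factor beta.

    ``beta = 1 / (1 + sqrt(2 ln n_source / N))``; by convention 1.0 when the
    source pool is empty (nothing to discount).
    """
    if N < 1:
        raise ValueError("N must be >= 1")
    if n_source <= 0:
        return 1.0
    return 1.0 / (1.0 + math.sqrt(2.0 * math.log(n_source) / N))


@dataclass(eq=False)
class TrAdaBoostModel:
    """Fitted ensemble: ordered base hypotheses and their vote weights."""

    hypotheses: list
    beta_t: np.ndarray
    beta_source: float
    N: int
    classes: np.ndarray
    history: list[dict] | None = None

    @property
    def n_trained(self) -> int:
        return len(self.hypotheses)

    @property
    def vote_start(self) -> int:
        """First 1-based round included in the vote (second half of N)."""
        start = math.ceil(self.N / 2)
        # If training stopped before the nominal window opens, vote over
        # whatever was trained rather than returning nothing.
        return min(start, self.n_trained)


def tradaboost_fit(
    source_X: np.ndarray,
    source_y: Sequence,
    target_X: np.ndarray,
    target_y: Sequence,
    N: int,
    C: float = 1.0,
    rng=None,
    *,
    record_history: bool = False,
) -> TrAdaBoostModel:
    """Train the TrAdaBoost ensemble.

    The source pool may be empty, in which case the procedure reduces to an
    AdaBoost-style boosted SVM on the target rows.  ``rng`` is accepted for
    interface symmetry but unused: with penalty-weighted (not resampled) base
    learners the whole procedure is deterministic.

    Raw target errors >= 0.5 are clipped to :data:`EPS_MAX`; after more than
    :data:`MAX_BAD_ROUNDS` consecutive such rounds training stops early.
    """
    del rng  # deterministic procedure; see docstring
    target_X = np.asarray(target_X, dtype=float)
    target_y = np.asarray(target_y)
    source_y = np.asarray(source_y)
    source_X = np.asarray(source_X, dtype=float)
    if len(source_y) == 0:
        source_X = np.empty((0, target_X.shape[1]))
    if N < 1:
        raise ValueError("N must be >= 1")
    if len(target_y) == 0 or len(np.unique(target_y)) < 2:
        raise ValueError("target set must be non-empty with >= 2 classes")
    if len(source_y) and source_X.shape[1] != target_X.shape[1]:
        raise ValueError("source and target feature dimensions differ")

    n_src, n_tgt = len(source_y), len(target_y)
    X = np.vstack([source_X, target_X]) if n_src else target_X
    y = np.concatenate([source_y, target_y])
    is_target = np.zeros(n_src + n_tgt, dtype=bool)
    is_target[n_src:] = True
    origin = np.where(is_target, "target", "source")

    beta = source_discount(n_src, N)
    classes = np.unique(y)
    w = np.full(n_src + n_tgt, 1.0 / (n_src + n_tgt))

    hypotheses: list = []
    beta_ts: list[float] = []
    history: list[dict] = []
    bad_rounds = 0
    for _ in range(N):
        p = w / w.sum()
        clf = fit_weighted_svm(WeightedDataset(X, y, origin, p), C=C)
        miss = clf.predict(X) != y
        eps_raw = float(p[is_target & miss].sum() / p[is_target].sum())
        eps = float(np.clip(eps_raw, EPS_MIN, EPS_MAX))
        beta_t = eps / (1.0 - eps)
        w = p.copy()
        w[~is_target & miss] *= beta
        w[is_target & miss] /= beta_t
        hypotheses.append(clf)
        beta_ts.append(beta_t)
        if record_history:
            history.append(
                {
                    "w_start": p,
                    "w_updated": w.copy(),
                    "miss": miss,
                    "is_target": is_target,
                    "eps_raw": eps_raw,
                    "eps": eps,
                }
            )
        bad_rounds = bad_rounds + 1 if eps_raw >= 0.5 else 0
        if bad_rounds > MAX_BAD_ROUNDS:
            break

    return TrAdaBoostModel(
        hypotheses=hypotheses,
        beta_t=np.asarray(beta_ts),
        beta_source=beta,
        N=N,
        classes=classes,
        history=history if record_history else None,
    )


def tradaboost_predict(model: TrAdaBoostModel, X: np.ndarray) -> np.ndarray:
    """Vote-weighted prediction over the second half of the rounds.

    Each hypothesis ``t`` in rounds ``ceil(N/2) .. n_trained`` casts a vote
    of weight ``ln(1/beta_t)`` for its predicted class; ties go to the lowest
    class label in canonical (sorted) order.
    """
    if model.n_trained < 1:
        raise ValueError("model has no trained hypotheses")
    X = np.asarray(X, dtype=float)
    expected = model.hypotheses[0].n_features_in_
    if X.ndim != 2 or X.shape[1] != expected:
        raise ValueError(f"expected feature dimension {expected}, got {X.shape}")
    class_index = {label: i for i, label in enumerate(model.classes)}
    votes = np.zeros((X.shape[0], len(model.classes)))
    for t in range(model.vote_start - 1, model.n_trained):
        weight = math.log(1.0 / model.beta_t[t])
        pred = model.hypotheses[t].predict(X)
        cols = np.fromiter((class_index[p] for p in pred), dtype=int, count=len(pred))
        votes[np.arange(len(pred)), cols] += weight
    return model.classes[np.argmax(votes, axis=1)]


def evaluate_accuracy(predicted: Sequence, truth: Sequence) -> float:
    """Fraction of exact label matches."""
    predicted = np.asarray(predicted)
    truth = np.asarray(truth)
    if predicted.shape != truth.shape or predicted.size == 0:
        raise ValueError("predicted and truth must be equal-length and non-empty")
    return float(np.mean(predicted == truth))
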