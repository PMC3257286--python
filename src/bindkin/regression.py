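"""Ordinary least squares on descriptor subsets with CV metrics.

This is the learner inside feature selection: plain OLS of a log10 rate
on a small set of descriptor columns, scored by k-fold cross-validated
RMSE during the search and by leave-one-out (LOO) metrics when a model
is stored.  LOO uses the hat-matrix closed form — for OLS the residual
of observation i under the model fit without i is e_i / (1 − h_ii) — so
it costs one fit, not n.

Weights are reported both in raw response-per-descriptor units and as
normalized (z-score) weights: the coefficients that would result from
z-scoring each feature (sample sd, n−1), i.e. w_j · sd(x_j).  Normalized
weights are comparable across descriptors with different units.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from .screening import pearson
from .tables_io import RateTable

logger = logging.getLogger(__name__)


def rmse(pred, obs) -> float:
    """Root mean squared difference between two equal-length vectors."""
    pred = np.asarray(pred, dtype=float)
    obs = np.asarray(obs, dtype=float)
    if pred.shape != obs.shape or pred.ndim != 1:
        raise ValueError("pred and obs must be equal-length 1-D vectors")
    if pred.size == 0:
        raise ValueError("rmse of empty vectors is undefined")
    d = pred - obs
    return float(np.sqrt(d @ d / d.size))


@dataclass
class LinearRateModel:
    """Intercept + ordered (feature, weight) linear model for a log10 rate."""

    target: str  # log10_kon | log10_koff
    features: tuple[str, ...]
    intercept: float
    weights: tuple[float, ...]
    normalized_weights: tuple[float, ...]
    metrics: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.features = tuple(self.features)
        self.weights = tuple(float(w) for w in self.weights)
        self.normalized_weights = tuple(float(w) for w in self.normalized_weights)
        if not (len(self.features) == len(self.weights)
                == len(self.normalized_weights)):
            raise ValueError("features, weights and normalized_weights "
                             "must have equal length")
        vals = (self.intercept, *self.weights, *self.normalized_weights,
                *self.metrics.values())
        if not np.all(np.isfinite(list(vals))):
            raise ValueError("non-finite model parameter or metric")

    @property
    def n_features(self) -> int:
        return len(self.features)

    def predict(self, X) -> np.ndarray:
        """Evaluate on a (n, n_features) matrix, columns in feature order."""
        X = np.atleast_2d(np.asarray(X, dtype=float))
        if X.shape[1] != self.n_features:
            raise ValueError(
                f"expected {self.n_features} feature columns, got {X.shape[1]}"
            )
        return self.intercept + X @ np.asarray(self.weights)

    def predict_table(self, base) -> np.ndarray:
        """Evaluate on a DescriptorTable, pulling columns by name."""
        return self.predict(base.columns(self.features))

    def to_dict(self) -> dict:
        return {
            "target": self.target,
            "features": list(self.features),
            "weights": list(self.weights),
            "intercept": self.intercept,
            "normalized_weights": list(self.normalized_weights),
            "metrics": dict(self.metrics),
        }

    @classmethod
    def from_dict(cls, doc: dict) -> "LinearRateModel":
        return cls(
            target=doc["target"],
            features=tuple(doc["features"]),
            intercept=float(doc["intercept"]),
            weights=tuple(doc["weights"]),
            normalized_weights=tuple(doc["normalized_weights"]),
            metrics=dict(doc.get("metrics", {})),
        )


def save_model(model: LinearRateModel, path) -> None:
    Path(path).write_text(json.dumps(model.to_dict(), indent=2))


def load_model(path) -> LinearRateModel:
    return LinearRateModel.from_dict(json.loads(Path(path).read_text()))


@dataclass(frozen=True)
class FoldPlan:
    """A fixed assignment of rows to k cross-validation folds.

    One plan is drawn per feature-selection run and shared by every
    candidate subset, so subset comparisons are paired.
    """

    k: int
    assignment: tuple[int, ...]
    seed: int

    def __post_init__(self) -> None:
        counts = np.bincount(self.assignment, minlength=self.k)
        if len(counts) != self.k or counts.min() == 0:
            raise ValueError("every fold must receive at least one row")
        if counts.max() - counts.min() > 1:
            raise ValueError("fold sizes must differ by at most one")

    def test_indices(self, fold: int) -> np.ndarray:
        return np.flatnonzero(np.asarray(self.assignment) == fold)


def make_fold_plan(n: int, k: int, seed: int) -> FoldPlan:
    """Uniform random fold assignment with sizes differing by <= 1."""
    if k < 2:
        raise ValueError("need at least 2 folds")
    if n < k:
        raise ValueError(f"cannot split {n} rows into {k} folds")
    rng = np.random.default_rng(seed)
    assignment = np.arange(n) % k
    rng.shuffle(assignment)
    return FoldPlan(k=k, assignment=tuple(int(a) for a in assignment), seed=seed)


def _design(table: RateTable, features: Sequence[str]) -> np.ndarray:
    X = table.base.columns(features)
    return np.column_stack([np.ones(X.shape[0]), X])


def _lstsq_full_rank(A: np.ndarray, y: np.ndarray, features: Sequence[str]):
    beta, _, rank, _ = np.linalg.lstsq(A, y, rcond=None)
    if rank < A.shape[1]:
        # name the columns that sit in the span of their predecessors
        suspects = []
        for j in range(1, A.shape[1]):
            if np.linalg.matrix_rank(A[:, : j + 1]) == np.linalg.matrix_rank(A[:, :j]):
                suspects.append(features[j - 1])
        raise np.linalg.LinAlgError(
            f"rank-deficient design; collinear features: {suspects or list(features)}"
        )
    return beta


def fit_ols(table: RateTable, features: Sequence[str]) -> LinearRateModel:
    """Least-squares fit of the response on the named descriptor columns."""
    features = tuple(features)
    n = table.base.n
    if n <= len(features) + 1:
        raise ValueError(
            f"need more than {len(features) + 1} rows to fit "
            f"{len(features)} features, have {n}"
        )
    A = _design(table, features)
    y = table.response
    beta = _lstsq_full_rank(A, y, features)
    resid = y - A @ beta
    sd = table.base.columns(features).std(axis=0, ddof=1)
    return LinearRateModel(
        target=table.response_name,
        features=features,
        intercept=float(beta[0]),
        weights=tuple(beta[1:]),
        normalized_weights=tuple(beta[1:] * sd),
        metrics={"rms": rmse(A @ beta, y)},
    )


def loo_metrics(table: RateTable, features: Sequence[str]) -> tuple[float, float]:
    """Leave-one-out (cv_rmse, cv_corr) via the hat-matrix closed form."""
    features = tuple(features)
    n = table.base.n
    if n < len(features) + 3:
        raise ValueError("too few rows for leave-one-out metrics")
    A = _design(table, features)
    y = table.response
    beta = _lstsq_full_rank(A, y, features)
    G = A.T @ A
    h = np.einsum("ij,ji->i", A, np.linalg.solve(G, A.T))
    if np.any(h >= 1.0 - 1e-12):
        raise np.linalg.LinAlgError(
            "a leave-one-out refit is rank-deficient (leverage 1 row)"
        )
    e_loo = (y - A @ beta) / (1.0 - h)
    pred = y - e_loo
    return rmse(pred, y), pearson(pred, y)


def kfold_rmse(table: RateTable, features: Sequence[str], plan: FoldPlan) -> float:
    """Pooled out-of-fold RMSE under a fixed fold plan.

    Reference implementation: refits on each training fold with lstsq.
    The selection loop uses the algebraically equivalent `KFoldScorer`.
    """
    features = tuple(features)
    A = _design(table, features)
    y = table.response
    if len(plan.assignment) != A.shape[0]:
        raise ValueError("fold plan does not match table row count")
    pred = np.empty_like(y)
    assignment = np.asarray(plan.assignment)
    for fold in range(plan.k):
        test = assignment == fold
        train = ~test
        if train.sum() <= A.shape[1]:
            raise ValueError(
                f"fold {fold}: {int(train.sum())} training rows cannot fit "
                f"{A.shape[1] - 1} features"
            )
        beta = _lstsq_full_rank(A[train], y[train], features)
        pred[test] = A[test] @ beta
    return rmse(pred, y)


class KFoldScorer:
    """Fast k-fold RMSE for many column subsets of one table.

    Precomputes, per fold, the Gram matrix and cross-products of the
    full intercept+descriptor design on the training rows; scoring a
    subset then only solves a small normal-equations system per fold.
    """

    def __init__(self, X: np.ndarray, y: np.ndarray, plan: FoldPlan):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=float)
        if len(plan.assignment) != X.shape[0]:
            raise ValueError("fold plan does not match matrix row count")
        A = np.column_stack([np.ones(X.shape[0]), X])
        assignment = np.asarray(plan.assignment)
        self.n = X.shape[0]
        self._folds = []
        for fold in range(plan.k):
            test = assignment == fold
            train = ~test
            At = A[train]
            self._folds.append((At.T @ At, At.T @ y[train],
                                A[test], y[test], int(train.sum())))

    def score(self, subset: Sequence[int]) -> float:
        """Pooled out-of-fold RMSE for descriptor column indices `subset`.

        Raises ``numpy.linalg.LinAlgError`` on a singular training fold.
        """
        ix = np.concatenate([[0], np.asarray(subset, dtype=int) + 1])
        sse = 0.0
        for G, b, A_test, y_test, n_train in self._folds:
            if n_train <= len(ix):
                raise ValueError("training fold too small for this subset")
            Gs = G[np.ix_(ix, ix)]
            beta = np.linalg.solve(Gs, b[ix])
            # guard against silently "solving" a singular system
            if not np.allclose(Gs @ beta, b[ix], rtol=1e-6, atol=1e-8):
                raise np.linalg.LinAlgError("singular normal equations")
            e = y_test - A_test[:, ix] @ beta
            sse += e @ e
        return float(np.sqrt(sse / self.n))


def fit_with_cv(table: RateTable, features: Sequence[str],
                cv_rmse_kfold: float | None = None) -> LinearRateModel:
    """OLS fit with LOO metrics attached (the stored-model constructor)."""
    model = fit_ols(table, features)
    cv_rmse, cv_corr = loo_metrics(table, features)
    model.metrics.update({"cv_rmse": cv_rmse, "cv_corr": cv_corr})
    if cv_rmse_kfold is not None:
        model.metrics["cv_rmse_kfold"] = float(cv_rmse_kfold)
    return model
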