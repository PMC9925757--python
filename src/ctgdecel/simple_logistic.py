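"""Boosted additive logistic regression ("simple logistic").

Multiclass LogitBoost with weighted simple (one-attribute) linear
regression functions as base learners: at every boosting iteration and for
every class, the working response is fit by the single attribute that
minimises the weighted squared error, so the final model is an additive
logistic model over individual attributes.  Boosting is capped (default 400
iterations) and stopped early when an internal validation deviance has not
improved for a patience window (default 50), after which the model is
refitted on all data for the selected number of iterations.
"""

from __future__ import annotations

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin

__all__ = ["SimpleLogistic"]

_Z_MAX = 3.0
_W_MIN = 1e-10


class SimpleLogistic(ClassifierMixin, BaseEstimator):
    """Multiclass LogitBoost with simple-regression base functions.

    Parameters
    ----------
    max_iter:
        Maximum number of boosting iterations.
    patience:
        Stop when the internal validation deviance has not reached a new
        minimum for this many iterations.
    validation_fraction:
        Fraction of the training data held out to select the iteration
        count; the final model is refit on all data.
    random_state:
        Seed for the internal validation split.
    """

    def __init__(
        self,
        max_iter: int = 400,
        patience: int = 50,
        validation_fraction: float = 0.2,
        random_state: int = 1,
    ) -> None:
        self.max_iter = max_iter
        self.patience = patience
        self.validation_fraction = validation_fraction
        self.random_state = random_state

    # -- model --------------------------------------------------------------
    def fit(self, X, y) -> "SimpleLogistic":
        X = np.asarray(X, dtype=float)
        y = np.asarray(y)
        self.classes_, y_idx = np.unique(y, return_inverse=True)
        if len(self.classes_) < 2:
            raise ValueError("need at least two classes")
        n = len(y_idx)
        rng = np.random.default_rng(self.random_state)
        # stratified internal split to pick the iteration count
        val_mask = np.zeros(n, dtype=bool)
        for j in range(len(self.classes_)):
            idx = np.flatnonzero(y_idx == j)
            rng.shuffle(idx)
            n_val = max(1, int(round(len(idx) * self.validation_fraction)))
            if len(idx) - n_val < 1:
                n_val = len(idx) - 1
            if n_val > 0:
                val_mask[idx[:n_val]] = True
        if val_mask.all() or not val_mask.any() or len(np.unique(y_idx[~val_mask])) < 2:
            best_m = self.max_iter
        else:
            _, dev_path = self._boost(
                X[~val_mask], y_idx[~val_mask], X_val=X[val_mask], y_val=y_idx[val_mask]
            )
            best_m = int(np.argmin(dev_path)) + 1
        self.ensemble_, _ = self._boost(X, y_idx, n_iter=best_m)
        self.n_iter_ = best_m
        return self

    def _boost(
        self,
        X: np.ndarray,
        y_idx: np.ndarray,
        X_val: np.ndarray | None = None,
        y_val: np.ndarray | None = None,
        n_iter: int | None = None,
    ):
        n, p = X.shape
        J = len(self.classes_)
        Y = np.zeros((n, J))
        Y[np.arange(n), y_idx] = 1.0
        F = np.zeros((n, J))
        P = np.full((n, J), 1.0 / J)
        F_val = np.zeros((len(X_val), J)) if X_val is not None else None
        ensemble: list[list[tuple[int, float, float]]] = []
        dev_path: list[float] = []
        best_dev, since_best = np.inf, 0
        total = n_iter if n_iter is not None else self.max_iter
        for _ in range(total):
            stage: list[tuple[int, float, float]] = []
            fm = np.zeros((n, J))
            fm_val = np.zeros((len(X_val), J)) if X_val is not None else None
            for j in range(J):
                w = np.clip(P[:, j] * (1.0 - P[:, j]), _W_MIN, None)
                z = np.clip((Y[:, j] - P[:, j]) / w, -_Z_MAX, _Z_MAX)
                a, alpha, beta = _best_simple_regression(X, z, w)
                stage.append((a, alpha, beta))
                fm[:, j] = alpha + beta * X[:, a]
                if fm_val is not None:
                    fm_val[:, j] = alpha + beta * X_val[:, a]
            fm = (J - 1) / J * (fm - fm.mean(axis=1, keepdims=True))
            F += fm
            P = _softmax(F)
            ensemble.append(stage)
            if fm_val is not None:
                fm_val = (J - 1) / J * (fm_val - fm_val.mean(axis=1, keepdims=True))
                F_val += fm_val
                dev = _deviance(F_val, y_val)
                dev_path.append(dev)
                if dev < best_dev - 1e-12:
                    best_dev, since_best = dev, 0
                else:
                    since_best += 1
                    if since_best >= self.patience:
                        break
        return ensemble, np.array(dev_path) if dev_path else np.array([np.inf])

    def decision_function(self, X) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        J = len(self.classes_)
        F = np.zeros((len(X), J))
        for stage in self.ensemble_:
            fm = np.zeros((len(X), J))
            for j, (a, alpha, beta) in enumerate(stage):
                fm[:, j] = alpha + beta * X[:, a]
            F += (J - 1) / J * (fm - fm.mean(axis=1, keepdims=True))
        return F

    def predict_proba(self, X) -> np.ndarray:
        return _softmax(self.decision_function(X))

    def predict(self, X) -> np.ndarray:
        return self.classes_[np.argmax(self.decision_function(X), axis=1)]


def _softmax(F: np.ndarray) -> np.ndarray:
    F = F - F.max(axis=1, keepdims=True)
    e = np.exp(F)
    return e / e.sum(axis=1, keepdims=True)


def _deviance(F: np.ndarray, y_idx: np.ndarray) -> float:
    P = _softmax(F)
    return float(-np.sum(np.log(np.clip(P[np.arange(len(y_idx)), y_idx], 1e-12, None))))


def _best_simple_regression(
    X: np.ndarray, z: np.ndarray, w: np.ndarray
) -> tuple[int, float, float]:
    """Weighted least-squares line on the single best attribute.

    Returns (attribute index, intercept, slope) minimising the weighted SSE.
    """
    sw = w.sum()
    xw_mean = (w[:, None] * X).sum(axis=0) / sw
    zw_mean = float((w * z).sum() / sw)
    xc = X - xw_mean
    sxx = (w[:, None] * xc * xc).sum(axis=0)
    sxz = (w[:, None] * xc * (z - zw_mean)[:, None]).sum(axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        beta = np.where(sxx > 1e-12, sxz / np.where(sxx > 0, sxx, 1.0), 0.0)
    # weighted SSE of each candidate line; constant terms in z cancel in argmin
    sse = -beta * sxz  # = -beta^2 * sxx, up to the common Σw(z-z̄)² term
    a = int(np.argmin(sse))
    return a, zw_mean - beta[a] * xw_mean[a], float(beta[a])
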