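"""Induction learners and lightweight grid search.

Three learner families score variable subsets and fit prediction models:
partial least squares (``pls``), ordinary linear regression (``lm``) and an
RBF-kernel support vector machine (``svm_rbf``).  SVM targets are
standardized inside each fit (the kernel is scale-sensitive) and restored on
prediction; PLS relies on its internal centering (features arrive already
z-scored).

Grid search is hand-rolled as plain fold loops: the wrapper selection
algorithms call it thousands of times on ~50-sample subsets, where
estimator-cloning frameworks would dominate the runtime.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from sklearn.cross_decomposition import PLSRegression
from sklearn.linear_model import LinearRegression
from sklearn.model_selection import KFold
from sklearn.svm import SVR

__all__ = ["LearnerSpec", "make_estimator", "param_grid", "grid_search"]

DEFAULT_SVM_C = (0.1, 0.5, 1.0, 2.0, 5.0, 10.0)
DEFAULT_SVM_GAMMA = (0.005, 0.01, 0.05, 0.1, 0.5, 1.0)


@dataclass(frozen=True)
class LearnerSpec:
    """An induction learner plus its tuning grid and resampling settings.

    ``kind``: pls | lm | svm_rbf.  ``folds``/``repeats`` govern the outer
    RMSE cross-validation; ``tuning`` is "nested" (fresh 3-fold grid search
    inside every training partition; unbiased, slower) or "tune_once" (one
    5-fold grid search on the full subset, then fixed parameters; the fast
    path for the heavy wrapper searches).
    """

    kind: str = "lm"
    pls_max_components: int = 15
    svm_C: tuple[float, ...] = DEFAULT_SVM_C
    svm_gamma: tuple[float, ...] = DEFAULT_SVM_GAMMA
    svm_epsilon: float = 0.1
    folds: int = 5
    repeats: int = 5
    seed: int = 0
    tuning: str = "nested"

    def __post_init__(self) -> None:
        if self.kind not in ("pls", "lm", "svm_rbf"):
            raise ValueError(f"unknown learner kind {self.kind!r}")
        if self.folds < 2:
            raise ValueError("folds must be >= 2")
        if self.tuning not in ("nested", "tune_once"):
            raise ValueError(f"unknown tuning mode {self.tuning!r}")
        if self.kind == "svm_rbf" and (len(self.svm_C) == 0 or len(self.svm_gamma) == 0):
            raise ValueError("empty SVM grid")


class _StandardizedSVR:
    """RBF-SVR with internal target standardization."""

    def __init__(self, C: float, gamma: float, epsilon: float = 0.1):
        self.C, self.gamma, self.epsilon = C, gamma, epsilon
        self._svr = SVR(kernel="rbf", C=C, gamma=gamma, epsilon=epsilon)

    def fit(self, X, y):
        y = np.asarray(y, dtype=float)
        self._ym = y.mean()
        self._ys = y.std()
        if self._ys < 1e-12:          # constant target: predict the constant
            self._ys = 0.0
            return self
        self._svr.fit(X, (y - self._ym) / self._ys)
        return self

    def predict(self, X):
        if self._ys == 0.0:
            return np.full(len(X), self._ym)
        return self._svr.predict(X) * self._ys + self._ym


def make_estimator(kind: str, params: dict, spec: LearnerSpec | None = None):
    if kind == "lm":
        return LinearRegression()
    if kind == "pls":
        return PLSRegression(n_components=params["n_components"], scale=False)
    if kind == "svm_rbf":
        eps = spec.svm_epsilon if spec is not None else 0.1
        return _StandardizedSVR(C=params["C"], gamma=params["gamma"], epsilon=eps)
    raise ValueError(f"unknown learner kind {kind!r}")


def param_grid(spec: LearnerSpec, n_features: int, n_train: int) -> list[dict]:
    """Hyperparameter candidates, capped to what the data can support."""
    if spec.kind == "lm":
        return [{}]
    if spec.kind == "pls":
        kmax = min(spec.pls_max_components, n_features, n_train - 1)
        if kmax < 1:
            warnings.warn("training set too small for any PLS factor; using 1")
            kmax = 1
        return [{"n_components": k} for k in range(1, kmax + 1)]
    return [{"C": c, "gamma": g} for c in spec.svm_C for g in spec.svm_gamma]


def _fit_predict(kind, params, spec, Xtr, ytr, Xte):
    est = make_estimator(kind, params, spec)
    est.fit(Xtr, ytr)
    return np.ravel(est.predict(Xte))


def grid_search(X: np.ndarray, y: np.ndarray, spec: LearnerSpec,
                folds: int, seed: int) -> dict:
    """Pick the grid entry with the lowest pooled k-fold RMSE (ties: grid order)."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    grid = param_grid(spec, X.shape[1], len(y))
    if len(grid) == 1:
        return grid[0]
    folds = min(folds, len(y))
    splits = list(KFold(folds, shuffle=True, random_state=seed).split(X))
    best_params, best_rmse = grid[0], np.inf
    for params in grid:
        sq = 0.0
        m = 0
        skip = False
        for tr, te in splits:
            if spec.kind == "pls" and params["n_components"] > min(X.shape[1], len(tr) - 1):
                skip = True
                break
            pred = _fit_predict(spec.kind, params, spec, X[tr], y[tr], X[te])
            sq += float(np.sum((y[te] - pred) ** 2))
            m += len(te)
        if skip or m == 0:
            continue
        rmse = np.sqrt(sq / m)
        if rmse < best_rmse - 1e-15:
            best_params, best_rmse = params, rmse
    return best_params
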