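"""Pigment prediction models: PLSR and RBF-SVR with LOOCV validation.

Models are fitted on a variable subset of the 32-column feature table and
validated by leave-one-out cross-validation: for each of the n samples,
feature normalization and hyperparameter tuning are redone on the other
n - 1 samples, the model is fitted and the held-out sample predicted, so no
information leaks from the held-out leaf.  Grids follow the study design:
SVR C in [0.1, 10] and gamma in [0.005, 1] (logarithmic coverage), PLSR
latent factors 1..min(15, p).

Two merit functions are reported.  The defaults are the standard
definitions: R^2 = squared Pearson correlation between measured and
predicted, RMSE = sqrt(mean((y_i - Y_i)^2)).  Printed variants of both
formulas circulate with typesetting corruption that makes them
dimensionally inconsistent (an R^2 numerator squaring the residuals over a
product of first-power deviation sums; an RMSE deviating each measurement
from the mean prediction rather than its own); those literal variants
remain available behind fidelity flags so the discrepancy can be inspected
rather than silently corrected.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .features import FeatureTable
from .learners import (DEFAULT_SVM_C, DEFAULT_SVM_GAMMA, LearnerSpec,
                       grid_search, make_estimator)

__all__ = ["ModelSpec", "FittedModel", "EvalReport", "fit_predict", "fit_full",
           "loocv", "r_squared", "rmse"]

_EPS = 1e-12


@dataclass(frozen=True)
class ModelSpec:
    """A model family plus its tuning grid."""

    family: str = "svr_rbf"              # "plsr" | "svr_rbf"
    pls_max_components: int = 15
    svm_C: tuple[float, ...] = DEFAULT_SVM_C
    svm_gamma: tuple[float, ...] = DEFAULT_SVM_GAMMA
    svm_epsilon: float = 0.1
    tune_folds: int = 5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.family not in ("plsr", "svr_rbf"):
            raise ValueError(f"unknown model family {self.family!r}")
        if self.family == "svr_rbf":
            if min(self.svm_C) < 0.1 - _EPS or max(self.svm_C) > 10 + _EPS:
                raise ValueError("SVR C grid outside [0.1, 10]")
            if min(self.svm_gamma) < 0.005 - _EPS or max(self.svm_gamma) > 1 + _EPS:
                raise ValueError("SVR gamma grid outside [0.005, 1]")
        if self.pls_max_components < 1:
            raise ValueError("need at least one latent factor")

    def _learner(self) -> LearnerSpec:
        kind = {"plsr": "pls", "svr_rbf": "svm_rbf"}[self.family]
        return LearnerSpec(kind=kind, pls_max_components=self.pls_max_components,
                           svm_C=self.svm_C, svm_gamma=self.svm_gamma,
                           svm_epsilon=self.svm_epsilon, seed=self.seed)


@dataclass
class FittedModel:
    """A tuned model fitted on a full training table, ready for mapping.

    Carries everything pixel-wise prediction needs: the variable subset, the
    training normalization parameters, the formula mode and the training
    target range (for outlier flagging).
    """

    estimator: object
    family: str
    params: dict
    subset: list[str]
    norm_means: pd.Series
    norm_sds: pd.Series
    mode: str
    target: str
    y_min: float
    y_max: float

    def predict(self, X_normalized: pd.DataFrame) -> np.ndarray:
        return np.ravel(self.estimator.predict(np.asarray(X_normalized[self.subset],
                                                          dtype=float)))


@dataclass
class EvalReport:
    """LOOCV validation report for one model x target."""

    family: str
    target: str
    subset: list[str]
    r2: float
    rmse: float
    predictions: pd.DataFrame            # columns measured, predicted
    fold_params: list[dict]
    metadata: dict = field(default_factory=dict)

    def to_json(self, path=None) -> str:
        payload = {k: v for k, v in asdict(self).items() if k != "predictions"}
        payload["predictions"] = self.predictions.to_dict(orient="list")
        text = json.dumps(payload, indent=2)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text


def r_squared(measured, predicted, definition: str = "correlation") -> float:
    """Coefficient of determination between measured and predicted values.

    definition: "correlation" (squared Pearson r, default),
    "one_minus_residual" (1 - SSres/SStot), or "as_printed" (the literal
    corrupted formula, kept for fidelity).
    """
    y = np.asarray(measured, dtype=float)
    Y = np.asarray(predicted, dtype=float)
    if len(y) != len(Y):
        raise ValueError("length mismatch")
    if len(y) < 2:
        raise ValueError("need at least 2 samples")
    dy = y - y.mean()
    dY = Y - Y.mean()
    if definition == "correlation":
        vy, vY = np.sum(dy ** 2), np.sum(dY ** 2)
        if vy < _EPS or vY < _EPS:
            raise ValueError("zero variance in measured or predicted values")
        return float((np.sum(dy * dY)) ** 2 / (vy * vY))
    if definition == "one_minus_residual":
        vy = np.sum(dy ** 2)
        if vy < _EPS:
            raise ValueError("zero variance in measured values")
        return float(1.0 - np.sum((y - Y) ** 2) / vy)
    if definition == "as_printed":
        den = np.sum(dy) * np.sum(dY)    # sums of first-power deviations (~0)
        return float(np.sum((y - Y) ** 2) / den) if abs(den) > _EPS else float("nan")
    raise ValueError(f"unknown R^2 definition {definition!r}")


def rmse(measured, predicted, as_printed: bool = False) -> float:
    """Root mean square error; the as-printed variant deviates y_i from Ȳ."""
    y = np.asarray(measured, dtype=float)
    Y = np.asarray(predicted, dtype=float)
    if len(y) != len(Y):
        raise ValueError("length mismatch")
    if len(y) == 0:
        raise ValueError("empty input")
    ref = Y.mean() if as_printed else Y
    return float(np.sqrt(np.mean((y - ref) ** 2)))


def fit_predict(spec: ModelSpec, X_train: pd.DataFrame, y_train,
                X_test: pd.DataFrame) -> np.ndarray:
    """Tune on the training rows (inner grid search), fit, predict the test rows."""
    if len(X_train) == 0:
        raise ValueError("empty training set")
    learner = spec._learner()
    Xa = np.asarray(X_train, dtype=float)
    ya = np.asarray(y_train, dtype=float)
    params = grid_search(Xa, ya, learner, folds=spec.tune_folds, seed=spec.seed)
    est = make_estimator(learner.kind, params, learner)
    est.fit(Xa, ya)
    return np.ravel(est.predict(np.asarray(X_test, dtype=float)))


def fit_full(spec: ModelSpec, table: FeatureTable, target: str,
             subset: list[str] | None = None) -> FittedModel:
    """Fit one tuned model on the whole table (for pixel mapping)."""
    if subset is None:
        subset = table.feature_names
    Xraw = table.raw[subset]
    means = Xraw.mean()
    sds = Xraw.std(ddof=1)
    Xn = (Xraw - means) / sds
    y = table.y[target].to_numpy(dtype=float)
    learner = spec._learner()
    params = grid_search(np.asarray(Xn), y, learner, folds=spec.tune_folds,
                         seed=spec.seed)
    est = make_estimator(learner.kind, params, learner)
    est.fit(np.asarray(Xn), y)
    return FittedModel(estimator=est, family=spec.family, params=params,
                       subset=list(subset), norm_means=means, norm_sds=sds,
                       mode=table.mode, target=target,
                       y_min=float(y.min()), y_max=float(y.max()))


def loocv(spec: ModelSpec, table: FeatureTable, target: str,
          subset: list[str] | None = None) -> EvalReport:
    """Leave-one-out validation with per-fold normalization and tuning.

    Works from the raw (unnormalized) feature values so each fold's z-score
    parameters come from its own n-1 training rows only.
    """
    if subset is None:
        subset = table.feature_names
    Xraw = table.raw[subset].to_numpy(dtype=float)
    y = table.y[target].to_numpy(dtype=float)
    n = len(y)
    if n < 3:
        raise ValueError("LOOCV needs at least 3 samples")
    learner = spec._learner()
    preds = np.empty(n)
    fold_params: list[dict] = []
    for i in range(n):
        tr = np.delete(np.arange(n), i)
        mu = Xraw[tr].mean(axis=0)
        sd = Xraw[tr].std(axis=0, ddof=1)
        sd[sd < _EPS] = 1.0
        Xtr = (Xraw[tr] - mu) / sd
        Xte = (Xraw[[i]] - mu) / sd
        params = grid_search(Xtr, y[tr], learner, folds=spec.tune_folds,
                             seed=spec.seed)
        est = make_estimator(learner.kind, params, learner)
        est.fit(Xtr, y[tr])
        preds[i] = float(np.ravel(est.predict(Xte))[0])
        fold_params.append(params)
    return EvalReport(
        family=spec.family, target=target, subset=list(subset),
        r2=r_squared(y, preds), rmse=rmse(y, preds),
        predictions=pd.DataFrame({"measured": y, "predicted": preds}),
        fold_params=fold_params,
        metadata={"n": n, "seed": spec.seed, "mode": table.mode})
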