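"""Input-variable selection: CORR forward filtering, SFS and RFE.

All three algorithms score candidate variable subsets with the same
evaluation function — repeated k-fold cross-validated RMSE of an induction
learner (:func:`cv_rmse`) — and differ only in their search strategy:

* CORR ranks all 32 variables by |Pearson r| against the target and walks
  the ranking, evaluating the first k variables for every k; the chosen
  subset is the prefix with the lowest RMSE (smallest k on ties).
* SFS grows a subset greedily from empty, at each iteration adding the
  candidate that lowers RMSE most, stopping when no candidate improves on
  the best previous subset (or a cap is reached).
* RFE starts from all variables and repeatedly drops the least important one
  (|coefficient| for linear learners; seeded held-out permutation importance
  for the RBF-SVM), recording the subset RMSE at every size; the chosen
  subset is the size with the lowest recorded RMSE.

Everything is deterministic given the learner seed; SFS re-seeds its
resampling at each iteration so fold draws differ between iterations but
never between runs.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from sklearn.model_selection import KFold, RepeatedKFold

from .features import FeatureTable, rank_by_correlation
from .learners import LearnerSpec, grid_search, make_estimator

__all__ = ["LearnerSpec", "SelectionResult", "cv_rmse",
           "corr_select", "sfs_select", "rfe_select"]


@dataclass
class SelectionResult:
    """Outcome of one selection run: the search trace and the chosen subset."""

    algorithm: str
    learner: str
    target: str
    candidates: list[str]        # variables in consideration order
    curve: list[float]           # RMSE per evaluated step
    subset: list[str]
    chosen_step: int             # index into curve of the chosen subset
    metadata: dict = field(default_factory=dict)

    def to_json(self, path=None) -> str:
        payload = json.dumps(asdict(self), indent=2)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(payload)
        return payload


def _require_normalized(table: FeatureTable) -> None:
    if not table.normalized:
        raise ValueError("selection expects a normalized feature table")


def cv_rmse(X: pd.DataFrame, y, learner: LearnerSpec) -> float:
    """Repeated k-fold RMSE of the learner on a variable subset.

    For each repeat, held-out predictions from the k folds are pooled into
    one RMSE; the result is the mean over repeats.  Tuning follows
    ``learner.tuning``: "nested" re-runs a 3-fold grid search inside every
    training partition; "tune_once" runs one 5-fold grid search on the full
    subset up front.  Deterministic given the learner seed.
    """
    if X.shape[1] == 0:
        raise ValueError("empty variable subset")
    Xa = np.asarray(X, dtype=float)
    ya = np.asarray(y, dtype=float)
    n = len(ya)
    if n < learner.folds:
        raise ValueError(f"need at least {learner.folds} samples, got {n}")
    fixed = grid_search(Xa, ya, learner, folds=5, seed=learner.seed) \
        if learner.tuning == "tune_once" else None
    rkf = RepeatedKFold(n_splits=learner.folds, n_repeats=learner.repeats,
                        random_state=learner.seed)
    per_repeat = np.zeros(learner.repeats)
    counts = np.zeros(learner.repeats)
    for s, (tr, te) in enumerate(rkf.split(Xa)):
        rep = s // learner.folds
        if np.std(ya[tr]) < 1e-12:
            warnings.warn("constant training target in a fold; fold skipped")
            continue
        params = fixed if fixed is not None else \
            grid_search(Xa[tr], ya[tr], learner, folds=3, seed=learner.seed + s)
        est = make_estimator(learner.kind, params, learner)
        est.fit(Xa[tr], ya[tr])
        pred = np.ravel(est.predict(Xa[te]))
        per_repeat[rep] += float(np.sum((ya[te] - pred) ** 2))
        counts[rep] += len(te)
    ok = counts > 0
    return float(np.mean(np.sqrt(per_repeat[ok] / counts[ok])))


def corr_select(table: FeatureTable, target: str, learner: LearnerSpec) -> SelectionResult:
    """Forward filtering over the |r| ranking: evaluate every prefix length."""
    _require_normalized(table)
    ranking = rank_by_correlation(table, target)
    order = ranking["variable"].tolist()
    y = table.y[target]
    curve = [cv_rmse(table.X[order[:k]], y, learner) for k in range(1, len(order) + 1)]
    k_star = int(np.argmin(curve))          # smallest k on ties (argmin is first)
    return SelectionResult(
        algorithm="corr", learner=learner.kind, target=target,
        candidates=order, curve=curve, subset=order[:k_star + 1],
        chosen_step=k_star,
        metadata={"folds": learner.folds, "repeats": learner.repeats,
                  "seed": learner.seed, "tuning": learner.tuning,
                  "abs_r": ranking["abs_r"].tolist()})


def sfs_select(table: FeatureTable, target: str, learner: LearnerSpec,
               max_vars: int | None = None) -> SelectionResult:
    """Greedy sequential forward selection with an improvement stopping rule."""
    _require_normalized(table)
    names = table.feature_names
    if max_vars is None:
        max_vars = len(names)
    y = table.y[target]
    subset: list[str] = []
    curve: list[float] = []
    best_prev = np.inf
    it = 0
    while len(subset) < max_vars:
        spec_it = LearnerSpec(**{**asdict(learner), "seed": learner.seed + 1000 * it})
        remaining = [v for v in names if v not in subset]
        if not remaining:
            break
        scores = [cv_rmse(table.X[subset + [v]], y, spec_it) for v in remaining]
        j = int(np.argmin(scores))
        if scores[j] >= best_prev:          # no improvement on the best previous subset
            break
        subset.append(remaining[j])
        curve.append(scores[j])
        best_prev = scores[j]
        it += 1
    return SelectionResult(
        algorithm="sfs", learner=learner.kind, target=target,
        candidates=list(subset), curve=curve, subset=list(subset),
        chosen_step=len(curve) - 1,
        metadata={"folds": learner.folds, "repeats": learner.repeats,
                  "seed": learner.seed, "tuning": learner.tuning,
                  "max_vars": max_vars})


def _importance(X: pd.DataFrame, y: np.ndarray, learner: LearnerSpec,
                seed: int) -> np.ndarray:
    """Variable importance for one RFE step.

    Linear learners (lm, pls): |coefficient| on the (already normalized)
    features after a tuned fit on the full current set.  RBF-SVM: held-out
    permutation importance — 5-fold CV, and within each fold the RMSE
    increase when one feature column of the validation part is permuted
    (10 seeded permutations), summed over folds.
    """
    Xa = np.asarray(X, dtype=float)
    if learner.kind in ("lm", "pls"):
        params = grid_search(Xa, y, learner, folds=5, seed=seed)
        est = make_estimator(learner.kind, params, learner)
        est.fit(Xa, y)
        return np.abs(np.ravel(est.coef_))
    rng = np.random.default_rng(seed)
    imp = np.zeros(Xa.shape[1])
    folds = min(5, len(y))
    for tr, te in KFold(folds, shuffle=True, random_state=seed).split(Xa):
        params = grid_search(Xa[tr], y[tr], learner, folds=3, seed=seed)
        est = make_estimator(learner.kind, params, learner)
        est.fit(Xa[tr], y[tr])
        base = np.sqrt(np.mean((y[te] - np.ravel(est.predict(Xa[te]))) ** 2))
        for j in range(Xa.shape[1]):
            for _ in range(10):
                Xp = Xa[te].copy()
                Xp[:, j] = rng.permutation(Xp[:, j])
                rm = np.sqrt(np.mean((y[te] - np.ravel(est.predict(Xp))) ** 2))
                imp[j] += (rm - base) / 10.0
    return imp


def rfe_select(table: FeatureTable, target: str, learner: LearnerSpec) -> SelectionResult:
    """Recursive feature elimination from the full set down to one variable."""
    _require_normalized(table)
    y = table.y[target].to_numpy(dtype=float)
    current = list(table.feature_names)
    curve: list[float] = []
    sets: list[list[str]] = []
    eliminated: list[str] = []
    step = 0
    while current:
        curve.append(cv_rmse(table.X[current], table.y[target], learner))
        sets.append(list(current))
        if len(current) == 1:
            eliminated.append(current.pop())
            break
        imp = _importance(table.X[current], y, learner, seed=learner.seed + 1000 * step)
        j = int(np.argmin(imp))
        eliminated.append(current.pop(j))
        step += 1
    # chosen: lowest recorded RMSE; ties -> fewest variables (later step)
    best = min(range(len(curve)), key=lambda i: (curve[i], len(sets[i])))
    return SelectionResult(
        algorithm="rfe", learner=learner.kind, target=target,
        candidates=eliminated, curve=curve, subset=sets[best], chosen_step=best,
        metadata={"folds": learner.folds, "repeats": learner.repeats,
                  "seed": learner.seed, "tuning": learner.tuning})
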