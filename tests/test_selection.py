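"""Variable selection: the CV-RMSE evaluation function and CORR/SFS/RFE."""

import numpy as np
import pandas as pd
import pytest
from sklearn.linear_model import LinearRegression
from sklearn.model_selection import RepeatedKFold

import leafspec as ls
from leafspec.selection import _importance

from conftest import make_toy_table


def _toy_linear(n=40, p=6, seed=0, noise=0.0):
    """Target is a linear function of the first two columns."""
    rng = np.random.default_rng(seed)
    X = rng.normal(size=(n, p))
    y = 3.0 * X[:, 0] - 2.0 * X[:, 1] + noise * rng.normal(size=n)
    return make_toy_table(X, y)


class TestCvRmse:
    def test_perfect_linear_fit(self):
        tab = _toy_linear(noise=0.0)
        spec = ls.LearnerSpec(kind="lm", repeats=2, seed=1)
        assert ls.cv_rmse(tab.X[["v0", "v1"]], tab.y["chl_ab"], spec) < 1e-8

    def test_permuted_target_near_null_sd(self):
        """With the signal destroyed, CV RMSE approaches the target SD."""
        tab = _toy_linear(n=120, noise=0.0, seed=2)
        rng = np.random.default_rng(3)
        y_perm = pd.Series(rng.permutation(tab.y["chl_ab"].to_numpy()), name="chl_ab")
        spec = ls.LearnerSpec(kind="lm", repeats=2, seed=1)
        r = ls.cv_rmse(tab.X[["v0", "v1"]], y_perm, spec)
        null_sd = y_perm.std(ddof=0)
        assert abs(r - null_sd) / null_sd < 0.25

    def test_deterministic_under_seed(self):
        tab = _toy_linear(noise=0.5)
        spec = ls.LearnerSpec(kind="svm_rbf", repeats=2, seed=9, tuning="tune_once")
        a = ls.cv_rmse(tab.X, tab.y["chl_ab"], spec)
        b = ls.cv_rmse(tab.X, tab.y["chl_ab"], spec)
        assert a == b

    def test_matches_handrolled_fold_loop(self):
        """Pipeline CV RMSE equals an independently coded fold loop to 1e-10."""
        rng = np.random.default_rng(7)
        X = rng.normal(size=(10, 3))
        y = 2.0 * X[:, 0] + 0.3 * rng.normal(size=10)
        tab = make_toy_table(X, y)
        spec = ls.LearnerSpec(kind="lm", folds=5, repeats=3, seed=11)
        got = ls.cv_rmse(tab.X, tab.y["chl_ab"], spec)

        # oracle: replicate the resampling scheme with sklearn primitives only
        Xa = tab.X.to_numpy()
        ya = tab.y["chl_ab"].to_numpy()
        rkf = RepeatedKFold(n_splits=5, n_repeats=3, random_state=11)
        sq = np.zeros(3)
        m = np.zeros(3)
        for s, (tr, te) in enumerate(rkf.split(Xa)):
            rep = s // 5
            fit = LinearRegression().fit(Xa[tr], ya[tr])
            sq[rep] += np.sum((ya[te] - fit.predict(Xa[te])) ** 2)
            m[rep] += len(te)
        want = np.mean(np.sqrt(sq / m))
        assert got == pytest.approx(want, abs=1e-10)

    def test_empty_subset_rejected(self):
        tab = _toy_linear()
        with pytest.raises(ValueError):
            ls.cv_rmse(tab.X[[]], tab.y["chl_ab"], ls.LearnerSpec(kind="lm"))


class TestCorrSelect:
    def test_recovers_informative_prefix(self):
        """Target built from the two most correlated variables: k* is small."""
        tab = _toy_linear(n=60, noise=0.1, seed=4)
        spec = ls.LearnerSpec(kind="lm", repeats=2, seed=5)
        res = ls.corr_select(tab, "chl_ab", spec)
        assert res.chosen_step + 1 in (2, 3)
        assert len(res.curve) == 6
        assert min(res.curve) <= res.curve[-1]

    def test_single_candidate(self):
        rng = np.random.default_rng(6)
        X = rng.normal(size=(30, 1))
        tab = make_toy_table(X, 2 * X[:, 0])
        res = ls.corr_select(tab, "chl_ab", ls.LearnerSpec(kind="lm", repeats=2))
        assert res.curve and len(res.curve) == 1
        assert res.subset == ["v0"]

    def test_matches_exhaustive_prefix_oracle(self):
        """The curve equals direct cv_rmse evaluation of every ranked prefix."""
        tab = _toy_linear(n=40, noise=0.3, seed=8)
        spec = ls.LearnerSpec(kind="lm", repeats=2, seed=3)
        res = ls.corr_select(tab, "chl_ab", spec)
        order = ls.rank_by_correlation(tab, "chl_ab")["variable"].tolist()
        assert res.candidates == order
        for k in (1, 3, 6):
            want = ls.cv_rmse(tab.X[order[:k]], tab.y["chl_ab"], spec)
            assert res.curve[k - 1] == pytest.approx(want, abs=1e-12)
        assert res.chosen_step == int(np.argmin(res.curve))

    def test_unnormalized_table_rejected(self):
        tab = ls.FeatureTable(X=pd.DataFrame({"v": [1.0, 2.0, 3.0]}),
                              y=pd.DataFrame({"chl_ab": [1.0, 2.0, 3.0]}))
        with pytest.raises(ValueError, match="normalized"):
            ls.corr_select(tab, "chl_ab", ls.LearnerSpec(kind="lm"))


class TestSfsSelect:
    def test_exact_single_feature_stops_at_one(self):
        rng = np.random.default_rng(10)
        X = rng.normal(size=(40, 5))
        tab = make_toy_table(X, X[:, 3].copy())
        res = ls.sfs_select(tab, "chl_ab", ls.LearnerSpec(kind="lm", repeats=2, seed=2))
        assert res.subset == ["v3"]

    def test_accepted_rmse_strictly_decreasing(self):
        tab = _toy_linear(n=60, noise=0.5, seed=12)
        res = ls.sfs_select(tab, "chl_ab",
                            ls.LearnerSpec(kind="lm", repeats=2, seed=2))
        assert all(b < a for a, b in zip(res.curve, res.curve[1:]))

    def test_matches_bruteforce_greedy(self):
        """p=6 toy problem: subset identical to an exhaustive greedy re-run."""
        tab = _toy_linear(n=40, noise=0.4, seed=13)
        spec = ls.LearnerSpec(kind="lm", repeats=2, seed=21)
        res = ls.sfs_select(tab, "chl_ab", spec)

        from dataclasses import asdict
        subset, best_prev, it = [], np.inf, 0
        while True:
            spec_it = ls.LearnerSpec(**{**asdict(spec), "seed": spec.seed + 1000 * it})
            remaining = [v for v in tab.feature_names if v not in subset]
            if not remaining:
                break
            scores = {v: ls.cv_rmse(tab.X[subset + [v]], tab.y["chl_ab"], spec_it)
                      for v in remaining}
            best = min(scores, key=lambda v: (scores[v], remaining.index(v)))
            if scores[best] >= best_prev:
                break
            subset.append(best)
            best_prev = scores[best]
            it += 1
        assert res.subset == subset

    def test_max_vars_cap(self):
        tab = _toy_linear(n=60, noise=2.0, seed=14)
        res = ls.sfs_select(tab, "chl_ab",
                            ls.LearnerSpec(kind="lm", repeats=2, seed=2), max_vars=1)
        assert len(res.subset) == 1


class TestRfeSelect:
    def test_informative_feature_survives(self):
        rng = np.random.default_rng(15)
        X = rng.normal(size=(40, 5))
        tab = make_toy_table(X, X[:, 2] + 0.01 * rng.normal(size=40))
        res = ls.rfe_select(tab, "chl_ab", ls.LearnerSpec(kind="lm", repeats=2, seed=3))
        assert res.candidates[-1] == "v2"        # eliminated last
        assert "v2" in res.subset

    def test_curve_length_equals_p(self):
        tab = _toy_linear(n=40, noise=0.5, seed=16)
        res = ls.rfe_select(tab, "chl_ab", ls.LearnerSpec(kind="lm", repeats=2, seed=3))
        assert len(res.curve) == 6
        assert res.curve[res.chosen_step] == min(res.curve)

    def test_elimination_order_matches_refit_oracle(self):
        """p=5: each dropped variable has the smallest |coef| of an independent refit."""
        tab = _toy_linear(n=50, p=5, noise=0.3, seed=17)
        spec = ls.LearnerSpec(kind="lm", repeats=2, seed=4)
        res = ls.rfe_select(tab, "chl_ab", spec)
        current = list(tab.feature_names)
        for dropped in res.candidates[:-1]:
            coefs = np.abs(LinearRegression().fit(
                tab.X[current].to_numpy(), tab.y["chl_ab"].to_numpy()).coef_)
            assert current[int(np.argmin(coefs))] == dropped
            current.remove(dropped)

    def test_svm_importance_is_seeded(self):
        tab = _toy_linear(n=40, noise=0.5, seed=18)
        spec = ls.LearnerSpec(kind="svm_rbf", repeats=2, seed=5, tuning="tune_once")
        a = _importance(tab.X, tab.y["chl_ab"].to_numpy(), spec, seed=7)
        b = _importance(tab.X, tab.y["chl_ab"].to_numpy(), spec, seed=7)
        np.testing.assert_array_equal(a, b)


def test_selection_results_serialize(tmp_path):
    tab = _toy_linear(n=30, noise=0.5, seed=19)
    res = ls.corr_select(tab, "chl_ab", ls.LearnerSpec(kind="lm", repeats=2, seed=6))
    path = tmp_path / "sel.json"
    res.to_json(path)
    import json
    back = json.loads(path.read_text())
    assert back["algorithm"] == "corr"
    assert back["subset"] == res.subset
    assert set(back["subset"]) <= set(back["candidates"])
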