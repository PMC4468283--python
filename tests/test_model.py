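import itertools

import numpy as np
import pandas as pd
import pytest
from scipy.optimize import minimize

from rbhvoice.errors import ValidationError
from rbhvoice.io import FeatureTable
from rbhvoice.model import (CFSSelector, RegressionModel, SMORegressor,
                            _abs_correlations, cfs_best_first, cfs_merit,
                            cfs_select, evaluate, load_presets, train_svr)
from rbhvoice.synthgen import synth_feature_table


def qp_primal_objective(X, y, C, eps):
    """Independent QP oracle: solve the primal epsilon-SVR with SLSQP."""
    n, p = X.shape
    sd = X.std(axis=0)
    Z = (X - X.mean(axis=0)) / np.where(sd > 0, sd, 1.0)

    def unpack(v):
        return v[:p], v[p], v[p + 1:p + 1 + n], v[p + 1 + n:]

    def objective(v):
        w, _, xi, xs = unpack(v)
        return 0.5 * w @ w + C * (xi.sum() + xs.sum())

    cons = []
    for i in range(n):
        cons.append({"type": "ineq", "fun": lambda v, i=i:
                     eps + unpack(v)[2][i]
                     - (y[i] - (Z[i] @ unpack(v)[0] + unpack(v)[1]))})
        cons.append({"type": "ineq", "fun": lambda v, i=i:
                     eps + unpack(v)[3][i]
                     + (y[i] - (Z[i] @ unpack(v)[0] + unpack(v)[1]))})
    bounds = [(None, None)] * (p + 1) + [(0, None)] * (2 * n)
    res = minimize(objective, np.zeros(p + 1 + 2 * n), method="SLSQP",
                   bounds=bounds, constraints=cons,
                   options={"maxiter": 500, "ftol": 1e-12})
    return res.fun


class TestSMORegressor:
    def test_recovers_noiseless_line(self):
        rng = np.random.default_rng(0)
        X = rng.standard_normal((50, 1))
        y = 2.0 * X[:, 0] + 1.0
        reg = SMORegressor(C=100.0, epsilon=0.01).fit(X, y)
        assert reg.coef_[0] == pytest.approx(2.0, abs=0.01)
        assert reg.intercept_ == pytest.approx(1.0, abs=0.02)

    def test_constant_target(self):
        X = np.random.default_rng(1).standard_normal((20, 3))
        reg = SMORegressor().fit(X, np.full(20, 1.5))
        assert np.all(reg.coef_ == 0.0)
        assert reg.intercept_ == pytest.approx(1.5)

    @pytest.mark.parametrize("seed", range(5))
    def test_objective_matches_qp_oracle(self, seed):
        """SMO optimum agrees with an SLSQP quadratic-programming oracle."""
        rng = np.random.default_rng(seed)
        n = int(rng.integers(10, 31))
        p = int(rng.integers(1, 6))
        X = rng.standard_normal((n, p))
        y = rng.standard_normal(n)
        reg = SMORegressor(C=1.0, epsilon=0.1, tol=1e-8).fit(X, y)
        oracle = qp_primal_objective(X, y, 1.0, 0.1)
        assert abs(reg.objective_ - oracle) <= 1e-4

    def test_doubling_c_on_interpolable_problem(self):
        """When the tube fits the data exactly, C does not matter."""
        rng = np.random.default_rng(2)
        X = rng.standard_normal((40, 3))
        y = X @ np.array([1.0, -0.5, 0.3]) + 0.7
        a = SMORegressor(C=10.0, epsilon=1e-4, tol=1e-8).fit(X, y)
        b = SMORegressor(C=20.0, epsilon=1e-4, tol=1e-8).fit(X, y)
        assert np.abs(a.predict(X) - b.predict(X)).max() <= 1e-6

    def test_sklearn_params_protocol(self):
        reg = SMORegressor(C=2.0)
        assert reg.get_params()["C"] == 2.0
        reg.set_params(epsilon=0.5)
        assert reg.epsilon == 0.5


class TestCFS:
    def test_single_feature_merit_is_abs_correlation(self):
        r_cf = np.array([0.3, 0.8])
        r_ff = np.eye(2)
        assert cfs_merit((1,), r_cf, r_ff) == pytest.approx(0.8)

    def test_merit_sign_flip_invariance(self):
        rng = np.random.default_rng(3)
        X = rng.standard_normal((40, 5))
        y = X[:, 0] + 0.5 * rng.standard_normal(40)
        r1 = _abs_correlations(X, y)
        Xf = X * np.array([1, -1, 1, -1, 1])
        r2 = _abs_correlations(Xf, y)
        for s in [(0,), (0, 1), (1, 2, 3)]:
            assert cfs_merit(s, *r1) == pytest.approx(cfs_merit(s, *r2))

    def test_best_first_matches_exhaustive_8_features(self):
        """Best-first search finds the global CFS optimum over 2^8 subsets."""
        rng = np.random.default_rng(3)
        X = rng.standard_normal((60, 8))
        y = 0.8 * X[:, 0] + 0.5 * X[:, 3] + 0.3 * rng.standard_normal(60)
        r_cf, r_ff = _abs_correlations(X, y)
        found, found_merit = cfs_best_first(r_cf, r_ff)
        # independent oracle: full enumeration with its own merit formula
        best, best_merit = None, 0.0
        for k in range(1, 9):
            for subset in itertools.combinations(range(8), k):
                idx = list(subset)
                rcf = np.mean(r_cf[idx])
                rff = (np.mean(r_ff[np.ix_(idx, idx)]) * k - 1) * k / max(
                    k * (k - 1), 1) if k > 1 else 0.0
                merit = k * rcf / np.sqrt(k + k * (k - 1) * rff)
                if merit > best_merit:
                    best, best_merit = subset, merit
        assert found == best
        assert found_merit == pytest.approx(best_merit)

    def test_informative_feature_ranked_first(self):
        table, target = synth_feature_table(40, {"signal": 1.0},
                                            noise_sd=0.05, seed=5, n_noise=9)
        result = cfs_select(table, target, folds=10, seed=0)
        assert result.ranked_features[0] == "signal"
        assert result.frequencies["signal"] == 1.0

    def test_selection_deterministic(self):
        table, target = synth_feature_table(30, {"a": 1.0, "b": -0.5},
                                            noise_sd=0.3, seed=6, n_noise=5)
        r1 = cfs_select(table, target, folds=10, seed=42)
        r2 = cfs_select(table, target, folds=10, seed=42)
        assert r1.ranked_features == r2.ranked_features
        assert r1.fold_subsets == r2.fold_subsets

    def test_too_few_items_for_folds(self):
        table, target = synth_feature_table(5, {"a": 1.0}, seed=0)
        with pytest.raises(ValidationError):
            cfs_select(table, target, folds=10)

    def test_true_features_dominate_ranking(self):
        """With published weights + noise sd 0.1, most true features
        reach the top of the CFS ranking (20 seeded repetitions)."""
        weights = {f: float(w) for f, w in
                   zip(load_presets()["R_best_I"].feature_names,
                       load_presets()["R_best_I"].weights)}
        hits = []
        for rep in range(20):
            table, target = synth_feature_table(50, weights, noise_sd=0.1,
                                                seed=100 + rep, n_noise=8)
            result = cfs_select(table, target, folds=10, seed=rep)
            top7 = set(result.ranked_features[:7])
            hits.append(len(top7 & set(weights)))
        assert all(h >= 5 for h in hits)


class TestRegressionModel:
    def test_train_svr_round_trips_serialization(self):
        table, target = synth_feature_table(30, {"a": 0.8, "b": -0.4}, seed=7)
        m = train_svr(table, target, ["a", "b"])
        back = RegressionModel.from_json(m.to_json())
        np.testing.assert_allclose(back.predict(table), m.predict(table))

    def test_missing_feature_named_in_error(self):
        table, _ = synth_feature_table(10, {"a": 1.0}, seed=8)
        m = RegressionModel(feature_names=["a", "CFx"], weights=[0.5, 0.2])
        with pytest.raises(ValidationError, match="CFx"):
            m.predict(table)

    def test_zero_standardized_vector_predicts_intercept(self):
        table, target = synth_feature_table(30, {"a": 1.0}, seed=9)
        m = train_svr(table, target, ["a"])
        at_mean = FeatureTable(pd.DataFrame({"a": [float(m.means[0])]},
                                            index=["x"]))
        # bypass table-level standardization: means/scales come from training
        assert m.predict(at_mean)[0] == pytest.approx(m.intercept, abs=1e-9)

    def test_evaluate_perfect_and_negated(self):
        x = np.array([0.1, 0.7, 1.3, 2.0, 2.2, 0.4, 1.8, 0.9, 1.1, 2.9])
        r, rho, _ = evaluate(x, x)
        assert r == pytest.approx(1.0)
        assert rho == pytest.approx(1.0)
        r, _, _ = evaluate(-x, x)
        assert r == pytest.approx(-1.0)

    def test_evaluate_attenuation_matches_closed_form(self):
        """r against a noisy target approaches sqrt(var_s/(var_s+var_n))."""
        rng = np.random.default_rng(10)
        signal = rng.standard_normal(4000)
        noise = 0.5 * rng.standard_normal(4000)
        r, _, _ = evaluate(signal, signal + noise)
        expected = np.sqrt(1.0 / (1.0 + 0.25))
        assert r == pytest.approx(expected, abs=0.05)


class TestPresets:
    def test_all_published_sets_present(self):
        presets = load_presets()
        expected = {"R_best_I", "R_best_I_noCFx", "R_best_II", "R_best_II_noCFx",
                    "B_best", "H_best_I", "H_best_II", "H_best_III", "H_best_IV",
                    "R_cfx_cqx", "B_cfx_cqx", "H_cfx_cqx"}
        assert expected == set(presets)

    def test_best_roughness_set_composition(self):
        m = load_presets()["R_best_I"]
        assert len(m.feature_names) == 7
        prosodic = [f for f in m.feature_names if f not in ("CFx", "CQx")]
        assert len(prosodic) == 6 and "CFx" in m.feature_names

    def test_unit_cfx_relative_score(self):
        """A +1-standardized CFx with all else at the mean scores 0.210."""
        m = load_presets()["R_best_I"]
        data = {f: [0.0, 0.0] for f in m.feature_names}
        data["CFx"] = [-1.0, 1.0]  # mean 0, sd 1 within the table
        table = FeatureTable(pd.DataFrame(data, index=["lo", "hi"]))
        assert m.relative
        assert m.predict(table)[1] == pytest.approx(0.210, abs=1e-9)

    def test_breathiness_set_has_no_egg_features(self):
        m = load_presets()["B_best"]
        assert "CFx" not in m.feature_names and "CQx" not in m.feature_names
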