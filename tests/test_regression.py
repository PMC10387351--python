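import numpy as np
import pandas as pd
import pytest
from scipy.optimize import minimize

from atriapop.regression import (
    DadLogit,
    RegressionDataset,
    build_design_matrix,
    fit_logistic,
    interpret,
)
from atriapop.synth import synth_logistic


class TestDesignMatrix:
    def factors(self, n=50, seed=0):
        rng = np.random.default_rng(seed)
        return pd.DataFrame({
            "g_CaL": rng.lognormal(0, 0.2, n),
            "v_NCX": rng.lognormal(0, 0.2, n),
        })

    def test_zscored_log_columns(self):
        ds = build_design_matrix(self.factors())
        assert np.abs(ds.X.mean(axis=0)).max() < 1e-12
        assert np.allclose(ds.X.std(axis=0), 1.0, atol=1e-12)

    def test_constant_column_dropped_with_warning(self):
        f = self.factors()
        f["g_K1"] = 1.0
        with pytest.warns(UserWarning, match="g_K1"):
            ds = build_design_matrix(f)
        assert ds.feature_names == ["g_CaL", "v_NCX"]

    def test_nonpositive_factor_rejected(self):
        f = self.factors()
        f.loc[3, "g_CaL"] = 0.0
        with pytest.raises(ValueError, match="g_CaL"):
            build_design_matrix(f)

    def test_hand_computed_z(self):
        """A factor e^0.2 in a column with log-sd 0.2 and log-mean 0 maps
        to z = 1 exactly."""
        logs = np.array([0.2, -0.2, 0.2, -0.2])
        f = pd.DataFrame({"g_CaL": np.exp(logs), "pad": np.exp([0.1, -0.1, 0.2, -0.2])})
        ds = build_design_matrix(f)
        col = ds.feature_names.index("g_CaL")
        assert ds.X[0, col] == pytest.approx(1.0)


def nll(beta, X1, y):
    eta = X1 @ beta
    return float(np.sum(np.log1p(np.exp(eta)) - y * eta))


class TestFit:
    def test_recovers_known_coefficients(self):
        """n=5000 draws from a known beta: estimates land inside the
        bootstrap 95% confidence intervals."""
        beta = np.array([1.0, -0.7, 0.4])
        ds, truth = synth_logistic(beta, n=5000, seed=3)
        res = DadLogit(ds).fit()
        ci = res.bootstrap(n_boot=60, seed=5)
        for k, b in zip(ds.feature_names, beta):
            assert ci.loc[k, "lo"] <= b <= ci.loc[k, "hi"]
            assert res.params[k] == pytest.approx(b, abs=0.15)

    def test_permuted_labels_give_null_coefficients(self):
        """With labels shuffled independently of X, every coefficient stays
        inside the 95% permutation-null envelope."""
        ds, _ = synth_logistic(np.array([1.5, -1.0]), n=800, seed=1)
        rng = np.random.default_rng(2)
        y_perm = rng.permutation(ds.y)
        obs = DadLogit(RegressionDataset(ds.X, y_perm, ds.feature_names)).fit()
        null = []
        for k in range(200):
            ys = rng.permutation(ds.y)
            if ys.min() == ys.max():
                continue
            null.append(
                DadLogit(RegressionDataset(ds.X, ys, ds.feature_names))
                .fit().params.to_numpy()
            )
        envelope = np.quantile(np.abs(np.array(null)), 0.95, axis=0)
        assert (np.abs(obs.params.to_numpy()) <= envelope * 1.05).all()

    def test_single_class_rejected(self):
        X = np.random.default_rng(0).normal(size=(30, 2))
        with pytest.raises(ValueError, match="single-class"):
            DadLogit(RegressionDataset(X, np.ones(30), ["a", "b"]))

    def test_matches_brute_force_likelihood_maximizer(self):
        """With vanishing ridge, IRLS agrees with a naive optimizer of the
        Bernoulli log-likelihood to 1e-4 on small problems."""
        ds, _ = synth_logistic(np.array([0.8, -0.5, 0.3]), n=400, seed=7)
        res = fit_logistic(ds, ridge=1e-10)
        X1 = np.column_stack([np.ones(len(ds.y)), ds.X])
        opt = minimize(nll, np.zeros(4), args=(X1, ds.y), method="Nelder-Mead",
                       options={"xatol": 1e-8, "fatol": 1e-10, "maxiter": 20000})
        assert np.allclose(
            np.r_[res.intercept, res.params.to_numpy()], opt.x, atol=1e-4
        )

    def test_invariant_to_row_order(self):
        ds, _ = synth_logistic(np.array([0.6, -0.4]), n=500, seed=11)
        perm = np.random.default_rng(3).permutation(len(ds.y))
        shuffled = RegressionDataset(ds.X[perm], ds.y[perm], ds.feature_names)
        a = DadLogit(ds).fit().params
        b = DadLogit(shuffled).fit().params
        assert np.allclose(a.to_numpy(), b.to_numpy(), atol=1e-8)

    def test_bias_shrinks_with_n(self):
        """Recovery error decreases from n=500 to n=5000."""
        beta = np.array([1.0, -0.8])
        errs = []
        for n in (500, 5000):
            est = []
            for seed in range(6):
                ds, _ = synth_logistic(beta, n=n, seed=100 + seed)
                est.append(DadLogit(ds).fit().params.to_numpy())
            errs.append(np.abs(np.mean(est, axis=0) - beta).mean())
        assert errs[1] < errs[0]

    def test_quasi_separation_flagged(self):
        """A dominant coefficient produces near-separable data; the fit
        reports it rather than failing silently."""
        ds, _ = synth_logistic(np.array([25.0]), n=400, seed=5)
        res = fit_logistic(ds, ridge=1e-8)
        assert res.quasi_separation

    def test_cross_check_against_sklearn(self):
        from sklearn.linear_model import LogisticRegression

        ds, _ = synth_logistic(np.array([0.9, -0.6, 0.2]), n=2000, seed=9)
        ridge = 1e-2
        mine = fit_logistic(ds, ridge=ridge)
        sk = LogisticRegression(C=1.0 / ridge, tol=1e-10, max_iter=5000)
        sk.fit(ds.X, ds.y)
        assert np.allclose(mine.params.to_numpy(), sk.coef_[0], atol=2e-3)


class TestInterpret:
    def test_sign_annotation_and_ranking(self):
        ds, _ = synth_logistic(np.array([0.8, -0.5]), n=2000, seed=2,
                               feature_names=["g_CaL", "v_NCX"])
        res = DadLogit(ds).fit()
        rep = interpret(res)
        assert rep.loc["g_CaL", "effect"] == "promotes DADs"
        assert rep.loc["v_NCX", "effect"] == "protects against DADs"
        assert sorted(rep["rank"]) == [1, 2]
        assert set(rep.index) == set(ds.feature_names)
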