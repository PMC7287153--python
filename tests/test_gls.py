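import numpy as np
import pandas as pd
import pytest

from cladeshift import gls, pca
from cladeshift.simulate import (
    SimulationConfig,
    make_fixture,
    simulate_traits,
    simulate_yule,
)
from cladeshift.tree import parse_newick

R1 = pd.DataFrame([[1.0]], index=["x"], columns=["x"])


def star_tree(n, depth=1.0):
    tips = ",".join(f"t{i}:{depth}" for i in range(n))
    return parse_newick(f"({tips});")


class TestLambdaTransform:
    def test_identity_at_one(self):
        C = np.array([[2.0, 1.0], [1.0, 2.0]])
        np.testing.assert_allclose(gls.lambda_transform(C, 1.0), C)

    def test_star_at_zero(self):
        C = np.array([[2.0, 1.0], [1.0, 2.0]])
        np.testing.assert_allclose(
            gls.lambda_transform(C, 0.0), np.diag([2.0, 2.0])
        )

    def test_half(self):
        C = np.array([[2.0, 1.0], [1.0, 2.0]])
        np.testing.assert_allclose(
            gls.lambda_transform(C, 0.5), [[2.0, 0.5], [0.5, 2.0]]
        )

    @pytest.mark.parametrize("lam", [-0.1, 1.5])
    def test_out_of_range_rejected(self, lam):
        with pytest.raises(ValueError):
            gls.lambda_transform(np.eye(2), lam)


class TestGlsLoglik:
    def test_identity_covariance_matches_iid_mle(self):
        rng = np.random.default_rng(0)
        y = rng.standard_normal(25)
        X = np.ones((25, 1))
        ll, beta, s2 = gls.gls_loglik(y, X, np.eye(25))
        mu, var = y.mean(), y.var()
        expect = -0.5 * 25 * (np.log(2 * np.pi * var) + 1)
        assert ll == pytest.approx(expect, abs=1e-10)
        assert beta[0] == pytest.approx(mu)
        assert s2 == pytest.approx(var)

    def test_matches_statsmodels_ols(self):
        import statsmodels.api as sm

        rng = np.random.default_rng(1)
        X = np.column_stack([np.ones(30), rng.standard_normal((30, 2))])
        y = X @ [1.0, 2.0, -0.5] + rng.standard_normal(30)
        ll, beta, _ = gls.gls_loglik(y, X, np.eye(30))
        fit = sm.OLS(y, X).fit()
        assert ll == pytest.approx(fit.llf, abs=1e-8)
        np.testing.assert_allclose(beta, fit.params, atol=1e-10)

    def test_scale_symmetry(self):
        rng = np.random.default_rng(2)
        y = rng.standard_normal(12)
        X = np.ones((12, 1))
        V = np.eye(12) + 0.3
        ll1, b, s2 = gls.gls_loglik(y, X, V)
        ll2, _, _ = gls.gls_loglik(y, X, 4.0 * V, beta=b, sigma2=s2 / 4.0)
        assert ll1 == pytest.approx(ll2, abs=1e-10)

    def test_mle_is_a_maximum(self):
        rng = np.random.default_rng(3)
        y = rng.standard_normal(15)
        X = np.column_stack([np.ones(15), rng.standard_normal(15)])
        V = np.eye(15)
        ll, beta, s2 = gls.gls_loglik(y, X, V)
        for _ in range(50):
            eps = rng.normal(0, 0.05, size=beta.shape)
            ll2, _, _ = gls.gls_loglik(y, X, V, beta=beta + eps, sigma2=s2)
            assert ll2 <= ll + 1e-12

    def test_singular_design_rejected(self):
        y = np.arange(6.0)
        X = np.column_stack([np.ones(6), np.ones(6)])
        with pytest.raises(np.linalg.LinAlgError):
            gls.gls_loglik(y, X, np.eye(6))


class TestFitLambda:
    def test_aic_nesting_bound(self):
        tree = simulate_yule(40, seed=4)
        for i in range(5):
            X = simulate_traits(tree, R1, {"x": 0.5}, seed=100 + i)
            lf = gls.fit_lambda(tree, X["x"])
            assert lf.aic_hat <= min(lf.aic0, lf.aic1) + 2 + 1e-9
            assert lf.loglik >= max(lf.loglik0, lf.loglik1) - 1e-6

    def test_endpoints_match_dense_oracle(self):
        tree = simulate_yule(25, seed=5)
        X = simulate_traits(tree, R1, None, seed=6)
        lf = gls.fit_lambda(tree, X["x"])
        order, C = tree.phylo_covariance()
        y = X["x"].loc[order].to_numpy()
        ones = np.ones((len(order), 1))
        for lam, ll in ((0.0, lf.loglik0), (1.0, lf.loglik1)):
            V = lam * C + (1 - lam) * np.diag(np.diag(C))
            Vi = np.linalg.inv(V)
            mu = (ones.T @ Vi @ y).item() / (ones.T @ Vi @ ones).item()
            r = y - mu
            s2 = (r @ Vi @ r).item() / len(y)
            direct = -0.5 * (
                len(y) * np.log(2 * np.pi * s2)
                + np.linalg.slogdet(V)[1]
                + len(y)
            )
            assert ll == pytest.approx(direct, abs=1e-8)


class TestPgls:
    def test_star_tree_equals_ols(self):
        tree = star_tree(20)
        rng = np.random.default_rng(8)
        y = pd.Series(
            rng.standard_normal(20), index=tree.tip_labels, name="y"
        )
        X = pd.DataFrame(
            {"a": rng.standard_normal(20), "b": rng.standard_normal(20)},
            index=tree.tip_labels,
        )
        f1 = gls.pgls(tree, y, X, mode="ols")
        f2 = gls.pgls(tree, y, X, mode="pgls_ml_lambda")
        np.testing.assert_allclose(
            f1.params["coef"], f2.params["coef"], atol=1e-8
        )
        np.testing.assert_allclose(f1.params["t"], f2.params["t"], atol=1e-6)

    def test_ols_matches_statsmodels(self):
        import statsmodels.api as sm

        tree = star_tree(28)
        rng = np.random.default_rng(9)
        X = pd.DataFrame(
            {"a": rng.standard_normal(28)}, index=tree.tip_labels
        )
        y = pd.Series(
            2.0 + 1.5 * X["a"].to_numpy() + rng.standard_normal(28),
            index=tree.tip_labels,
            name="y",
        )
        fit = gls.pgls(tree, y, X, mode="ols")
        sm_fit = sm.OLS(
            y.to_numpy(), sm.add_constant(X.to_numpy())
        ).fit()
        np.testing.assert_allclose(
            fit.params["coef"], sm_fit.params, atol=1e-9
        )
        np.testing.assert_allclose(fit.params["t"], sm_fit.tvalues, atol=1e-8)
        np.testing.assert_allclose(fit.params["p"], sm_fit.pvalues, atol=1e-8)
        assert fit.fvalue == pytest.approx(sm_fit.fvalue, abs=1e-8)
        assert fit.r2 == pytest.approx(sm_fit.rsquared, abs=1e-10)

    def test_f_df_shape(self):
        # 30 taxa, 2 predictors -> F(2, 27)
        tree = star_tree(30)
        rng = np.random.default_rng(10)
        y = pd.Series(
            rng.standard_normal(30), index=tree.tip_labels, name="y"
        )
        X = pd.DataFrame(
            {"a": rng.standard_normal(30), "b": rng.standard_normal(30)},
            index=tree.tip_labels,
        )
        assert gls.pgls(tree, y, X).f_df == (2, 27)

    def test_rank_deficient_design_rejected(self):
        tree = star_tree(10)
        y = pd.Series(np.arange(10.0), index=tree.tip_labels, name="y")
        X = pd.DataFrame(
            {"a": np.ones(10), "b": np.ones(10)}, index=tree.tip_labels
        )
        with pytest.raises(np.linalg.LinAlgError):
            gls.pgls(tree, y, X)

    def test_null_habitat_type_i_exact_with_true_lambda(self):
        """With no true habitat effect and the error covariance fixed at the
        true lambda, the PGLS F test rejects at the nominal rate."""
        ds = make_fixture(SimulationConfig(seed=0, habitat_effects={}))
        tree, hab = ds.tree, ds.habitat
        X = gls.habitat_design(hab)
        rej = 0
        n = 600
        for i in range(n):
            y = simulate_traits(tree, R1, None, seed=70000 + i)["x"]
            y.name = "y"
            fit = gls.pgls(tree, y, X, mode="pgls_fixed_lambda", lam=1.0)
            rej += fit.f_p < 0.05
        assert 0.03 <= rej / n <= 0.07

    def test_null_habitat_type_i_plugin_lambda_inflation(self):
        """The plug-in ML-lambda F test is mildly anticonservative when the
        predictor is phylogenetically clumped: the habitat factor absorbs
        clade structure, lambda is under-estimated from the residuals, and
        the nominal-0.05 test rejects at roughly twice the nominal rate.
        This pins the size of that known distortion."""
        ds = make_fixture(SimulationConfig(seed=0, habitat_effects={}))
        tree, hab = ds.tree, ds.habitat
        X = gls.habitat_design(hab)
        rej = 0
        n = 600
        for i in range(n):
            y = simulate_traits(tree, R1, None, seed=70000 + i)["x"]
            y.name = "y"
            fit = gls.pgls(tree, y, X, mode="pgls_ml_lambda")
            rej += fit.f_p < 0.05
        assert 0.04 <= rej / n <= 0.16

    def test_strong_effect_detected_with_direction(self):
        from cladeshift.simulate import SLOW_BLOCK

        hits = 0
        n = 60
        for seed in range(n):
            cfg = SimulationConfig(
                seed=seed,
                habitat_effects={"CS": {t: 3.0 for t in SLOW_BLOCK}},
            )
            ds = make_fixture(cfg)
            Xz = (ds.traits - ds.traits.mean()) / ds.traits.std(ddof=1)
            res = pca.phylo_pca(ds.tree, Xz)
            sgn = np.sign(res.loadings.loc["LMA", "PC1"])
            pc1 = res.scores["PC1"] * sgn
            pc1.name = "PC1"
            Xb = pd.DataFrame({"notCS": (ds.habitat != "CS").astype(float)})
            fit = gls.pgls(ds.tree, pc1, Xb, mode="pgls_ml_lambda")
            hits += (
                fit.params.loc["notCS", "p"] < 0.05
                and fit.params.loc["notCS", "t"] < 0
            )
        assert hits / n >= 0.9

    def test_ml_lambda_beats_fixed_zero_on_bm_traits(self):
        """On high-signal (BM) responses the ML-lambda model usually has
        lower AIC than the star-phylogeny model.

        At 34 taxa the extra lambda parameter costs 2 AIC units while the
        likelihood gain from modelling phylogeny is modest once a
        clade-aligned factor is in the design, so the attainable rate is
        about 0.75-0.85, not near-certainty; the test asserts a clear
        majority."""
        wins = 0
        sig_wins = 0
        n = 60
        lam1 = {
            t: 1.0 for t in ("PH", "LA", "LMA", "LT", "LD", "AR", "RSR")
        }
        for seed in range(n):
            ds = make_fixture(
                SimulationConfig(
                    seed=seed, habitat_effects={}, lambda_per_trait=lam1
                )
            )
            Xz = (ds.traits - ds.traits.mean()) / ds.traits.std(ddof=1)
            y = Xz["LMA"]
            y.name = "LMA"
            X = gls.habitat_design(ds.habitat)
            f_ml = gls.pgls(ds.tree, y, X, mode="pgls_ml_lambda")
            f_star = gls.pgls(ds.tree, y, X, mode="ols")
            wins += f_ml.aic < f_star.aic
            lf = gls.fit_lambda(ds.tree, y)
            sig_wins += lf.aic_hat < lf.aic0
        assert wins / n >= 0.7
        assert sig_wins / n >= 0.7

    def test_habitat_design_reference(self):
        hab = pd.Series(
            {"a": "CS", "b": "HF", "c": "WA", "d": "CS"}, name="habitat"
        )
        X = gls.habitat_design(hab, "CS")
        assert list(X.columns) == ["HF", "WA"]
        assert X.loc["b", "HF"] == 1.0 and X.loc["b", "WA"] == 0.0
        with pytest.raises(ValueError):
            gls.habitat_design(hab, "XX")
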