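import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cladeshift import modularity as mo
from cladeshift.simulate import (
    SimulationConfig,
    default_trait_covariance,
    make_fixture,
    simulate_traits,
    simulate_yule,
)
from cladeshift.tree import parse_newick
from oracles import cr_brute

TRAITS7 = ("PH", "LA", "LMA", "LT", "LD", "AR", "RSR")


def two_plus_two(a, b, c):
    """4-trait covariance: within-module off-diagonals a (w,x) and b (y,z),
    every between-module covariance c."""
    S = np.array(
        [
            [1.0, a, c, c],
            [a, 1.0, c, c],
            [c, c, 1.0, b],
            [c, c, b, 1.0],
        ]
    )
    return pd.DataFrame(S, index=list("wxyz"), columns=list("wxyz"))


P22 = mo.ModulePartition(modules={"M1": ("w", "x"), "M2": ("y", "z")})


def random_psd(rng, p=7):
    A = rng.standard_normal((p, p))
    return A @ A.T / p + np.eye(p) * 0.1


class TestCrStatistic:
    def test_zero_between_module_covariance(self):
        assert mo.cr_statistic(two_plus_two(0.5, 0.7, 0.0), P22) == 0.0

    def test_closed_form_two_plus_two(self):
        # CR = sqrt(2)|c| / sqrt(|a||b|)
        for a, b, c in [(0.5, 0.5, 0.5), (0.4, 0.9, 0.3), (0.2, 0.8, -0.5)]:
            expect = np.sqrt(2) * abs(c) / np.sqrt(abs(a) * abs(b))
            assert mo.cr_statistic(two_plus_two(a, b, c), P22) == pytest.approx(
                expect, abs=1e-10
            )

    def test_equal_covariance_gives_sqrt_two(self):
        assert mo.cr_statistic(two_plus_two(0.5, 0.5, 0.5), P22) == pytest.approx(
            np.sqrt(2), abs=1e-10
        )

    def test_matches_brute_force_on_random_matrices(self):
        rng = np.random.default_rng(0)
        part = mo.DEFAULT_PARTITION
        for _ in range(20):
            S = random_psd(rng)
            df = pd.DataFrame(S, index=TRAITS7, columns=TRAITS7)
            got = mo.cr_statistic(df, part)
            pos = {t: i for i, t in enumerate(TRAITS7)}
            idx1 = [pos[t] for t in part.modules["LEAF"]]
            idx2 = [pos[t] for t in part.modules["LIFEFORM"]]
            assert got == pytest.approx(cr_brute(S, idx1, idx2), abs=1e-10)

    def test_invariant_to_reordering_within_modules(self):
        rng = np.random.default_rng(1)
        S = random_psd(rng)
        df = pd.DataFrame(S, index=TRAITS7, columns=TRAITS7)
        base = mo.cr_statistic(df, mo.DEFAULT_PARTITION)
        shuffled = mo.ModulePartition(
            modules={
                "LEAF": ("AR", "LD", "LA", "LT", "LMA"),
                "LIFEFORM": ("RSR", "PH"),
            }
        )
        assert mo.cr_statistic(df, shuffled) == pytest.approx(base, abs=1e-12)

    @given(k=st.floats(0.05, 20))
    @settings(max_examples=25, deadline=None)
    def test_homogeneous_scaling_invariance(self, k):
        rng = np.random.default_rng(2)
        S = random_psd(rng)
        df = pd.DataFrame(S, index=TRAITS7, columns=TRAITS7)
        assert mo.cr_statistic(df * k, mo.DEFAULT_PARTITION) == pytest.approx(
            mo.cr_statistic(df, mo.DEFAULT_PARTITION), rel=1e-9
        )

    def test_zero_within_module_covariance_rejected(self):
        with pytest.raises(ZeroDivisionError):
            mo.cr_statistic(two_plus_two(0.0, 0.0, 0.3), P22)

    def test_partition_validation(self):
        with pytest.raises(ValueError, match="2 modules"):
            mo.ModulePartition(
                modules={"A": ("x", "y"), "B": ("z", "w"), "C": ("u", "v")}
            )
        with pytest.raises(ValueError, match=">= 2"):
            mo.ModulePartition(modules={"A": ("x",), "B": ("y", "z")})


class TestContrastsCovariance:
    def test_star_tree_matches_gls_quadratic_form(self):
        """On any tree, the PIC cross-product matrix equals the GLS
        quadratic form (X-1a)' C^-1 (X-1a) divided by n-1."""
        tree = simulate_yule(12, seed=3)
        rng = np.random.default_rng(4)
        X = pd.DataFrame(
            rng.standard_normal((12, 3)),
            index=tree.tip_labels,
            columns=list("abc"),
        )
        S = mo.contrasts_covariance(tree, X)
        order, C = tree.phylo_covariance()
        Xv = X.loc[order].to_numpy()
        Ci = np.linalg.inv(C)
        ones = np.ones(12)
        a = (ones @ Ci @ Xv) / (ones @ Ci @ ones)
        D = Xv - a
        expect = D.T @ Ci @ D / 11
        np.testing.assert_allclose(S.to_numpy(), expect, atol=1e-8)

    def test_between_block_entries_average_zero(self):
        tree = simulate_yule(20, seed=5)
        R = default_trait_covariance(
            within=0.6, between=0.0,
            trait_names=("PH", "RSR", "LA", "LMA"),
            block1=("PH", "RSR"), block2=("LA", "LMA"),
        )
        lam1 = {t: 1.0 for t in R.columns}
        offs = []
        for i in range(400):
            X = simulate_traits(tree, R, lam1, seed=11000 + i)
            S = mo.contrasts_covariance(tree, X)
            offs.append(S.loc[["PH", "RSR"], ["LA", "LMA"]].to_numpy())
        offs = np.array(offs)
        se = offs.std(axis=0, ddof=1) / np.sqrt(len(offs))
        assert np.all(np.abs(offs.mean(axis=0)) < 3.5 * se + 1e-12)

    def test_bilinearity_in_one_trait(self):
        tree = simulate_yule(10, seed=6)
        rng = np.random.default_rng(7)
        X = pd.DataFrame(
            rng.standard_normal((10, 3)),
            index=tree.tip_labels,
            columns=list("abc"),
        )
        S1 = mo.contrasts_covariance(tree, X)
        X2 = X.copy()
        X2["a"] *= 2.0
        S2 = mo.contrasts_covariance(tree, X2)
        assert S2.loc["a", "a"] == pytest.approx(4 * S1.loc["a", "a"])
        assert S2.loc["a", "b"] == pytest.approx(2 * S1.loc["a", "b"])
        assert S2.loc["b", "c"] == pytest.approx(S1.loc["b", "c"])


class TestCrTest:
    @staticmethod
    def _traits(tree, modular, seed, within=0.8):
        if modular:
            R = default_trait_covariance(
                within=within, between=0.0,
                block1=("PH", "RSR"), block2=("LA", "LMA", "LT", "LD", "AR"),
            )
        else:
            R = default_trait_covariance(within=0.6, between=0.6)
        lam1 = {t: 1.0 for t in R.columns}
        return simulate_traits(tree, R, lam1, seed=seed)

    def test_p_value_positive_and_deterministic(self):
        tree = simulate_yule(20, seed=8)
        X = self._traits(tree, modular=True, seed=100)
        r1 = mo.cr_test(tree, X, seed=5)
        r2 = mo.cr_test(tree, X, seed=5)
        assert r1.p_value == r2.p_value > 0
        assert r1.cr_observed == r2.cr_observed

    def test_minimum_permutations_enforced(self):
        tree = simulate_yule(10, seed=9)
        X = self._traits(tree, modular=False, seed=101)
        with pytest.raises(ValueError, match="99"):
            mo.cr_test(tree, X, n_permutations=50)

    def test_modular_truth_detected(self):
        tree = simulate_yule(34, seed=10)
        hits = 0
        n = 100
        for i in range(n):
            X = self._traits(tree, modular=True, seed=12000 + i)
            hits += mo.cr_test(tree, X, seed=i).p_value < 0.05
        assert hits / n >= 0.8

    def test_integrated_truth_calibrated(self):
        tree = simulate_yule(34, seed=11)
        rej = 0
        n = 400
        for i in range(n):
            X = self._traits(tree, modular=False, seed=13000 + i)
            rej += mo.cr_test(tree, X, seed=i).p_value < 0.05
        assert 0.02 <= rej / n <= 0.09


class TestByClade:
    def test_full_tree_scope_matches_cr_test(self):
        ds = make_fixture(SimulationConfig(seed=12))
        Xz = (ds.traits - ds.traits.mean()) / ds.traits.std(ddof=1)
        res = mo.modularity_by_clade(
            ds.tree, Xz, ds.truth["clades"], seed=3
        )
        direct = mo.cr_test(ds.tree, Xz, seed=3)
        assert res[0].scope == "all"
        assert res[0].cr_observed == direct.cr_observed
        assert res[0].p_value == direct.p_value
        assert {r.scope for r in res[1:]} == {
            "CladeI", "CladeII", "CladeIII"
        }

    def test_tiny_clade_reported_na(self):
        ds = make_fixture(SimulationConfig(seed=13))
        clades = dict(ds.truth["clades"])
        clades["Tiny"] = clades["CladeI"][:3]
        Xz = (ds.traits - ds.traits.mean()) / ds.traits.std(ddof=1)
        res = mo.modularity_by_clade(ds.tree, Xz, clades, seed=3)
        tiny = next(r for r in res if r.scope == "Tiny")
        assert tiny.cr_observed is None and tiny.p_value is None
        assert "small" in tiny.note

    def test_single_modular_clade_detected_selectively(self):
        """When only one clade evolves modular traits, that clade's CR test
        fires while the others stay quiet."""
        from cladeshift.simulate import modularity_scenario_config

        R_mod = default_trait_covariance(
            within=0.9, between=0.0,
            block1=("PH", "RSR"), block2=("LA", "LMA", "LT", "LD", "AR"),
        )
        R_int = default_trait_covariance(within=0.6, between=0.6)
        hits = 0
        n = 60
        for seed in range(n):
            cfg = SimulationConfig(
                seed=seed,
                R=R_int.copy(),
                lambda_per_trait={t: 1.0 for t in R_int.columns},
                clade_R={
                    "CladeI": R_int, "CladeII": R_mod, "CladeIII": R_int
                },
                habitat_effects={},
            )
            ds = make_fixture(cfg)
            Xz = (ds.traits - ds.traits.mean()) / ds.traits.std(ddof=1)
            res = mo.modularity_by_clade(
                ds.tree, Xz, ds.truth["clades"], seed=seed
            )
            p = {r.scope: r.p_value for r in res}
            hits += (
                p["CladeII"] < 0.05
                and p["CladeI"] >= 0.05
                and p["CladeIII"] >= 0.05
            ) or (
                p["CladeII"] < min(p["CladeI"], p["CladeIII"])
            )
        assert hits / n >= 0.7
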