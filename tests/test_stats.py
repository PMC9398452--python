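"""Exact tests, regressions, PGLS and the gene-wise screen."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from tespread import stats as ts


def brute_force_mwu_p(x, y):
    """Independent oracle: enumerate group assignments, count pairwise wins."""
    pooled = list(x) + list(y)
    n1 = len(x)

    def u_of(groups):
        gx = [pooled[i] for i in groups]
        gy = [pooled[i] for i in range(len(pooled)) if i not in set(groups)]
        return sum((a > b) + 0.5 * (a == b) for a in gx for b in gy)

    u_obs = sum((a > b) + 0.5 * (a == b) for a in x for b in y)
    u_min = min(u_obs, n1 * len(y) - u_obs)
    us = [u_of(g) for g in itertools.combinations(range(len(pooled)), n1)]
    return min(1.0, 2 * sum(u <= u_min + 1e-9 for u in us) / len(us))


class TestMannWhitney:
    def test_complete_separation_4v4(self):
        r = ts.mannwhitney_exact([5, 6, 7, 8], [1, 2, 3, 4])
        assert r.exact and r.p_value == pytest.approx(2 / 70)

    def test_identical_multisets(self):
        r = ts.mannwhitney_exact([1, 2, 3], [1, 2, 3])
        assert r.p_value == 1.0

    def test_u7_case_4v4(self):
        r = ts.mannwhitney_exact([1, 2, 6, 8], [3, 4, 5, 7])
        assert r.statistic == 7.0
        assert r.p_value == pytest.approx(62 / 70)

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            ts.mannwhitney_exact([], [1.0])

    def test_matches_brute_force_small_groups(self, rng):
        for n1, n2 in itertools.product(range(1, 5), repeat=2):
            x = rng.normal(0, 1, n1).round(1)
            y = rng.normal(0.5, 1, n2).round(1)
            r = ts.mannwhitney_exact(x, y)
            assert r.p_value == pytest.approx(brute_force_mwu_p(x, y))

    def test_large_groups_fall_back_to_approximation(self, rng):
        r = ts.mannwhitney_exact(rng.normal(0, 1, 30), rng.normal(1, 1, 30))
        assert not r.exact and r.p_value < 0.05


class TestBinomialSignTest:
    def test_half_successes_p_one(self):
        assert ts.binomial_sign_test(10, 20).p_value == 1.0

    @given(k=st.integers(0, 30), n=st.integers(1, 30))
    @settings(max_examples=60, deadline=None)
    def test_symmetry_at_half(self, k, n):
        if k > n:
            return
        a = ts.binomial_sign_test(k, n).p_value
        b = ts.binomial_sign_test(n - k, n).p_value
        assert a == pytest.approx(b)

    def test_invalid_k_rejected(self):
        with pytest.raises(ValueError):
            ts.binomial_sign_test(5, 3)


class TestSpearman:
    def test_rho_formula_n8(self):
        # untied n=8 with S = sum d^2 = 134: rho = 1 - 6*134/504
        x = list(range(1, 9))
        y = None
        for perm in itertools.permutations(range(1, 9)):
            if sum((a - b) ** 2 for a, b in zip(x, perm)) == 134:
                y = perm
                break
        r = ts.spearman(x, list(y))
        assert r.statistic == pytest.approx(1 - 6 * 134 / 504)
        assert r.statistic == pytest.approx(-0.5952, abs=1e-4)

    def test_antisymmetry_reversed(self):
        x = [1, 2, 3, 4, 5, 6, 7, 8]
        assert ts.spearman(x, x[::-1]).statistic == pytest.approx(-1.0)

    def test_exact_p_perfect_monotone(self):
        r = ts.spearman(list(range(8)), list(range(8)))
        assert r.exact and r.p_value == pytest.approx(2 / math.factorial(8))

    def test_exact_matches_permutation_oracle(self, rng):
        for n in (4, 5, 6):
            x = rng.permutation(n) + 1.0
            y = rng.permutation(n) + 1.0
            r = ts.spearman(x, y)
            # oracle: scipy rho over all permutations of y
            from scipy.stats import spearmanr

            obs = abs(spearmanr(x, y).statistic)
            count = sum(
                abs(spearmanr(x, perm).statistic) >= obs - 1e-12
                for perm in itertools.permutations(y)
            )
            assert r.p_value == pytest.approx(count / math.factorial(n))

    def test_constant_input_rejected(self):
        with pytest.raises(ValueError):
            ts.spearman([1, 1, 1], [1, 2, 3])

    def test_ties_use_approximation(self):
        r = ts.spearman([1, 1, 2, 3, 4, 5, 6, 7], [2, 1, 3, 4, 5, 6, 7, 8])
        assert not r.exact


class TestLogisticFit:
    def test_null_coefficients_near_zero(self, rng):
        y = rng.integers(0, 2, 500)
        X = pd.DataFrame({"length": rng.uniform(500, 5000, 500), "effect": rng.normal(2, 1, 500)})
        fit = ts.logistic_fit(y, X)
        assert fit["converged"] and not fit["separation"]
        assert abs(fit["zvalues"]["effect"]) < 3

    def test_parameter_recovery(self, rng):
        n = 1000
        effect = rng.normal(0, 1, n)
        logit = 0.5 - 1.0 * effect
        y = rng.random(n) < 1 / (1 + np.exp(-logit))
        fit = ts.logistic_fit(y.astype(int), pd.DataFrame({"effect": effect}))
        assert fit["coef"]["effect"] == pytest.approx(-1.0, abs=0.2)

    def test_complete_separation_flagged(self):
        y = [0] * 10 + [1] * 10
        X = pd.DataFrame({"effect": list(range(10)) + list(range(20, 30))})
        fit = ts.logistic_fit(y, X)
        assert fit["separation"]

    def test_constant_response_rejected(self):
        with pytest.raises(ValueError):
            ts.logistic_fit([1] * 20, pd.DataFrame({"x": range(20)}))

    def test_too_few_observations_rejected(self):
        with pytest.raises(ValueError):
            ts.logistic_fit([0, 1] * 3, pd.DataFrame({"x": range(6)}))


class TestLmSequentialAnova:
    def test_normal_equations_oracle(self, rng):
        n = 40
        X = pd.DataFrame({"a": rng.normal(size=n), "b": rng.normal(size=n)})
        y = 1 + 2 * X["a"] - 0.5 * X["b"] + rng.normal(0, 0.3, n)
        fit = ts.lm_sequential_anova(y, X)
        design = np.column_stack([np.ones(n), X.to_numpy()])
        beta = np.linalg.solve(design.T @ design, design.T @ y.to_numpy())
        assert np.allclose(fit["coef"].to_numpy(), beta, atol=1e-10)

    def test_orthogonal_design_sequential_equals_marginal(self):
        # balanced +-1 design: predictors orthogonal, order cannot matter
        a = np.array([1, 1, -1, -1, 1, 1, -1, -1], dtype=float)
        b = np.array([1, -1, 1, -1, 1, -1, 1, -1], dtype=float)
        y = 2 + a - 3 * b + np.array([0.1, -0.1, 0.05, -0.05, 0.02, -0.02, 0.01, -0.01])
        f_ab = ts.lm_sequential_anova(y, pd.DataFrame({"a": a, "b": b}))["anova"]
        f_ba = ts.lm_sequential_anova(y, pd.DataFrame({"b": b, "a": a}))["anova"]
        assert f_ab.loc["a", "F"] == pytest.approx(f_ba.loc["a", "F"])
        assert f_ab.loc["b", "F"] == pytest.approx(f_ba.loc["b", "F"])

    def test_noiseless_recovery(self):
        x = np.arange(10, dtype=float)
        y = 3 + 2 * x
        fit = ts.lm_sequential_anova(y, pd.DataFrame({"x": x}))
        assert fit["coef"]["const"] == pytest.approx(3.0, abs=1e-10)
        assert fit["coef"]["x"] == pytest.approx(2.0, abs=1e-10)

    def test_rank_deficient_rejected(self):
        x = np.arange(10, dtype=float)
        with pytest.raises(ValueError):
            ts.lm_sequential_anova(x, pd.DataFrame({"a": x, "b": 2 * x}))

    def test_interaction_term_expressible(self, rng):
        """Interaction regressions are fit by adding a product column."""
        n = 60
        eff = rng.normal(2, 1, n)
        close = rng.integers(0, 2, n).astype(float)
        y = 1 + 0.3 * eff + 0.2 * close + 0.5 * eff * close + rng.normal(0, 0.2, n)
        X = pd.DataFrame({"effect": eff, "close": close, "effect:close": eff * close})
        fit = ts.lm_sequential_anova(y, X)
        assert fit["anova"].loc["effect:close", "p"] < 0.01


class TestPgls:
    def test_printed_tree_parses_to_eight_tips(self):
        tree = ts.parse_tree()
        labels = {leaf.taxon.label for leaf in tree.leaf_node_iter()}
        assert labels == set(ts.MELANOGASTER_COMPLEX) | set(ts.YAKUBA_COMPLEX)

    def test_star_tree_equals_ols(self, rng):
        newick = "(a:1,b:1,c:1,d:1,e:1,f:1,g:1,h:1);"
        tree = ts.parse_tree(newick)
        labels = list("abcdefgh")
        X = pd.DataFrame({"x": rng.normal(size=8)})
        y = 1 + 0.5 * X["x"].to_numpy() + rng.normal(0, 0.2, 8)
        pg = ts.pgls_brownian(tree, y, X, labels)
        ols = ts.lm_sequential_anova(y, X)
        assert np.allclose(pg["coef"].to_numpy(), ols["coef"].to_numpy(), atol=1e-10)
        assert pg["anova"].loc["x", "F"] == pytest.approx(ols["anova"].loc["x", "F"], abs=1e-8)

    def test_brownian_covariance_shared_paths(self):
        tree = ts.parse_tree("((a:1,b:1):2,c:3);")
        C = ts.brownian_covariance(tree, ["a", "b", "c"])
        assert C[0, 0] == pytest.approx(3.0)
        assert C[0, 1] == pytest.approx(2.0)  # shared root-to-MRCA path
        assert C[0, 2] == pytest.approx(0.0)

    def test_label_mismatch_rejected(self):
        tree = ts.parse_tree("((a:1,b:1):2,c:3);")
        with pytest.raises(ValueError):
            ts.brownian_covariance(tree, ["a", "z"])

    def test_brownian_simulation_recovers_slope(self, rng):
        """Slope recovered within its 95% CI on data simulated under
        Brownian motion along the printed 8-tip tree (smoke version; the
        full 100-replicate calibration runs in the acceptance suite)."""
        tree = ts.parse_tree()
        labels = [l.taxon.label for l in tree.leaf_node_iter()]
        C = ts.brownian_covariance(tree, labels)
        L = np.linalg.cholesky(C)
        x = rng.normal(size=8)
        hits = 0
        from scipy.stats import t as tdist

        for _ in range(20):
            y = 2 + 1.5 * x + L @ rng.normal(0, 0.5, 8)
            fit = ts.pgls_brownian(tree, y, pd.DataFrame({"x": x}), labels)
            half = tdist.ppf(0.975, fit["df_resid"]) * fit["se"]["x"]
            if abs(fit["coef"]["x"] - 1.5) <= half:
                hits += 1
        assert hits >= 15


class TestSuvarScreen:
    def _data(self, rng, shift=0.0, n_genes=200, n_suvar=20):
        genomes = list(ts.MELANOGASTER_COMPLEX + ts.YAKUBA_COMPLEX)
        effect = pd.Series(rng.uniform(1, 3, 8), index=genomes)
        ranks = {}
        for i in range(n_genes):
            base = rng.uniform(1, 1000)
            noise = rng.normal(0, 100, 8)
            bias = 0.0
            if i < n_suvar and shift != 0:
                # candidate genes: rank tracks the effect negatively
                bias = shift * 300 * (effect.to_numpy() - effect.mean())
            ranks[f"g{i}"] = base + noise + bias
        df = pd.DataFrame(ranks).T
        df.columns = genomes
        complexes = {g: ("mel" if g in ts.MELANOGASTER_COMPLEX else "yak") for g in genomes}
        suvar = [f"g{i}" for i in range(n_suvar)]
        return df, effect, suvar, complexes

    def test_constant_gene_excluded(self, rng):
        df, effect, suvar, cx = self._data(rng)
        df.loc["g0"] = 500.0
        out = ts.suvar_screen(df, effect, suvar, cx)
        assert "g0" not in out["table"].index

    def test_shifted_candidate_set_detected(self, rng):
        df, effect, suvar, cx = self._data(rng, shift=-1.0)
        out = ts.suvar_screen(df, effect, suvar, cx)
        assert out["comparisons"]["rho"]["mannwhitney_p"] < 0.01

    def test_null_candidate_set_not_detected(self, rng):
        df, effect, suvar, cx = self._data(rng, shift=0.0)
        out = ts.suvar_screen(df, effect, suvar, cx)
        assert out["comparisons"]["rho"]["mannwhitney_p"] > 0.01

    def test_too_few_genomes_rejected(self, rng):
        df, effect, suvar, cx = self._data(rng)
        with pytest.raises(ValueError):
            ts.suvar_screen(df[list(df.columns[:3])], effect, suvar, cx)
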