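"""Interaction-model fits: neutral expectations, nesting, parameter
recovery and the component/dependence correlations."""

import numpy as np
import pandas as pd
import pytest

from stresscreen.cytometry import ExpressionMatrix
from stresscreen.dependence import screen_dependence
from stresscreen.interactions import (
    component_dependence_correlation,
    fit_additive,
    fit_combined,
    fit_multiplicative,
    variance_explained,
)
from stresscreen.synthetic import TruthConfig, make_truth, matrix_from_truth

from conftest import screen_pairs


def _matrix(values, conditions=("KCl",)):
    df = pd.DataFrame.from_dict(values, orient="index", columns=list(conditions))
    counts = pd.DataFrame(1, index=df.index, columns=df.columns)
    return ExpressionMatrix(values=df.astype(float), n_replicates=counts)


class TestPureModels:
    def test_additive_expectation(self):
        m = _matrix({"WT": [100], "x": [150], "y": [80], "x y": [130]})
        fit = fit_additive(m, "KCl", ["x", "y"])
        assert fit.pairs["expected"].iloc[0] == pytest.approx(130.0)  # 100+50-20
        assert fit.pairs["score"].iloc[0] == pytest.approx(0.0)  # no interaction

    def test_multiplicative_expectation(self):
        m = _matrix({"WT": [100], "x": [150], "y": [80], "x y": [120]})
        fit = fit_multiplicative(m, "KCl", ["x", "y"])
        assert fit.pairs["expected"].iloc[0] == pytest.approx(120.0)  # 100*1.5*0.8

    def test_neutral_gene_is_identity_in_multiplicative(self):
        m = _matrix({"WT": [100], "x": [100], "y": [80], "x y": [80]})
        fit = fit_multiplicative(m, "KCl", ["x", "y"])
        assert fit.pairs["expected"].iloc[0] == pytest.approx(80.0)

    def test_additive_generated_screen_fits_perfectly(self):
        cfg = TruthConfig(m_range=(1.0, 1.0), a_frac_range=(-0.3, 0.5))
        genes = [f"g{i}" for i in range(8)]
        truth = make_truth(genes, ["KCl"], cfg, seed=1)
        pairs = screen_pairs(genes[:3], genes)
        matrix = matrix_from_truth(truth, pairs, replicate_cv=0)
        fit = fit_additive(matrix, "KCl", genes)
        assert fit.r2 == pytest.approx(1.0)
        assert np.allclose(fit.pairs["score"], 0.0, atol=1e-9)

    def test_multiplicative_generated_screen_fits_perfectly(self):
        cfg = TruthConfig(m_range=(0.3, 3.0), a_frac_range=(0.0, 0.0))
        genes = [f"g{i}" for i in range(8)]
        truth = make_truth(genes, ["KCl"], cfg, seed=2)
        pairs = screen_pairs(genes[:3], genes)
        matrix = matrix_from_truth(truth, pairs, replicate_cv=0)
        fit = fit_multiplicative(matrix, "KCl", genes)
        assert fit.r2 == pytest.approx(1.0)


class TestVarianceExplained:
    def test_perfect_and_null_fits(self):
        obs = np.array([1.0, 2.0, 3.0, 4.0])
        assert variance_explained(obs, obs) == 1.0
        assert variance_explained(obs, np.full(4, obs.mean())) == 0.0

    def test_matches_brute_force(self):
        rng = np.random.default_rng(3)
        obs = rng.normal(100, 20, size=10)
        exp = obs + rng.normal(0, 5, size=10)
        sse = sum((o - e) ** 2 for o, e in zip(obs, exp))
        sst = sum((o - np.mean(obs)) ** 2 for o in obs)
        assert variance_explained(obs, exp) == pytest.approx(1 - sse / sst)

    def test_degenerate_variance_errors(self):
        with pytest.raises(ValueError):
            variance_explained(np.ones(5), np.ones(5))


class TestCombinedFit:
    def test_pure_multiplicative_data_recovers_m_equals_M(self):
        cfg = TruthConfig(m_range=(0.3, 3.0), a_frac_range=(0.0, 0.0))
        genes = [f"g{i}" for i in range(8)]
        truth = make_truth(genes, ["KCl"], cfg, seed=4)
        pairs = screen_pairs(genes[:3], genes)
        matrix = matrix_from_truth(truth, pairs, replicate_cv=0)
        fit = fit_combined(matrix, "KCl", genes)
        mult = fit_multiplicative(matrix, "KCl", genes)
        for g in genes:
            c = fit.components[g]
            assert c.m == pytest.approx(c.M, abs=1e-6)
        assert np.allclose(fit.pairs["expected"], mult.pairs["expected"], atol=1e-6)

    def test_pure_additive_data_recovers_a_equals_F(self):
        cfg = TruthConfig(m_range=(1.0, 1.0), a_frac_range=(-0.3, 0.5))
        genes = [f"g{i}" for i in range(8)]
        truth = make_truth(genes, ["KCl"], cfg, seed=5)
        pairs = screen_pairs(genes[:3], genes)
        matrix = matrix_from_truth(truth, pairs, replicate_cv=0)
        fit = fit_combined(matrix, "KCl", genes)
        add = fit_additive(matrix, "KCl", genes)
        for g in genes:
            c = fit.components[g]
            assert c.a == pytest.approx(c.F, abs=1e-6 * abs(c.F) + 1e-9)
        assert fit.r2 == pytest.approx(add.r2, abs=1e-6)

    def test_combined_identity_and_nesting(self):
        """expected_combined = expected_additive + WT*(m_x-1)(m_y-1) for every
        fitted pair, and the combined SSE never exceeds either pure model's."""
        genes = [f"g{i}" for i in range(10)]
        truth = make_truth(genes, ["KCl"], TruthConfig(), seed=6)
        pairs = screen_pairs(genes[:4], genes)
        matrix = matrix_from_truth(truth, pairs, replicate_cv=0.05, n_replicates=2, seed=7)
        comb = fit_combined(matrix, "KCl", genes)
        add = fit_additive(matrix, "KCl", genes)
        mult = fit_multiplicative(matrix, "KCl", genes)
        wt = matrix.wt("KCl")
        for (_, row), (_, arow) in zip(comb.pairs.iterrows(), add.pairs.iterrows()):
            mx = comb.components[row["gene_x"]].m
            my = comb.components[row["gene_y"]].m
            assert row["expected"] == pytest.approx(
                arow["expected"] + wt * (mx - 1) * (my - 1), rel=1e-9
            )
        assert comb.sse <= min(add.sse, mult.sse) + 1e-6

    def test_constrained_solver_agrees_with_substituted(self):
        genes = [f"g{i}" for i in range(6)]
        truth = make_truth(genes, ["KCl"], TruthConfig(), seed=8)
        pairs = screen_pairs(genes[:3], genes)
        matrix = matrix_from_truth(truth, pairs, replicate_cv=0.05, n_replicates=2, seed=9)
        sub = fit_combined(matrix, "KCl", genes, method="substituted")
        con = fit_combined(matrix, "KCl", genes, method="constrained")
        for g in genes:
            assert con.components[g].m == pytest.approx(sub.components[g].m, rel=1e-4)
        assert con.sse == pytest.approx(sub.sse, rel=1e-6)
        assert con.diagnostics["max_constraint_residual"] <= 1e-8 * matrix.wt("KCl")

    def test_gene_without_doubles_pinned_to_additive(self):
        m = _matrix(
            {"WT": [100], "x": [150], "y": [80], "z": [120], "x y": [130]}
        )
        fit = fit_combined(m, "KCl", ["x", "y", "z"])
        c = fit.components["z"]
        assert c.no_doubles and c.m == 1.0 and c.a == pytest.approx(20.0)

    def test_noisy_recovery_tracks_truth(self):
        genes = [f"g{i}" for i in range(12)]
        truth = make_truth(genes, ["KCl"], TruthConfig(), seed=10)
        pairs = screen_pairs(genes[:5], genes)
        matrix = matrix_from_truth(truth, pairs, replicate_cv=0.05, n_replicates=2, seed=11)
        fit = fit_combined(matrix, "KCl", genes)
        m_true = truth.m["KCl"].to_numpy()
        m_fit = np.array([fit.components[g].m for g in genes])
        assert np.corrcoef(m_true, m_fit)[0, 1] > 0.95


class TestComponentDependenceCorrelation:
    @staticmethod
    def _coupled_screen(seed=12, n_query=8, n_target=16):
        cfg = TruthConfig(couple_dfrac_to_components=True)
        genes = [f"g{i}" for i in range(n_query + n_target)]
        truth = make_truth(genes, ["KCl"], cfg, seed=seed)
        pairs = screen_pairs(genes[:n_query], genes)
        matrix = matrix_from_truth(
            truth, pairs, include_triples=True, replicate_cv=0.05, n_replicates=2, seed=seed + 1
        )
        fit = fit_combined(matrix, "KCl", genes)
        dep = screen_dependence(matrix, genes)
        return fit, dep[dep["condition"] == "KCl"]

    def test_perfect_linear_relation_gives_r_one(self):
        fit, dep = self._coupled_screen()
        comps = list(fit.components.values())
        lookup = {c.gene: c for c in comps}
        # choose D so the dependent effect D*F equals m exactly: R must be 1
        fake = dep.copy()
        fake["D"] = [lookup[g].m / lookup[g].F for g in fake["gene"]]
        out = component_dependence_correlation(comps, fake)
        r, _p = out["multiplicative_vs_dependent"]
        assert r == pytest.approx(1.0, abs=1e-9)

    def test_coupled_generation_yields_significant_correlations(self):
        fit, dep = self._coupled_screen()
        out = component_dependence_correlation(list(fit.components.values()), dep)
        r_mult, p_mult = out["multiplicative_vs_dependent"]
        r_add, p_add = out["additive_vs_independent"]
        assert r_mult > 0 and p_mult < 0.05
        assert r_add > 0 and p_add < 0.05

    def test_shuffled_pairing_kills_correlation(self):
        """Permuting which gene's dependent effect is paired with which
        fitted component destroys the correlation."""
        from scipy import stats

        fit, dep = self._coupled_screen(seed=20)
        lookup = dep.set_index("gene")["D"]
        comps = [c for c in fit.components.values() if c.gene in lookup.index]
        m = np.array([c.m for c in comps])
        dep_effect = np.array([lookup[c.gene] * c.F for c in comps])
        rng = np.random.default_rng(0)
        r, p = stats.pearsonr(m, rng.permutation(dep_effect))
        assert abs(r) < 0.5 and p > 0.05
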