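import math

import numpy as np
import pytest

from pteroevo import (DataError, FitOptions, ModelFit, RegimeScheme,
                      TraitTable, aicc, akaike_weights, compare, fit, loglik,
                      read_newick, simulate_yule)
from pteroevo.models import _moments, format_comparison, random_regime_null

from conftest import simulate_ou4, simulate_bm
from helpers import dense_mvn_loglik, random_model_params


class TestLoglik:
    def test_bm_worked_example(self, small_tree, small_traits):
        # density of (2,4,3) under N(3*1, [[2,1,0],[1,2,0],[0,0,2]]):
        # quad form 2, log det 6 -> -0.5(3 log 2pi + log 6 + 2)
        expect = -0.5 * (3 * math.log(2 * math.pi) + math.log(6.0) + 2.0)
        ll = loglik("BM", small_tree, small_traits, None,
                    {"sigma2": 1.0, "z0": 3.0})
        assert ll == pytest.approx(expect, abs=1e-9)
        assert ll == pytest.approx(-4.6526953, abs=1e-6)

    def test_ou1_covariance_closed_form(self, small_tree):
        # sigma2/(2a) e^{-a d}(1 - e^{-2 a s}), a = ln 2
        a = math.log(2.0)
        node_cat = {v: "0" for v in range(small_tree.n_nodes)}
        _, V, _ = _moments(small_tree, node_cat, {"0": a}, {"0": 1.0},
                           theta_cols=["0"])
        lab = small_tree.tip_labels
        i, j = lab.index("A"), lab.index("B")
        cov_ab = 1.0 / (2 * a) * math.exp(-2 * a) * (1 - math.exp(-2 * a))
        var_a = 1.0 / (2 * a) * (1 - math.exp(-4 * a))
        assert V[i, j] == pytest.approx(cov_ab, abs=1e-12)
        assert V[i, i] == pytest.approx(var_a, abs=1e-12)

    def test_ou1_small_alpha_approaches_bm(self, small_tree, small_traits):
        ll_bm = loglik("BM", small_tree, small_traits, None,
                       {"sigma2": 1.0, "z0": 3.0})
        ll_ou = loglik("OU1", small_tree, small_traits, None,
                       {"sigma2": 1.0, "alpha": 1e-8, "theta": 3.0})
        assert ll_ou == pytest.approx(ll_bm, abs=1e-5)

    def test_hansen_weights_sum_to_one(self, yule56, scheme4_56):
        node_cat = scheme4_56.node_categories(yule56)
        for a in (0.05, 0.6, 5.0):
            W, _, _ = _moments(yule56, node_cat,
                               {c: a for c in "SMLI"},
                               {c: 1.0 for c in "SMLI"},
                               theta_cols=["S", "M", "L", "I"])
            assert np.allclose(W.sum(axis=1), 1.0, atol=1e-12)

    def test_alpha_zero_rejected_for_ou(self, small_tree, small_traits):
        with pytest.raises(DataError):
            loglik("OU1", small_tree, small_traits, None,
                   {"sigma2": 1.0, "alpha": 0.0, "theta": 3.0})

    def test_nonfinite_params_rejected(self, small_tree, small_traits):
        with pytest.raises(DataError):
            loglik("BM", small_tree, small_traits, None,
                   {"sigma2": float("nan"), "z0": 3.0})


class TestOracleEquivalence:
    """Every model's likelihood against the dense joint-propagation oracle."""

    @pytest.mark.parametrize("model", ["BM", "BMS", "EB", "OU1", "OUM",
                                       "OUMV", "OUMA", "OUMVA"])
    def test_matches_dense_oracle(self, model):
        rng = np.random.default_rng(2024)
        for trial in range(20):
            n = int(rng.integers(5, 11))
            tree = simulate_yule(n, crown_age=float(rng.uniform(2.0, 10.0)),
                                 seed=int(rng.integers(1 << 30)))
            cats = ["S", "M", "L"]
            tips = dict(zip(tree.tip_labels,
                            (cats[i] for i in rng.integers(0, 3, n))))
            internal = cats[int(rng.integers(0, 3))]
            scheme = RegimeScheme("three_cat", tips,
                                  internal_category=internal)
            params = random_model_params(rng, cats)[model]
            y = rng.uniform(40.0, 90.0, size=n)
            traits = dict(zip(tree.tip_labels, y))
            use_scheme = None if model in ("BM", "EB", "OU1") else scheme
            ll = loglik(model, tree, traits, use_scheme, params)
            if model in ("BM", "EB", "OU1"):
                node_cat = {v: "0" for v in range(tree.n_nodes)}
            else:
                node_cat = scheme.node_categories(tree)
            ll_oracle = dense_mvn_loglik(tree, y, model, node_cat, params)
            assert ll == pytest.approx(ll_oracle, abs=1e-8), \
                f"{model} trial {trial}"


class TestFit:
    def test_bm_closed_form(self, small_tree, small_traits):
        f = fit("BM", small_tree, small_traits)
        assert f.z0 == pytest.approx(3.0, abs=1e-9)
        assert f.sigma2 == pytest.approx(2.0 / 3.0, abs=1e-9)  # ML divisor n
        assert f.k == 2

    def test_constant_trait_flagged_degenerate(self, small_tree):
        f = fit("BM", small_tree, {"A": 5.0, "B": 5.0, "C": 5.0})
        assert f.degenerate
        assert not f.converged
        assert "sigma2" in f.boundary
        assert np.isfinite(f.loglik)

    def test_nested_maximized_likelihood_ordering(self, yule56, scheme4_56):
        sim = simulate_ou4(yule56, scheme4_56, seed=13)
        f_bm = fit("BM", yule56, sim.traits)
        f_ou1 = fit("OU1", yule56, sim.traits)
        f_oum = fit("OUM", yule56, sim.traits, scheme4_56)
        tol = 1e-4
        assert f_ou1.loglik >= f_bm.loglik - tol
        assert f_oum.loglik >= f_ou1.loglik - tol

    def test_variant_models_nest_oum(self, yule56, scheme4_56):
        sim = simulate_ou4(yule56, scheme4_56, seed=17)
        opts = FitOptions(n_restarts=4, seed=1)
        f_oum = fit("OUM", yule56, sim.traits, scheme4_56, opts)
        for model in ("OUMV", "OUMA", "OUMVA"):
            f = fit(model, yule56, sim.traits, scheme4_56, opts)
            assert f.loglik >= f_oum.loglik - 1e-4, model

    def test_deterministic_given_seed(self, yule56, scheme4_56):
        sim = simulate_ou4(yule56, scheme4_56, seed=19)
        opts = FitOptions(n_restarts=3, seed=5)
        a = fit("BMS", yule56, sim.traits, scheme4_56, opts)
        b = fit("BMS", yule56, sim.traits, scheme4_56, opts)
        assert a.loglik == b.loglik and a.sigma2 == b.sigma2

    def test_log_transform_only_changes_trait_vector(self, yule56):
        sim = simulate_bm(yule56, seed=23)
        manual = TraitTable.from_means(
            {t: math.exp(math.log(v)) for t, v in sim.tip_values.items()})
        f_raw = fit("BM", yule56, manual)
        f_log = fit("BM", yule56, manual, options=FitOptions(log_transform=True))
        logged = {t: math.log(v) for t, v in sim.tip_values.items()}
        f_manual = fit("BM", yule56, logged)
        # flag == manual pre-transform; and differs from the raw fit
        assert f_log.loglik == pytest.approx(f_manual.loglik, abs=1e-9)
        assert f_log.sigma2 == pytest.approx(f_manual.sigma2, rel=1e-9)
        assert f_log.loglik != pytest.approx(f_raw.loglik, abs=1e-3)


class TestCompare:
    def test_aicc_formula_exact(self):
        for ll, k, n in [(-181.13, 6, 56), (-50.0, 3, 20)]:
            expect = -2 * ll + 2 * k + 2 * k * (k + 1) / (n - k - 1)
            assert aicc(ll, k, n) == pytest.approx(expect, abs=1e-9)

    def test_equal_models_share_weight(self):
        fits = [ModelFit(model="a", loglik=-100.0, k=3, n=30),
                ModelFit(model="b", loglik=-100.0, k=3, n=30)]
        tab = compare(fits, n=30)
        assert np.allclose(tab["weight"], 0.5)

    def test_weights_sum_to_one_and_order_invariant(self):
        lls = [-100.0, -102.0, -95.0]
        fits = [ModelFit(model=f"m{i}", loglik=ll, k=3, n=40)
                for i, ll in enumerate(lls)]
        t1 = compare(fits, n=40)
        t2 = compare(fits[::-1], n=40)
        assert t1["weight"].sum() == pytest.approx(1.0)
        w1 = t1.set_index("model")["weight"]
        w2 = t2.set_index("model")["weight"]
        assert np.allclose(w1.sort_index(), w2.sort_index())

    def test_fingerprint_mismatch_rejected(self, yule56, scheme4_56):
        sim1 = simulate_ou4(yule56, scheme4_56, seed=29)
        sim2 = simulate_ou4(yule56, scheme4_56, seed=31)
        f1 = fit("BM", yule56, sim1.traits)
        f2 = fit("OU1", yule56, sim2.traits)
        with pytest.raises(DataError):
            compare([f1, f2])

    def test_format_comparison_mentions_models(self, yule56, scheme4_56):
        sim = simulate_ou4(yule56, scheme4_56, seed=37)
        fits = [fit("BM", yule56, sim.traits),
                fit("OUM", yule56, sim.traits, scheme4_56)]
        compare(fits)
        text = format_comparison(fits)
        assert "log_L" in text and "AICc" in text and "theta_L" in text


class TestRandomRegimeNull:
    def test_zero_reps_returns_observed_only(self, yule56, scheme3_56):
        from conftest import simulate_ou3
        sim = simulate_ou3(yule56, scheme3_56, seed=41)
        res = random_regime_null(yule56, sim.traits, scheme3_56, n_reps=0,
                                 seed=0)
        assert res.aiccs.size == 0
        assert res.exceedance == 0
        assert np.isfinite(res.observed.aicc)

    def test_four_cat_rejected(self, yule56, scheme4_56):
        sim = simulate_ou4(yule56, scheme4_56, seed=43)
        with pytest.raises(DataError):
            random_regime_null(yule56, sim.traits, scheme4_56, n_reps=2)
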