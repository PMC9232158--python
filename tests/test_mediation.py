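import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from dispmed import (Encoding, FormulaSpec, MediatorModelSet, Population,
                     Regime, StudyData, effects_from_models, estimate_effects,
                     fit_mediation_models, percent_of_total, regime_mean,
                     standardization_population)
from dispmed.exceptions import DegenerateDataError, DispmedError
from dispmed.glm import sigmoid
from dispmed.mediation import EffectEstimates
from dispmed.simulate import generate_population, model_from_coefficients

from conftest import (S1_MARG, S1_OUT, S1_ROWS, S1_SEQ, S1_WEIGHTS, s1_schema,
                      s1_generator_params)
from oracles import brute_force_effects, regime_mean_bf


def _logit(p):
    return np.log(p / (1 - p))


class TestModelFitting:
    def test_sequential_vs_marginal_predictors(self):
        data = generate_population(s1_generator_params(800, seed=1))
        mset, outcome = fit_mediation_models(data, formula=FormulaSpec.main_effects())
        assert "m1" in mset.sequential[1].term_names
        assert "m1" not in mset.marginal[1].term_names
        assert {"x", "m1", "m2", "sex"} <= set(outcome.term_names)

    def test_interaction_terms_counted(self):
        data = generate_population(s1_generator_params(2000, seed=2))
        _, outcome = fit_mediation_models(
            data, formula=FormulaSpec(interactions=True, age_squared=False))
        # outcome predictors: x, m1, m2, sex -> C(4,2)=6 products
        products = [t for t in outcome.term_names if ":" in t]
        assert len(products) == 6

    def test_sequential_coefficients_recovered(self):
        params = s1_generator_params(50_000, seed=3)
        data = generate_population(params)
        mset, _ = fit_mediation_models(data, formula=FormulaSpec.main_effects())
        m2 = mset.sequential[1]
        for name, truth in params.beta_m["m2"].items():
            est = m2.coef(name)
            se = m2.bse[m2.term_names.index(name)]
            assert abs(est - truth) < 4 * se, name


class TestStandardizationPopulation:
    def test_exposed_reference(self):
        data = generate_population(s1_generator_params(200, seed=5))
        pop = standardization_population(data, reference="exposed")
        n_exposed = int(data.frame["x"].sum())
        assert pop.n == n_exposed
        assert pop.weights.sum() == pytest.approx(1.0)
        assert np.all(pop.weights == 1.0 / n_exposed)

    def test_all_reference(self):
        data = generate_population(s1_generator_params(200, seed=5))
        pop = standardization_population(data, reference="all")
        assert pop.n == data.n

    def test_empty_reference_errors(self):
        data = generate_population(s1_generator_params(100, seed=5))
        data.frame["x"] = 1.0
        with pytest.raises(DegenerateDataError):
            standardization_population(data, reference="unexposed")


class TestRegimeMean:
    def test_hand_enumeration_single_mediator(self):
        # one row, no live confounders, P(M1=1|x=0)=0.2, outcome probs at
        # x_out=1: 0.1 (M1=0) and 0.3 (M1=1); block-B mediator inert
        # -> joint(x_m=0) mean = 0.8*0.1 + 0.2*0.3 = 0.14
        schema = s1_schema()
        enc = Encoding(schema, {}, {})
        seq = [model_from_coefficients({"const": _logit(0.2), "x": 0.5}, enc),
               model_from_coefficients({"const": 0.3}, enc)]
        out = model_from_coefficients(
            {"const": _logit(0.1), "m1": _logit(0.3) - _logit(0.1)}, enc)
        mset = MediatorModelSet(sequential=seq, marginal=seq, schema=schema,
                                encoding=enc)
        pop = Population(encoded={"c": np.zeros(1)}, weights=np.ones(1), n=1)
        val = regime_mean(mset, out, pop, Regime.joint(1, 0), mode="enumerate")
        assert val == pytest.approx(0.14, abs=1e-12)

    def test_intercept_only_outcome_constant_across_regimes(self, s1):
        mset, _, pop = s1
        enc = mset.encoding
        out = model_from_coefficients({"const": -0.7}, enc)
        expected = float(sigmoid(np.array([-0.7]))[0])
        for regime in [Regime.joint(1, 1), Regime.joint(0, 0),
                       Regime.independent(1, 0, 1)]:
            for mode in ("enumerate", "mc"):
                val = regime_mean(mset, out, pop, regime, mode=mode, draws=50,
                                  seed=3)
                assert val == pytest.approx(expected, abs=1e-12)

    def test_mc_within_monte_carlo_error_of_enumerate(self, s1):
        mset, out, pop = s1
        K = 2000
        for regime in [Regime.joint(1, 1), Regime.independent(1, 0, 1)]:
            exact = regime_mean(mset, out, pop, regime, mode="enumerate")
            mc = regime_mean(mset, out, pop, regime, mode="mc", draws=K, seed=9)
            bound = 3 * np.sqrt(0.25 * float(pop.weights @ pop.weights) / K)
            assert abs(mc - exact) < bound

    def test_invalid_inputs(self, s1):
        mset, out, pop = s1
        with pytest.raises(DispmedError):
            regime_mean(mset, out, pop, Regime.joint(1, 1), mode="mc", draws=0)
        with pytest.raises(DispmedError):
            Regime(x_out=1, source="other")
        with pytest.raises(DispmedError):
            Regime.joint(2, 0)


class TestDecomposition:
    def test_matches_brute_force_oracle(self, s1):
        mset, out, pop = s1
        got = effects_from_models(mset, out, pop, mode="enumerate")
        expected = brute_force_effects(S1_SEQ, S1_MARG, S1_OUT, ["m1", "m2"],
                                       ["A", "B"], S1_ROWS, S1_WEIGHTS, "x")
        for key, val in expected.items():
            assert getattr(got, key) == pytest.approx(val, abs=1e-10), key

    def test_identities_exact_both_modes(self, s1):
        mset, out, pop = s1
        for mode, draws in (("enumerate", 0), ("mc", 37)):
            eff = effects_from_models(mset, out, pop, mode=mode,
                                      draws=max(draws, 1), seed=5)
            assert eff.ata == pytest.approx(eff.de + eff.ie_all, abs=1e-12)
            assert eff.ie_all == pytest.approx(eff.ie_a + eff.ie_b + eff.ie_dep,
                                               abs=1e-12)

    def test_zero_exposure_coefficients_zero_indirect(self, s1):
        _, out, pop = s1
        schema = s1_schema()
        enc = Encoding(schema, {}, {})
        seq = [model_from_coefficients({"const": -0.4, "c": 0.3}, enc),
               model_from_coefficients({"const": -0.8, "c": -0.2, "m1": 0.6}, enc)]
        marg = [model_from_coefficients({"const": -0.4, "c": 0.3}, enc),
                model_from_coefficients({"const": -0.7, "c": -0.15}, enc)]
        mset = MediatorModelSet(sequential=seq, marginal=marg, schema=schema,
                                encoding=enc)
        eff = effects_from_models(mset, out, pop, mode="enumerate")
        assert eff.ie_all == 0.0 and eff.ie_a == 0.0
        assert eff.ie_b == 0.0 and eff.ie_dep == 0.0
        assert eff.ata == eff.de

    def test_no_exposure_in_outcome_zero_direct(self, s1):
        mset, _, pop = s1
        enc = mset.encoding
        out = model_from_coefficients(
            {"const": -1.2, "c": 0.25, "m1": 0.7, "m2": -0.3}, enc)
        eff = effects_from_models(mset, out, pop, mode="enumerate")
        assert eff.de == 0.0

    def test_conditionally_independent_mediators_zero_dependence(self, s1):
        _, _, pop = s1
        schema = s1_schema()
        enc = Encoding(schema, {}, {})
        # sequential == marginal, no cross-mediator terms, additive outcome
        coefs = [{"const": -0.4, "x": 0.5, "c": 0.3},
                 {"const": -0.8, "x": 0.3, "c": -0.2}]
        models = [model_from_coefficients(c, enc) for c in coefs]
        mset = MediatorModelSet(sequential=models, marginal=models,
                                schema=schema, encoding=enc)
        out = model_from_coefficients(
            {"const": -1.2, "x": 0.4, "c": 0.25, "m1": 0.7, "m2": -0.3}, enc)
        eff = effects_from_models(mset, out, pop, mode="enumerate")
        assert abs(eff.ie_dep) < 1e-12

    def test_block_relabelling_contract(self, s1):
        # swapping the block labels and keeping the default anchoring gives
        # the same values as the original labels under the complementary
        # anchoring (the anchoring is order dependent by construction)
        mset, out, pop = s1
        base_alt = effects_from_models(mset, out, pop, mode="enumerate",
                                       anchor="b_first")
        swapped = MediatorModelSet(
            sequential=mset.sequential, marginal=mset.marginal,
            schema=mset.schema.swap_blocks(), encoding=mset.encoding)
        sw = effects_from_models(swapped, out, pop, mode="enumerate",
                                 anchor="a_first")
        assert sw.ie_a == pytest.approx(base_alt.ie_b, abs=1e-14)
        assert sw.ie_b == pytest.approx(base_alt.ie_a, abs=1e-14)
        assert sw.ie_dep == pytest.approx(base_alt.ie_dep, abs=1e-14)

    @given(seed=st.integers(min_value=0, max_value=10_000))
    @settings(deadline=None, max_examples=25, derandomize=True)
    def test_identities_property_random_models(self, seed):
        rng = np.random.default_rng(seed)
        schema = s1_schema()
        enc = Encoding(schema, {}, {})

        def rand_coefs(names):
            return {n: float(rng.normal(scale=0.8)) for n in names}

        seq = [model_from_coefficients(rand_coefs(["const", "x", "c"]), enc),
               model_from_coefficients(rand_coefs(["const", "x", "c", "m1"]), enc)]
        marg = [model_from_coefficients(rand_coefs(["const", "x", "c"]), enc),
                model_from_coefficients(rand_coefs(["const", "x", "c"]), enc)]
        out = model_from_coefficients(
            rand_coefs(["const", "x", "c", "m1", "m2", "m1:m2", "x:m1"]), enc)
        mset = MediatorModelSet(sequential=seq, marginal=marg, schema=schema,
                                encoding=enc)
        pop = Population(encoded={"c": np.array([0.0, 1.0, 1.0])},
                         weights=np.array([0.5, 0.25, 0.25]), n=3)
        eff = effects_from_models(mset, out, pop, mode="enumerate")
        assert eff.ata == pytest.approx(eff.de + eff.ie_all, abs=1e-12)
        assert eff.ie_all == pytest.approx(eff.ie_a + eff.ie_b + eff.ie_dep,
                                           abs=1e-12)
        pct = percent_of_total(eff)
        if eff.ata != 0:
            assert pct["de"] + pct["ie_all"] == pytest.approx(100.0, abs=1e-8)
            assert (pct["de"] + pct["ie_a"] + pct["ie_b"]
                    + pct["ie_dep"]) == pytest.approx(100.0, abs=1e-8)


class TestPercentOfTotal:
    def test_simple_values(self):
        eff = EffectEstimates(ata=2.0, de=0.5, ie_all=1.5, ie_a=1.0, ie_b=0.4,
                              ie_dep=0.1)
        pct = percent_of_total(eff)
        assert pct["de"] == pytest.approx(25.0)
        assert pct["ie_all"] == pytest.approx(75.0)

    def test_full_mediation(self):
        eff = EffectEstimates(ata=1.0, de=0.0, ie_all=1.0, ie_a=1.0, ie_b=0.0,
                              ie_dep=0.0)
        pct = percent_of_total(eff)
        assert pct["ie_all"] == 100.0 and pct["de"] == 0.0

    def test_zero_total_undefined(self):
        eff = EffectEstimates(ata=0.0, de=0.1, ie_all=-0.1, ie_a=0.0, ie_b=0.0,
                              ie_dep=-0.1)
        pct = percent_of_total(eff)
        assert all(np.isnan(v) for v in pct.values())


class TestEstimateEffects:
    def test_mc_and_enumerate_agree_at_large_k(self):
        data = generate_population(s1_generator_params(3000, seed=7))
        fs = FormulaSpec.main_effects()
        exact = estimate_effects(data, formula=fs, mode="enumerate")
        mc = estimate_effects(data, formula=fs, mode="mc", draws=4000, seed=8)
        for key in ("ata", "de", "ie_all"):
            assert getattr(mc, key) == pytest.approx(getattr(exact, key),
                                                     abs=0.15), key

    def test_reference_population_changes_results(self):
        data = generate_population(s1_generator_params(4000, seed=9))
        fs = FormulaSpec.main_effects()
        exposed = estimate_effects(data, formula=fs, mode="enumerate",
                                   reference="exposed")
        unexposed = estimate_effects(data, formula=fs, mode="enumerate",
                                     reference="unexposed")
        assert exposed.ata != unexposed.ata
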