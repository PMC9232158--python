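import numpy as np
import pytest

from dispmed import (Encoding, GeneratorParams, calibrate_intercepts,
                     generate_population, inject_missingness, rikslike_preset,
                     riks_missingness_rates, true_effects)
from dispmed.design import FormulaSpec, design_info_for
from dispmed.exceptions import ConfigError
from dispmed.glm import fit_logistic
from dispmed.simulate import confounder_grid

from conftest import s1_generator_params
from oracles import brute_force_true_effects


class TestGenerate:
    def test_null_params_give_half_prevalences(self):
        params = s1_generator_params(100_000, seed=1)
        params.beta_x = {"const": 0.0}
        params.beta_m = {"m1": {"const": 0.0}, "m2": {"const": 0.0}}
        params.beta_y = {"const": 0.0}
        data = generate_population(params)
        tol = 3 * np.sqrt(0.25 / params.n)
        for col in ["x", "y", "m1", "m2"]:
            assert abs(data.frame[col].mean() - 0.5) < tol

    def test_reproducible_given_seed(self):
        a = generate_population(rikslike_preset(n=500, seed=3))
        b = generate_population(rikslike_preset(n=500, seed=3))
        c = generate_population(rikslike_preset(n=500, seed=4))
        assert a.frame.equals(b.frame)
        assert not a.frame.equals(c.frame)

    def test_mediator_exposure_or_recovered(self):
        # m1 | x has generating conditional OR = 2; the fitted logistic
        # must recover it at large n
        params = s1_generator_params(50_000, seed=2)
        data = generate_population(params)
        enc = Encoding.from_data(data.frame, data.schema)
        info = design_info_for(["x", "sex"], enc, FormulaSpec.main_effects())
        encoded = enc.encode(data.frame)
        model = fit_logistic(info.matrix(encoded, n=data.n), encoded["m1"], info)
        slope = model.coef("x")
        se = model.bse[info.term_names.index("x")]
        assert abs(slope - np.log(2.0)) < 3 * se

    def test_nonfinite_predictor_rejected(self):
        params = s1_generator_params(100, seed=0)
        params.beta_x = {"const": float("inf")}
        with pytest.raises(ConfigError, match="non-finite"):
            generate_population(params)

    def test_invalid_year_probs_rejected(self):
        with pytest.raises(ConfigError, match="probability vector"):
            p = s1_generator_params(10, seed=0)
            GeneratorParams(**{**p.__dict__, "year_probs": {2012: 0.5, 2013: 0.2}})

    def test_save_load_roundtrip(self, tmp_path):
        params = rikslike_preset(n=100, seed=1)
        path = tmp_path / "params.yaml"
        params.save(path)
        loaded = GeneratorParams.load(path)
        assert loaded.to_dict() == params.to_dict()


class TestCalibration:
    def test_intercepts_hit_targets_on_grid(self):
        # after calibration the implied marginals (computed independently by
        # brute-force enumeration over the grid) equal the targets
        params = s1_generator_params(0, seed=None)
        targets = {"x": 0.40, "m1": 0.30, "m2": 0.15, "y": 0.10}
        cal = calibrate_intercepts(params, targets, age_step=5.0)
        frame, w = confounder_grid(cal, age_step=5.0)
        rows = [{"sex": s} for s in frame["sex"]]

        import itertools
        from oracles import _lp, _sigmoid
        px = np.array([_sigmoid(_lp(cal.beta_x, r)) for r in rows])
        assert float(w @ px) == pytest.approx(0.40, abs=1e-9)
        p_m1 = p_m2 = p_y = 0.0
        for row, wi, xi in zip(rows, w, px):
            for x in (0, 1):
                wx = wi * (xi if x else 1 - xi)
                for m1, m2 in itertools.product([0, 1], repeat=2):
                    v = dict(row, x=x)
                    q1 = _sigmoid(_lp(cal.beta_m["m1"], v))
                    v["m1"] = m1
                    q2 = _sigmoid(_lp(cal.beta_m["m2"], v))
                    v["m2"] = m2
                    pr = wx * (q1 if m1 else 1 - q1) * (q2 if m2 else 1 - q2)
                    p_m1 += pr * m1
                    p_m2 += pr * m2
                    p_y += pr * _sigmoid(_lp(cal.beta_y, v))
        assert p_m1 == pytest.approx(0.30, abs=1e-9)
        assert p_m2 == pytest.approx(0.15, abs=1e-9)
        assert p_y == pytest.approx(0.10, abs=1e-9)

    def test_rikslike_marginals_match_truth_implied(self):
        # sampled prevalences converge to the calibration targets
        from dispmed.simulate import RIKSLIKE_TARGETS
        data = generate_population(rikslike_preset(n=100_000, seed=17))
        for col, target in RIKSLIKE_TARGETS.items():
            se = np.sqrt(target * (1 - target) / data.n)
            assert abs(data.frame[col].mean() - target) < 3 * se + 0.003, col


class TestTrueEffects:
    def test_matches_brute_force_oracle(self):
        params = s1_generator_params(0, seed=None)
        frame, w = confounder_grid(params, age_step=10.0)
        rows = [{"sex": s} for s in frame["sex"]]
        expected = brute_force_true_effects(
            params.beta_x, [params.beta_m["m1"], params.beta_m["m2"]],
            params.beta_y, ["m1", "m2"], ["A", "B"], rows, list(w), "x")
        got = true_effects(params, c_grid=(frame, w))
        for key, val in expected.items():
            assert getattr(got, key) == pytest.approx(val, abs=1e-10), key

    def test_no_exposure_to_mediator_paths_zero_indirect(self):
        params = s1_generator_params(0, seed=None)
        params.beta_m = {"m1": {"const": -0.6, "sex": 0.3},
                         "m2": {"const": -1.0, "sex": -0.2, "m1": 0.5}}
        eff = true_effects(params)
        assert eff.ie_all == 0.0 and eff.ie_a == 0.0
        assert eff.ie_b == 0.0 and eff.ie_dep == 0.0

    def test_no_direct_path_zero_de(self):
        params = s1_generator_params(0, seed=None)
        params.beta_y = {"const": -1.5, "sex": 0.2, "m1": 0.8, "m2": 0.4}
        eff = true_effects(params)
        assert eff.de == 0.0

    def test_conditionally_independent_mediators_zero_dependence(self):
        params = s1_generator_params(0, seed=None)
        params.beta_m = {"m1": {"const": -0.6, "x": 0.7, "sex": 0.3},
                         "m2": {"const": -1.0, "x": 0.35, "sex": -0.2}}
        eff = true_effects(params)
        assert abs(eff.ie_dep) < 1e-12

    def test_bad_grid_weights_rejected(self):
        params = s1_generator_params(0, seed=None)
        frame, w = confounder_grid(params, age_step=10.0)
        with pytest.raises(ConfigError, match="sum to 1"):
            true_effects(params, c_grid=(frame, w * 2))

    def test_generator_moments_match_implied_marginals(self):
        # sample moments converge to the enumerated joint's marginals
        params = s1_generator_params(100_000, seed=23)
        data = generate_population(params)
        import itertools
        from oracles import _lp, _sigmoid
        frame, w = confounder_grid(params, age_step=10.0)
        p_m = {m: 0.0 for m in ("m1", "m2", "y")}
        for sex, wi in zip(frame["sex"], w):
            px = _sigmoid(_lp(params.beta_x, {"sex": sex}))
            for x in (0, 1):
                wx = wi * (px if x else 1 - px)
                for m1, m2 in itertools.product([0, 1], repeat=2):
                    v = {"sex": sex, "x": x}
                    q1 = _sigmoid(_lp(params.beta_m["m1"], v))
                    v["m1"] = m1
                    q2 = _sigmoid(_lp(params.beta_m["m2"], v))
                    v["m2"] = m2
                    pr = wx * (q1 if m1 else 1 - q1) * (q2 if m2 else 1 - q2)
                    p_m["m1"] += pr * m1
                    p_m["m2"] += pr * m2
                    p_m["y"] += pr * _sigmoid(_lp(params.beta_y, v))
        for col, p in p_m.items():
            se = np.sqrt(p * (1 - p) / params.n)
            assert abs(data.frame[col].mean() - p) < 3 * se, col


class TestMissingness:
    def test_zero_rates_identity(self):
        data = generate_population(rikslike_preset(n=200, seed=1))
        masked = inject_missingness(data, "mcar", {}, seed=2)
        assert masked.frame.equals(data.frame)

    def test_mcar_rate_recovered(self):
        data = generate_population(rikslike_preset(n=20_000, seed=8))
        masked = inject_missingness(data, "mcar", {"smoking": 0.095}, seed=9)
        frac = masked.frame["smoking"].isna().mean()
        assert abs(frac - 0.095) < 3 * np.sqrt(0.095 * 0.905 / data.n)

    def test_mar_rate_ratio_matches_logit_shift(self):
        data = generate_population(rikslike_preset(n=50_000, seed=10))
        rate, shift = 0.10, np.log(2.0)
        masked = inject_missingness(data, "mar", {"smoking": rate}, seed=11,
                                    mar_driver="lowered_consciousness",
                                    mar_shift=shift)
        y = data.frame["lowered_consciousness"].to_numpy(bool)
        miss = masked.frame["smoking"].isna().to_numpy()
        p1, p0 = miss[y].mean(), miss[~y].mean()
        expected1 = 1 / (1 + np.exp(-(np.log(rate / (1 - rate)) + shift)))
        assert p0 == pytest.approx(rate, abs=3 * np.sqrt(rate * (1 - rate) / (~y).sum()))
        assert p1 == pytest.approx(expected1,
                                   abs=3 * np.sqrt(expected1 * (1 - expected1) / y.sum()))

    def test_mar_driver_must_stay_observed(self):
        data = generate_population(rikslike_preset(n=100, seed=1))
        with pytest.raises(ConfigError, match="fully observed"):
            inject_missingness(data, "mar", {"lowered_consciousness": 0.1},
                               mar_driver="lowered_consciousness", mar_shift=1.0)

    def test_riks_rates_any_missing_near_published(self):
        rates = riks_missingness_rates()
        expected = 1.0
        for r in rates.values():
            expected *= 1 - r
        assert 1 - expected == pytest.approx(0.148, abs=0.01)
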