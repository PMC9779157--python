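"""Hazard, first-passage, likelihood and calibration machinery."""

import itertools
import json
import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st
from scipy.integrate import quad

from preevac import (
    CoefficientSet,
    DiscreteTimeProbitHazard,
    NonIdentifiableError,
    Pedestrian,
    RiskContext,
    RiskUtility,
    default_coefficients,
    default_distributions,
    expand_panels,
    first_passage,
    fit_mle,
    hazard,
    linear_predictor,
    log_likelihood,
    natural_response_estimate,
    sample_population,
    simulate_survey,
    stage_probabilities,
)


def normal_cdf_oracle(x):
    """Standard normal CDF by numerical integration, independent of scipy.stats."""
    val, _ = quad(lambda u: math.exp(-u * u / 2) / math.sqrt(2 * math.pi), -12, x)
    return val


def enumerate_first_passage(hazards):
    """Exhaustive 2^T outcome-tree enumeration of the first-escape law."""
    T = len(hazards)
    pmf = np.zeros(T)
    censor = 0.0
    for bits in itertools.product((0, 1), repeat=T):
        prob = math.prod(p if b else 1 - p for b, p in zip(bits, hazards))
        if 1 in bits:
            pmf[bits.index(1)] += prob
        else:
            censor += prob
    return pmf, censor


def _zero_ctx():
    return {"rcs": 0.0, "dfd": 0.0, "rnc": 0.0}


class TestLinearPredictor:
    def test_constant_only(self):
        c = CoefficientSet(const=-3.212)
        assert linear_predictor({"age": 0}, _zero_ctx(), c) == pytest.approx(-3.212)

    def test_gender_contrast_is_its_coefficient(self, coeffs):
        base = dict(age=2, gen=0, edu=2, time=2, group=1, zone=2, mode=6)
        ctx = RiskContext(0.75, 0.5, 0.25)
        lp_f = linear_predictor(base, ctx, coeffs)
        lp_m = linear_predictor(dict(base, gen=1), ctx, coeffs)
        assert lp_m - lp_f == pytest.approx(0.011)

    def test_scaling_coefficients_leaves_zero_covariates_at_const(self):
        attrs = {"age": 0.4, "gen": -0.2}
        doubled = {k: 2 * v for k, v in attrs.items()}
        zeros = {"age": 0, "gen": 0}
        a = linear_predictor(zeros, _zero_ctx(), CoefficientSet(const=1.5, attr_coeffs=attrs))
        b = linear_predictor(zeros, _zero_ctx(), CoefficientSet(const=1.5, attr_coeffs=doubled))
        assert a == b == 1.5

    def test_missing_covariate_is_an_error(self, coeffs):
        with pytest.raises(ValueError, match="gen"):
            linear_predictor({"age": 1}, _zero_ctx(), coeffs)

    def test_pedestrian_object_accepted(self, coeffs):
        ped = Pedestrian(id=0, age_grade=1, gender=1, education=1,
                         familiarity_time=1, group_size=1, zone_distance=1,
                         travel_mode=1)
        lp = linear_predictor(ped, RiskContext(1.0, 1.0, 1.0), coeffs, period=2)
        expected = (-3.185 + 0.011 - 0.015 - 0.013 + 0.013 + 0.004 + 0.002 + 3.0)
        assert lp == pytest.approx(expected)


class TestHazard:
    def test_zero_index_is_one_half(self):
        assert hazard(0.0, CoefficientSet()) == pytest.approx(0.5)

    def test_matches_cdf_integration_oracle(self):
        c = CoefficientSet()
        for lp in (-3.212, -1.0, 0.3, 2.5):
            assert hazard(lp, c) == pytest.approx(normal_cdf_oracle(lp), abs=1e-10)

    def test_floors_at_natural_rate(self):
        c = CoefficientSet(natural_rate=0.1981)
        assert hazard(-40.0, c) == pytest.approx(0.1981)
        assert hazard(40.0, c) == pytest.approx(1.0)

    def test_sigma_rescales_the_index(self):
        assert hazard(2.0, CoefficientSet(sigma=2.0)) == pytest.approx(
            hazard(1.0, CoefficientSet()))

    @given(st.floats(-5, 5), st.floats(0.01, 2))
    def test_strictly_increasing_in_lp_and_bounded(self, lo, gap):
        c = CoefficientSet(natural_rate=0.1)
        assert hazard(lo + gap, c) > hazard(lo, c)
        assert 0.1 < hazard(lo, c) < 1.0


class TestStageProbabilities:
    def test_degenerate_thresholds_zero_middle_category(self):
        c = CoefficientSet(thresholds=(-1.0, -1.0))
        probs = stage_probabilities(0.5, c)
        assert probs[1] == pytest.approx(0.0)
        assert probs.sum() == pytest.approx(1.0)

    def test_two_intercept_structure(self):
        c = CoefficientSet(thresholds=(-3.212, -3.185))
        probs = stage_probabilities(0.0, c)
        assert probs[0] == pytest.approx(normal_cdf_oracle(-3.212), abs=1e-9)
        assert probs[2] == pytest.approx(1 - normal_cdf_oracle(-3.185), abs=1e-9)
        assert probs[1] == pytest.approx(
            normal_cdf_oracle(-3.185) - normal_cdf_oracle(-3.212), abs=1e-9)

    @given(st.floats(-4, 4), st.floats(-3, 3), st.floats(0, 2))
    def test_probabilities_nonnegative_and_normalised(self, lp, t1, gap):
        c = CoefficientSet(thresholds=(t1, t1 + gap))
        probs = stage_probabilities(lp, c)
        assert (probs >= 0).all()
        assert probs.sum() == pytest.approx(1.0, abs=1e-12)

    def test_unordered_thresholds_rejected(self):
        with pytest.raises(ValueError, match="ascending"):
            CoefficientSet(thresholds=(-3.0, -3.5))


class TestFirstPassage:
    def test_constant_half(self):
        fp = first_passage([0.5, 0.5])
        assert np.allclose(fp.pmf, [0.5, 0.25])
        assert fp.censor == pytest.approx(0.25)

    def test_example_chain(self):
        fp = first_passage([0.1, 0.2, 0.3])
        assert fp.pmf[2] == pytest.approx(0.9 * 0.8 * 0.3)

    def test_all_zero_hazards_fully_censored(self):
        fp = first_passage([0.0, 0.0, 0.0])
        assert fp.censor == 1.0
        assert fp.pmf.sum() == 0.0

    def test_matches_enumeration_oracle(self, rng):
        for _ in range(50):
            T = int(rng.integers(1, 7))
            hazards = rng.random(T)
            pmf, censor = enumerate_first_passage(hazards)
            fp = first_passage(hazards)
            assert np.allclose(fp.pmf, pmf, atol=1e-12)
            assert censor == pytest.approx(fp.censor, abs=1e-12)

    def test_out_of_range_hazard_rejected(self):
        with pytest.raises(ValueError):
            first_passage([0.5, 1.2])

    @given(st.lists(st.floats(0, 1), min_size=1, max_size=20))
    def test_mass_conservation(self, hazards):
        fp = first_passage(hazards)
        assert fp.pmf.sum() + fp.censor == pytest.approx(1.0, abs=1e-12)


def _tiny_table(rows):
    base = dict(age=1, gen=1, edu=1, time=1, group=1, zone=1, mode=1,
                rcs=0.25, dfd=0.25, rnc=0.25, is_control=0)
    return pd.DataFrame([dict(base, pid=i, **r) for i, r in enumerate(rows)])


class TestLogLikelihood:
    def test_single_escape_at_known_hazard(self):
        # hazard 0.5 at period 1 -> log 0.5
        df = _tiny_table([{"response": 1, "period": 1}])
        c = CoefficientSet(const=0.0, thresholds=(0.0,),
                           attr_coeffs={}, context_coeffs={})
        assert log_likelihood(df, c) == pytest.approx(math.log(0.5))

    def test_equals_brute_force_chain_product(self, coeffs):
        rng = np.random.default_rng(0)
        pop = sample_population(default_distributions(40, seed=5))
        df = simulate_survey(pop, coeffs, seed=6, n_periods=4)
        ll = log_likelihood(df, coeffs)
        # independent oracle: per-respondent product of the first-passage terms
        total = 0.0
        for _, row in df.iterrows():
            hazards = []
            for t in range(1, int(row["period"]) + 1):
                lp = linear_predictor(
                    {f: row[f] for f in ("age", "gen", "edu", "time", "group", "zone", "mode")},
                    {c: row[c] for c in ("rcs", "dfd", "rnc")},
                    coeffs, period=t)
                hazards.append(hazard(lp, coeffs))
            fp = first_passage(hazards)
            prob = fp.pmf[-1] if row["response"] == 1 else fp.censor
            total += math.log(prob)
        assert ll == pytest.approx(total, rel=1e-10)

    def test_raising_hazard_at_observed_escape_increases_likelihood(self):
        df = _tiny_table([{"response": 1, "period": 2}])
        lls = [log_likelihood(df, CoefficientSet(const=c0, thresholds=(-1.0, c0)))
               for c0 in (-1.0, -0.5)]
        assert lls[1] > lls[0]

    def test_impossible_observation_is_minus_inf_not_an_exception(self):
        # an escape observed where the hazard is exactly zero
        df = _tiny_table([{"response": 1, "period": 1}])
        c = CoefficientSet(const=-math.inf, thresholds=(-math.inf,))
        assert log_likelihood(df, c) == -math.inf

    def test_censored_contribution_can_be_disabled(self, coeffs):
        df = _tiny_table([{"response": 1, "period": 1},
                          {"response": 0, "period": 2}])
        full = log_likelihood(df, coeffs)
        events_only = log_likelihood(df, coeffs, include_censored=False)
        assert events_only > full  # dropping a (negative) censored term


class TestExpandPanels:
    def test_single_escape_at_final_period(self):
        df = _tiny_table([{"response": 1, "period": 3},
                          {"response": 0, "period": 2}])
        panel = expand_panels(df)
        first = panel[panel["pid"] == 0]
        assert list(first["t"]) == [1, 2, 3]
        assert list(first["y"]) == [0, 0, 1]
        second = panel[panel["pid"] == 1]
        assert list(second["y"]) == [0, 0]

    def test_control_rows_never_enter(self):
        df = _tiny_table([{"response": 1, "period": 1}])
        df.loc[0, "is_control"] = 1
        with pytest.raises(ValueError, match="no usable"):
            expand_panels(df)


class TestFitting:
    def test_constant_covariate_flagged_non_identifiable(self, coeffs):
        pop = sample_population(default_distributions(300, seed=8))
        df = simulate_survey(pop, coeffs, seed=9)
        df["rcs"] = 0.75  # no variation
        with pytest.raises(NonIdentifiableError):
            fit_mle(df, covariates=["gen", "age", "rcs"], natural_rate=coeffs.natural_rate)

    def test_recovery_smoke_with_strong_signal(self):
        truth = CoefficientSet(
            const=-0.5, thresholds=(-0.8, -0.4),
            attr_coeffs={"gen": 0.5, "age": -0.3},
            context_coeffs={"rcs": 1.0}, natural_rate=0.0)
        pop = sample_population(default_distributions(8000, seed=12))
        df = simulate_survey(pop, truth, seed=13)
        res = fit_mle(df, covariates=["gen", "age", "rcs"], natural_rate=0.0)
        assert res.converged
        for name, tv in [("gen", 0.5), ("age", -0.3), ("rcs", 1.0),
                         ("intercept_1", -0.8), ("intercept_2", -0.4)]:
            assert abs(res.params[name] - tv) < 3 * res.se[name], name

    def test_significance_screening_drops_null_covariate(self):
        truth = CoefficientSet(const=-0.5, thresholds=(-0.8, -0.4),
                               attr_coeffs={"gen": 0.5}, context_coeffs={})
        pop = sample_population(default_distributions(6000, seed=14))
        df = simulate_survey(pop, truth, seed=15)
        res = fit_mle(df, covariates=["gen", "edu"], natural_rate=0.0,
                      screen_alpha=0.05)
        assert res.excluded == ["edu"]
        assert "edu" not in res.params.index
        assert "gen" in res.params.index

    def test_natural_rate_estimated_from_controls(self, coeffs):
        pop = sample_population(default_distributions(2000, seed=16))
        df = simulate_survey(pop, coeffs, seed=17, control_subjects=2973)
        res = fit_mle(df, covariates=["gen", "age"], natural_rate="from_controls")
        assert res.natural_rate_se == pytest.approx(
            math.sqrt(res.natural_rate * (1 - res.natural_rate) / 2973))
        assert abs(res.natural_rate - 0.1981) < 4 * 0.0074

    def test_self_consistency_refit_on_fitted_model(self):
        truth = CoefficientSet(const=-0.6, thresholds=(-0.9, -0.5),
                               attr_coeffs={"gen": 0.4, "group": 0.3},
                               context_coeffs={}, natural_rate=0.0)
        pop = sample_population(default_distributions(20000, seed=18))
        df = simulate_survey(pop, truth, seed=19)
        first = fit_mle(df, covariates=["gen", "group"], natural_rate=0.0)
        df2 = simulate_survey(pop, first.coeffs, seed=20)
        second = fit_mle(df2, covariates=["gen", "group"], natural_rate=0.0)
        for name in first.params.index:
            assert abs(first.params[name] - second.params[name]) < 3 * (
                first.se[name] + second.se[name]), name

    def test_fit_report_fields(self, coeffs):
        pop = sample_population(default_distributions(1500, seed=21))
        df = simulate_survey(pop, coeffs, seed=22)
        res = fit_mle(df, covariates=["gen", "age"], natural_rate=coeffs.natural_rate)
        text = res.summary()
        assert "S.E." in text and "Covariance" in text and "converged" in text
        payload = json.loads(res.to_json())
        assert set(payload["estimates"]) == set(res.params.index)
        assert payload["converged"] is True
        assert payload["pearson_chi2"] >= 0


class TestEstimatorInterface:
    def test_sklearn_param_protocol(self):
        est = DiscreteTimeProbitHazard(natural_rate=0.1)
        assert est.get_params()["natural_rate"] == 0.1
        est.set_params(max_iter=99)
        assert est.max_iter == 99
        with pytest.raises(ValueError):
            est.set_params(bogus=1)

    def test_predict_proba_matches_hazard_formula(self, rng):
        X = rng.normal(size=(500, 2))
        lp = -0.3 + X @ np.array([0.8, -0.5])
        y = (rng.random(500) < 0.5).astype(float)
        est = DiscreteTimeProbitHazard().fit(X, y)
        proba = est.predict_proba(X)
        assert proba.shape == (500, 2)
        assert np.allclose(proba.sum(axis=1), 1.0)
        eta = est.intercept_ + X @ est.coef_
        from scipy.special import ndtr
        assert np.allclose(proba[:, 1], ndtr(eta))

    def test_unfitted_estimator_raises(self):
        with pytest.raises(RuntimeError, match="not fitted"):
            DiscreteTimeProbitHazard().predict(np.zeros((2, 2)))


class TestCoefficientSet:
    def test_json_round_trip(self, tmp_path, coeffs):
        path = tmp_path / "coeffs.json"
        coeffs.to_json(path)
        back = CoefficientSet.from_json(path)
        assert back == coeffs

    @pytest.mark.parametrize("kwargs", [
        {"sigma": 0.0}, {"sigma": -1.0}, {"natural_rate": 1.0},
        {"natural_rate": -0.1}, {"attr_coeffs": {"height": 1.0}},
        {"context_coeffs": {"wind": 1.0}},
    ])
    def test_invalid_parameters_rejected(self, kwargs):
        with pytest.raises(ValueError):
            CoefficientSet(**kwargs)

    def test_shipped_calibration_structure(self, coeffs):
        assert coeffs.thresholds == (-3.212, -3.185)
        assert "edu" not in coeffs.attr_coeffs  # excluded as not significant
        assert coeffs.attr_coeffs["gen"] > 0 and coeffs.attr_coeffs["age"] < 0


class TestRiskUtility:
    @given(st.floats(-5, 5), st.floats(-5, 5), st.floats(-5, 5))
    def test_difference_and_lambda_identities(self, sub, obj, thr):
        ru = RiskUtility(subjective=sub, objective=obj, threshold=thr)
        assert ru.difference == sub - obj
        if sub != 0:
            assert ru.evacuation_coefficient * sub == pytest.approx(thr, abs=1e-9)
        else:
            assert math.isnan(ru.evacuation_coefficient)

    def test_decision_rule(self):
        assert RiskUtility(2.0, 1.0, 0.5).decision == 1   # RE 1.0 >= ECT 0.5
        assert RiskUtility(2.0, 1.9, 0.5).decision == 0


class TestNaturalResponse:
    def test_control_group_rate(self):
        est = natural_response_estimate(2973, 589)
        assert round(est.rate_percent, 2) == 19.81

    def test_binomial_se_rounds_to_printed_value(self):
        est = natural_response_estimate(2973, 589)
        se = math.sqrt(est.rate * (1 - est.rate) / 2973)
        assert est.se == pytest.approx(se)
        assert round(est.se, 3) == 0.007

    def test_zero_responses(self):
        est = natural_response_estimate(100, 0)
        assert est.rate == 0.0 and est.se == 0.0

    @pytest.mark.parametrize("subjects,responses", [(0, 0), (10, 11), (10, -1)])
    def test_invalid_counts_rejected(self, subjects, responses):
        with pytest.raises(ValueError):
            natural_response_estimate(subjects, responses)
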