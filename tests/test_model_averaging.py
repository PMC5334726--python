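import math

import numpy as np
import pandas as pd
import pytest
from scipy.special import logit

from naturedose import model_averaging as ma
from naturedose.terms import TermBlock, default_blocks

from oracles import brute_force_mle, logistic_loglik, ordinal_loglik, poisson_loglik


def cont(name):
    return TermBlock(name=name, source=name)


class TestAICc:
    @pytest.mark.parametrize(
        "lnL, k, n, expected",
        [
            (0.0, 1, 100, 2.0 + 4.0 / 98.0),  # 2.040816...
            (-50.0, 3, 30, 100.0 + 6.0 + 24.0 / 26.0),  # 106.9230...
        ],
    )
    def test_closed_form(self, lnL, k, n, expected):
        assert ma.compute_aicc(lnL, k, n) == pytest.approx(expected, rel=1e-12)

    def test_large_n_limit_is_aic(self):
        assert ma.compute_aicc(-10.0, 2, 10**9) == pytest.approx(24.0, abs=1e-6)

    def test_small_n_rejected(self):
        with pytest.raises(ValueError):
            ma.compute_aicc(0.0, 5, 6)


def _fitted(aicc, term="x", beta=1.0, var=0.04, response="y", family="gaussian"):
    params = pd.Series({"Intercept": 0.0, term: beta})
    cov = pd.DataFrame(np.diag([0.01, var]),
                       index=params.index, columns=params.index)
    return ma.FittedModel(
        response=response, family=family, blocks=(cont(term),), params=params,
        cov=cov, llf=0.0, n=100, k=2, aicc=aicc, converged=True,
    )


class TestRankAndRetain:
    def test_equal_aicc_equal_weights(self):
        cs = ma.rank_and_retain([_fitted(10.0), _fitted(10.0)])
        np.testing.assert_allclose(cs.weights, [0.5, 0.5])

    def test_delta_two_weight_ratio_e(self):
        cs = ma.rank_and_retain([_fitted(10.0), _fitted(12.0)])
        assert cs.weights[0] / cs.weights[1] == pytest.approx(math.e)

    def test_delta_beyond_cutoff_dropped(self):
        cs = ma.rank_and_retain([_fitted(10.0), _fitted(17.0)])
        assert len(cs.retained) == 1
        assert cs.weights.sum() == pytest.approx(1.0)

    def test_empty_list_rejected(self):
        with pytest.raises(ValueError):
            ma.rank_and_retain([])


class TestModelAverage:
    def test_single_model_degenerate_average(self):
        cs = ma.rank_and_retain([_fitted(10.0, beta=0.7, var=0.09)])
        est = {e.term: e for e in ma.model_average(cs)}
        assert est["x"].coefficient == pytest.approx(0.7)
        assert est["x"].unconditional_se == pytest.approx(0.3)

    def test_zero_substitution_hand_example(self):
        """Two equal-weight models; the term is present (beta 1, var 0.04)
        in one and absent in the other.  Direct summation of the
        unconditional-SE formula gives sqrt(0.5*(0.04+0.25) + 0.5*0.25)."""
        with_term = _fitted(10.0, beta=1.0, var=0.04)
        without = ma.FittedModel(
            response="y", family="gaussian", blocks=(),
            params=pd.Series({"Intercept": 0.0}),
            cov=pd.DataFrame([[0.01]], index=["Intercept"], columns=["Intercept"]),
            llf=0.0, n=100, k=1, aicc=10.0, converged=True,
        )
        est = {e.term: e for e in ma.model_average(
            ma.rank_and_retain([with_term, without]))}
        assert est["x"].coefficient == pytest.approx(0.5)
        assert est["x"].unconditional_se == pytest.approx(math.sqrt(0.27))

    def test_identical_coefficient_no_between_model_variance(self):
        a, b = _fitted(10.0, beta=0.3, var=0.01), _fitted(11.0, beta=0.3, var=0.01)
        est = {e.term: e for e in ma.model_average(ma.rank_and_retain([a, b]))}
        assert est["x"].coefficient == pytest.approx(0.3)
        assert est["x"].unconditional_se == pytest.approx(0.1)

    def test_order_invariance(self):
        models = [_fitted(10.0, beta=1.0), _fitted(10.5, beta=0.2, var=0.09)]
        fwd = {e.term: e.coefficient
               for e in ma.model_average(ma.rank_and_retain(models))}
        rev = {e.term: e.coefficient
               for e in ma.model_average(ma.rank_and_retain(models[::-1]))}
        assert fwd == pytest.approx(rev)

    def test_average_within_padded_range(self, small_survey):
        blocks = default_blocks()
        spec = ma.ModelSpec("depression", "binomial",
                            (blocks["age"], blocks["frequency"]))
        cs = ma.all_subsets(spec, small_survey)
        for est in ma.model_average(cs):
            betas = [m.params.get(est.term, 0.0) for m in cs.retained]
            assert min(betas) - 1e-12 <= est.coefficient <= max(betas) + 1e-12


class TestGLMFits:
    def test_binomial_intercept_only_logit_half(self):
        df = pd.DataFrame({"y": [1] * 5 + [0] * 5})
        fm = ma.fit_glm("y", "binomial", (), df)
        assert fm.params["Intercept"] == pytest.approx(0.0, abs=1e-8)

    def test_poisson_intercept_only_log_mean(self):
        df = pd.DataFrame({"y": [2.0] * 40})
        fm = ma.fit_glm("y", "poisson", (), df)
        assert fm.params["Intercept"] == pytest.approx(math.log(2.0), abs=1e-8)

    def test_two_by_two_logistic_slope_is_log_odds_ratio(self):
        y = np.r_[np.ones(10), np.zeros(10), np.ones(5), np.zeros(15)]
        x = np.r_[np.ones(20), np.zeros(20)]
        fm = ma.fit_glm("y", "binomial", (cont("x"),),
                        pd.DataFrame({"y": y, "x": x}))
        assert fm.params["x"] == pytest.approx(math.log(3.0), abs=1e-8)

    def test_matches_direct_likelihood_oracle(self, rng):
        n = 40
        x1, x2 = rng.normal(size=n), rng.normal(size=n)
        X = np.column_stack([np.ones(n), x1, x2])
        y = (rng.random(n) < 1 / (1 + np.exp(-(0.4 + 0.8 * x1 - 0.5 * x2)))).astype(float)
        df = pd.DataFrame({"y": y, "x1": x1, "x2": x2})
        fm = ma.fit_glm("y", "binomial", (cont("x1"), cont("x2")), df)
        oracle = brute_force_mle(logistic_loglik, X, y)
        np.testing.assert_allclose(fm.params.to_numpy(), oracle, atol=1e-6)

        yc = rng.poisson(np.exp(0.2 + 0.3 * x1))
        dfc = pd.DataFrame({"y": yc, "x1": x1})
        fmc = ma.fit_glm("y", "poisson", (cont("x1"),), dfc)
        oracle_c = brute_force_mle(poisson_loglik, X[:, :2], yc.astype(float))
        np.testing.assert_allclose(fmc.params.to_numpy(), oracle_c, atol=1e-6)

    def test_gaussian_k_counts_error_variance(self, small_survey):
        fm = ma.fit_glm("social_cohesion", "gaussian",
                        (default_blocks()["age"],), small_survey)
        assert fm.k == 3  # intercept + slope + variance

    def test_rank_deficiency_rejected(self):
        df = pd.DataFrame({"y": [0, 1, 0, 1], "a": [1.0, 2, 3, 4],
                           "b": [2.0, 4, 6, 8]})
        with pytest.raises(ValueError, match="rank"):
            ma.fit_glm("y", "binomial", (cont("a"), cont("b")), df)

    def test_perfect_separation_flagged(self):
        df = pd.DataFrame({"y": [0, 0, 0, 1, 1, 1],
                           "x": [0.0, 1, 2, 10, 11, 12]})
        fm = ma.fit_glm("y", "binomial", (cont("x"),), df)
        assert not fm.converged


class TestCumulativeLink:
    def test_two_level_reduces_to_logistic(self, rng):
        worst = 0.0
        for _ in range(3):
            n = 120
            x = rng.normal(size=n)
            yb = (rng.random(n) < 1 / (1 + np.exp(-(0.3 + 0.7 * x)))).astype(int)
            df = pd.DataFrame({"y": yb + 1, "yb": yb, "x": x})
            fo = ma.fit_cumulative_link("y", (cont("x"),), df)
            fb = ma.fit_glm("yb", "binomial", (cont("x"),), df)
            worst = max(
                worst,
                abs(fo.params["x"] - fb.params["x"]),
                abs(-fo.cutpoints[0] - fb.params["Intercept"]),
            )
        assert worst < 1e-6

    def test_intercept_only_closed_form(self):
        df = pd.DataFrame({"y": [1] * 20 + [2] * 30 + [3] * 50})
        fm = ma.fit_cumulative_link("y", (), df)
        assert fm.cutpoints[0] == pytest.approx(logit(0.2))
        assert fm.cutpoints[1] == pytest.approx(logit(0.5))
        assert fm.k == 2

    def test_loglik_matches_direct_evaluation(self, rng):
        n = 80
        x = rng.normal(size=n)
        u = rng.random(n)
        cut = np.array([-0.8, 0.6])
        invlogit = lambda z: 1 / (1 + np.exp(-z))
        y = 1 + (u > invlogit(cut[0] - 0.5 * x)).astype(int) \
              + (u > invlogit(cut[1] - 0.5 * x)).astype(int)
        df = pd.DataFrame({"y": y, "x": x})
        fm = ma.fit_cumulative_link("y", (cont("x"),), df)
        direct = ordinal_loglik(
            fm.params.to_numpy(), np.array(fm.cutpoints), x[:, None], y
        )
        assert fm.llf == pytest.approx(direct, abs=1e-8)


class TestModelSets:
    def test_five_responses_times_four_sets(self):
        specs = ma.build_model_sets()
        assert len(specs) == 5
        assert all(set(s) == {"i", "ii", "iii", "iv"} for s in specs.values())

    def test_response_never_its_own_predictor(self):
        specs = ma.build_model_sets()
        for response, sets in specs.items():
            for spec in sets.values():
                assert all(b.source != response for b in spec.candidate_blocks)

    def test_exercise_absent_from_physical_behaviour_models(self):
        specs = ma.build_model_sets()
        for spec in specs["exercise_days"].values():
            assert "exercise_days" not in [b.name for b in spec.candidate_blocks]

    def test_frequency_and_duration_never_cooccur(self):
        specs = ma.build_model_sets()
        for sets in specs.values():
            for spec in sets.values():
                names = [b.name for b in spec.candidate_blocks]
                assert not ("frequency" in names and "duration" in names)

    def test_all_subsets_count_is_two_to_the_p(self, small_survey):
        blocks = default_blocks()
        spec = ma.ModelSpec(
            "depression", "binomial",
            (blocks["age"], blocks["gender"], blocks["frequency"]),
        )
        cs = ma.all_subsets(spec, small_survey, delta_max=np.inf)
        assert len(cs.models) == 8
        assert cs.weights.sum() == pytest.approx(1.0)


class TestMcFadden:
    def test_definition(self):
        assert ma.mcfadden_r2(-50.0, -100.0) == pytest.approx(0.5)
        assert ma.mcfadden_r2(-100.0, -100.0) == 0.0
        with pytest.raises(ValueError):
            ma.mcfadden_r2(-1.0, 0.0)

    def test_intercept_only_zero_by_construction(self, small_survey):
        null = ma.fit_glm("depression", "binomial", (), small_survey)
        assert ma.mcfadden_r2(null.llf, null.llf) == 0.0
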