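import itertools
import math

import numpy as np
import pandas as pd
import pytest

from naturedose import attributable as af

from conftest import random_risk_data


def _hand_model():
    """4 respondents, intercept -1, one factor with coefficient 1,
    exposures {1,1,0,0}; coefficients imposed directly (no fitting)."""
    design = pd.DataFrame(
        {"Intercept": [1.0] * 4, "f": [1.0, 1.0, 0.0, 0.0]}
    )
    params = pd.Series({"Intercept": -1.0, "f": 1.0})
    cov = pd.DataFrame(np.eye(2) * 0.01, index=params.index, columns=params.index)
    invlogit = lambda z: 1 / (1 + math.exp(-z))
    observed = 2 * invlogit(0.0) + 2 * invlogit(-1.0)
    return af.RiskModel(("f",), params, cov, design, observed)


class TestExpectedCases:
    def test_hand_example(self):
        model = _hand_model()
        e1 = af.expected_cases(model, {"f"})
        assert e1 == pytest.approx(4.0 / (1 + math.e), rel=1e-12)  # 4*invlogit(-1)

    def test_empty_removal_equals_observed_cases(self, rng):
        df, cols = random_risk_data(rng, 400, 3)
        model = af.fit_risk_model(df, cols)
        assert af.expected_cases(model, frozenset()) == pytest.approx(
            model.observed_cases, abs=1e-8
        )

    def test_removing_positive_factors_lowers_expectation(self):
        model = _hand_model()
        assert af.expected_cases(model, {"f"}) < af.expected_cases(model, set())

    def test_unknown_factor_rejected(self):
        with pytest.raises(ValueError):
            af.expected_cases(_hand_model(), {"nope"})


class TestSequentialAF:
    def test_single_factor_chain(self):
        model = _hand_model()
        out = af.sequential_af(model, ("f",))
        expected = (model.observed_cases - af.expected_cases(model, {"f"})) \
            / model.observed_cases
        assert out["f"] == pytest.approx(expected, rel=1e-12)

    def test_fractions_sum_to_total(self, rng):
        df, cols = random_risk_data(rng, 300, 4)
        model = af.fit_risk_model(df, cols)
        for ordering in itertools.islice(itertools.permutations(cols), 5):
            out = af.sequential_af(model, ordering)
            total = (af.expected_cases(model, frozenset())
                     - af.expected_cases(model, frozenset(cols))) \
                / model.observed_cases
            assert sum(out.values()) == pytest.approx(total, rel=1e-10)

    def test_non_permutation_rejected(self, rng):
        df, cols = random_risk_data(rng, 200, 3)
        model = af.fit_risk_model(df, cols)
        with pytest.raises(ValueError):
            af.sequential_af(model, (cols[0], cols[0], cols[1]))


class TestAveraging:
    def test_permutation_equals_shapley(self, rng):
        df, cols = random_risk_data(rng, 300, 4)
        model = af.fit_risk_model(df, cols)
        tp = af.average_af_permutation(model)
        ts = af.average_af_shapley(model)
        for a, b in zip(tp.rows, ts.rows):
            assert a.aaf == pytest.approx(b.aaf, abs=1e-12)
        assert tp.total_af == pytest.approx(ts.total_af, abs=1e-12)

    def test_decomposition_identity(self, rng):
        df, cols = random_risk_data(rng, 250, 5)
        model = af.fit_risk_model(df, cols)
        tab = af.average_af_shapley(model)
        assert sum(r.aaf for r in tab.rows) == pytest.approx(
            tab.total_af, abs=1e-10
        )

    def test_exchangeable_factors_get_equal_aafs(self):
        rng = np.random.default_rng(2)
        n = 300
        shared = rng.integers(0, 2, n).astype(float)
        df = pd.DataFrame({"f0": shared, "f1": shared.copy()})
        eta = -1 + 0.5 * df.f0 + 0.5 * df.f1
        df["depression"] = (rng.random(n) < 1 / (1 + np.exp(-eta))).astype(int)
        # identical exposure patterns are collinear for fitting, so impose
        # identical coefficients directly
        params = pd.Series({"Intercept": -1.0, "f0": 0.5, "f1": 0.5})
        design = pd.DataFrame({"Intercept": np.ones(n), "f0": shared,
                               "f1": shared})
        cov = pd.DataFrame(np.eye(3) * 0.01, index=params.index,
                           columns=params.index)
        invlogit = lambda z: 1 / (1 + np.exp(-z))
        obs = float(invlogit(-1 + shared).sum())
        model = af.RiskModel(("f0", "f1"), params, cov, design, obs)
        tab = af.average_af_shapley(model)
        assert tab.rows[0].aaf == pytest.approx(tab.rows[1].aaf, abs=1e-12)

    def test_null_coefficients_zero_aaf(self):
        n = 100
        design = pd.DataFrame({"Intercept": np.ones(n),
                               "f0": np.r_[np.ones(50), np.zeros(50)],
                               "f1": np.r_[np.zeros(30), np.ones(70)]})
        params = pd.Series({"Intercept": -0.5, "f0": 0.0, "f1": 0.0})
        cov = pd.DataFrame(np.eye(3) * 0.01, index=params.index,
                           columns=params.index)
        obs = float(n / (1 + np.exp(0.5)))
        model = af.RiskModel(("f0", "f1"), params, cov, design, obs)
        tab = af.average_af_shapley(model)
        assert all(r.aaf == pytest.approx(0.0, abs=1e-14) for r in tab.rows)
        assert tab.total_af == pytest.approx(0.0, abs=1e-14)

    def test_relabelling_invariance(self, rng):
        df, cols = random_risk_data(rng, 250, 3)
        model = af.fit_risk_model(df, cols)
        renamed = df.rename(columns={"f0": "zzz"})
        model2 = af.fit_risk_model(renamed, ("zzz", "f1", "f2"))
        t1 = af.average_af_shapley(model)
        t2 = af.average_af_shapley(model2)
        assert t1.aaf_of("f0") == pytest.approx(t2.aaf_of("zzz"), abs=1e-12)

    def test_permutation_cap_directs_to_shapley(self, rng):
        df, cols = random_risk_data(rng, 600, 9, scale=0.3)
        model = af.fit_risk_model(df, cols)
        with pytest.raises(ValueError, match="shapley"):
            af.average_af_permutation(model)
        tab = af.average_af_shapley(model)  # 2^9 subsets still fine
        assert sum(r.aaf for r in tab.rows) == pytest.approx(tab.total_af,
                                                             abs=1e-10)


class TestBootstrap:
    def test_percentile_ci_behaviour(self, rng):
        n = 600
        df = pd.DataFrame({
            "f0": rng.integers(0, 2, n).astype(float),
            "f1": rng.integers(0, 2, n).astype(float),  # true coefficient 0
        })
        eta = -1 + 0.9 * df.f0
        df["depression"] = (rng.random(n) < 1 / (1 + np.exp(-eta))).astype(int)
        ci = af.aaf_bootstrap_ci(df, ("f0", "f1"), B=100, seed=4)
        point = af.average_af_shapley(af.fit_risk_model(df, ("f0", "f1")))
        row0 = ci[ci.factor == "f0"].iloc[0]
        row1 = ci[ci.factor == "f1"].iloc[0]
        assert row0.aaf_ci_low <= point.aaf_of("f0") <= row0.aaf_ci_high
        assert row1.aaf_ci_low <= 0.0 <= row1.aaf_ci_high
        assert row0.n_replicates + row0.n_failed == 100

    def test_too_few_replicates_rejected(self, rng):
        df, cols = random_risk_data(rng, 200, 2)
        with pytest.raises(ValueError):
            af.aaf_bootstrap_ci(df, cols, B=10)
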