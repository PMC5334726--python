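import numpy as np
import pandas as pd
import pytest
from scipy.stats import chisquare, spearmanr

from naturedose import scales
from naturedose import synthetic as syn


class TestConfigValidation:
    def test_bad_probability_vector_rejected(self):
        with pytest.raises(ValueError):
            syn.DoseSpec(frequency_probs=(0.5, 0.1, 0.1, 0.1, 0.1, 0.2))

    def test_nonincreasing_cutpoints_rejected(self):
        with pytest.raises(ValueError):
            syn.OutcomeSpec(family="ordinal", cutpoints=(0.0, -1.0, 1.0, 2.0))

    def test_zero_respondents_rejected(self):
        with pytest.raises(ValueError):
            syn.GenerativeConfig(n_respondents=0)

    def test_unachievable_rank_correlation_rejected(self):
        cfg = syn.GenerativeConfig(
            n_respondents=10, dose=syn.DoseSpec(rank_correlation=0.999)
        )
        with pytest.raises(ValueError, match="unachievable"):
            syn.generate_survey(cfg)


class TestDeterminism:
    def test_same_config_same_table(self):
        a = syn.generate_survey(syn.default_config(300, seed=11)).data
        b = syn.generate_survey(syn.default_config(300, seed=11)).data
        pd.testing.assert_frame_equal(a, b)

    def test_different_seed_differs(self):
        a = syn.generate_survey(syn.default_config(300, seed=11)).data
        b = syn.generate_survey(syn.default_config(300, seed=12)).data
        assert not a.equals(b)

    def test_csv_round_trip_is_byte_identical(self, tmp_path):
        table = syn.generate_survey(syn.default_config(100, seed=2))
        p1, p2 = tmp_path / "a.csv", tmp_path / "b.csv"
        table.write_csv(p1)
        syn.generate_survey(syn.default_config(100, seed=2)).write_csv(p2)
        assert p1.read_bytes() == p2.read_bytes()


class TestDoseStructure:
    def test_spearman_hits_target(self):
        df = syn.generate_survey(syn.default_config(10_000, seed=5)).data
        rs = spearmanr(df.freq_visits_per_week, df.duration_min_per_week).statistic
        assert rs == pytest.approx(0.67, abs=0.05)

    def test_never_visitors_report_no_time(self, small_survey):
        never = small_survey[small_survey.freq_category == "never"]
        assert (never.duration_category == "no time").all()
        assert (never.duration_min_per_week == 0).all()

    def test_encoded_columns_match_category_tables(self, small_survey):
        expect = small_survey.freq_category.map(scales.FREQUENCY_ENCODING)
        assert (small_survey.freq_visits_per_week == expect).all()
        expect = small_survey.duration_category.map(scales.DURATION_ENCODING)
        assert (small_survey.duration_min_per_week == expect).all()

    def test_marginal_fidelity_chi_square(self):
        cfg = syn.default_config(10_000, seed=21)
        df = syn.generate_survey(cfg).data
        counts = df.freq_category.value_counts()
        obs = np.array([counts.get(c, 0) for c in scales.FREQUENCY_CATEGORIES])
        exp = np.array(cfg.dose.frequency_probs) * len(df)
        assert chisquare(obs, exp).pvalue > 0.01

    def test_intensity_mean_and_sd(self):
        df = syn.generate_survey(syn.default_config(10_000, seed=3)).data
        assert df.vegetation_cover_pct.mean() == pytest.approx(24.0, abs=0.5)
        assert df.vegetation_cover_pct.std() == pytest.approx(9.1, abs=0.5)
        assert df.vegetation_cover_pct.between(0, 100).all()


class TestOutcomeGeneration:
    def test_null_depression_prevalence_half(self):
        # all coefficients zero, intercept zero: inverse-logit(0) = 0.5
        cfg = syn.GenerativeConfig(
            n_respondents=100_000,
            seed=13,
            outcomes={"depression": syn.OutcomeSpec(family="binomial", intercept=0.0)},
        )
        prev = syn.generate_survey(cfg).data.depression.mean()
        se = np.sqrt(0.25 / 100_000)
        assert abs(prev - 0.5) < 3 * se

    def test_ordinal_intercept_only_matches_cutpoints(self):
        cutpoints = (-1.5, -0.5, 0.5, 1.5)
        cfg = syn.GenerativeConfig(
            n_respondents=50_000,
            seed=17,
            outcomes={"self_health": syn.OutcomeSpec(family="ordinal",
                                                     cutpoints=cutpoints)},
        )
        df = syn.generate_survey(cfg).data
        invlogit = lambda z: 1 / (1 + np.exp(-z))
        for k, theta in enumerate(cutpoints, start=1):
            frac = (df.self_health <= k).mean()
            p = invlogit(theta)
            assert abs(frac - p) < 3 * np.sqrt(p * (1 - p) / len(df))

    def test_poisson_truncated_at_seven(self, small_survey):
        assert small_survey.exercise_days.between(0, 7).all()

    def test_step_effect_changes_prevalence_at_threshold(self):
        from scipy.special import logit

        cfg = syn.GenerativeConfig(
            n_respondents=20_000,
            seed=23,
            outcomes={
                "depression": syn.OutcomeSpec(
                    family="binomial",
                    intercept=float(logit(0.4)),
                    step_effects=(syn.StepEffect(
                        "freq_visits_per_week", 2.5, float(logit(0.1) - logit(0.4))
                    ),),
                )
            },
        )
        df = syn.generate_survey(cfg).data
        below = df[df.freq_visits_per_week < 2.5].depression.mean()
        above = df[df.freq_visits_per_week >= 2.5].depression.mean()
        assert below == pytest.approx(0.4, abs=0.02)
        assert above == pytest.approx(0.1, abs=0.02)

    def test_ranges(self, small_survey):
        assert small_survey.self_health.between(1, 5).all()
        assert small_survey.social_cohesion.between(0, 12).all()
        assert small_survey.nature_relatedness.between(1, 5).all()
        assert small_survey.respondent_id.is_unique


class TestProvenance:
    def test_true_parameters_recorded(self):
        table = syn.generate_survey(syn.default_config(50, seed=1))
        prov = table.provenance
        assert prov["seed"] == 1
        assert "depression" in prov["true_parameters"]
        assert prov["rank_correlation_target"] == 0.67
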