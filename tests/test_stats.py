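"""Statistical model chain: design-determined degrees of freedom, contrast
behavior, the random-intercept mixed model against independent oracles, and
multinomial deviance partitioning."""

import numpy as np
import pandas as pd
import pytest

from oscispeech import stats, synthgen


@pytest.fixture(scope="module")
def truth_table(default_table):
    return default_table


def _balanced_table(rng, n_per_cell=40, effect=None, sigma=1.0):
    """Balanced score x condition table with controllable group means."""
    rows = []
    for cond in ("SiB", "SiSSN"):
        for score in (0, 20, 40, 60, 80, 100):
            mu = 0.0 if effect is None else effect(score)
            vals = mu + sigma * rng.standard_normal(n_per_cell)
            for v in vals:
                rows.append({"condition": cond, "score": score, "alpha_db": v,
                             "subject": "S1"})
    return pd.DataFrame(rows)


class TestPowerScoreAnova:
    def test_full_design_denominator_df(self, truth_table):
        """6 subjects x 175 trials x 2 conditions: the score term is tested
        against 2100 - 5 - 1 - 1 = 2093 residual df."""
        res = stats.power_score_anova(truth_table, band="alpha")
        term = res.term("score")
        assert term.df_num == 5.0
        assert term.df_den == 2093.0

    def test_interaction_term_present_when_requested(self, truth_table):
        res = stats.power_score_anova(truth_table, band="beta", include_interaction=True)
        inter = res.term("score:condition")
        assert inter.df_num == 5.0

    def test_polynomial_contrasts_reported(self, truth_table):
        res = stats.power_score_anova(truth_table, band="alpha")
        names = [t.name for t in res.terms]
        for label in ("score_linear", "score_quadratic", "score_cubic",
                      "score_quartic", "score_quintic"):
            assert label in names

    def test_positive_coupling_gives_positive_linear_contrast(self, truth_table):
        res = stats.power_score_anova(truth_table, band="alpha")
        assert res.term("score_linear").statistic > 0
        assert res.term("score").p_value < 0.05

    def test_missing_level_rebuilds_contrasts(self, truth_table):
        sub = truth_table[truth_table["score"] != 40]
        res = stats.power_score_anova(sub, band="alpha")
        assert res.term("score").df_num == 4.0
        assert not any(t.name == "score_quintic" for t in res.terms)

    def test_single_condition_rejected(self, truth_table):
        with pytest.raises(ValueError):
            stats.power_score_anova(
                truth_table[truth_table["condition"] == "SiB"], band="alpha"
            )


class TestSuccessiveDifferences:
    def test_equal_means_give_null_contrasts(self):
        rng = np.random.default_rng(0)
        tab = _balanced_table(rng, n_per_cell=500)
        res = stats.successive_difference_tests(tab, band="alpha")
        for t in res.terms:
            assert abs(t.estimate) < 0.2
            assert t.p_value > 0.001

    def test_step_effect_isolated_to_first_contrast(self):
        """A pure 0-vs-nonzero step in the generator shows up only in the
        0 -> 20 contrast."""
        rng = np.random.default_rng(1)
        tab = _balanced_table(rng, n_per_cell=400, effect=lambda s: 1.0 * (s > 0))
        res = stats.successive_difference_tests(tab, band="alpha")
        assert res.term("step_0_to_20").p_value < 1e-6
        for name in ("step_20_to_40", "step_40_to_60", "step_60_to_80",
                     "step_80_to_100"):
            assert res.term(name).p_value > 0.01

    def test_contrasts_telescope_to_extreme_difference(self):
        """For balanced data the five step estimates sum to
        mean(power | 100) - mean(power | 0)."""
        rng = np.random.default_rng(2)
        tab = _balanced_table(rng, n_per_cell=50, effect=lambda s: 0.01 * s)
        res = stats.successive_difference_tests(tab, band="alpha")
        total = sum(t.estimate for t in res.terms)
        means = tab.groupby("score")["alpha_db"].mean()
        assert total == pytest.approx(means[100] - means[0], abs=1e-10)


class TestMixedModel:
    def test_matches_lmer_satterthwaite_oracle(self):
        """Frozen oracle: the same cohort fitted with R's lmerTest
        (lmer + Satterthwaite) gives slope 0.19911520, SE 0.04297284,
        df 475.548, sigma^2 7.8102988, tau^2 7.7105587."""
        p = synthgen.SynthParams(n_trials_per_condition=40, seed=7)
        tab = synthgen.simulate_behavior(p).rename(
            columns={"truth_alpha_db": "alpha_db", "truth_beta_db": "beta_db"}
        )
        res = stats.alpha_beta_association(tab)
        t = res.term("alpha")
        assert t.estimate == pytest.approx(0.19911520, abs=2e-6)
        assert t.se == pytest.approx(0.04297284, abs=2e-6)
        assert t.df_den == pytest.approx(475.548, abs=0.5)
        assert res.extras["sigma2"] == pytest.approx(7.8102988, rel=1e-4)
        assert res.extras["tau2"] == pytest.approx(7.7105587, rel=1e-3)

    def test_matches_statsmodels_mixedlm(self):
        """Cross-check fixed effects and variance components against
        statsmodels' general MixedLM on fresh data."""
        import statsmodels.formula.api as smf

        p = synthgen.SynthParams(n_trials_per_condition=30, seed=19)
        tab = synthgen.simulate_behavior(p).rename(
            columns={"truth_alpha_db": "alpha_db", "truth_beta_db": "beta_db"}
        )
        res = stats.alpha_beta_association(tab)
        m = smf.mixedlm(
            "beta_db ~ alpha_db + C(condition)", tab, groups=tab["subject"]
        ).fit(reml=True)
        assert res.term("alpha").estimate == pytest.approx(m.params["alpha_db"], abs=1e-4)
        assert res.extras["sigma2"] == pytest.approx(m.scale, rel=1e-3)
        assert res.extras["tau2"] == pytest.approx(float(m.cov_re.iloc[0, 0]), rel=2e-2)

    def test_shared_latent_gives_positive_significant_slope(self):
        p = synthgen.SynthParams(n_trials_per_condition=60, seed=3)
        tab = synthgen.simulate_behavior(p)
        res = stats.alpha_beta_association(tab)
        t = res.term("alpha")
        assert t.estimate > 0
        assert t.p_value < 0.05

    def test_between_subject_offsets_alone_give_no_slope(self):
        """Subject mean offsets without within-subject coupling must not
        produce an alpha-beta association (the random intercept absorbs
        them)."""
        rej = 0
        for rep in range(20):
            p = synthgen.SynthParams(
                gamma_alpha=0.0, gamma_beta=0.0, n_trials_per_condition=40,
                seed=500 + rep,
            )
            tab = synthgen.simulate_behavior(p)
            res = stats.alpha_beta_association(tab)
            rej += res.term("alpha").p_value < 0.05
        assert rej <= 4  # ~5% nominal; allows binomial slack

    def test_single_subject_falls_back_to_ols(self):
        p = synthgen.SynthParams(n_subjects=1, n_trials_per_condition=30, seed=4)
        tab = synthgen.simulate_behavior(p)
        res = stats.alpha_beta_association(tab)
        assert any("fell back" in n for n in res.notes)


class TestIndividualDifferences:
    def test_distinct_subject_means_detected(self, truth_table):
        """Default subject offsets span ~5-6 dB: the subject term must be
        overwhelmingly significant for both bands and the ratio."""
        for outcome in ("alpha_db", "beta_db", "log_ratio"):
            res = stats.individual_differences_anova(truth_table, outcome=outcome)
            assert res.term("subject").p_value < 1e-6
            assert res.term("subject").df_num == 5.0

    def test_permuting_subjects_destroys_effect(self, truth_table):
        rng = np.random.default_rng(0)
        shuffled = truth_table.copy()
        shuffled["subject"] = rng.permutation(shuffled["subject"].to_numpy())
        res = stats.individual_differences_anova(shuffled, outcome="alpha_db")
        assert res.term("subject").p_value > 0.01

    def test_single_subject_rejected(self, truth_table):
        with pytest.raises(ValueError):
            stats.individual_differences_anova(
                truth_table[truth_table["subject"] == "S1"], outcome="alpha_db"
            )


class TestMultinomialDeviance:
    def test_continuous_predictor_df_is_five(self, truth_table):
        """Each continuous predictor spans 5 equations over the 6-level
        response, so its drop-one likelihood-ratio test has 5 df (the
        condition factor likewise contributes 5, one per non-reference
        level)."""
        res = stats.multinomial_deviance(truth_table)
        assert res.term("alpha").df_num == 5.0
        assert res.term("beta").df_num == 5.0
        assert res.term("condition").df_num == 5.0

    def test_term_order_invariance(self, truth_table):
        a = stats.multinomial_deviance(truth_table, predictors=("alpha", "beta"))
        b = stats.multinomial_deviance(truth_table, predictors=("beta", "alpha"))
        for name in ("alpha", "beta", "condition"):
            assert a.term(name).statistic == pytest.approx(
                b.term(name).statistic, abs=1e-4
            )

    def test_deviance_chain_additivity(self, truth_table):
        """deviance(base -> full) decomposes along the nested chain
        base -> base+alpha -> full."""
        res = stats.multinomial_deviance(truth_table)
        dev = res.extras["deviance_vs_base"]
        assert dev["full"] == pytest.approx(
            dev["alpha"] + res.term("beta").statistic, abs=1e-3
        )
        assert dev["full"] == pytest.approx(
            dev["beta"] + res.term("alpha").statistic, abs=1e-3
        )

    def test_two_latent_generator_gives_independent_contributions(self):
        p = synthgen.SynthParams(n_latents=2, n_trials_per_condition=60, seed=8)
        tab = synthgen.simulate_behavior(p)
        res = stats.multinomial_deviance(tab)
        assert res.term("alpha").p_value < 0.05
        assert res.term("beta").p_value < 0.05

    def test_redundant_predictor_not_significant(self):
        """beta = alpha + noise adds no score information beyond alpha."""
        rng = np.random.default_rng(9)
        p = synthgen.SynthParams(n_trials_per_condition=60, seed=10)
        tab = synthgen.simulate_behavior(p).copy()
        tab["alpha_db"] = tab["truth_alpha_db"]
        tab["beta_db"] = tab["truth_alpha_db"] + rng.standard_normal(len(tab))
        res = stats.multinomial_deviance(tab)
        assert res.term("alpha").p_value < 0.05
        assert res.term("beta").p_value > 0.05


class TestPreDuringCorrelation:
    def test_identity_gives_r2_one(self, truth_table):
        tab = truth_table.copy()
        tab["alpha_pre_db"] = tab["truth_alpha_pre_db"]
        tab["alpha_during_db"] = tab["truth_alpha_pre_db"]
        res = stats.pre_during_correlation(tab, band="alpha")
        assert res.extras["r_squared"] == pytest.approx(1.0)

    def test_full_design_df(self, truth_table):
        res = stats.pre_during_correlation(truth_table, band="alpha")
        assert res.extras["df"] == 2098
        assert res.extras["r_squared"] > 0.5

    def test_within_subject_recovers_rho(self, truth_table):
        res = stats.pre_during_correlation(truth_table, band="alpha", within_subject=True)
        assert res.extras["r_squared"] == pytest.approx(0.8, abs=0.05)
        assert res.extras["df"] == 2100 - 1 - 6

    def test_too_few_trials_rejected(self, truth_table):
        with pytest.raises(ValueError):
            stats.pre_during_correlation(truth_table.head(2), band="alpha")
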