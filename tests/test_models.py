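"""Moderation models: OLS/Wald machinery, stratification, descriptives."""

import numpy as np
import pandas as pd
import pytest

from medconn import models, synthetic
from medconn.config import SimulationConfig
from medconn.models import ModerationFit, ModerationSpec


@pytest.fixture(scope="module")
def noiseless_table():
    cfg = SimulationConfig(n_subjects=120, seed=21, noise_sd=0.0)
    return cfg, synthetic.simulate_analysis_table(cfg)


@pytest.fixture(scope="module")
def noisy_table():
    cfg = SimulationConfig(n_subjects=400, seed=22)
    return cfg, synthetic.simulate_analysis_table(cfg)


class TestFitModeration:
    def test_noiseless_data_recovers_planted_coefficients_exactly(
        self, noiseless_table
    ):
        cfg, table = noiseless_table
        fit = models.fit_moderation(ModerationSpec(), table)
        expo = "delta_overall_between"
        slopes = {
            "low": fit.coef(expo)["B"],
            "moderate": fit.coef(expo)["B"] + fit.coef(f"{expo}:medi_moderate")["B"],
            "high": fit.coef(expo)["B"] + fit.coef(f"{expo}:medi_high")["B"],
        }
        for g, planted in cfg.planted_betas.items():
            assert slopes[g] == pytest.approx(planted, rel=1e-9)
        for cov, beta in cfg.covariate_betas.items():
            assert fit.coef(cov)["B"] == pytest.approx(beta, rel=1e-8)
        assert fit.r_squared == pytest.approx(1.0, abs=1e-10)

    def test_matches_normal_equations_oracle(self, noisy_table):
        _, table = noisy_table
        spec = ModerationSpec()
        fit = models.fit_moderation(spec, table)
        y, X, _ = models.build_design(spec, table)
        Xa, ya = X.to_numpy(float), y.to_numpy(float)
        beta = np.linalg.solve(Xa.T @ Xa, Xa.T @ ya)
        resid = ya - Xa @ beta
        sigma2 = resid @ resid / (len(ya) - Xa.shape[1])
        cov = sigma2 * np.linalg.inv(Xa.T @ Xa)
        se = np.sqrt(np.diag(cov))
        tss = ((ya - ya.mean()) ** 2).sum()
        assert np.allclose(fit.params["B"].to_numpy(), beta, rtol=1e-9)
        halfwidth = (fit.params["UL"] - fit.params["B"]).to_numpy()
        assert np.allclose(halfwidth, 1.959963984540054 * se, rtol=1e-9)
        assert fit.r_squared == pytest.approx(1 - resid @ resid / tss, rel=1e-10)

    def test_confidence_bounds_bracket_estimates(self, noisy_table):
        _, table = noisy_table
        fit = models.fit_moderation(ModerationSpec(), table)
        assert (fit.params["LL"] <= fit.params["B"]).all()
        assert (fit.params["B"] <= fit.params["UL"]).all()
        assert ((fit.params["p"] > 0) & (fit.params["p"] <= 1)).all()

    def test_rank_deficiency_names_collinear_columns(self, noisy_table):
        _, table = noisy_table
        table = table.copy()
        table["age_twin"] = table["age"]
        spec = ModerationSpec(covariates=(*models.DEFAULT_COVARIATES, "age_twin"))
        with pytest.raises(ValueError, match="age_twin"):
            models.fit_moderation(spec, table)

    def test_sample_smaller_than_parameters_rejected(self, noisy_table):
        _, table = noisy_table
        with pytest.raises(ValueError, match="too small"):
            models.fit_moderation(ModerationSpec(), table.head(10))

    def test_shifting_a_covariate_moves_only_the_intercept(self, noisy_table):
        _, table = noisy_table
        fit1 = models.fit_moderation(ModerationSpec(), table)
        shifted = table.copy()
        shifted["age"] = shifted["age"] + 100.0
        fit2 = models.fit_moderation(ModerationSpec(), shifted)
        others = [t for t in fit1.params.index if t != "const"]
        assert np.allclose(
            fit1.params.loc[others, "B"], fit2.params.loc[others, "B"], rtol=1e-7
        )
        assert not np.isclose(
            fit1.params.loc["const", "B"], fit2.params.loc["const", "B"]
        )


class TestInteractionWald:
    def test_zero_coefficients_give_zero_statistic_unit_p(self):
        params = pd.DataFrame(
            {"B": [0.0, 0.0], "LL": [-1, -1], "UL": [1, 1], "p": [1.0, 1.0]},
            index=["a", "b"],
        )
        cov = pd.DataFrame(np.eye(2) * 0.3, index=["a", "b"], columns=["a", "b"])
        fit = ModerationFit(params=params, cov_params=cov,
                            interaction_terms=["a", "b"])
        stat, df, p = models.interaction_wald(fit)
        assert stat == 0.0 and df == 2 and p == 1.0

    def test_single_term_is_squared_z_ratio(self, noisy_table):
        _, table = noisy_table
        fit = models.continuous_sensitivity(ModerationSpec(), table)
        term = fit.interaction_terms[0]
        b = fit.params.loc[term, "B"]
        se = np.sqrt(fit.cov_params.loc[term, term])
        assert fit.wald_df == 1
        assert fit.wald_chi2 == pytest.approx((b / se) ** 2, rel=1e-10)

    def test_matches_statsmodels_quadratic_form(self, noisy_table):
        import statsmodels.api as sm

        _, table = noisy_table
        spec = ModerationSpec()
        fit = models.fit_moderation(spec, table)
        y, X, interactions = models.build_design(spec, table)
        res = sm.OLS(y.to_numpy(float), X).fit(use_t=False)
        R = np.zeros((len(interactions), X.shape[1]))
        for i, term in enumerate(interactions):
            R[i, list(X.columns).index(term)] = 1.0
        oracle = res.wald_test(R, use_f=False, scalar=True)
        assert fit.wald_chi2 == pytest.approx(float(oracle.statistic), rel=1e-9)
        assert fit.wald_p == pytest.approx(float(oracle.pvalue), rel=1e-9)

    def test_singular_covariance_rejected(self):
        params = pd.DataFrame(
            {"B": [1.0, 1.0], "LL": [0, 0], "UL": [2, 2], "p": [0.1, 0.1]},
            index=["a", "b"],
        )
        cov = pd.DataFrame(np.ones((2, 2)), index=["a", "b"], columns=["a", "b"])
        fit = ModerationFit(params=params, cov_params=cov,
                            interaction_terms=["a", "b"])
        with pytest.raises(ValueError, match="singular"):
            models.interaction_wald(fit)

    def test_no_interaction_terms_rejected(self):
        fit = ModerationFit(params=pd.DataFrame(), cov_params=pd.DataFrame())
        with pytest.raises(ValueError, match="no interaction"):
            models.interaction_wald(fit)


class TestStratifiedSlopes:
    def test_noiseless_strata_equal_planted_slopes(self, noiseless_table):
        cfg, table = noiseless_table
        strat = models.stratified_slopes(ModerationSpec(), table).set_index("group")
        for g, planted in cfg.planted_betas.items():
            assert strat.loc[g, "B"] == pytest.approx(planted, rel=1e-9)

    def test_homogeneous_plant_gives_indistinguishable_slopes(self):
        cfg = SimulationConfig(
            n_subjects=600, seed=30,
            planted_betas={"low": -2.0, "moderate": -2.0, "high": -2.0},
        )
        table = synthetic.simulate_analysis_table(cfg)
        strat = models.stratified_slopes(ModerationSpec(), table).set_index("group")
        for g in ("low", "moderate", "high"):
            assert strat.loc[g, "LL"] <= -2.0 <= strat.loc[g, "UL"]

    def test_sign_flip_recovered_at_default_settings(self, noisy_table):
        _, table = noisy_table
        strat = models.stratified_slopes(ModerationSpec(), table).set_index("group")
        assert strat.loc["low", "B"] < 0 < strat.loc["high", "B"]

    def test_empty_stratum_flagged_not_fatal(self, noisy_table):
        _, table = noisy_table
        sub = table[table["medi_group"] != "moderate"]
        strat = models.stratified_slopes(ModerationSpec(), sub).set_index("group")
        assert np.isnan(strat.loc["moderate", "B"])
        assert strat.loc["moderate", "n"] == 0
        assert not np.isnan(strat.loc["low", "B"])


class TestAgeStratified:
    def test_default_age_range_produces_three_strata(self, noisy_table):
        _, table = noisy_table
        out = models.age_stratified(ModerationSpec(), table)
        assert list(out["age_group"]) == ["younger", "middle", "older"]
        assert (out["n"] > 0).all()

    def test_interaction_planted_only_in_oldest_stratum(self):
        cfg = SimulationConfig(n_subjects=900, seed=31, noise_sd=0.4)
        table = synthetic.simulate_analysis_table(cfg)
        # overwrite the outcome: moderation only above the upper age tertile
        q2 = np.quantile(table["age"], 2 / 3)
        old = table["age"].to_numpy() > q2
        slopes = table["medi_group"].map(
            {"low": -4.0, "moderate": 0.0, "high": 4.0}
        ).to_numpy()
        delta = table["delta_overall_between"].to_numpy()
        noise = np.random.default_rng(99).normal(0, 0.4, len(table))
        table["delta_MEMORY"] = np.where(
            old, slopes * delta, -1.0 * delta
        ) + noise
        out = models.age_stratified(ModerationSpec(), table).set_index("age_group")
        assert out.loc["older", "p"] < 0.10
        assert out.loc["older", "p"] < out.loc["younger", "p"]
        assert out.loc["older", "p"] < out.loc["middle", "p"]

    def test_identical_strata_give_identical_statistics(self):
        cfg = SimulationConfig(n_subjects=80, seed=32)
        block = synthetic.simulate_analysis_table(cfg)
        blocks = []
        for shift in (0.0, 25.0, 50.0):  # same data, age shifted by a constant
            b = block.copy()
            b["age"] = 20.0 + (b["age"] - 20.0) / 3.0 + shift
            blocks.append(b)
        table = pd.concat(blocks, ignore_index=True)
        table["subject"] = np.arange(len(table))
        out = models.age_stratified(ModerationSpec(), table)
        assert out["wald_chi2"].nunique() == 1 or np.allclose(
            out["wald_chi2"], out["wald_chi2"].iloc[0], rtol=1e-8
        )


class TestContinuousSensitivity:
    def test_constant_score_is_rank_deficient(self, noisy_table):
        _, table = noisy_table
        table = table.copy()
        table["medi_total"] = 30
        with pytest.raises(ValueError, match="rank-deficient"):
            models.continuous_sensitivity(ModerationSpec(), table)

    def test_same_complete_cases_as_group_model(self, noisy_table):
        _, table = noisy_table
        g = models.fit_moderation(ModerationSpec(), table)
        c = models.continuous_sensitivity(ModerationSpec(), table)
        assert g.n == c.n

    def test_planted_linear_moderation_recovered(self):
        cfg = SimulationConfig(n_subjects=500, seed=33)
        table = synthetic.simulate_analysis_table(cfg)
        gamma = 0.15  # per MeDi point
        rng = np.random.default_rng(7)
        table["delta_MEMORY"] = (
            (0.2 + gamma * table["medi_total"]) * table["delta_overall_between"]
            + rng.normal(0, 0.4, len(table))
        )
        fit = models.continuous_sensitivity(ModerationSpec(), table)
        term = fit.interaction_terms[0]
        assert fit.params.loc[term, "LL"] <= gamma <= fit.params.loc[term, "UL"]


class TestDescribeCohort:
    def test_two_by_two_chi_square_matches_hand_formula(self):
        # observed {{10,20},{20,10}}: all expected cells 15 -> chi2 = 20/3
        data = pd.DataFrame(
            {
                "medi_group": ["low"] * 30 + ["high"] * 30,
                "female": [0] * 10 + [1] * 20 + [0] * 20 + [1] * 10,
            }
        )
        out = models.describe_cohort(
            data, continuous=[], categorical=["female"]
        ).set_index("variable")
        assert out.loc["female", "statistic"] == pytest.approx(20 / 3, rel=1e-12)

    def test_identical_group_distributions_give_null_statistics(self):
        base = pd.DataFrame({"age": np.arange(30.0, 60.0), "female": [0, 1] * 15})
        data = pd.concat(
            [base.assign(medi_group=g) for g in ("low", "moderate", "high")],
            ignore_index=True,
        )
        out = models.describe_cohort(
            data, continuous=["age"], categorical=["female"]
        ).set_index("variable")
        assert out.loc["age", "statistic"] == pytest.approx(0.0, abs=1e-12)
        assert out.loc["female", "statistic"] == pytest.approx(0.0, abs=1e-12)

    def test_constant_variable_reported_with_unit_p_and_warning(self):
        data = pd.DataFrame(
            {"medi_group": ["low", "moderate", "high"] * 10, "mean_fa": 0.44}
        )
        with pytest.warns(UserWarning, match="constant"):
            out = models.describe_cohort(data, continuous=["mean_fa"],
                                         categorical=[])
        assert out["p"].iloc[0] == 1.0

    def test_anova_type_one_error_is_calibrated(self):
        """Three groups drawn from one normal population reject at ~5%."""
        rng = np.random.default_rng(42)
        n_rej = 0
        reps = 400
        groups = np.repeat(["low", "moderate", "high"], 30)
        for _ in range(reps):
            data = pd.DataFrame(
                {"medi_group": groups, "age": rng.normal(50, 10, 90)}
            )
            out = models.describe_cohort(data, continuous=["age"], categorical=[])
            n_rej += out["p"].iloc[0] < 0.05
        rate = n_rej / reps
        assert 0.05 == pytest.approx(rate, abs=3.5 * np.sqrt(0.05 * 0.95 / reps))


class TestRecoveryExperiment:
    def test_noiseless_replicates_have_zero_bias_and_rmse(self):
        cfg = SimulationConfig(n_subjects=120, seed=40, noise_sd=0.0)
        rep = models.recovery_experiment(cfg, n_replicates=3)
        assert np.allclose(rep.per_group["bias"], 0.0, atol=1e-8)
        assert np.allclose(rep.per_group["rmse"], 0.0, atol=1e-8)
        assert rep.sign_flip_rate == 1.0
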