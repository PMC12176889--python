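"""Residualized-change moderation model, simple effects, diagnostics."""

import numpy as np
import pandas as pd
import pytest

from netflex import (
    CohortSpec,
    diagnostics,
    fit_moderation,
    generate_cohort,
    simple_effects,
    vif_table,
    write_fit,
)


def hand_cohort():
    """Six subjects, 2 groups x 3, binary index: small enough to solve the
    normal equations independently."""
    return pd.DataFrame(
        {
            "subject": [f"s{i}" for i in range(6)],
            "group": [0, 0, 0, 1, 1, 1],
            "mmse_baseline": [27.0, 28.0, 26.0, 27.0, 29.0, 25.0],
            "mmse_followup": [27.5, 28.0, 26.5, 28.0, 30.0, 26.0],
            "flexibility": [0.0, 1.0, 0.0, 0.0, 1.0, 1.0],
        }
    )


class TestFitModeration:
    def test_noiseless_synthetic_recovery(self):
        gamma = (2.0, 0.9, -1.5, 4.0, 8.0)
        table = generate_cohort(CohortSpec(gamma=gamma, noise_sd=0.0, seed=21))
        fit = fit_moderation(table)
        assert np.allclose(fit.params[:5], gamma, atol=1e-8)
        assert fit.r2 == pytest.approx(1.0)

    def test_matches_normal_equations_on_hand_dataset(self):
        table = hand_cohort()
        fit = fit_moderation(table)
        x = np.column_stack(
            [
                np.ones(6),
                table.mmse_baseline,
                table.group,
                table.flexibility,
                table.group * table.flexibility,
            ]
        )
        y = table.mmse_followup.to_numpy()
        expected = np.linalg.solve(x.T @ x, x.T @ y)
        assert np.allclose(fit.params, expected, atol=1e-10)

    def test_model_structure_mirrors_study_design(self):
        """Predictor set and residual df match the reported t(47) on n=52."""
        table = generate_cohort(CohortSpec(seed=0))
        fit = fit_moderation(table, index_name="flexibility")
        assert fit.terms == [
            "intercept",
            "mmse_baseline",
            "group",
            "flexibility",
            "group:flexibility",
        ]
        assert fit.n == 52
        assert fit.df_resid == 47

    def test_covariates_appended_additively(self):
        table = generate_cohort(CohortSpec(seed=5))
        fit = fit_moderation(table, covariates=["age", "sex", "education"])
        assert fit.terms[-3:] == ["age", "sex", "education"]
        assert fit.df_resid == 52 - 8

    def test_constant_index_rejected_with_column_named(self):
        table = generate_cohort(CohortSpec(seed=3))
        table["flexibility"] = 0.25
        with pytest.raises(ValueError, match="flexibility"):
            fit_moderation(table)

    def test_too_few_complete_cases_rejected(self):
        table = hand_cohort().iloc[:5]
        with pytest.raises(ValueError, match="complete cases"):
            fit_moderation(table)

    def test_incomplete_cases_dropped(self):
        table = generate_cohort(CohortSpec(seed=9))
        table.loc[0, "mmse_followup"] = np.nan
        table.loc[5, "flexibility"] = np.nan
        fit = fit_moderation(table)
        assert fit.n == 50
        assert fit.df_resid == 45

    def test_interaction_coefficient_invariant_to_centering(self):
        table = generate_cohort(CohortSpec(seed=30))
        fit = fit_moderation(table)
        centered = table.copy()
        m = centered.flexibility.mean()
        centered["flexibility"] = centered.flexibility - m
        fit_c = fit_moderation(centered)
        b_int = fit.coef("group:flexibility")
        assert fit_c.coef("group:flexibility") == pytest.approx(b_int, abs=1e-8)
        # group main effect absorbs beta_interaction * mean
        assert fit_c.coef("group") == pytest.approx(
            fit.coef("group") + b_int * m, abs=1e-8
        )

    def test_r2_equals_independent_sse_sst(self):
        table = generate_cohort(CohortSpec(seed=17))
        fit = fit_moderation(table)
        x, y = fit._exog, fit._endog
        beta = np.linalg.lstsq(x, y, rcond=None)[0]
        sse = float(np.sum((y - x @ beta) ** 2))
        sst = float(np.sum((y - y.mean()) ** 2))
        assert fit.r2 == pytest.approx(1.0 - sse / sst, abs=1e-10)
        assert fit.r2_adj <= fit.r2

    def test_parameter_recovery_bias_below_5_percent(self):
        """Across 1000 stochastic replicates at n = 52, the mean estimated
        interaction stays within 5% of the planted value."""
        gamma = (11.27, 0.64, -3.76, -5.11, 20.94)
        estimates = []
        for rep in range(1000):
            table = generate_cohort(CohortSpec(gamma=gamma, noise_sd=1.0, seed=rep))
            estimates.append(fit_moderation(table).coef("group:flexibility"))
        bias = abs(np.mean(estimates) - gamma[4])
        assert bias < 0.05 * abs(gamma[4])


class TestSimpleEffects:
    def test_zero_group_and_interaction_gives_zero_contrasts(self):
        gamma = (10.0, 0.5, 0.0, 2.0, 0.0)
        table = generate_cohort(CohortSpec(gamma=gamma, noise_sd=0.0, seed=2))
        eff = simple_effects(fit_moderation(table), table)
        assert np.allclose(eff.table.contrast, 0.0, atol=1e-8)

    def test_noiseless_contrast_is_linear_in_moderator(self):
        gamma = (10.0, 0.5, -2.0, 1.0, 16.0)
        table = generate_cohort(CohortSpec(gamma=gamma, noise_sd=0.0, seed=6))
        fit = fit_moderation(table)
        eff = simple_effects(fit, table)
        for _, row in eff.table.iterrows():
            expected = gamma[2] + gamma[4] * row.moderator
            assert row.contrast == pytest.approx(expected, abs=1e-8)
            assert row.emm_music - row.emm_control == pytest.approx(expected, abs=1e-8)

    def test_levels_are_mean_and_plus_minus_one_sd(self):
        table = generate_cohort(CohortSpec(seed=12))
        eff = simple_effects(fit_moderation(table), table)
        m, s = table.flexibility.mean(), table.flexibility.std(ddof=1)
        assert list(eff.table.level) == ["-1 SD", "mean", "+1 SD"]
        assert np.allclose(eff.table.moderator, [m - s, m, m + s])

    def test_power_higher_where_planted_contrast_larger(self):
        """With a pure positive interaction the group contrast grows with
        the moderator, so significance should be more frequent at +1 SD
        than at -1 SD (500 stochastic replicates)."""
        gamma = (11.27, 0.64, 0.0, 0.0, 30.0)
        hits_high = hits_low = 0
        for rep in range(500):
            table = generate_cohort(CohortSpec(gamma=gamma, noise_sd=4.0, seed=rep))
            eff = simple_effects(fit_moderation(table), table).table
            if eff.loc[eff.level == "+1 SD", "p"].iloc[0] < 0.05:
                hits_high += 1
            if eff.loc[eff.level == "-1 SD", "p"].iloc[0] < 0.05:
                hits_low += 1
        assert hits_high > hits_low


class TestDiagnostics:
    def test_orthogonal_design_all_vif_one(self):
        # 2^3 factorial: mutually orthogonal +/-1 columns
        signs = np.array(
            [[1, 1, 1], [1, 1, -1], [1, -1, 1], [1, -1, -1],
             [-1, 1, 1], [-1, 1, -1], [-1, -1, 1], [-1, -1, -1]],
            dtype=float,
        )
        exog = np.column_stack([np.ones(8), signs])
        vifs = vif_table(exog, ["intercept", "a", "b", "c"])
        assert np.allclose(vifs.vif, 1.0)

    def test_duplicated_predictor_flags_infinite_vif(self):
        rng = np.random.default_rng(4)
        z = rng.normal(size=20)
        exog = np.column_stack([np.ones(20), z, z])
        vifs = vif_table(exog, ["intercept", "z", "z_copy"])
        assert (vifs.vif > 1e10).all() or np.isinf(vifs.vif).any()

    def test_heteroscedastic_noise_raises_breusch_pagan_flag(self):
        """Noise proportional to the fitted value should trip the
        Breusch-Pagan screen in the large majority of replicates."""
        gamma = (11.27, 0.64, -3.76, -5.11, 20.94)
        flags = 0
        n_rep = 200
        for rep in range(n_rep):
            # larger cohort: the Breusch-Pagan screen needs more than a
            # pilot-sized n to reach high power
            table = generate_cohort(
                CohortSpec(n_music=250, n_control=270, gamma=gamma, noise_sd=0.0, seed=rep)
            )
            rng = np.random.default_rng(10_000 + rep)
            mu = table.mmse_followup.to_numpy()
            scale = 0.4 * (mu - mu.min() + 0.2)
            table = table.assign(mmse_followup=mu + rng.normal(0.0, scale))
            if diagnostics(fit_moderation(table))["heteroscedastic_flag"]:
                flags += 1
        assert flags / n_rep > 0.9

    def test_report_fields_present(self, tmp_path):
        table = generate_cohort(CohortSpec(seed=1))
        fit = fit_moderation(table)
        diag = diagnostics(fit)
        for key in ("shapiro_w", "shapiro_p", "breusch_pagan_p", "max_vif", "resid_fitted_corr"):
            assert key in diag
        eff = simple_effects(fit, table)
        write_fit(fit, eff, tmp_path)
        assert (tmp_path / "moderation_coefficients.csv").exists()
        assert (tmp_path / "moderation_simple_effects.csv").exists()
        report = (tmp_path / "moderation_report.txt").read_text()
        assert "group:flexibility" in report and "df = 47" in report
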