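"""Mixed-model estimation: balanced-case oracle, parameter recovery,
missing-data handling, effect sizes and remission odds ratios."""

import numpy as np
import pandas as pd
import pytest

from trialcea import (
    Contrast,
    TrialConfig,
    apply_missingness,
    cohens_d,
    did_contrast,
    fit_mixed_model,
    fit_remission_model,
    generate_trial,
    interaction_wald,
    marginal_odds_ratio,
    within_arm_change,
)
from trialcea.sensitivity import complete_case_filter

from conftest import balanced_table

MEANS = {
    "control": {"pre": 4354.0, "post": 4052.0, "followup": 3808.0},
    "intervention": {"pre": 4657.0, "post": 5585.0, "followup": 5199.0},
}


class TestBalancedOracle:
    """On balanced complete data, ML mixed-model LS means and contrasts
    equal cell-mean arithmetic (the closed-form oracle)."""

    def test_lsmeans_equal_cell_means(self):
        df = balanced_table(MEANS, n=10, sd=120.0, seed=2)
        fit = fit_mixed_model(df, "y")
        cells = df.groupby(["arm", "timepoint"], observed=True)["y"].mean()
        for arm in ("control", "intervention"):
            for tp in ("pre", "post", "followup"):
                assert fit.lsmeans.loc[arm, tp] == pytest.approx(
                    cells[arm][tp], abs=1e-6 * max(1.0, abs(cells[arm][tp]))
                )

    def test_did_contrast_equals_cell_arithmetic(self):
        df = balanced_table(MEANS, n=10, sd=0.0)
        fit = fit_mixed_model(df, "y")
        # (5585-4657) - (4052-4354) = 1230
        assert did_contrast(fit, "post").estimate == pytest.approx(1230.0, abs=1e-4)
        # (5199-4657) - (3808-4354) = 1088
        assert did_contrast(fit, "followup").estimate == pytest.approx(1088.0, abs=1e-4)

    def test_sign_convention_costlier_intervention_positive(self):
        df = balanced_table(MEANS, n=6, sd=0.0)
        fit = fit_mixed_model(df, "y")
        assert did_contrast(fit, "post").estimate > 0

    def test_equal_arms_give_zero_contrast(self):
        means = {a: {"pre": 1.0, "post": 2.0, "followup": 3.0} for a in
                 ("control", "intervention")}
        df = balanced_table(means, n=6, sd=0.0)
        fit = fit_mixed_model(df, "y")
        assert did_contrast(fit, "post").estimate == pytest.approx(0.0, abs=1e-8)

    def test_pre_timepoint_rejected(self):
        df = balanced_table(MEANS, n=6, sd=0.0)
        fit = fit_mixed_model(df, "y")
        with pytest.raises(ValueError):
            did_contrast(fit, "pre")


class TestModelFitting:
    def test_requires_two_arms(self):
        df = balanced_table(MEANS, n=6, sd=1.0)
        with pytest.raises(ValueError):
            fit_mixed_model(df[df["arm"] == "control"], "y")

    def test_missing_outcomes_dropped_from_likelihood(self, small_trial_missing):
        fit = fit_mixed_model(small_trial_missing, "eq5d_index")
        assert fit.converged
        assert fit.n_obs == small_trial_missing["eq5d_index"].notna().sum()
        assert fit.random_intercept_var >= 0
        assert fit.residual_var > 0

    def test_interaction_recovery(self):
        """Generating interaction of 0.10 recovered within +-0.02."""
        util = {
            "control": {"pre": 0.70, "post": 0.60, "followup": 0.60},
            "intervention": {"pre": 0.70, "post": 0.70, "followup": 0.70},
        }
        cfg = TrialConfig(n_per_arm=1000, utility_mean=util)
        tab = generate_trial(cfg, seed=13)
        fit = fit_mixed_model(tab, "eq5d_index")
        assert did_contrast(fit, "post").estimate == pytest.approx(0.10, abs=0.02)

    def test_ml_less_biased_than_complete_case_under_mar(self):
        """With dropout driven by baseline utility, likelihood-based
        estimation stays near the truth while complete-case cell means
        drift (selection on the baseline residual enters the change
        score)."""
        util = {
            "control": {"pre": 0.70, "post": 0.65, "followup": 0.60},
            "intervention": {"pre": 0.70, "post": 0.70, "followup": 0.70},
        }
        comp = {
            "diagnostic": {a: {"post": 1.0, "followup": 1.0} for a in
                           ("control", "intervention")},
            "eq5d": {
                "control": {"post": 1.0, "followup": 1.0},
                "intervention": {"post": 0.6, "followup": 0.6},
            },
            "ticp": {a: {"post": 1.0, "followup": 1.0} for a in
                     ("control", "intervention")},
        }
        cfg = TrialConfig(
            n_per_arm=800, utility_mean=util, completion_rate=comp, mar_strength=-6.0
        )
        truth = 0.10
        ml_err, cc_err = [], []
        for i in range(8):
            tab = apply_missingness(generate_trial(cfg, seed=100 + i), cfg, seed=100 + i)
            fit = fit_mixed_model(tab, "eq5d_index")
            ml_err.append(did_contrast(fit, "followup").estimate - truth)
            cc = complete_case_filter(tab, ["eq5d_index"])
            cells = cc.groupby(["arm", "timepoint"], observed=True)["eq5d_index"].mean()
            cc_err.append(
                (cells["intervention"]["followup"] - cells["intervention"]["pre"])
                - (cells["control"]["followup"] - cells["control"]["pre"])
                - truth
            )
        assert abs(np.mean(ml_err)) < abs(np.mean(cc_err)) / 2
        assert abs(np.mean(cc_err)) > 0.02  # the mechanism really biases CC


class TestEffectSize:
    def test_unit_sigma_identity(self):
        fit = _fit_with_sigma(residual_var=1.0)
        c = Contrast(0.5, 0.1, "post", "y")
        assert cohens_d(fit, c) == pytest.approx(0.5)

    def test_zero_contrast_zero_d(self):
        fit = _fit_with_sigma(residual_var=4.0)
        assert cohens_d(fit, Contrast(0.0, 0.1, "post", "y")) == 0.0

    def test_total_sigma_option(self):
        fit = _fit_with_sigma(residual_var=0.25, ri_var=0.75)
        c = Contrast(1.0, 0.1, "post", "y")
        assert cohens_d(fit, c, sigma="residual") == pytest.approx(2.0)
        assert cohens_d(fit, c, sigma="total") == pytest.approx(1.0)

    def test_zero_sigma_rejected(self):
        fit = _fit_with_sigma(residual_var=0.0)
        with pytest.raises(ZeroDivisionError):
            cohens_d(fit, Contrast(1.0, 0.1, "post", "y"))

    def test_standardised_effect_recovery(self):
        """A generating total-sd-standardised DiD of ~0.69 is recovered
        within +-0.05 at large n."""
        # means kept far from the value-set bounds so clipping is inert
        total_sd = np.hypot(0.18, 0.14)
        target_d = 0.69
        delta = target_d * total_sd
        util = {
            "control": {"pre": 0.30, "post": 0.30, "followup": 0.30},
            "intervention": {"pre": 0.30, "post": 0.30, "followup": round(0.30 + delta, 6)},
        }
        cfg = TrialConfig(n_per_arm=2000, utility_mean=util)
        tab = generate_trial(cfg, seed=17)
        fit = fit_mixed_model(tab, "eq5d_index")
        d = cohens_d(fit, did_contrast(fit, "followup"), sigma="total")
        assert d == pytest.approx(target_d, abs=0.05)


def _fit_with_sigma(residual_var=1.0, ri_var=0.0):
    from trialcea.inference import MixedModelFit

    idx = ["Intercept"]
    return MixedModelFit(
        outcome="y",
        fe_params=pd.Series([0.0], index=idx),
        cov_params=pd.DataFrame([[1.0]], index=idx, columns=idx),
        random_intercept_var=ri_var,
        residual_var=residual_var,
        lsmeans=pd.DataFrame(),
        converged=True,
    )


class TestWithinArmChange:
    def test_matches_cell_means(self):
        df = balanced_table(MEANS, n=8, sd=0.0)
        fit = fit_mixed_model(df, "y")
        ch = within_arm_change(fit, "intervention", "followup")
        assert ch.estimate == pytest.approx(5199.0 - 4657.0, abs=1e-4)
        ch = within_arm_change(fit, "control", "post")
        assert ch.estimate == pytest.approx(4052.0 - 4354.0, abs=1e-4)


class TestInteractionTest:
    def test_wald_detects_large_interaction(self):
        df = balanced_table(MEANS, n=20, sd=150.0, seed=3)
        chi2, df_, p = interaction_wald(fit_mixed_model(df, "y"))
        assert df_ == 2
        assert p < 1e-6

    def test_wald_accepts_null(self):
        means = {a: {"pre": 1.0, "post": 1.5, "followup": 1.2} for a in
                 ("control", "intervention")}
        df = balanced_table(means, n=30, sd=1.0, seed=4)
        _, _, p = interaction_wald(fit_mixed_model(df, "y"))
        assert p > 0.05


class TestRemission:
    def test_marginal_or_matches_2x2_oracle(self):
        """Generating probabilities 0.02 vs 0.32 give a marginal OR near
        (0.32/0.68)/(0.02/0.98) ~ 23.1 at n=10000 per arm."""
        cfg = TrialConfig(n_per_arm=10000)
        tab = generate_trial(cfg, seed=19)
        or_, se_log = marginal_odds_ratio(tab, "post")
        oracle = (0.32 / 0.68) / (0.02 / 0.98)
        assert np.log(or_) == pytest.approx(np.log(oracle), abs=3 * se_log)
        assert abs(np.log(or_) - np.log(oracle)) < 0.25

    def test_null_probabilities_give_or_near_one(self):
        # moderate n: the random-effects design grows one column per
        # participant, so the mixed logistic is meant for trial-sized data
        cfg = TrialConfig(
            n_per_arm=400,
            remission_prob={
                "control": {"post": 0.2, "followup": 0.2},
                "intervention": {"post": 0.2, "followup": 0.2},
            },
        )
        tab = generate_trial(cfg, seed=23)
        fit = fit_remission_model(tab)
        assert fit.marginal.loc["post", "odds_ratio"] == pytest.approx(1.0, abs=0.45)
        assert fit.odds_ratios.loc["post", "odds_ratio"] == pytest.approx(1.0, abs=0.5)
        assert fit.marginal.loc["post", "pvalue"] > 0.05

    def test_mixed_logistic_direction_and_reproducibility(self, small_trial):
        fit1 = fit_remission_model(small_trial)
        fit2 = fit_remission_model(small_trial)
        pd.testing.assert_frame_equal(fit1.odds_ratios, fit2.odds_ratios)
        assert (fit1.odds_ratios["odds_ratio"] > 1).all()
        assert fit1.proportions.loc["intervention", "post"] > fit1.proportions.loc[
            "control", "post"
        ]

    def test_zero_cell_uses_continuity_correction(self):
        rows = []
        for arm, p in (("control", 0.0), ("intervention", 0.5)):
            for i in range(20):
                rows.append(
                    {
                        "participant_id": f"{arm}{i}",
                        "arm": arm,
                        "timepoint": "post",
                        "remission": float(i % 2 == 0) if p else 0.0,
                    }
                )
        or_, se = marginal_odds_ratio(pd.DataFrame(rows), "post")
        assert np.isfinite(or_) and or_ > 1
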