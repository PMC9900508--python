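"""Synthetic trial generator: structure, calibration convergence,
missingness mechanism and reproducibility."""

import numpy as np
import pandas as pd
import pytest

from trialcea import TrialConfig, TariffTable, apply_missingness, generate_trial
from trialcea.costing import cost_table
from trialcea.simulate import (
    DEFAULT_CATEGORY_MEANS_USD,
    rates_from_category_means,
    read_trial_csv,
    write_trial_csv,
)


class TestStructure:
    def test_default_dimensions(self, small_trial):
        # 47 per arm x 2 arms x 3 timepoints
        assert len(small_trial) == 282
        assert small_trial["participant_id"].nunique() == 94
        counts = small_trial.groupby("participant_id").size()
        assert (counts == 3).all()

    def test_remission_undefined_at_pre(self, small_trial):
        pre = small_trial[small_trial["timepoint"] == "pre"]
        assert pre["remission"].isna().all()
        rest = small_trial[small_trial["timepoint"] != "pre"]
        assert rest["remission"].notna().all()

    def test_resource_counts_nonnegative(self, small_trial):
        from trialcea.costing import RESOURCE_ITEMS

        assert (small_trial[list(RESOURCE_ITEMS)].to_numpy() >= 0).all()

    def test_unemployment_persistent_within_participant(self, small_trial):
        per_pid = small_trial.groupby("participant_id")["unemployed"].nunique()
        assert (per_pid == 1).all()


class TestReproducibility:
    def test_same_seed_identical(self, default_config):
        a = generate_trial(default_config, seed=11)
        b = generate_trial(default_config, seed=11)
        pd.testing.assert_frame_equal(a, b)

    def test_different_seed_differs(self, default_config):
        a = generate_trial(default_config, seed=11)
        b = generate_trial(default_config, seed=12)
        assert not a["eq5d_index"].equals(b["eq5d_index"])

    def test_missingness_reproducible(self, default_config, small_trial):
        a = apply_missingness(small_trial, default_config, seed=5)
        b = apply_missingness(small_trial, default_config, seed=5)
        pd.testing.assert_frame_equal(a, b)

    def test_csv_round_trip(self, tmp_path, small_trial_missing):
        p = tmp_path / "trial.csv"
        write_trial_csv(small_trial_missing, p)
        back = read_trial_csv(p)
        assert len(back) == len(small_trial_missing)
        assert back["eq5d_index"].isna().sum() == small_trial_missing[
            "eq5d_index"
        ].isna().sum()


class TestCalibrationConvergence:
    """Law-of-large-numbers checks against the generating parameters."""

    def test_remission_rates(self, big_trial):
        cfg = TrialConfig()
        for arm in ("control", "intervention"):
            for tp in ("post", "followup"):
                emp = big_trial[
                    (big_trial["arm"] == arm) & (big_trial["timepoint"] == tp)
                ]["remission"].mean()
                assert emp == pytest.approx(cfg.remission_prob[arm][tp], abs=0.01)

    def test_custom_remission_probability(self):
        cfg = TrialConfig(
            n_per_arm=10000,
            remission_prob={
                "control": {"post": 0.02, "followup": 0.09},
                "intervention": {"post": 0.32, "followup": 0.40},
            },
        )
        tab = generate_trial(cfg, seed=7)
        emp = tab[(tab["arm"] == "intervention") & (tab["timepoint"] == "post")][
            "remission"
        ].mean()
        assert emp == pytest.approx(0.32, abs=0.01)

    def test_utility_means(self, big_trial):
        cfg = TrialConfig()
        for arm in ("control", "intervention"):
            for tp in ("pre", "post", "followup"):
                emp = big_trial[
                    (big_trial["arm"] == arm) & (big_trial["timepoint"] == tp)
                ]["eq5d_index"].mean()
                assert emp == pytest.approx(cfg.utility_mean[arm][tp], abs=0.01)

    def test_societal_cost_cell_means_near_targets(self, big_trial):
        """Costing the generated resource use reproduces the per-cell
        category targets the rates were solved from."""
        tariff = TariffTable()
        costs = cost_table(big_trial, tariff)
        merged = costs.merge(
            big_trial[["participant_id", "timepoint", "unemployed"]],
            on=["participant_id", "timepoint"],
        )
        for (arm, tp), targets in DEFAULT_CATEGORY_MEANS_USD.items():
            cell = merged[(merged["arm"] == arm) & (merged["timepoint"] == tp)]
            hc = (cell["other_health_care"] + cell["medication"]).mean()
            indirect = (cell["sick_leave"] + cell["domestic_cutback"]).mean()
            assert hc == pytest.approx(targets["health_care_excl_clinic"], rel=0.05)
            assert indirect == pytest.approx(
                targets["indirect_excl_unemployment"], rel=0.05
            )

    def test_rates_solved_from_category_means_invert_the_tariff(self):
        tariff = TariffTable()
        rates = rates_from_category_means(DEFAULT_CATEGORY_MEANS_USD, tariff)
        cell = ("control", "pre")
        implied = sum(
            rates[item][cell] * tariff.usd_per_unit(item)
            for item in (
                "primary_care_visits",
                "specialist_visits",
                "psychiatric_visits",
                "medication_units",
            )
        )
        assert implied == pytest.approx(1517.0, rel=1e-9)


class TestMissingness:
    def test_all_complete_leaves_table_unchanged(self, small_trial):
        cfg = TrialConfig(
            completion_rate={
                inst: {
                    arm: {"post": 1.0, "followup": 1.0}
                    for arm in ("control", "intervention")
                }
                for inst in ("diagnostic", "eq5d", "ticp")
            }
        )
        out = apply_missingness(small_trial, cfg, seed=3)
        pd.testing.assert_frame_equal(out, small_trial)

    def test_pre_treatment_never_missing(self, small_trial_missing):
        pre = small_trial_missing[small_trial_missing["timepoint"] == "pre"]
        assert pre["eq5d_index"].notna().all()
        assert pre["sick_leave_days"].notna().all()

    def test_marginal_completion_rate_recovered(self):
        """85% follow-up diagnostic completion in the intervention arm."""
        cfg = TrialConfig(n_per_arm=10000)
        tab = apply_missingness(generate_trial(cfg, seed=21), cfg, seed=21)
        cell = tab[(tab["arm"] == "intervention") & (tab["timepoint"] == "followup")]
        assert cell["remission"].notna().mean() == pytest.approx(0.85, abs=0.01)

    def test_mar_mechanism(self):
        """Missingness correlates with baseline utility but, given
        baseline, carries no information about the unobserved value."""
        cfg = TrialConfig(n_per_arm=10000, mar_strength=-3.0)
        complete = generate_trial(cfg, seed=31)
        observed = apply_missingness(complete, cfg, seed=31)

        fu = observed[
            (observed["arm"] == "intervention") & (observed["timepoint"] == "followup")
        ].set_index("participant_id")
        miss = fu["eq5d_index"].isna().astype(float)
        base = (
            complete[complete["timepoint"] == "pre"]
            .set_index("participant_id")["eq5d_index"]
            .loc[fu.index]
        )
        truth = (
            complete[
                (complete["arm"] == "intervention")
                & (complete["timepoint"] == "followup")
            ]
            .set_index("participant_id")["eq5d_index"]
            .loc[fu.index]
        )

        r_base = np.corrcoef(miss, base)[0, 1]
        assert r_base < -0.05  # worse baseline health -> more dropout

        # conditional independence: partial association of missingness with
        # the true (unobserved) value, controlling for baseline, is ~0
        X = np.column_stack([np.ones(len(miss)), base, truth])
        beta = np.linalg.lstsq(X, miss.to_numpy(), rcond=None)[0]
        resid = miss.to_numpy() - X @ beta
        se = np.sqrt(
            np.linalg.inv(X.T @ X)[2, 2] * resid.var(ddof=3)
        )
        assert abs(beta[2]) < 3 * se

    def test_mcar_mode_ignores_baseline(self):
        cfg = TrialConfig(n_per_arm=5000, mar_strength=0.0)
        tab = apply_missingness(generate_trial(cfg, seed=41), cfg, seed=41)
        cell = tab[(tab["arm"] == "intervention") & (tab["timepoint"] == "followup")]
        assert cell["eq5d_index"].notna().mean() == pytest.approx(0.77, abs=0.02)


class TestValidation:
    @pytest.mark.parametrize(
        "kwargs",
        [
            {"n_per_arm": 0},
            {"unemployment_prob": 1.2},
            {"utility_sd": -0.1},
            {
                "remission_prob": {
                    "control": {"post": -0.1, "followup": 0.1},
                    "intervention": {"post": 0.3, "followup": 0.4},
                }
            },
            {
                "completion_rate": {
                    "eq5d": {"control": {"post": 1.4}},
                }
            },
        ],
    )
    def test_invalid_config_rejected(self, kwargs):
        with pytest.raises(ValueError):
            TrialConfig(**kwargs)

    def test_config_yaml_round_trip(self, tmp_path, default_config):
        p = tmp_path / "cfg.yaml"
        default_config.to_yaml(p)
        back = TrialConfig.from_yaml(p)
        assert back == default_config
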