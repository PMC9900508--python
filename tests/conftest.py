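import numpy as np
import pandas as pd
import pytest

from trialcea import TrialConfig, TariffTable, generate_trial, apply_missingness


@pytest.fixture(scope="session")
def default_config():
    return TrialConfig()


@pytest.fixture(scope="session")
def small_trial(default_config):
    """Complete default-calibrated trial, 47 per arm."""
    return generate_trial(default_config, seed=1)


@pytest.fixture(scope="session")
def small_trial_missing(default_config, small_trial):
    return apply_missingness(small_trial, default_config, seed=1)


@pytest.fixture(scope="session")
def big_trial():
    """Large trial for law-of-large-numbers checks."""
    return generate_trial(TrialConfig(n_per_arm=10000), seed=7)


@pytest.fixture(scope="session")
def tariff():
    return TariffTable()


def balanced_table(
    means: dict, *, n: int = 6, sd: float = 0.0, seed: int = 0
) -> pd.DataFrame:
    """Tiny balanced complete table with prescribed arm x timepoint means.

    With sd=0 the cell means are exact, giving a closed-form oracle for
    least-squares means and difference-in-differences contrasts.
    """
    rng = np.random.default_rng(seed)
    rows = []
    for arm, by_tp in means.items():
        for i in range(n):
            for tp, mu in by_tp.items():
                rows.append(
                    {
                        "participant_id": f"{arm}-{i}",
                        "arm": arm,
                        "timepoint": tp,
                        "y": mu + (rng.normal(0, sd) if sd else 0.0),
                    }
                )
    df = pd.DataFrame(rows)
    df["timepoint"] = pd.Categorical(
        df["timepoint"], categories=["pre", "post", "followup"], ordered=True
    )
    return df
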