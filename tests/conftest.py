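import numpy as np
import pandas as pd
import pytest

from acticohort import (
    ActivityProfile,
    DEFAULT_CONFIG,
    default_group_profiles,
)


@pytest.fixture(scope="session")
def config():
    return DEFAULT_CONFIG


@pytest.fixture(scope="session")
def group_profiles():
    return default_group_profiles()


@pytest.fixture()
def rng():
    return np.random.default_rng(2024)


def make_profile(**overrides) -> ActivityProfile:
    """A small, valid profile for targeted generator tests."""
    base = dict(
        name="test",
        state_fractions={"sleep_sedentary": 0.6, "light": 0.3,
                         "moderate": 0.09, "vigorous": 0.01},
        enmo_median_mg={"sleep_sedentary": 10.0, "light": 52.0,
                        "moderate": 190.0, "vigorous": 550.0},
        enmo_sigma={"sleep_sedentary": 0.4, "light": 0.3,
                    "moderate": 0.25, "vigorous": 0.2},
        bout_mean_min={"sleep_sedentary": 5.0, "light": 3.0,
                       "moderate": 2.0, "vigorous": 1.0},
        nonwear_schedule=(),
    )
    base.update(overrides)
    return ActivityProfile(**base)


def make_epochs(wear_flags, enmo=None, start="2023-01-02", epoch_s=60):
    """Build an epoch DataFrame directly (bypassing the signal chain)."""
    n = len(wear_flags)
    starts = pd.Timestamp(start) + pd.to_timedelta(np.arange(n) * epoch_s, unit="s")
    return pd.DataFrame(
        {
            "epoch_start": starts,
            "enmo_mg": np.zeros(n) if enmo is None else np.asarray(enmo, float),
            "wear": np.asarray(wear_flags, bool),
        }
    )
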