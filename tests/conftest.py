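import warnings

import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

import cortexeval as ce

settings.register_profile(
    "ci", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("ci")

warnings.filterwarnings("ignore", category=FutureWarning)


@pytest.fixture(scope="session")
def small_longitudinal():
    """A small three-group longitudinal cohort shared across tests."""
    cfg = ce.adni_like_config(seed=101, group_sizes={"CN": 25, "LMCI": 30, "AD": 20},
                              n_sites=5)
    subjects, visits = ce.generate_longitudinal(cfg)
    return cfg, subjects, visits


@pytest.fixture(scope="session")
def region_series(small_longitudinal):
    """One region of the small cohort in long (subject, time, y) form."""
    _, _, visits = small_longitudinal
    return pd.DataFrame({
        "subject_id": visits["subject_id"],
        "visit_time_months": visits["visit_time_months"],
        "y": visits["lh_ENT"],
    })
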