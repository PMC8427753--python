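import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def published_counts():
    """The 2x2 outcome-by-collateral counts of the source 108-patient
    cohort: (tp, fn, fp, tn) with positive test = good collaterals and
    positive state = favorable 90-day outcome."""
    return dict(tp=28, fn=9, fp=8, tn=63)


@pytest.fixture(scope="session")
def reconstructed_cohort(published_counts):
    """Patient-level 108-row table reconstructed from the published 2x2
    counts (good-collateral indicator x favorable-outcome indicator)."""
    c = published_counts
    rows = []
    for good, fav, n in [(True, True, c["tp"]), (True, False, c["fp"]),
                         (False, True, c["fn"]), (False, False, c["tn"])]:
        rows += [{"good_collateral": good, "mrs_90": 1 if fav else 4}] * n
    df = pd.DataFrame(rows)
    df["patient_id"] = [f"P{i:03d}" for i in range(len(df))]
    return df


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20210826)
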