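import numpy as np
import pandas as pd
import pytest
from hypothesis import settings, HealthCheck

settings.register_profile(
    "repro",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("repro")

from mmplocus import ExpressionMatrix, OutcomeTable


@pytest.fixture
def rng():
    return np.random.default_rng(20230919)


@pytest.fixture
def small_counts():
    """3 genes x 4 samples raw counts with one non-detected zero."""
    df = pd.DataFrame(
        {
            "s1": [3.0, 0.0, 15.0],
            "s2": [7.0, 2.0, 15.0],
            "s3": [15.0, 5.0, 15.0],
            "s4": [1.0, 4.0, 15.0],
        },
        index=["gA", "gB", "gC"],
    )
    return ExpressionMatrix(df)


def make_outcomes(times, events, ids=None):
    ids = ids or [f"s{i}" for i in range(len(times))]
    return OutcomeTable(ids, np.asarray(times, float), np.asarray(events, bool))


@pytest.fixture
def outcome_factory():
    return make_outcomes
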