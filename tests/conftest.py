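import numpy as np
import pandas as pd
import pytest

from triageshift import DEFAULT_SCHEMA, SiteProfile, generate_cohort


@pytest.fixture(scope="session")
def schema():
    return DEFAULT_SCHEMA


@pytest.fixture(scope="session")
def base_profile():
    """A mid-size single site with defaults: moderate separation, no shift."""
    return SiteProfile("demo", 2000, 0.25)


@pytest.fixture(scope="session")
def base_cohort(base_profile):
    return generate_cohort(base_profile, seed=42)


def toy_cohort(values: dict, labels=None, site="toy") -> pd.DataFrame:
    """Small hand-built cohort table from per-column value lists."""
    n = len(next(iter(values.values())))
    frame = pd.DataFrame(values)
    if "label" not in frame.columns:
        frame["label"] = labels if labels is not None else np.zeros(n, dtype=int)
    if "site_id" not in frame.columns:
        frame["site_id"] = site
    if "timestamp" not in frame.columns:
        frame["timestamp"] = pd.date_range("2021-01-01", periods=n, freq="h")
    if "age" not in frame.columns:
        frame["age"] = 50
    return frame
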