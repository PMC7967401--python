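import numpy as np
import pandas as pd
import pytest

from dermtrends.gt_io import TopicSeries
from dermtrends.registry import default_registry

STUDY_MONTHS = pd.period_range("2004-01", "2019-12", freq="M")


@pytest.fixture(scope="session")
def registry():
    return default_registry()


@pytest.fixture(scope="session")
def months():
    return STUDY_MONTHS


def make_series(values, topic_id="topic", start="2004-01", imputed=True, region="world"):
    """Build a TopicSeries from plain values for tests."""
    values = np.asarray(values, dtype=float if imputed else object)
    idx = pd.period_range(start, periods=len(values), freq="M")
    return TopicSeries(topic_id=topic_id, region=region, months=idx, values=values, imputed=imputed)


@pytest.fixture
def make_imputed():
    return make_series
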