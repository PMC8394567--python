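import datetime as dt

import numpy as np
import pandas as pd
import pytest


@pytest.fixture
def fix_csv(tmp_path):
    """Write a fix table CSV and return its path."""

    def _write(rows, columns=("animal_id", "timestamp", "lat", "lon"), name="fixes.csv"):
        path = tmp_path / name
        pd.DataFrame(rows, columns=list(columns)).to_csv(path, index=False)
        return path

    return _write


@pytest.fixture
def full_year_daily():
    """Gap-free daily table for one animal covering 2016-07-01..2017-06-30."""
    start = dt.date(2016, 7, 1)
    n = (dt.date(2017, 6, 30) - start).days + 1
    return pd.DataFrame(
        {
            "animal_id": "d1",
            "date": [start + dt.timedelta(days=i) for i in range(n)],
            "lat": 40.0,
            "lon": -111.0,
            "n_fixes": 1,
        }
    )


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
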