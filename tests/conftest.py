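import numpy as np
import pandas as pd
import pytest

from ckdcra.synthetic_data import (
    SURVEY_COLUMNS,
    default_config,
    generate_census,
    generate_cohort,
)
from ckdcra.risk_model import builtin_specs

_ROW_DEFAULTS = {
    "age": 30,
    "sex": "male",
    "residence": "urban",
    "province": "province_1",
    "education": "primary",
    "occupation": "occ_1",
    "sbp": 120.0,
    "dbp": 80.0,
    "bmi": 22.0,
    "smoking": "never",
    "tg": np.nan,
    "hdl": np.nan,
    "glucose": np.nan,
}


@pytest.fixture(scope="session")
def cfg():
    """Calibrated default cohort configuration at a test-sized n."""
    return default_config(n_individuals=4000, seed=7)


@pytest.fixture(scope="session")
def cohort(cfg):
    return generate_cohort(cfg)


@pytest.fixture(scope="session")
def census():
    return generate_census()


@pytest.fixture(scope="session")
def specs():
    return builtin_specs()


@pytest.fixture
def make_survey():
    """Build a survey frame from partial row dicts, filling sensible defaults."""

    def build(rows):
        full = []
        for i, row in enumerate(rows):
            r = dict(_ROW_DEFAULTS)
            r.setdefault("id", i + 1)
            r.setdefault("wave", 2011)
            r.update(row)
            full.append(r)
        return pd.DataFrame(full)[SURVEY_COLUMNS]

    return build


@pytest.fixture
def make_census():
    """Build a census table from {StratumKey: count}."""

    def build(counts):
        rows = [
            {
                "age_group": s.age_group,
                "sex": s.sex,
                "residence": s.residence,
                "count": c,
            }
            for s, c in counts.items()
        ]
        return pd.DataFrame(rows)

    return build
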