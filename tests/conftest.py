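import numpy as np
import pandas as pd
import pytest

from ciaspipe import NormTable, NormativeBand, SubtestNorm
from ciaspipe.norms import SUBTESTS


def make_band(age_lo=18, age_hi=34, mean=10.0, sd=2.0, direction=+1):
    """A band with identical norms for every subtest (convenient for hand checks)."""
    return NormativeBand(
        age_lo,
        age_hi,
        {st: SubtestNorm(mean=mean, sd=sd, direction=direction) for st in SUBTESTS},
    )


@pytest.fixture
def simple_band():
    return make_band()


@pytest.fixture
def simple_table():
    return NormTable(
        [
            make_band(18, 34),
            make_band(35, 49),
            make_band(50, 59),
            make_band(60, 69),
        ]
    )


def make_long_row(pid, visit, *, arm="active", site="S01", age=30, sex="male",
                  panss=96.0, z=None, missing=()):
    """One long-format row whose raw scores map to the requested z under the
    simple_table norms (mean 10, sd 2, direction +1)."""
    z = dict(z or {})
    row = {
        "patient_id": pid,
        "arm": arm,
        "site": site,
        "age": age,
        "sex": sex,
        "visit": visit,
        "panss_total": panss,
        "panss_pos": 26.0,
        "panss_neg": 22.0,
    }
    for st in SUBTESTS:
        row[st] = np.nan if st in missing else 10.0 + 2.0 * z.get(st, 0.0)
    return row


def make_long_frame(rows):
    return pd.DataFrame(rows)
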