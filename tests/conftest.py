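import numpy as np
import pandas as pd
import pytest

from stripscreen import SimulationConfig
from stripscreen.colorimetry import COMBINED_RGB_COLUMN, FEATURE_SCHEMA


@pytest.fixture
def tiny_config():
    """Small, fast cohort for pipeline-level tests."""
    return SimulationConfig(n_participants=30, strip_rows=8, strip_cols=8, seed=13)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def make_participants(rows):
    """Build a participants table from (id, enroll, deliver, pe, pih, iugr,
    ev_pe, ev_pih, ev_iugr) tuples."""
    cols = ["id", "enrollment_week", "delivery_week", "pe", "pih", "iugr",
            "event_week_pe", "event_week_pih", "event_week_iugr"]
    return pd.DataFrame(rows, columns=cols)


def make_features(entries, value=100.0):
    """Feature table stub: one row per (participant_id, week), every feature
    column set to a constant (or per-entry dict overrides)."""
    rows = []
    for e in entries:
        pid, week = e[0], e[1]
        overrides = e[2] if len(e) > 2 else {}
        row = {"participant_id": pid, "week": week}
        for c in (*FEATURE_SCHEMA, COMBINED_RGB_COLUMN):
            row[c] = overrides.get(c, value)
        rows.append(row)
    return pd.DataFrame(rows)
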