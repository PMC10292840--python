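import numpy as np
import pandas as pd
import pytest

from agemeta import from_dataframe


def make_frame(rows):
    """Schema frame from compact (record, study, r, var_r, n, year) tuples."""
    base = []
    for rid, sid, r, var_r, n, year in rows:
        base.append({
            "record_id": rid, "study_id": sid, "estimate_id": rid,
            "preference": "risk", "r": r, "var_r": var_r, "n": n, "year": year,
            "metric": "pearson", "design": "continuous",
            "age_span_decades": 4.0, "prop_female": np.nan,
            "incentivized": "missing", "task_type": "missing",
            "domain": "missing", "context": "missing",
            "effort_type": "missing", "citations_per_year": np.nan,
        })
    return pd.DataFrame(base)


@pytest.fixture
def small_dataset():
    """The 8-record / 3-study fixture with known (independently computed)
    three-level REML results."""
    y = [-0.30, -0.10, 0.05, 0.20, 0.25, 0.10, -0.05, 0.15]
    v = [0.010, 0.012, 0.020, 0.008, 0.015, 0.025, 0.018, 0.009]
    study = ["s1", "s1", "s1", "s2", "s2", "s3", "s3", "s3"]
    x = [2.0, 3.5, 5.0, 4.0, 4.5, 3.0, 2.5, 5.5]
    years = [2000, 2000, 2000, 2005, 2005, 2010, 2010, 2010]
    df = make_frame([
        (f"e{i}", study[i], y[i], v[i], 100, years[i]) for i in range(8)
    ])
    df["age_span_decades"] = x
    return from_dataframe(df)


@pytest.fixture
def dataset_factory():
    """Build a validated dataset from (record, study, r, var_r, n, year) rows."""
    def build(rows, **col_overrides):
        df = make_frame(rows)
        for col, vals in col_overrides.items():
            df[col] = vals
        return from_dataframe(df)

    return build
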