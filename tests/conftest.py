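import warnings

import numpy as np
import pandas as pd
import pytest

from pjindex import (
    Cohort,
    CohortSpec,
    EMRTable,
    SimSpec,
    TwoByTwo,
    build_cohort,
    generate_cohort,
)


def make_emr_frame(rows):
    """Rows as (sid, sex, birth, visit, vtype, code) tuples -> raw frame."""
    return pd.DataFrame(
        rows,
        columns=["subject_id", "sex", "birth_date", "visit_date", "visit_type", "icd9_code"],
    )


@pytest.fixture
def tiny_emr() -> EMRTable:
    rows = [
        ("A", "F", "1950-01-01", "2011-09-01", "outpatient", "2500"),
        ("A", "F", "1950-01-01", "2011-10-01", "inpatient", "4140"),
        ("A", "F", "1950-01-01", "2012-01-15", "emergency", "4280"),
        ("B", "M", "1960-05-05", "2011-11-01", "outpatient", "4280"),
        ("B", "M", "1960-05-05", "2011-12-01", "outpatient", "2500"),
        ("C", "F", "1951-03-03", "2011-08-01", "outpatient", "2500"),
        ("C", "F", "1951-03-03", "2011-12-20", "inpatient", "V720"),
        ("D", "M", "1961-07-07", "2011-06-01", "outpatient", "4140"),
        ("E", "F", "1949-09-09", "2010-01-01", "outpatient", "2500"),
    ]
    return EMRTable(make_emr_frame(rows))


def manual_cohort(case_codes, control_codes, spec=None) -> Cohort:
    """Build a Cohort directly from per-subject code collections."""
    idx = pd.Timestamp("2012-07-01")
    rows, codes = [], {}
    for i, cs in enumerate(case_codes):
        sid = f"case{i:04d}"
        rows.append({"subject_id": sid, "label": "case", "index_date": idx,
                     "sex": "F" if i % 2 else "M",
                     "birth_date": idx - pd.Timedelta(days=int(365.25 * (50 + i % 40)))})
        codes[sid] = frozenset(cs)
    for i, cs in enumerate(control_codes):
        sid = f"ctrl{i:04d}"
        rows.append({"subject_id": sid, "label": "control", "index_date": idx,
                     "sex": "F" if i % 2 else "M",
                     "birth_date": idx - pd.Timedelta(days=int(365.25 * (50 + i % 40)))})
        codes[sid] = frozenset(cs)
    return Cohort(pd.DataFrame(rows), codes, spec or CohortSpec())


@pytest.fixture
def table1_cohort() -> Cohort:
    """200-subject cohort reproducing the worked 2x2 example: 100 cases of
    which 20 carry DA and 40 carry DB; 100 controls with 2 and 6 carriers."""
    case_codes = [
        {"514"} | ({"427"} if i < 40 else set()) if i < 20
        else {"427"} if i < 40
        else {"250"}
        for i in range(100)
    ]
    control_codes = [
        {"514"} if i < 2 else {"427"} if i < 8 else {"250"} for i in range(100)
    ]
    return manual_cohort(case_codes, control_codes)


@pytest.fixture(scope="session")
def small_sim():
    """Shared desk-scale simulated cohort: 800 cases / 2000 controls."""
    spec = SimSpec(n_cases=800, n_controls=2000, seed=42)
    emr, truth = generate_cohort(spec)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        cohort = build_cohort(emr, CohortSpec(), control_ratio=2.5,
                              match_on="none", seed=42)
    return spec, emr, truth, cohort


def random_table(rng: np.random.Generator, positive: bool = True) -> TwoByTwo:
    lo = 1 if positive else 0
    return TwoByTwo(*(int(rng.integers(lo, 500)) for _ in range(4)))
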