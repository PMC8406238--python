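"""Shared fixtures: small synthetic cohorts generated at test time."""
from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from fmtrack import simulate
from fmtrack.tables import FeatureTable, SampleMetadata


@pytest.fixture(scope="session")
def clean_cohort():
    """Zero-count-noise cohort: presence is deterministic, truth recoverable."""
    return simulate.simulate_cohort(seed=42, multinomial=False)


@pytest.fixture(scope="session")
def noisy_cohort():
    """Default cohort with multinomial read sampling."""
    return simulate.simulate_cohort(seed=42)


@pytest.fixture()
def tiny_table():
    return FeatureTable(
        pd.DataFrame(
            [[3.0, 0.0, 1.0], [1.0, 2.0, 0.0]],
            index=["s1", "s2"],
            columns=["f1", "f2", "f3"],
        )
    )


def make_metadata(rows):
    """rows: (sample_id, subject, role, arm, day, phase, donors)."""
    df = pd.DataFrame(
        rows,
        columns=["sample_id", "subject_id", "role", "arm", "day", "phase",
                 "assigned_donor_ids"],
    ).set_index("sample_id")
    return SampleMetadata(df)


@pytest.fixture()
def mini_patient_metadata():
    """One patient with baseline/antibiotics/treatment/follow-up, one donor."""
    rows = [
        ("d0", "D1", "donor", "donor", -14, "baseline", ()),
        ("d1", "D1", "donor", "donor", 28, "capsule", ()),
        ("b0", "P1", "patient", "fmt", -28, "baseline", ("D1",)),
        ("b1", "P1", "patient", "fmt", -21, "baseline", ("D1",)),
        ("a0", "P1", "patient", "fmt", -7, "antibiotics", ("D1",)),
        ("t0", "P1", "patient", "fmt", 0, "induction", ("D1",)),
        ("t1", "P1", "patient", "fmt", 7, "induction", ("D1",)),
        ("t2", "P1", "patient", "fmt", 21, "capsule", ("D1",)),
        ("f0", "P1", "patient", "fmt", 126, "followup", ("D1",)),
    ]
    return make_metadata(rows)
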