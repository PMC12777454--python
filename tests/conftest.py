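"""Shared fixtures: all test data is generated programmatically."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from sczrec.arms import TREATMENT_ARMS
from sczrec.cohort import apply_inclusion_criteria, assemble_consultations, feature_columns
from sczrec.simulate import CohortSpec, generate


def consultations_from_spec(spec: CohortSpec) -> pd.DataFrame:
    patients, visits, rx, _ = generate(spec)
    clean, capped, log = apply_inclusion_criteria(patients, visits)
    return assemble_consultations(clean, capped, rx, log)


@pytest.fixture(scope="session")
def small_cohort() -> pd.DataFrame:
    """~120-patient synthetic cohort with planted structure."""
    return consultations_from_spec(CohortSpec(n_patients=120, seed=7))


@pytest.fixture(scope="session")
def raw_tables():
    """Raw generated tables plus the same cohort cleaned, for ingestion tests."""
    spec = CohortSpec(n_patients=60, seed=3)
    patients, visits, rx, truth = generate(spec)
    return patients, visits, rx, truth, spec


def make_consultation_row(
    patient_id: str = "P1",
    visit_index: int = 1,
    drug: str = "risperidone",
    gender: str = "M",
    ethnicity: str = "White",
    age: float = 30.0,
    comorbidity: float = 1.0,
    los: float = 5.0,
    visit_count: int = 1,
    switch_count: int = 0,
    inter_admission: float = np.nan,
    inter_switch: float = np.nan,
    **extra,
) -> dict:
    """A hand-built consultation row with every schema column present."""
    row = {
        "patient_id": patient_id,
        "visit_index": visit_index,
        "admit_time": pd.Timestamp("2020-01-01"),
        "drug": drug,
        "gender": gender,
        "ethnicity": ethnicity,
        "age": age,
        "comorbidity_count": comorbidity,
        "util_inter_admission_days": inter_admission,
        "util_inter_switch_days": inter_switch,
        "util_los_days": los,
        "util_visit_count": visit_count,
        "util_switch_count": switch_count,
    }
    for col in feature_columns(3):
        row.setdefault(col, np.nan)
    row.update(extra)
    return row


def clone_group_cohort(
    n_groups: int = 8,
    clones_per_group: int = 15,
    drug: str = "risperidone",
) -> pd.DataFrame:
    """Groups of feature-identical single-visit patients.

    Within a group every patient shares the feature signature and the raw
    utilisation profile (hence the observed affinity); across groups both
    differ, so the nearest neighbours of any patient are its clones and
    anything beyond them is noise.
    """
    rows = []
    i = 0
    for g in range(n_groups):
        for _ in range(clones_per_group):
            rows.append(
                make_consultation_row(
                    patient_id=f"G{g}_{i}",
                    drug=drug,
                    gender="M" if g % 2 == 0 else "F",
                    ethnicity="White",
                    age=20.0 + 2.5 * g,
                    comorbidity=float(3 * g),
                    los=1.0 + 4.0 * g,
                )
            )
            i += 1
    return pd.DataFrame(rows)


ALL_ARMS = TREATMENT_ARMS
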