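"""Shared fixtures: small constructed cohorts with hand-counted expectations."""

import numpy as np
import pandas as pd
import pytest

from drugrec import PreprocessConfig
from drugrec.schema import DRUG_COLUMNS

RACES = ["Caucasian", "AfricanAmerican", "Asian", "Hispanic", "Other"]
AGES = [f"[{10*i}-{10*(i+1)})" for i in range(10)]
DIAGS = ["428", "486", "250.01", "584", "715", "153", "812", "V45", "272", "531"]


def _base_row(i: int) -> dict:
    """Deterministic filler values for row *i* (varied, never imbalanced)."""
    return {
        "encounter_id": 1000 + i,
        "patient_nbr": None,  # set by caller
        "race": RACES[i % 5],
        "gender": "Female" if i % 2 == 0 else "Male",
        "age": AGES[i % 10],
        "weight": "?",
        "medical_specialty": "?",
        "admission_type_id": 1,
        "discharge_disposition_id": 1 if i % 2 == 0 else 2,
        "time_in_hospital": (i % 14) + 1,
        "diag_1": DIAGS[i % 10],
        "max_glu_serum": "None" if i % 5 else "Norm",
        "a1cresult": "None" if i % 4 else ">7",
        "change": "No",
        "diabetesmed": "No",
        "readmitted": ["NO", ">30", "<30"][i % 3],
        "insulin": "No",
        "metformin": "No",
        "glipizide": "No",
        "nateglinide": "No",
    }


@pytest.fixture
def preprocess_fixture():
    """A 50-row encounter table with fully hand-counted expectations.

    Construction plan (45 unique patients 1..45, plus duplicate encounters
    for patients 1..5):

    * patients 1-15: insulin Up + metformin Steady (2 drugs, dose changed)
    * patients 16-25: insulin Steady + glipizide Steady (2 drugs, no change)
    * patients 26-35: insulin Steady only (1 drug -> dropped at min=2)
    * patients 36-45: no drugs at all (dropped)
    * duplicates of patients 1-5 carry NO drugs, so keeping anything but the
      first encounter would demote those patients below the filter
    * weight is present for patient 1 only (24/25 = 96% missing among the
      25 survivors); medical_specialty is present for 10 of the survivors
      (60% missing); admission_type_id is 3 for patient 2 and 1 elsewhere
      (96% constant); nateglinide is never administered
    * diabetesmed is "Yes" for every survivor, hence 100% constant
    """
    rows = []
    for p in range(1, 46):
        row = _base_row(p)
        row["patient_nbr"] = p
        if p <= 15:
            row.update(insulin="Up", metformin="Steady", change="Ch", diabetesmed="Yes")
        elif p <= 25:
            row.update(insulin="Steady", glipizide="Steady", diabetesmed="Yes")
        elif p <= 35:
            row.update(insulin="Steady", diabetesmed="Yes")
        if p == 1:
            row["weight"] = "[75-100)"
        if p == 2:
            row["admission_type_id"] = 3
        if p == 3:
            row["race"] = "?"
        if p <= 25 and p % 5 in (1, 2):  # 10 of the 25 survivors
            row["medical_specialty"] = "InternalMedicine"
        rows.append(row)
    for p in range(1, 6):  # drug-free duplicate encounters, later in file order
        row = _base_row(45 + p)
        row["patient_nbr"] = p
        rows.append(row)
    df = pd.DataFrame(rows)
    df["race"] = df["race"].replace("?", np.nan)
    df["weight"] = df["weight"].replace("?", np.nan)
    df["medical_specialty"] = df["medical_specialty"].replace("?", np.nan)

    expected = {
        "n_rows": 25,
        "feature_columns": 8 + 5 + 9,  # scalars + race one-hots + diag one-hots
        "drug_columns": ["metformin", "glipizide", "insulin"],  # canonical order
        "drop_reasons": {
            "encounter_id": "identifier",
            "patient_nbr": "identifier",
            "weight": "missingness",
            "medical_specialty": "missingness",
            "admission_type_id": "imbalance",
            "diabetesmed": "imbalance",
            "nateglinide": "low_prevalence",
            "race": "replaced_by_indicator",
            "diag_1": "replaced_by_indicator",
        },
    }
    config = PreprocessConfig(explicit_drop=("encounter_id", "patient_nbr"))
    return df, config, expected


@pytest.fixture
def tiny_raw_csv(tmp_path):
    """Three-row raw CSV (one '?' race) in the hospital-export dialect."""
    header = "encounter_id,patient_nbr,race,gender,age,insulin,metformin,time_in_hospital"
    lines = [
        header,
        "1,101,Caucasian,Female,[50-60),Up,No,3",
        "2,102,?,Male,[60-70),Steady,Down,5",
        "3,103,AfricanAmerican,Female,[40-50),No,Up,1",
    ]
    path = tmp_path / "raw.csv"
    path.write_text("\n".join(lines) + "\n")
    return path
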