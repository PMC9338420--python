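"""Reading and writing encounter tables in the 130-US-hospitals CSV dialect.

The raw data are hospital-encounter rows: demographics, admission metadata,
utilisation counts, ICD-9 diagnosis codes, two lab-result summaries, and one
column per anti-diabetic medication holding a dose-change token
(``No``/``Down``/``Steady``/``Up``).  This module normalises that dialect into
a pandas DataFrame with canonical lower-case column names, a uniform missing
sentinel (NaN; the raw marker ``?`` and empty strings never survive parsing),
and validated numeric/token columns.  It also provides lossless CSV round
trips for the processed per-patient feature table and the patients x drugs
rating matrix.
"""

from __future__ import annotations

import os
import tempfile

import numpy as np
import pandas as pd

from .errors import RowParseError, SchemaError

#: Medication columns of the raw schema (canonical lower-case names).
DRUG_COLUMNS: tuple[str, ...] = (
    "metformin",
    "repaglinide",
    "nateglinide",
    "chlorpropamide",
    "glimepiride",
    "acetohexamide",
    "glipizide",
    "glyburide",
    "tolbutamide",
    "pioglitazone",
    "rosiglitazone",
    "acarbose",
    "miglitol",
    "troglitazone",
    "tolazamide",
    "examide",
    "citoglipton",
    "insulin",
    "glyburide-metformin",
    "glipizide-metformin",
    "glimepiride-pioglitazone",
    "metformin-rosiglitazone",
    "metformin-pioglitazone",
)

#: Dose-change tokens, in increasing dose-intensity order of the encoding.
DOSE_TOKENS: tuple[str, ...] = ("No", "Down", "Steady", "Up")

#: Columns that must parse as integers when present.
INTEGER_COLUMNS: tuple[str, ...] = (
    "admission_type_id",
    "discharge_disposition_id",
    "admission_source_id",
    "time_in_hospital",
    "num_lab_procedures",
    "num_procedures",
    "num_medications",
    "number_outpatient",
    "number_emergency",
    "number_inpatient",
    "number_diagnoses",
)

#: Race categories used for one-hot encoding downstream.
RACE_CATEGORIES: tuple[str, ...] = (
    "AfricanAmerican",
    "Asian",
    "Caucasian",
    "Hispanic",
    "Other",
)

MISSING_MARKERS = ("?", "")

_TOKEN_LOOKUP = {t.lower(): t for t in DOSE_TOKENS}


def _canon(name: str) -> str:
    return name.strip().lower()


def drug_columns_of(df: pd.DataFrame) -> list[str]:
    """Drug columns present in *df*, in canonical order."""
    return [c for c in DRUG_COLUMNS if c in df.columns]


def read_encounters(path, **csv_kwargs) -> pd.DataFrame:
    """Read a raw encounter CSV into a normalised DataFrame.

    Column names are matched case-insensitively after stripping whitespace;
    ``?`` and empty strings become NaN; dose tokens are normalised to the
    canonical ``No``/``Down``/``Steady``/``Up`` spelling; integer columns are
    validated.  Row order is preserved; unknown extra columns are retained.

    Raises
    ------
    SchemaError
        if ``patient_nbr`` or every drug column is absent.
    RowParseError
        if a numeric field or dose token cannot be parsed; names the
        0-based data-row index.
    """
    df = pd.read_csv(
        path,
        dtype=str,
        na_values=list(MISSING_MARKERS),
        keep_default_na=False,
        skipinitialspace=True,
        **csv_kwargs,
    )
    df.columns = [_canon(c) for c in df.columns]
    if df.columns.duplicated().any():
        dupes = df.columns[df.columns.duplicated()].tolist()
        raise SchemaError(f"duplicate columns after normalisation: {dupes}")

    missing = []
    if "patient_nbr" not in df.columns:
        missing.append("patient_nbr")
    drugs = drug_columns_of(df)
    if not drugs:
        missing.append(f"at least one drug column of {DRUG_COLUMNS[:3]}...")
    if missing:
        raise SchemaError(f"mandatory columns missing: {missing}")

    for col in drugs:
        df[col] = _normalise_tokens(df[col], col)

    for col in INTEGER_COLUMNS:
        if col in df.columns:
            parsed = pd.to_numeric(df[col], errors="coerce")
            bad = parsed.isna() & df[col].notna()
            if bad.any():
                row = int(np.flatnonzero(bad.to_numpy())[0])
                raise RowParseError(
                    f"unparseable integer in column '{col}': {df[col].iloc[row]!r}",
                    row,
                )
            df[col] = parsed.astype("Int64")
    return df


def _normalise_tokens(series: pd.Series, col: str) -> pd.Series:
    def norm(v):
        if pd.isna(v):
            return np.nan
        t = _TOKEN_LOOKUP.get(str(v).strip().lower())
        if t is None:
            raise SchemaError(f"unknown dose token {v!r} in column '{col}'")
        return t

    return series.map(norm)


def _atomic_to_csv(df: pd.DataFrame, path, **kwargs) -> None:
    """Write via a temp file + rename so no partial file is left behind."""
    directory = os.path.dirname(os.fspath(path)) or "."
    fd, tmp = tempfile.mkstemp(dir=directory, suffix=".csv.part")
    try:
        with os.fdopen(fd, "w", newline="") as fh:
            df.to_csv(fh, **kwargs)
        os.replace(tmp, path)
    except BaseException:
        if os.path.exists(tmp):
            os.unlink(tmp)
        raise


def write_feature_table(table: pd.DataFrame, path) -> None:
    """Write a per-patient numeric feature table as CSV.

    The patient identifier (the index) becomes the first column.  The round
    trip through :func:`read_feature_table` is lossless, including column
    names and patient identifiers.
    """
    if pd.Index(table.columns).duplicated().any():
        raise SchemaError("duplicate column names in feature table")
    out = table.copy()
    out.index.name = out.index.name or "patient_id"
    _atomic_to_csv(out, path, index=True)


def read_feature_table(path) -> pd.DataFrame:
    df = pd.read_csv(path, index_col=0)
    if pd.Index(df.columns).duplicated().any():
        raise SchemaError("duplicate column names in feature table file")
    return df
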