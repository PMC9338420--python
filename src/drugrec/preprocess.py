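"""Cleaning, transformation and variable selection for encounter data.

The pipeline turns raw hospital-encounter rows into a numeric per-patient
table: one row per unique patient (first encounter kept), patients on fewer
than ``min_medications`` drugs removed, noisy columns dropped (identifiers,
high missingness, near-constant value, rarely administered drugs), and every
remaining column made numeric — age brackets replaced by their midpoints,
yes/no flags binarised, race and first-diagnosis category one-hot encoded,
and each medication's dose-change token mapped onto the ordinal scale
0 = not administered, 1 = decreased, 2 = increased (``Steady`` configurable,
default 1).

Diagnosis strings are ICD-9 codes; the primary diagnosis is grouped into
nine disease categories by the code's three-digit prefix using the grouping
conventional for this data set (circulatory 390-459 & 785, respiratory
460-519 & 786, digestive 520-579 & 787, diabetes 250.xx, injury 800-999,
musculoskeletal 710-739, genitourinary 580-629 & 788, neoplasms 140-239,
everything else -- including V/E codes and missing -- "other").
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

from .errors import ConfigError, SchemaError
from .schema import DOSE_TOKENS, RACE_CATEGORIES, drug_columns_of

DIAGNOSIS_GROUPS: tuple[str, ...] = (
    "circulatory",
    "diabetes",
    "digestive",
    "genitourinary",
    "injury",
    "musculoskeletal",
    "neoplasms",
    "respiratory",
    "other",
)

# (low, high, extra singleton prefix) -> group; checked in order.
_ICD9_RANGES = (
    ("circulatory", 390, 459, 785),
    ("respiratory", 460, 519, 786),
    ("digestive", 520, 579, 787),
    ("genitourinary", 580, 629, 788),
    ("musculoskeletal", 710, 739, None),
    ("neoplasms", 140, 239, None),
    ("injury", 800, 999, None),
)

DEFAULT_DOSE_ENCODING: Mapping[str, float] = {
    "No": 0.0,
    "Down": 1.0,
    "Steady": 1.0,
    "Up": 2.0,
}

DEFAULT_READMITTED_ENCODING: Mapping[str, float] = {"NO": 0.0, ">30": 1.0, "<30": 2.0}

_AGE_RE = re.compile(r"^\[(\d+)-(\d+)\)$")


@dataclass
class PreprocessConfig:
    """Knobs of the cleaning pipeline.

    missingness_threshold : drop a column when its missing fraction exceeds
        this (default 0.50).
    imbalance_threshold : drop a non-drug column when a single value covers
        more than this fraction of rows (default 0.95).
    min_drug_prevalence : drop a drug column administered (token != No) to
        fewer than this fraction of patients (default 0.005, i.e. 0.5%).
    min_medications : keep only patients on at least this many drugs
        (default 2).
    explicit_drop : identifier/free-text columns removed outright.
    dose_encoding : token -> rating; must map No to 0 and be monotone
        No <= Down <= Up.
    """

    missingness_threshold: float = 0.50
    imbalance_threshold: float = 0.95
    min_drug_prevalence: float = 0.005
    min_medications: int = 2
    explicit_drop: tuple[str, ...] = (
        "encounter_id",
        "patient_nbr",
        "payer_code",
        "weight",
        "medical_specialty",
    )
    dose_encoding: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_DOSE_ENCODING)
    )
    readmitted_encoding: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_READMITTED_ENCODING)
    )

    def __post_init__(self):
        if not 0 < self.missingness_threshold <= 1:
            raise ConfigError("missingness_threshold must be in (0, 1]")
        if not 0 < self.imbalance_threshold <= 1:
            raise ConfigError("imbalance_threshold must be in (0, 1]")
        if not 0 <= self.min_drug_prevalence <= 1:
            raise ConfigError("min_drug_prevalence must be in [0, 1]")
        if self.min_medications < 0:
            raise ConfigError("min_medications must be >= 0")
        enc = self.dose_encoding
        if set(enc) != set(DOSE_TOKENS):
            raise ConfigError(f"dose_encoding must map exactly {DOSE_TOKENS}")
        if enc["No"] != 0:
            raise ConfigError("dose_encoding must assign No -> 0")
        if not (enc["No"] <= enc["Down"] <= enc["Up"]):
            raise ConfigError("dose_encoding must be monotone No <= Down <= Up")


def group_diagnosis(icd9) -> str:
    """Map an ICD-9 code string to one of the nine disease categories.

    Total function: missing values, V/E codes and anything unparseable map
    to ``"other"``.
    """
    if icd9 is None or (isinstance(icd9, float) and np.isnan(icd9)):
        return "other"
    code = str(icd9).strip()
    if not code or code[0] in "VEve":
        return "other"
    try:
        prefix = int(float(code))
    except ValueError:
        return "other"
    if prefix == 250:
        return "diabetes"
    for group, lo, hi, extra in _ICD9_RANGES:
        if lo <= prefix <= hi or prefix == extra:
            return group
    return "other"


def encode_age(bracket: str) -> float:
    """Midpoint of a ``"[L-U)"`` age bracket, e.g. ``"[40-50)"`` -> 45."""
    m = _AGE_RE.match(str(bracket).strip())
    if not m:
        raise ValueError(f"malformed age bracket: {bracket!r}")
    lo, hi = int(m.group(1)), int(m.group(2))
    return (lo + hi) / 2


def encode_dose(token: str, config: PreprocessConfig | None = None) -> float:
    """Ordinal rating of a dose-change token (No->0, Down->1, Up->2)."""
    enc = (config or PreprocessConfig()).dose_encoding
    if token not in enc:
        raise ValueError(f"unknown dose token: {token!r}")
    return enc[token]


def deduplicate_patients(encounters: pd.DataFrame) -> pd.DataFrame:
    """Keep each patient's first encounter in file order."""
    if "patient_nbr" not in encounters.columns:
        raise SchemaError("patient_nbr column required for deduplication")
    return encounters.drop_duplicates(subset="patient_nbr", keep="first")


def filter_medicated(
    encounters: pd.DataFrame, min_medications: int = 2
) -> pd.DataFrame:
    """Keep patients administered at least *min_medications* drugs.

    A drug counts as administered when its token differs from ``No``;
    counting runs over the drug columns present in the frame.
    """
    if min_medications < 0:
        raise ConfigError("min_medications must be >= 0")
    drugs = drug_columns_of(encounters)
    if not drugs:
        raise SchemaError("no drug columns present")
    administered = (
        encounters[drugs].apply(lambda s: s.fillna("No") != "No").sum(axis=1)
    )
    return encounters.loc[administered >= min_medications]


def select_variables(
    table: pd.DataFrame, config: PreprocessConfig | None = None
) -> tuple[pd.DataFrame, list[dict]]:
    """Apply column-level selection rules; return the table and a drop report.

    Rules, in priority order: explicitly dropped identifiers; columns with a
    missing fraction above ``missingness_threshold``; non-drug columns where
    one value covers more than ``imbalance_threshold`` of rows; drug columns
    administered to fewer than ``min_drug_prevalence`` of patients.  Each
    dropped column appears once in the report with its reason and the
    statistic that triggered the rule.
    """
    cfg = config or PreprocessConfig()
    n = len(table)
    report: list[dict] = []
    dropped: set[str] = set()
    drugs = set(drug_columns_of(table))

    for col in table.columns:
        if col in cfg.explicit_drop:
            report.append({"column": col, "reason": "identifier", "statistic": None})
            dropped.add(col)

    for col in table.columns:
        if col in dropped or n == 0:
            continue
        frac = float(table[col].isna().mean())
        if frac > cfg.missingness_threshold:
            report.append({"column": col, "reason": "missingness", "statistic": frac})
            dropped.add(col)

    # The imbalance rule is only meaningful when the sample is large enough
    # that a column *could* fall below the threshold (n > 1/(1 - t)); at
    # tiny n every column is trivially near-constant.
    imbalance_applicable = (
        cfg.imbalance_threshold < 1 and n > 1 / (1 - cfg.imbalance_threshold)
    )
    for col in table.columns:
        if col in dropped or col in drugs or not imbalance_applicable:
            continue
        counts = table[col].value_counts(dropna=False)
        top = float(counts.iloc[0] / n) if len(counts) else 1.0
        if top > cfg.imbalance_threshold:
            report.append({"column": col, "reason": "imbalance", "statistic": top})
            dropped.add(col)

    for col in sorted(drugs):
        if col in dropped or n == 0:
            continue
        prevalence = float((table[col].fillna("No") != "No").mean())
        if prevalence < cfg.min_drug_prevalence:
            report.append(
                {"column": col, "reason": "low_prevalence", "statistic": prevalence}
            )
            dropped.add(col)

    kept = [c for c in table.columns if c not in dropped]
    if not kept:
        raise SchemaError("variable selection dropped every column")
    return table[kept], report


@dataclass
class FeatureTableResult:
    """Output of :func:`build_feature_table`.

    features : numeric per-patient characteristics (demographics, admission
        metadata, utilisation counts, lab/medication flags, race and
        first-diagnosis one-hots), indexed by patient id.
    drug_ratings : per-patient encoded dose columns on the same index.
    report : drop report — one entry per raw column that is not carried
        through unchanged, with the reason.
    """

    features: pd.DataFrame
    drug_ratings: pd.DataFrame
    report: list[dict]

    @property
    def full(self) -> pd.DataFrame:
        """The combined clustering view: characteristics + encoded doses."""
        return pd.concat([self.features, self.drug_ratings], axis=1)


_BINARY_MAPS = {
    "change": {"Ch": 1.0, "No": 0.0},
    "diabetesmed": {"Yes": 1.0, "No": 0.0},
}


def build_feature_table(
    encounters: pd.DataFrame, config: PreprocessConfig | None = None
) -> FeatureTableResult:
    """Run the full cleaning pipeline on raw encounters.

    Order of operations: deduplicate patients -> medication filter ->
    variable selection -> transformations to a fully numeric table with no
    missing values.  Rows whose gender cannot be binarised are removed (the
    pipeline never imputes).
    """
    cfg = config or PreprocessConfig()
    df = deduplicate_patients(encounters)
    df = filter_medicated(df, cfg.min_medications)
    df = df.set_index(pd.Index(df["patient_nbr"], name="patient_id"))
    df, report = select_variables(df, cfg)

    drugs = drug_columns_of(df)
    out: dict[str, pd.Series] = {}
    consumed: set[str] = set()

    if "gender" in df.columns:
        g = df["gender"].map({"Female": 0.0, "Male": 1.0})
        df = df.loc[g.notna()]
        out["gender"] = g.loc[df.index]
        consumed.add("gender")

    if "age" in df.columns:
        out["age"] = df["age"].map(encode_age).astype(float)
        consumed.add("age")

    for col in (
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
    ):
        if col in df.columns:
            out[col] = pd.to_numeric(df[col]).astype(float)
            consumed.add(col)

    for col in ("max_glu_serum", "a1cresult"):
        if col in df.columns:
            # 1 = test performed (any result), 0 = "None"/missing.
            out[col] = (
                df[col].fillna("None").ne("None").astype(float)
            )
            consumed.add(col)

    for col, mapping in _BINARY_MAPS.items():
        if col in df.columns:
            vals = df[col].map(mapping)
            if vals.isna().any():
                bad = df[col][vals.isna()].iloc[0]
                raise SchemaError(f"unmappable value {bad!r} in column '{col}'")
            out[col] = vals.astype(float)
            consumed.add(col)

    if "readmitted" in df.columns:
        vals = df["readmitted"].map(cfg.readmitted_encoding)
        if vals.isna().any():
            bad = df["readmitted"][vals.isna()].iloc[0]
            raise SchemaError(f"unmappable readmitted value {bad!r}")
        out["readmitted"] = vals.astype(float)
        consumed.add("readmitted")

    if "race" in df.columns:
        race = df["race"].where(df["race"].isin(RACE_CATEGORIES), "Other")
        race = race.fillna("Other")
        for cat in RACE_CATEGORIES:
            out[f"race_{cat}"] = race.eq(cat).astype(float)
        consumed.add("race")
        report.append(
            {"column": "race", "reason": "replaced_by_indicator", "statistic": None}
        )

    if "diag_1" in df.columns:
        groups = df["diag_1"].map(group_diagnosis)
        for cat in DIAGNOSIS_GROUPS:
            out[f"diag_{cat}"] = groups.eq(cat).astype(float)
        consumed.add("diag_1")
        report.append(
            {"column": "diag_1", "reason": "replaced_by_indicator", "statistic": None}
        )
    for col in ("diag_2", "diag_3"):
        if col in df.columns:
            consumed.add(col)
            report.append(
                {
                    "column": col,
                    "reason": "secondary_diagnosis_unused",
                    "statistic": None,
                }
            )

    ratings = pd.DataFrame(
        {d: df[d].fillna("No").map(cfg.dose_encoding).astype(float) for d in drugs},
        index=df.index,
    )
    consumed.update(drugs)

    leftovers = [c for c in df.columns if c not in consumed]
    for col in leftovers:
        report.append(
            {"column": col, "reason": "untransformed_extra", "statistic": None}
        )

    features = pd.DataFrame(out, index=df.index)
    if features.isna().any().any():
        bad = features.columns[features.isna().any()].tolist()
        raise SchemaError(f"missing values survived transformation: {bad}")
    return FeatureTableResult(features=features, drug_ratings=ratings, report=report)
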