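"""Synthetic encounter data with planted cluster structure.

The generator emits raw-schema encounter tables (and, as a shortcut, rating
matrices) whose ground truth is known: each patient belongs to one of G
planted clusters, and each cluster carries a demographic profile (race,
gender balance, age-bracket distribution, utilisation-count means), a
dominant primary-diagnosis category, and a drug-dose signature — a per-drug
distribution over the four dose-change tokens.  Ten drugs are active (the
set retained from the real data); the remaining medication columns are
always ``No`` so the downstream prevalence filter has something to drop.
``?`` markers are injected into ``weight`` and ``medical_specialty`` so the
missingness filter is exercised, and a configurable fraction of patients
receives a duplicate encounter (identical apart from ``encounter_id``) to
exercise deduplication.

Noise knobs: ``dose_noise`` resamples an active drug's token uniformly with
the given probability; ``feature_noise`` lognormally blurs the count means;
``label_flip`` draws a patient's attributes from a different cluster while
the recorded ground truth keeps the original label.  Ground-truth labels are
returned separately and are never written into the data table.

The default configuration mirrors the structure reported for the real
cohort: six clusters with size proportions 875:910:412:1369:646:965, insulin
prevalent in three clusters and essentially absent in the other three, age
mass between 45 and 85 years, and one cluster entirely African American.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import ConfigError
from .preprocess import DEFAULT_DOSE_ENCODING, DIAGNOSIS_GROUPS
from .recommender import RatingMatrix
from .schema import DRUG_COLUMNS, DOSE_TOKENS, RACE_CATEGORIES

#: Drugs with nontrivial signatures (the retained set of the real cohort).
ACTIVE_DRUGS: tuple[str, ...] = (
    "insulin",
    "metformin",
    "glipizide",
    "glyburide",
    "pioglitazone",
    "rosiglitazone",
    "glimepiride",
    "repaglinide",
    "glyburide-metformin",
    "nateglinide",
)

AGE_BRACKETS = tuple(f"[{10 * i}-{10 * (i + 1)})" for i in range(10))

_COUNT_BOUNDS = {
    "time_in_hospital": (1, 14),
    "num_lab_procedures": (1, 132),
    "num_procedures": (0, 6),
    "num_medications": (1, 81),
    "number_outpatient": (0, 42),
    "number_emergency": (0, 76),
    "number_inpatient": (0, 21),
    "number_diagnoses": (1, 16),
}

_DIAG_CODE_POOLS = {
    "circulatory": ("401", "410", "428", "434", "785"),
    "respiratory": ("486", "491", "493", "786"),
    "digestive": ("531", "558", "571", "787"),
    "genitourinary": ("584", "599", "788"),
    "injury": ("812", "850", "959"),
    "musculoskeletal": ("715", "722", "730"),
    "neoplasms": ("153", "174", "200"),
    "diabetes": ("250.01", "250.42", "250.7", "250.83"),
    "other": ("272", "300", "V45", "E849"),
}

# Token probabilities (No, Down, Steady, Up) by signature role.
_UP_DIST = (0.05, 0.10, 0.15, 0.70)
_STEADY_DIST = (0.15, 0.10, 0.65, 0.10)
_BACKGROUND_DIST = (0.97, 0.01, 0.01, 0.01)
_UP_POINT = (0.0, 0.0, 0.0, 1.0)
_STEADY_POINT = (0.0, 0.0, 1.0, 0.0)
_NO_POINT = (1.0, 0.0, 0.0, 0.0)


def _concentrated(categories: Sequence[str], dominant: str, p: float) -> dict:
    """Distribution with mass *p* on *dominant*, remainder uniform."""
    rest = (1 - p) / (len(categories) - 1) if len(categories) > 1 else 0.0
    return {c: (p if c == dominant else rest) for c in categories}


@dataclass
class ClusterProfile:
    race_probs: Mapping[str, float]
    diag_probs: Mapping[str, float]
    gender_p_female: float
    age_bracket_probs: np.ndarray  # length 10
    count_means: Mapping[str, float]
    drug_signature: Mapping[str, tuple]  # drug -> (pNo, pDown, pSteady, pUp)
    # Admission metadata and outcome mixes are cluster-dependent: in real
    # cohorts admission route, discharge type and readmission correlate with
    # the patient group, so the generator plants them alongside demographics.
    readmitted_probs: tuple = (0.55, 0.35, 0.10)  # NO, >30, <30
    admission_type: int = 1
    discharge_disposition: int = 1
    admission_source: int = 7
    p_glu_measured: float = 0.10
    p_a1c_measured: float = 0.17
    metadata_concentration: float = 0.85

    def expected_non_no(self, dose_noise: float) -> float:
        total = 0.0
        for drug in ACTIVE_DRUGS:
            p_no = self.drug_signature.get(drug, _NO_POINT)[0]
            total += (1 - dose_noise) * (1 - p_no) + dose_noise * 0.75
        return total


def _age_probs(center_indices: Sequence[int]) -> np.ndarray:
    p = np.zeros(10)
    for i in center_indices:
        p[i] += 1.0
    return p / p.sum()


def _signature(up: Sequence[str], steady: Sequence[str], deterministic: bool) -> dict:
    sig = {}
    for d in ACTIVE_DRUGS:
        if d in up:
            sig[d] = _UP_POINT if deterministic else _UP_DIST
        elif d in steady:
            sig[d] = _STEADY_POINT if deterministic else _STEADY_DIST
        else:
            sig[d] = _NO_POINT if deterministic else _BACKGROUND_DIST
    return sig


_PROFILE_SPECS = [
    # (race, diag, p_female, age bracket idx, up drugs, steady drugs, counts,
    #  readmitted probs, admission_type, discharge, source, p_glu, p_a1c)
    ("AfricanAmerican", "circulatory", 0.61, (4, 5, 6, 7),
     ("insulin", "glipizide", "metformin"), ("glyburide",),
     dict(time_in_hospital=3, num_lab_procedures=35, num_procedures=1,
          num_medications=16, number_outpatient=0.5, number_emergency=0.3,
          number_inpatient=0.5, number_diagnoses=7),
     (0.70, 0.22, 0.08), 1, 1, 7, 0.08, 0.15),
    ("Caucasian", "respiratory", 0.50, (5, 6, 7, 8),
     ("metformin", "glipizide", "glyburide"), ("repaglinide",),
     dict(time_in_hospital=5, num_lab_procedures=50, num_procedures=2,
          num_medications=11, number_outpatient=1, number_emergency=0.5,
          number_inpatient=0.8, number_diagnoses=8),
     (0.55, 0.35, 0.10), 2, 1, 1, 0.10, 0.17),
    ("Caucasian", "other", 0.55, (5, 6, 7, 8),
     ("glyburide", "metformin", "glipizide"), ("nateglinide",),
     dict(time_in_hospital=7, num_lab_procedures=65, num_procedures=3,
          num_medications=9, number_outpatient=2, number_emergency=1,
          number_inpatient=1.2, number_diagnoses=6),
     (0.40, 0.45, 0.15), 3, 3, 4, 0.15, 0.20),
    ("Caucasian", "diabetes", 0.45, (5, 6, 7, 8),
     ("insulin", "metformin", "glipizide"), ("pioglitazone",),
     dict(time_in_hospital=4, num_lab_procedures=45, num_procedures=2,
          num_medications=14, number_outpatient=0.5, number_emergency=0.2,
          number_inpatient=0.4, number_diagnoses=9),
     (0.65, 0.25, 0.10), 1, 6, 7, 0.05, 0.25),
    ("Caucasian", "circulatory", 0.50, (5, 6, 7),
     ("glyburide", "glipizide", "metformin"), ("rosiglitazone",),
     dict(time_in_hospital=9, num_lab_procedures=75, num_procedures=4,
          num_medications=10, number_outpatient=1.5, number_emergency=0.8,
          number_inpatient=1.5, number_diagnoses=5),
     (0.30, 0.50, 0.20), 2, 18, 1, 0.12, 0.22),
    ("Caucasian", "genitourinary", 0.52, (4, 5, 6, 7),
     ("insulin", "metformin", "glimepiride"), ("glyburide",),
     dict(time_in_hospital=6, num_lab_procedures=55, num_procedures=3,
          num_medications=18, number_outpatient=1, number_emergency=0.5,
          number_inpatient=0.9, number_diagnoses=8),
     (0.50, 0.35, 0.15), 6, 25, 17, 0.10, 0.18),
]


def default_profiles(
    race_concentration: float = 0.95,
    diag_concentration: float = 0.95,
    deterministic_doses: bool = True,
) -> tuple[ClusterProfile, ...]:
    """Six cluster profiles mirroring the real cohort's structure.

    Dose signatures are deterministic token roles (each cluster has three
    ``Up`` drugs and one ``Steady`` drug) by default — ``dose_noise`` is the
    single dial for dose stochasticity; pass ``deterministic_doses=False``
    for soft per-drug token distributions instead.
    """
    profiles = []
    meta_conc = 1.0 if race_concentration >= 1.0 else 0.95
    for (race, diag, p_f, ages, up, steady, counts,
         readm, adm_type, discharge, source, p_glu, p_a1c) in _PROFILE_SPECS:
        profiles.append(
            ClusterProfile(
                race_probs=_concentrated(RACE_CATEGORIES, race, race_concentration),
                diag_probs=_concentrated(DIAGNOSIS_GROUPS, diag, diag_concentration),
                gender_p_female=p_f,
                age_bracket_probs=_age_probs(ages),
                count_means=counts,
                drug_signature=_signature(up, steady, deterministic_doses),
                readmitted_probs=readm,
                admission_type=adm_type,
                discharge_disposition=discharge,
                admission_source=source,
                p_glu_measured=p_glu,
                p_a1c_measured=p_a1c,
                metadata_concentration=meta_conc,
            )
        )
    return tuple(profiles)


#: Cluster-size proportions mirroring the real cohort's six groups.
DEFAULT_WEIGHTS = tuple(np.array([875, 910, 412, 1369, 646, 965]) / 5177)


@dataclass
class SyntheticConfig:
    """Study conditions for generated cohorts (defaults: six planted
    clusters, 2000 patients, mild noise)."""

    n_patients: int = 2000
    profiles: tuple[ClusterProfile, ...] = field(default_factory=default_profiles)
    cluster_weights: tuple[float, ...] = DEFAULT_WEIGHTS
    duplicate_rate: float = 0.1
    dose_noise: float = 0.1
    feature_noise: float = 0.1
    label_flip: float = 0.0
    race_missing_rate: float = 0.02
    min_medications: int = 2
    seed: int = 0

    def __post_init__(self):
        g = len(self.profiles)
        if g < 2:
            raise ConfigError("at least 2 clusters required")
        if len(self.cluster_weights) != g:
            raise ConfigError("cluster_weights length must match profiles")
        w = np.asarray(self.cluster_weights, dtype=float)
        if (w < 0).any() or w.sum() <= 0:
            raise ConfigError("cluster_weights must be nonnegative, not all zero")
        self.cluster_weights = tuple(w / w.sum())
        if not 0 <= self.label_flip < 0.5:
            raise ConfigError("label_flip must be in [0, 0.5)")
        if not 0 <= self.dose_noise <= 1:
            raise ConfigError("dose_noise must be in [0, 1]")
        if self.feature_noise < 0:
            raise ConfigError("feature_noise must be >= 0")
        if not 0 <= self.duplicate_rate <= 1:
            raise ConfigError("duplicate_rate must be in [0, 1]")
        for i, profile in enumerate(self.profiles):
            for name, dist in (
                ("race_probs", list(profile.race_probs.values())),
                ("diag_probs", list(profile.diag_probs.values())),
                ("age_bracket_probs", profile.age_bracket_probs),
            ):
                if abs(float(np.sum(dist)) - 1.0) > 1e-9:
                    raise ConfigError(f"cluster {i}: {name} must sum to 1")
            for drug, probs in profile.drug_signature.items():
                if abs(sum(probs) - 1.0) > 1e-9:
                    raise ConfigError(
                        f"cluster {i}: token distribution for '{drug}' must sum to 1"
                    )
            expected = profile.expected_non_no(self.dose_noise)
            if expected < self.min_medications:
                raise ConfigError(
                    f"cluster {i}: expected non-No drugs {expected:.2f} "
                    f"< min_medications {self.min_medications}"
                )

    @classmethod
    def strong_separation(
        cls,
        n_patients: int = 2000,
        seed: int = 0,
        dose_noise: float = 0.0,
        label_flip: float = 0.0,
        duplicate_rate: float = 0.1,
    ) -> "SyntheticConfig":
        """Noise-free, fully concentrated profiles with deterministic
        per-cluster dose signatures (the signal-recovery regime)."""
        return cls(
            n_patients=n_patients,
            profiles=default_profiles(
                race_concentration=1.0,
                diag_concentration=1.0,
                deterministic_doses=True,
            ),
            duplicate_rate=duplicate_rate,
            dose_noise=dose_noise,
            feature_noise=0.0,
            label_flip=label_flip,
            race_missing_rate=0.0,
            seed=seed,
        )


def _sample_tokens(
    rng: np.random.Generator, profile: ClusterProfile, dose_noise: float
) -> dict[str, str]:
    tokens = {}
    for drug in DRUG_COLUMNS:
        if drug in ACTIVE_DRUGS:
            probs = profile.drug_signature.get(drug, _NO_POINT)
            if dose_noise and rng.random() < dose_noise:
                tokens[drug] = DOSE_TOKENS[rng.integers(4)]
            else:
                tokens[drug] = DOSE_TOKENS[rng.choice(4, p=np.asarray(probs))]
        else:
            tokens[drug] = "No"
    return tokens


def _sample_count(
    rng: np.random.Generator, mean: float, bounds: tuple[int, int], sigma: float
) -> int:
    lam = mean * (np.exp(sigma * rng.normal()) if sigma else 1.0)
    return int(np.clip(rng.poisson(lam), bounds[0], bounds[1]))


def _choice(rng: np.random.Generator, dist: Mapping[str, float]) -> str:
    keys = list(dist.keys())
    return keys[rng.choice(len(keys), p=np.asarray(list(dist.values())))]


def generate_encounters(
    config: SyntheticConfig | None = None,
) -> tuple[pd.DataFrame, pd.Series]:
    """Generate a raw-schema encounter table and its ground-truth labels.

    Returns ``(encounters, truth)`` where *truth* maps ``patient_nbr`` to the
    planted cluster label.  The truth is never embedded in the table.
    """
    cfg = config or SyntheticConfig()
    rng = np.random.default_rng(cfg.seed)
    g = len(cfg.profiles)
    rows: list[dict] = []
    truth: dict[int, int] = {}
    encounter_counter = 1

    for i in range(cfg.n_patients):
        patient_nbr = 10000 + i
        cluster = int(rng.choice(g, p=np.asarray(cfg.cluster_weights)))
        truth[patient_nbr] = cluster
        source = cluster
        if cfg.label_flip and rng.random() < cfg.label_flip:
            others = [c for c in range(g) if c != cluster]
            source = int(others[rng.integers(len(others))])
        profile = cfg.profiles[source]

        tokens = _sample_tokens(rng, profile, cfg.dose_noise)
        race = _choice(rng, profile.race_probs)
        if cfg.race_missing_rate and rng.random() < cfg.race_missing_rate:
            race = "?"
        diag_main = _choice(rng, profile.diag_probs)
        row = {
            "encounter_id": encounter_counter,
            "patient_nbr": patient_nbr,
            "race": race,
            "gender": "Female" if rng.random() < profile.gender_p_female else "Male",
            "age": AGE_BRACKETS[
                rng.choice(10, p=profile.age_bracket_probs)
            ],
            "weight": "?" if rng.random() < 0.97 else "[75-100)",
            "admission_type_id": int(
                profile.admission_type
                if rng.random() < profile.metadata_concentration
                else rng.integers(1, 9)
            ),
            "discharge_disposition_id": int(
                profile.discharge_disposition
                if rng.random() < profile.metadata_concentration
                else rng.choice([1, 2, 3, 6, 18, 25])
            ),
            "admission_source_id": int(
                profile.admission_source
                if rng.random() < profile.metadata_concentration
                else rng.choice([1, 4, 7, 17])
            ),
            "payer_code": "?" if rng.random() < 0.4 else str(
                rng.choice(["MC", "HM", "BC", "SP"])
            ),
            "medical_specialty": "?" if rng.random() < 0.6 else str(
                rng.choice(
                    ["InternalMedicine", "Cardiology", "Family/GeneralPractice"]
                )
            ),
            "diag_1": str(rng.choice(_DIAG_CODE_POOLS[diag_main])),
            "diag_2": str(
                rng.choice(_DIAG_CODE_POOLS[_choice(rng, profile.diag_probs)])
            ),
            "diag_3": str(
                rng.choice(
                    _DIAG_CODE_POOLS[DIAGNOSIS_GROUPS[rng.integers(len(DIAGNOSIS_GROUPS))]]
                )
            ),
            "max_glu_serum": str(
                rng.choice(["Norm", ">200", ">300"], p=[0.5, 0.3, 0.2])
                if rng.random() < profile.p_glu_measured
                else "None"
            ),
            "a1cresult": str(
                rng.choice(["Norm", ">7", ">8"], p=[0.4, 0.3, 0.3])
                if rng.random() < profile.p_a1c_measured
                else "None"
            ),
            "readmitted": str(
                rng.choice(["NO", ">30", "<30"], p=np.asarray(profile.readmitted_probs))
            ),
        }
        for name, bounds in _COUNT_BOUNDS.items():
            row[name] = _sample_count(
                rng, profile.count_means[name], bounds, cfg.feature_noise
            )
        row.update(tokens)
        non_no = sum(1 for d in DRUG_COLUMNS if tokens[d] != "No")
        changed = any(tokens[d] in ("Down", "Up") for d in DRUG_COLUMNS)
        row["change"] = "Ch" if changed else "No"
        row["diabetesmed"] = "Yes" if non_no else "No"
        encounter_counter += 1
        rows.append(row)
        if cfg.duplicate_rate and rng.random() < cfg.duplicate_rate:
            dup = dict(row)
            dup["encounter_id"] = encounter_counter
            encounter_counter += 1
            rows.append(dup)

    order = rng.permutation(len(rows))
    # A patient's encounters are identical apart from encounter_id, so the
    # shuffle cannot change which attribute values deduplication keeps.
    df = pd.DataFrame([rows[i] for i in order]).reset_index(drop=True)
    truth_series = pd.Series(truth, name="cluster")
    truth_series.index.name = "patient_nbr"
    return df, truth_series


def generate_rating_matrix(
    config: SyntheticConfig | None = None,
) -> tuple[RatingMatrix, pd.Series]:
    """Directly generate a patients x drugs rating matrix (active drugs only)
    with planted cluster labels, skipping the raw schema."""
    cfg = config or SyntheticConfig()
    rng = np.random.default_rng(cfg.seed)
    g = len(cfg.profiles)
    data = np.zeros((cfg.n_patients, len(ACTIVE_DRUGS)))
    labels = np.zeros(cfg.n_patients, dtype=int)
    for i in range(cfg.n_patients):
        cluster = int(rng.choice(g, p=np.asarray(cfg.cluster_weights)))
        labels[i] = cluster
        source = cluster
        if cfg.label_flip and rng.random() < cfg.label_flip:
            others = [c for c in range(g) if c != cluster]
            source = int(others[rng.integers(len(others))])
        tokens = _sample_tokens(rng, cfg.profiles[source], cfg.dose_noise)
        data[i] = [DEFAULT_DOSE_ENCODING[tokens[d]] for d in ACTIVE_DRUGS]
    index = pd.Index([10000 + i for i in range(cfg.n_patients)], name="patient_id")
    ratings = pd.DataFrame(data, index=index, columns=list(ACTIVE_DRUGS))
    truth = pd.Series(labels, index=index, name="cluster")
    matrix = RatingMatrix(ratings, truth.copy())
    return matrix, truth


def table4_example() -> RatingMatrix:
    """The worked 5-patient x 4-medication example matrix with cluster labels
    {1, 2, 1, 3, 2}, used throughout the tests and documentation."""
    ratings = pd.DataFrame(
        [
            [1, 0, 2, 1],
            [0, 1, 1, 1],
            [2, 0, 0, 1],
            [1, 2, 0, 0],
            [1, 1, 2, 0],
        ],
        index=pd.Index([1, 2, 3, 4, 5], name="patient_id"),
        columns=["medication_1", "medication_2", "medication_3", "medication_4"],
        dtype=float,
    )
    clusters = pd.Series([1, 2, 1, 3, 2], index=ratings.index, name="cluster")
    return RatingMatrix(ratings, clusters)
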