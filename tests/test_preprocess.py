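"""Cleaning rules, encodings, diagnosis grouping and the feature pipeline."""

import numpy as np
import pandas as pd
import pytest

from drugrec import (
    ConfigError,
    PreprocessConfig,
    build_feature_table,
    deduplicate_patients,
    encode_age,
    encode_dose,
    filter_medicated,
    group_diagnosis,
    select_variables,
)
from drugrec.preprocess import DIAGNOSIS_GROUPS


class TestDeduplicate:
    def test_keeps_first_encounter_in_file_order(self):
        df = pd.DataFrame(
            {"patient_nbr": ["A", "B", "A", "C"], "insulin": ["Up", "No", "No", "No"]}
        )
        out = deduplicate_patients(df)
        assert list(out["patient_nbr"]) == ["A", "B", "C"]
        assert out["insulin"].iloc[0] == "Up"  # A's first row

    def test_idempotent_on_unique_input(self):
        df = pd.DataFrame({"patient_nbr": [1, 2, 3]})
        pd.testing.assert_frame_equal(deduplicate_patients(df), df)

    def test_three_encounters_per_patient_collapse(self):
        df = pd.DataFrame({"patient_nbr": list(range(10)) * 3})
        assert len(deduplicate_patients(df)) == 10


class TestFilterMedicated:
    def _frame(self, insulin, metformin):
        return pd.DataFrame({
            "patient_nbr": range(len(insulin)),
            "insulin": insulin,
            "metformin": metformin,
        })

    def test_two_drug_patient_kept_at_min_two(self):
        df = self._frame(["Up"], ["Steady"])
        assert len(filter_medicated(df, 2)) == 1

    def test_drug_free_patient_dropped_at_min_one(self):
        df = self._frame(["No"], ["No"])
        assert len(filter_medicated(df, 1)) == 0

    def test_counts_match_brute_force_on_mixed_fixture(self):
        rng = np.random.default_rng(42)
        tokens = rng.choice(["No", "Down", "Steady", "Up"], p=[0.6, 0.1, 0.2, 0.1],
                            size=(20, 2))
        df = self._frame(tokens[:, 0], tokens[:, 1])
        expected = sum(1 for row in tokens if (row != "No").sum() >= 2)
        assert len(filter_medicated(df, 2)) == expected

    def test_negative_min_rejected(self):
        with pytest.raises(ConfigError):
            filter_medicated(self._frame(["No"], ["No"]), -1)

    def test_monotone_in_min_medications(self):
        rng = np.random.default_rng(0)
        tokens = rng.choice(["No", "Up"], size=(30, 2))
        df = self._frame(tokens[:, 0], tokens[:, 1])
        sizes = [len(filter_medicated(df, m)) for m in range(0, 3)]
        assert sizes == sorted(sizes, reverse=True)


class TestGroupDiagnosis:
    @pytest.mark.parametrize(
        "code,group",
        [
            ("250.42", "diabetes"),
            ("250", "diabetes"),
            ("428", "circulatory"),
            ("390", "circulatory"),
            ("459", "circulatory"),
            ("785", "circulatory"),
            ("486", "respiratory"),
            ("786", "respiratory"),
            ("531", "digestive"),
            ("787", "digestive"),
            ("584", "genitourinary"),
            ("788", "genitourinary"),
            ("715", "musculoskeletal"),
            ("140", "neoplasms"),
            ("239", "neoplasms"),
            ("800", "injury"),
            ("999.9", "injury"),
            ("V57", "other"),
            ("E909", "other"),
            ("272", "other"),
            (None, "other"),
            ("", "other"),
            ("garbage", "other"),
        ],
    )
    def test_chapter_ranges(self, code, group):
        assert group_diagnosis(code) == group

    def test_total_mapping_over_all_numeric_prefixes(self):
        for prefix in range(1, 1000):
            assert group_diagnosis(str(prefix)) in DIAGNOSIS_GROUPS


class TestEncodings:
    @pytest.mark.parametrize("i", range(10))
    def test_age_bracket_midpoints(self, i):
        assert encode_age(f"[{10*i}-{10*(i+1)})") == 10 * i + 5

    def test_malformed_bracket_rejected(self):
        with pytest.raises(ValueError):
            encode_age("40-50")

    @pytest.mark.parametrize(
        "token,value", [("No", 0), ("Down", 1), ("Steady", 1), ("Up", 2)]
    )
    def test_default_dose_encoding(self, token, value):
        assert encode_dose(token) == value

    def test_unknown_token_named_in_error(self):
        with pytest.raises(ValueError, match="Maybe"):
            encode_dose("Maybe")

    def test_steady_override(self):
        cfg = PreprocessConfig(
            dose_encoding={"No": 0, "Down": 1, "Steady": 2, "Up": 2}
        )
        assert encode_dose("Steady", cfg) == 2

    def test_dose_encoding_order_preserving(self):
        enc = PreprocessConfig().dose_encoding
        assert enc["No"] < enc["Down"] <= enc["Steady"] <= enc["Up"]

    def test_non_monotone_encoding_rejected(self):
        with pytest.raises(ConfigError):
            PreprocessConfig(dose_encoding={"No": 0, "Down": 2, "Steady": 1, "Up": 1})


class TestSelectVariables:
    def test_rules_fire_with_reasons(self, preprocess_fixture):
        df, config, expected = preprocess_fixture
        survivors = filter_medicated(deduplicate_patients(df), 2)
        out, report = select_variables(survivors, config)
        reasons = {r["column"]: r["reason"] for r in report}
        for col in ("weight", "medical_specialty"):
            assert reasons[col] == "missingness"
        assert reasons["admission_type_id"] == "imbalance"
        assert reasons["nateglinide"] == "low_prevalence"
        assert "discharge_disposition_id" in out.columns  # balanced: retained

    def test_drug_columns_exempt_from_imbalance_rule(self):
        # 96% "No" but above the prevalence floor: the drug must survive.
        df = pd.DataFrame({
            "patient_nbr": range(100),
            "insulin": ["Up"] * 4 + ["No"] * 96,
            "metformin": ["Steady"] * 50 + ["Up"] * 50,
        })
        out, report = select_variables(df, PreprocessConfig(explicit_drop=()))
        assert "insulin" in out.columns

    def test_every_column_kept_or_reported_once(self, preprocess_fixture):
        df, config, _ = preprocess_fixture
        survivors = filter_medicated(deduplicate_patients(df), 2)
        out, report = select_variables(survivors, config)
        reported = [r["column"] for r in report]
        assert len(reported) == len(set(reported))
        assert set(df.columns) == set(out.columns) | set(reported)


class TestBuildFeatureTable:
    def test_hand_counted_fixture(self, preprocess_fixture):
        df, config, expected = preprocess_fixture
        result = build_feature_table(df, config)
        assert len(result.features) == expected["n_rows"]
        assert result.features.shape[1] == expected["feature_columns"]
        assert list(result.drug_ratings.columns) == expected["drug_columns"]
        reasons = {r["column"]: r["reason"] for r in result.report}
        assert reasons == expected["drop_reasons"]

    def test_one_hot_groups_sum_to_one(self, preprocess_fixture):
        df, config, _ = preprocess_fixture
        result = build_feature_table(df, config)
        race = result.features.filter(like="race_")
        diag = result.features.filter(like="diag_")
        assert (race.sum(axis=1) == 1).all()
        assert (diag.sum(axis=1) == 1).all()

    def test_no_missing_values_survive(self, preprocess_fixture):
        df, config, _ = preprocess_fixture
        result = build_feature_table(df, config)
        assert not result.features.isna().any().any()
        assert not result.drug_ratings.isna().any().any()

    def test_missing_race_lands_in_other(self, preprocess_fixture):
        df, config, _ = preprocess_fixture
        result = build_feature_table(df, config)
        assert result.features.loc[3, "race_Other"] == 1.0

    def test_dose_values_in_encoding_range(self, preprocess_fixture):
        df, config, _ = preprocess_fixture
        result = build_feature_table(df, config)
        assert set(np.unique(result.drug_ratings.to_numpy())) <= {0.0, 1.0, 2.0}

    def test_raising_prevalence_floor_never_adds_drugs(self, preprocess_fixture):
        df, config, _ = preprocess_fixture
        counts = []
        for floor in (0.0, 0.3, 0.7):
            cfg = PreprocessConfig(
                explicit_drop=config.explicit_drop, min_drug_prevalence=floor
            )
            counts.append(build_feature_table(df, cfg).drug_ratings.shape[1])
        assert counts == sorted(counts, reverse=True)

    def test_single_patient_fixture(self):
        df = pd.DataFrame([{
            "patient_nbr": 1, "race": "Asian", "gender": "Male", "age": "[40-50)",
            "diag_1": "250.42", "insulin": "Up", "metformin": "Down",
            "readmitted": "NO",
        }])
        result = build_feature_table(df, PreprocessConfig(explicit_drop=("patient_nbr",)))
        assert len(result.features) == 1
        assert result.features.filter(like="race_").sum(axis=1).iloc[0] == 1
        assert result.features["diag_diabetes"].iloc[0] == 1.0
        assert result.drug_ratings.loc[1, "insulin"] == 2.0
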