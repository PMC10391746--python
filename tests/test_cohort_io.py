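"""Cohort CSV reading, validation and round-trip identity."""

import pandas as pd
import pytest

from hematotox.cohort import (Cohort, normalize_value, read_cohort,
                              write_cohort)
from hematotox.errors import CohortValidationError, SchemaError
from hematotox.simulate import GeneratorConfig, generate_cohort

from conftest import event, make_outcome, make_record


def _write_minimal(tmp_path, patients_rows, labs_rows=(), infections_rows=(),
                   events_rows=()):
    pcols = ["patient_id", "ld_start_day",
             "anc_baseline", "anc_sample_day",
             "hemoglobin_baseline", "hemoglobin_sample_day",
             "platelets_baseline", "platelets_sample_day",
             "crp_baseline", "crp_sample_day",
             "ferritin_baseline", "ferritin_sample_day",
             "egfr", "ldh_above_uln", "ecog", "bm_plasma_cell_pct",
             "prior_bcma_therapy", "crs_max_grade", "icans_max_grade",
             "hospital_days", "pfs_time", "pfs_event", "os_time", "os_event",
             "death_cause", "response"]
    pd.DataFrame(patients_rows, columns=pcols).to_csv(
        tmp_path / "patients.csv", index=False)
    pd.DataFrame(list(labs_rows),
                 columns=["patient_id", "day", "analyte", "value", "unit"]
                 ).to_csv(tmp_path / "labs.csv", index=False)
    pd.DataFrame(list(infections_rows),
                 columns=["patient_id", "onset_day", "category", "source",
                          "grade"]).to_csv(tmp_path / "infections.csv",
                                           index=False)
    pd.DataFrame(list(events_rows),
                 columns=["patient_id", "day", "event_type"]).to_csv(
        tmp_path / "events.csv", index=False)
    return tmp_path


def _patient_row(pid, **over):
    row = {"patient_id": pid, "ld_start_day": -5,
           "anc_baseline": 2.5, "anc_sample_day": -1,
           "hemoglobin_baseline": 12.0, "hemoglobin_sample_day": -1,
           "platelets_baseline": 200, "platelets_sample_day": -1,
           "crp_baseline": 1.0, "crp_sample_day": -1,
           "ferritin_baseline": 300, "ferritin_sample_day": -1,
           "pfs_time": 12.0, "pfs_event": 0, "os_time": 12.0, "os_event": 0,
           "death_cause": "none", "response": "PR"}
    row.update(over)
    return row


class TestReadValidation:
    def test_well_formed_three_patient_fixture(self, tmp_path):
        _write_minimal(tmp_path, [_patient_row(f"P{i}") for i in (1, 2, 3)],
                       labs_rows=[{"patient_id": "P1", "day": 0,
                                   "analyte": "anc", "value": 2.0,
                                   "unit": "g_per_l"}])
        cohort = read_cohort(tmp_path)
        assert len(cohort) == 3
        assert len(cohort.report) == 0
        assert cohort.by_id("P1").anc_series.values == (2.0,)

    def test_per_ul_anc_normalized_to_g_per_l(self, tmp_path):
        _write_minimal(tmp_path, [_patient_row("P1")],
                       labs_rows=[{"patient_id": "P1", "day": 2,
                                   "analyte": "anc", "value": 1770,
                                   "unit": "per_ul"}])
        cohort = read_cohort(tmp_path)
        assert cohort.by_id("P1").anc_series.values == (1.77,)

    def test_duplicate_patient_id_raises_naming_it(self, tmp_path):
        _write_minimal(tmp_path, [_patient_row("P9"), _patient_row("P9")])
        with pytest.raises(CohortValidationError, match="P9"):
            read_cohort(tmp_path)

    def test_missing_column_names_it(self, tmp_path):
        _write_minimal(tmp_path, [_patient_row("P1")])
        df = pd.read_csv(tmp_path / "patients.csv")
        df.drop(columns=["ferritin_baseline"]).to_csv(
            tmp_path / "patients.csv", index=False)
        with pytest.raises(SchemaError, match="ferritin_baseline"):
            read_cohort(tmp_path)

    def test_non_numeric_lab_value_names_patient(self, tmp_path):
        _write_minimal(tmp_path, [_patient_row("P1", anc_baseline="oops")])
        with pytest.raises(CohortValidationError, match="P1"):
            read_cohort(tmp_path)

    def test_same_day_duplicate_draw_keeps_minimum_and_flags(self, tmp_path):
        _write_minimal(tmp_path, [_patient_row("P1")],
                       labs_rows=[
                           {"patient_id": "P1", "day": 3, "analyte": "anc",
                            "value": 0.8, "unit": "g_per_l"},
                           {"patient_id": "P1", "day": 3, "analyte": "anc",
                            "value": 0.4, "unit": "g_per_l"}])
        cohort = read_cohort(tmp_path)
        assert cohort.by_id("P1").anc_series.values == (0.4,)
        assert any("duplicate" in f for f in cohort.report.flags)

    def test_neutropenic_fever_dropped_with_flag(self, tmp_path):
        _write_minimal(tmp_path, [_patient_row("P1")],
                       infections_rows=[{"patient_id": "P1", "onset_day": 10,
                                         "category": "neutropenic_fever",
                                         "source": "none", "grade": 2}])
        cohort = read_cohort(tmp_path)
        assert cohort.by_id("P1").infections == ()
        assert any("neutropenic fever" in f for f in cohort.report.flags)

    def test_empty_lab_cell_is_missing_not_zero(self, tmp_path):
        _write_minimal(tmp_path, [_patient_row("P1", crp_baseline="",
                                               crp_sample_day="")])
        cohort = read_cohort(tmp_path)
        assert cohort.by_id("P1").baseline.crp is None


class TestNormalization:
    def test_idempotent(self):
        once = normalize_value("anc", 1770, "per_ul")
        assert once == pytest.approx(1.77)
        assert normalize_value("anc", once, "g_per_l") == once

    def test_unknown_unit_rejected(self):
        with pytest.raises(CohortValidationError):
            normalize_value("hemoglobin", 12, "per_ul")


class TestRoundTrip:
    def test_empty_cohort_round_trips(self, tmp_path):
        write_cohort(Cohort(records=[]), tmp_path)
        assert len(read_cohort(tmp_path)) == 0

    def test_hand_built_record_round_trips(self, tmp_path):
        rec = make_record(
            "P1", anc=[(0, 2.0), (5, 0.4), (12, 1.5)],
            platelets=[(0, 150.0), (10, 42.0)],
            hemoglobin=[(0, 10.0), (14, 7.5)],
            infections=[event(12, "bacterial", 3)],
            outcome=make_outcome(5.0, 1, 8.0, 1, "progression", "PD"),
            prbc_days=(14,),
            candidates={"crp": ((-1, 2.5),), "ferritin": ((0, 700.0),)},
        )
        write_cohort([rec], tmp_path)
        back = read_cohort(tmp_path)
        assert back.records[0] == rec

    @pytest.mark.parametrize("seed", [0, 7, 99])
    def test_synthetic_cohort_round_trips_exactly(self, tmp_path, seed):
        cohort = generate_cohort(GeneratorConfig(n_patients=100), seed)
        write_cohort(cohort, tmp_path / "a")
        back = read_cohort(tmp_path / "a")
        assert sorted(cohort.records, key=lambda r: r.patient_id) == back.records

    def test_write_is_byte_stable(self, tmp_path):
        cohort = generate_cohort(GeneratorConfig(n_patients=30), 5)
        write_cohort(cohort, tmp_path / "a")
        write_cohort(cohort, tmp_path / "b")
        for name in ("patients.csv", "labs.csv", "infections.csv", "events.csv"):
            assert (tmp_path / "a" / name).read_bytes() == \
                   (tmp_path / "b" / name).read_bytes()
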