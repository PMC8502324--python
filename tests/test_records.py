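"""Record validation, CSV round-trips, and design-matrix encoding."""

import csv

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from losnet.records import (
    AGE_CLASSES,
    ADMISSION_TYPES,
    DISCHARGE_MODES,
    DRGReference,
    EncodingSpec,
    RecordValidationError,
    TIME_SLOTS,
    UNITS,
    WEEKDAYS,
    encode_design_matrix,
    read_drg_reference,
    read_hospitalizations,
    select_top_diagnoses,
    write_hospitalizations,
)
from tests.conftest import make_record


record_strategy = st.builds(
    make_record,
    i=st.integers(0, 9999),
    unit=st.sampled_from(UNITS),
    sex=st.integers(0, 1),
    age_class=st.sampled_from(AGE_CLASSES),
    cancer=st.integers(0, 1),
    admission_type=st.sampled_from(ADMISSION_TYPES),
    time_slot=st.sampled_from(TIME_SLOTS),
    weekday=st.sampled_from(WEEKDAYS),
    discharge_mode=st.sampled_from(DISCHARGE_MODES),
    transfer=st.integers(0, 1),
    los_days=st.floats(0.0, 400.0, allow_nan=False),
    diagnosis_group=st.sampled_from(["heart failure", "pneumonia", "sepsis"]),
)


class TestRecordValidation:
    def test_valid_record_accepted(self):
        make_record()

    @pytest.mark.parametrize("field,value", [
        ("sex", 2),
        ("age_class", "0-17"),
        ("admission_type", "walk-in"),
        ("weekday", "Funday"),
        ("los_days", -1.0),
        ("unit", "dermatology"),
    ])
    def test_domain_violations_rejected(self, field, value):
        with pytest.raises((RecordValidationError, ValueError)):
            make_record(**{field: value})


class TestCSVRoundTrip:
    def test_toy_csv_reads_three_records(self, tmp_path):
        records = [make_record(i) for i in range(3)]
        path = tmp_path / "r.csv"
        write_hospitalizations(records, path)
        assert read_hospitalizations(path) == records

    @settings(max_examples=25, deadline=None)
    @given(records=st.lists(record_strategy, min_size=1, max_size=8))
    def test_write_read_identity(self, tmp_path_factory, records):
        path = tmp_path_factory.mktemp("rt") / "r.csv"
        write_hospitalizations(records, path)
        assert read_hospitalizations(path) == records

    def test_invalid_sex_names_row_and_field(self, tmp_path):
        path = tmp_path / "r.csv"
        write_hospitalizations([make_record(0)], path)
        text = path.read_text().replace("R0000,cardiology,1", "R0000,cardiology,2")
        path.write_text(text)
        with pytest.raises(RecordValidationError, match="row 2.*sex"):
            read_hospitalizations(path)

    def test_missing_los_is_error(self, tmp_path):
        path = tmp_path / "r.csv"
        write_hospitalizations([make_record(0)], path)
        path.write_text(path.read_text().replace("6.0", ""))
        with pytest.raises(RecordValidationError, match="los_days"):
            read_hospitalizations(path)


class TestDRGReference:
    def test_valid_row(self, tmp_path):
        path = tmp_path / "d.csv"
        path.write_text(
            "drg_code,benchmark_los,threshold_los,mean_reimbursement\nX01,5.764,12.0,3000\n")
        table = read_drg_reference(path)
        assert table["X01"].benchmark_los == 5.764

    def test_threshold_below_benchmark_rejected(self, tmp_path):
        path = tmp_path / "d.csv"
        path.write_text(
            "drg_code,benchmark_los,threshold_los,mean_reimbursement\nX01,5.764,5.0,3000\n")
        with pytest.raises(ValueError, match="threshold"):
            read_drg_reference(path)

    def test_duplicate_code_rejected(self, tmp_path):
        path = tmp_path / "d.csv"
        path.write_text(
            "drg_code,benchmark_los,threshold_los,mean_reimbursement\n"
            "X01,5.0,12.0,3000\nX01,5.0,12.0,3000\n")
        with pytest.raises(ValueError, match="duplicate"):
            read_drg_reference(path)

    def test_empty_file_gives_empty_map(self, tmp_path):
        path = tmp_path / "d.csv"
        path.write_text("drg_code,benchmark_los,threshold_los,mean_reimbursement\n")
        assert read_drg_reference(path) == {}


class TestTopDiagnoses:
    def _brute_force(self, records, k):
        # independent oracle: count, sort by (-count, name)
        counts = {}
        for r in records:
            counts[r.diagnosis_group] = counts.get(r.diagnosis_group, 0) + 1
        return tuple(sorted(counts, key=lambda g: (-counts[g], g))[:k])

    def test_matches_count_and_sort_oracle(self, rng):
        groups = [f"g{j:02d}" for j in range(12)]
        weights = rng.dirichlet(np.ones(12))
        records = [make_record(i, diagnosis_group=str(rng.choice(groups, p=weights)))
                   for i in range(100)]
        assert select_top_diagnoses(records, 10) == self._brute_force(records, 10)

    def test_tie_at_boundary_goes_lexicographic(self):
        # 'aa' and 'zz' tie at the rank-2 boundary with k=2
        records = ([make_record(i, diagnosis_group="mm") for i in range(3)]
                   + [make_record(10 + i, diagnosis_group="zz") for i in range(2)]
                   + [make_record(20 + i, diagnosis_group="aa") for i in range(2)])
        top = select_top_diagnoses(records, 2)
        assert top == ("mm", "aa")

    def test_fewer_groups_than_k(self):
        records = [make_record(i, diagnosis_group=g)
                   for i, g in enumerate(["a", "b", "c"])]
        assert set(select_top_diagnoses(records, 10)) == {"a", "b", "c"}

    def test_empty_records_error(self):
        with pytest.raises(ValueError):
            select_top_diagnoses([])


class TestDesignMatrix:
    def test_macro_has_30_columns(self):
        spec = EncodingSpec("macro", tuple(f"g{i}" for i in range(10)))
        X = encode_design_matrix([make_record(0)], spec)
        assert X.shape[1] == 30  # 1+4+1+3+3+7+11

    def test_micro_has_31_columns(self):
        spec = EncodingSpec("micro", tuple(f"g{i}" for i in range(10)),
                            unit="cardiology")
        X = encode_design_matrix([make_record(0)], spec)
        assert X.shape[1] == 31

    def test_row_has_one_active_level_per_block(self):
        spec = EncodingSpec("macro", ("heart failure",) + tuple(f"g{i}" for i in range(9)))
        rec = make_record(0, sex=1, age_class="41-65", cancer=0,
                          admission_type="planned", time_slot="morning",
                          weekday="Mon", diagnosis_group="heart failure")
        row = encode_design_matrix([rec], spec).iloc[0]
        # sex=1 plus one active level in each of the 5 categorical blocks
        assert row.sum() == 6
        for prefix in ("age_", "adm_", "slot_", "day_", "diag_"):
            block = row[[c for c in row.index if c.startswith(prefix)]]
            assert block.sum() == 1

    @settings(max_examples=20, deadline=None)
    @given(st.lists(record_strategy, min_size=1, max_size=12))
    def test_one_hot_block_sums(self, records):
        spec = EncodingSpec("macro", ("heart failure", "pneumonia"))
        X = encode_design_matrix(records, spec)
        assert set(np.unique(X.to_numpy())) <= {0, 1}
        for prefix in ("age_", "adm_", "slot_", "day_", "diag_"):
            block = X[[c for c in X.columns if c.startswith(prefix)]]
            assert (block.sum(axis=1) == 1).all()

    def test_deterministic_and_order_preserving(self):
        spec = EncodingSpec("macro", ("heart failure",))
        records = [make_record(i, sex=i % 2) for i in range(5)]
        X1 = encode_design_matrix(records, spec)
        X2 = encode_design_matrix(records, spec)
        assert X1.equals(X2)
        assert list(X1["sex_male"]) == [0, 1, 0, 1, 0]

    def test_micro_requires_unit(self):
        with pytest.raises(ValueError):
            EncodingSpec("micro", ("a",))

    def test_micro_rejects_foreign_units(self):
        spec = EncodingSpec("micro", ("a",), unit="oncology")
        with pytest.raises(ValueError, match="other units"):
            encode_design_matrix([make_record(0, unit="cardiology")], spec)
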