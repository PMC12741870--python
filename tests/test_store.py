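"""Cohort store: UIDs, append/replace, export/import, de-identification, merge."""

import zipfile

import pandas as pd
import pytest

from oartx import (
    CohortStore,
    append_patient,
    assign_uid,
    export_cohort,
    import_cohort,
    merge_cohorts,
)
from oartx.errors import ConfigurationError, IntegrityError, MergeConflictError
from oartx.store import (
    DirectoryCollector,
    InMemoryCollector,
    shift_days_for_uid,
)


def _rows(uid, plans=("IM1/SCH0101",), structures=("Bladder", "Rectum"), extra=None):
    rows = []
    for p in plans:
        for s in structures:
            row = {
                "patient_uid": uid,
                "plan_name": p,
                "structure": s,
                "fraction": 1,
                "volume_cm3": 100.0,
            }
            if extra:
                row.update(extra)
            rows.append(row)
    return pd.DataFrame(rows)


class TestAssignUid:
    def test_nineteenth_patient_format(self):
        store = CohortStore(institution_id="1234")
        for i in range(19):
            uid = assign_uid(store, f"SRC{i}")
        assert uid.uid == "1234-00019"

    def test_idempotent_for_same_source(self):
        store = CohortStore(institution_id="1234")
        a = assign_uid(store, "SRC-A")
        assign_uid(store, "SRC-B")
        assert assign_uid(store, "SRC-A").uid == a.uid

    def test_unset_institution_rejected(self):
        with pytest.raises(ConfigurationError):
            assign_uid(CohortStore(), "SRC")

    def test_width_overflow_widens(self):
        from oartx.store import PatientUID

        assert PatientUID("9", 123456).uid == "9-123456"


class TestAppend:
    def test_round_trip_and_replacement(self):
        store = CohortStore(institution_id="1")
        append_patient(store, _rows("1-00001"))
        assert len(store.rows) == 2
        append_patient(store, _rows("1-00001", plans=("IM1/SCH0101", "IM1/ADP0102")))
        assert len(store.rows) == 4  # replaced, not duplicated

    def test_two_patients_sum(self):
        store = CohortStore(institution_id="1")
        append_patient(store, _rows("1-00001"))
        append_patient(store, _rows("1-00002"))
        assert len(store.rows) == 4

    def test_duplicate_key_within_patient_rejected(self):
        df = pd.concat([_rows("1-00001")] * 2, ignore_index=True)
        with pytest.raises(IntegrityError):
            append_patient(CohortStore(institution_id="1"), df)

    def test_extensible_column_cannot_shadow_core(self):
        store = CohortStore(institution_id="1")
        with pytest.raises(ConfigurationError):
            store.register_column("volume_cm3")


class TestExport:
    def test_round_trip_equal_tables(self, tmp_path):
        store = CohortStore(institution_id="1")
        append_patient(store, _rows("1-00001", extra={"myMetric": 1.5}))
        path = export_cohort(store, tmp_path / "c.zip")
        back = import_cohort(path)
        pd.testing.assert_frame_equal(
            back.rows.sort_index(axis=1), store.rows.sort_index(axis=1), check_like=True
        )
        assert "myMetric" in back.column_registry

    def test_filter_contract(self, tmp_path):
        store = CohortStore(institution_id="1")
        append_patient(store, _rows("1-00001"))
        append_patient(store, _rows("1-00002", structures=("Heart",)))
        path = export_cohort(store, tmp_path / "c.zip", "structure == 'Heart'")
        assert set(import_cohort(path).rows["structure"]) == {"Heart"}

    def test_unknown_filter_column_lists_available(self, tmp_path):
        store = CohortStore(institution_id="1")
        append_patient(store, _rows("1-00001"))
        with pytest.raises(ConfigurationError) as exc:
            export_cohort(store, tmp_path / "c.zip", "nosuch == 1")
        assert "patient_uid" in str(exc.value)

    def test_export_is_byte_stable(self, tmp_path):
        store = CohortStore(institution_id="1")
        append_patient(store, _rows("1-00001"))
        a = export_cohort(store, tmp_path / "a.zip").read_bytes()
        b = export_cohort(store, tmp_path / "b.zip").read_bytes()
        assert a == b

    def test_no_source_ids_in_archive(self, tmp_path):
        store = CohortStore(institution_id="1")
        uid = assign_uid(store, "MRN-SECRET-42")
        append_patient(store, _rows(uid.uid))
        path = export_cohort(store, tmp_path / "c.zip")
        with zipfile.ZipFile(path) as zf:
            blob = b"".join(zf.read(n) for n in zf.namelist())
        assert b"MRN-SECRET-42" not in blob
        assert b"lookback" not in blob


class TestMerge:
    def test_identity_with_empty(self):
        a = CohortStore(institution_id="1")
        append_patient(a, _rows("1-00001"))
        merged = merge_cohorts(a, CohortStore(institution_id="2"))
        assert len(merged.rows) == len(a.rows)

    def test_disjoint_institutions_sum_and_union(self):
        a = CohortStore(institution_id="1")
        append_patient(a, _rows("1-00001"))
        b = CohortStore(institution_id="2")
        append_patient(b, _rows("2-00001"))
        merged = merge_cohorts(a, b)
        assert len(merged.rows) == 4
        assert set(merged.rows["patient_uid"].str.rsplit("-", n=1).str[0]) == {"1", "2"}

    def test_same_institution_reimport_deduplicates(self):
        a = CohortStore(institution_id="1")
        append_patient(a, _rows("1-00001"))
        merged = merge_cohorts(a, a)
        assert len(merged.rows) == 2

    def test_conflicting_rows_same_key_rejected(self):
        a = CohortStore(institution_id="1")
        append_patient(a, _rows("1-00001"))
        b = CohortStore(institution_id="1")
        append_patient(b, _rows("1-00001", extra=None).assign(volume_cm3=999.0))
        with pytest.raises(MergeConflictError):
            merge_cohorts(a, b)

    def test_associative_on_disjoint_institutions(self):
        stores = []
        for i in "123":
            s = CohortStore(institution_id=i)
            append_patient(s, _rows(f"{i}-00001"))
            stores.append(s)
        left = merge_cohorts(merge_cohorts(stores[0], stores[1]), stores[2])
        right = merge_cohorts(stores[0], merge_cohorts(stores[1], stores[2]))
        pd.testing.assert_frame_equal(left.rows, right.rows)

    def test_column_units_collision_suffixed(self, caplog):
        a = CohortStore(institution_id="1")
        append_patient(a, _rows("1-00001", extra={"myMetric": 1.0}))
        a.column_registry["myMetric"] = {"units": "Gy"}
        b = CohortStore(institution_id="2")
        append_patient(b, _rows("2-00001", extra={"myMetric": 2.0}))
        b.column_registry["myMetric"] = {"units": "%"}
        with caplog.at_level("WARNING"):
            merged = merge_cohorts(a, b)
        assert "myMetric__1" in merged.rows.columns
        assert "myMetric__2" in merged.rows.columns
        assert any("units" in r.message for r in caplog.records)

    def test_schema_version_mismatch_rejected(self):
        a = CohortStore(institution_id="1")
        b = CohortStore(institution_id="2", schema_version="9.9")
        with pytest.raises(MergeConflictError):
            merge_cohorts(a, b)


class TestCollectors:
    @pytest.mark.parametrize("backend", ["directory", "memory"])
    def test_snapshot_round_trip_lossless(self, tmp_path, backend):
        collector = (
            DirectoryCollector(tmp_path / "store")
            if backend == "directory"
            else InMemoryCollector()
        )
        store = CohortStore(institution_id="1", lookback={"SRC": "1-00001"})
        df = _rows("1-00001", extra={"myMetric": 2.5})
        append_patient(store, df, collector=collector)
        collector.save_store(store)
        loaded = collector.load_store()
        assert loaded.institution_id == "1"
        assert loaded.lookback == {"SRC": "1-00001"}
        snap = collector.load_patient("1-00001")
        assert set(snap.columns) >= {"patient_uid", "plan_name", "structure", "myMetric"}
        assert len(snap) == len(df)


def test_date_shift_deterministic_and_bounded():
    assert shift_days_for_uid("1234-00001") == shift_days_for_uid("1234-00001")
    assert 0 <= shift_days_for_uid("x") < 3653
    assert shift_days_for_uid("1234-00001") != shift_days_for_uid("1234-00002")
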