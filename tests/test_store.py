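"""EAV store: concept dictionary, scoped retrieval, hierarchy counting."""

import datetime as dt

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cdwquery.store import (
    Concept,
    ConceptConflictError,
    EAVStore,
    ScopeKey,
    UnknownConceptError,
    ValidationError,
    ValueRecord,
    distinct_count,
    distinct_keys,
)


def _rec(p, e=None, d=None, g=None, concept="ICD", value="I50"):
    return ValueRecord(patient_id=p, encounter_id=e, document_id=d, group_id=g,
                       concept_id=concept, value=value)


class TestConceptDictionary:
    def test_round_trip_and_idempotent_reregistration(self, store):
        concept = Concept("Modality2", "Modality", "code", "imaging")
        assert store.register_concept(concept) == "Modality2"
        assert store.register_concept(concept) == "Modality2"
        assert store.get_concept("Modality2") == concept

    def test_conflicting_redefinition_rejected(self, store):
        store.register_concept(Concept("X", "x", "code"))
        with pytest.raises(ConceptConflictError):
            store.register_concept(Concept("X", "x", "numeric"))

    def test_unregistered_concept_rejected_on_insert(self, store):
        with pytest.raises(UnknownConceptError):
            store.insert_value(_rec("P1", concept="NoSuchConcept"))


class TestInsertValidation:
    def test_missing_patient_rejected(self, store):
        with pytest.raises(ValidationError):
            store.insert_value(_rec(""))

    def test_group_without_document_rejected(self, store):
        with pytest.raises(ValidationError):
            store.insert_value(ValueRecord(
                patient_id="P1", group_id="G1", concept_id="ICD", value="I50"
            ))

    def test_orphan_document_shape_accepted(self, store):
        # null encounter with a document is the orphan-DICOM case
        rid = store.insert_value(_rec("P1", None, "STUDY:1.2", "1.2.3",
                                      concept="Modality", value="MR"))
        assert rid > 0
        recs = list(store.records_in_scope(
            "group", [ScopeKey("group", ("P1", None, "STUDY:1.2", "1.2.3"))]
        ))
        assert [r.value for r in recs] == ["MR"]

    def test_value_coerced_to_concept_kind(self, store):
        with pytest.raises(ValidationError):
            store.insert_value(_rec("P1", concept="LVEF", value="not a number"))


class TestScopedRetrieval:
    def test_exact_scope_containment(self, store):
        for d in ("D1", "D1", "D1"):
            store.insert_value(_rec("P1", "E1", d, concept="RadiologyFinding",
                                    value="text"))
        store.insert_value(_rec("P1", "E2", "D9", concept="RadiologyFinding",
                                value="other"))
        got = list(store.records_in_scope("encounter", [ScopeKey("encounter", ("P1", "E1"))]))
        assert len(got) == 3

    def test_empty_scope_set_yields_empty_stream(self, store):
        store.insert_value(_rec("P1"))
        assert list(store.records_in_scope("patient", [])) == []

    def test_null_slot_only_matches_null_key(self, store):
        store.insert_value(_rec("P1", None, "SD", "SG", "Modality", "MR"))
        store.insert_value(_rec("P1", "E1", "D1", "G1", "Modality", "MR"))
        null_key = ScopeKey("document", ("P1", None, "SD"))
        real_key = ScopeKey("document", ("P1", "E1", "D1"))
        assert {r.group_id for r in store.records_in_scope("document", [null_key])} == {"SG"}
        assert {r.group_id for r in store.records_in_scope("document", [real_key])} == {"G1"}

    def test_patient_scope_matches_brute_force_filter(self, store):
        rng = np.random.default_rng(5)
        inserted = []
        for _ in range(10):
            rec = _rec(f"P{rng.integers(3)}",
                       e=f"E{rng.integers(2)}" if rng.random() < 0.7 else None)
            store.insert_value(rec)
            inserted.append(rec)
        got = sorted(r.record_id for r in store.records_in_scope(
            "patient", [ScopeKey("patient", ("P1",))]
        ))
        expected = [i + 1 for i, r in enumerate(inserted) if r.patient_id == "P1"]
        assert got == expected


class TestChildren:
    def test_documents_under_encounter(self, store):
        store.insert_value(_rec("P1", "E1", "D1"))
        store.insert_value(_rec("P1", "E1", "D2"))
        store.insert_value(_rec("P1", "E2", "D3"))
        got = store.children("encounter", [ScopeKey("encounter", ("P1", "E1"))])
        assert got == {ScopeKey("document", ("P1", "E1", "D1")),
                       ScopeKey("document", ("P1", "E1", "D2"))}

    def test_orphan_document_appears_with_null_slot(self, store):
        store.insert_value(_rec("P1", None, "D9"))
        enc = store.children("patient", [ScopeKey("patient", ("P1",))])
        assert enc == {ScopeKey("encounter", ("P1", None))}
        docs = store.children("encounter", enc)
        assert docs == {ScopeKey("document", ("P1", None, "D9"))}

    def test_group_has_no_children(self, store):
        with pytest.raises(ValueError):
            store.children("group", [])

    def test_empty_input_empty_output(self, store):
        assert store.children("patient", []) == set()

    def test_scope_monotonicity(self, hospital_store):
        parents = set(list(hospital_store.entity_keys("encounter"))[:20])
        children = hospital_store.children("encounter", parents)
        coarse = {r.record_id for r in hospital_store.records_in_scope("encounter", parents)}
        fine = {r.record_id for r in hospital_store.records_in_scope("document", children)}
        assert fine <= coarse


class TestDistinctCount:
    def test_hand_counted(self, store):
        for p in ("PA", "PA", "PB", "PB", "PB"):
            store.insert_value(_rec(p))
        assert distinct_count("patient", store.all_records()) == 2
        assert distinct_count("patient", []) == 0

    def test_matches_tuple_set_oracle_on_random_store(self, store):
        rng = np.random.default_rng(11)
        for _ in range(200):
            e = f"E{rng.integers(4)}" if rng.random() < 0.8 else None
            d = f"D{rng.integers(6)}" if rng.random() < 0.6 else None
            g = f"G{rng.integers(8)}" if (d and rng.random() < 0.5) else None
            store.insert_value(_rec(f"P{rng.integers(5)}", e, d, g))
        records = store.all_records()
        tuples = [r.scope_tuple() for r in records]
        for level, depth in (("patient", 1), ("encounter", 2),
                             ("document", 3), ("group", 4)):
            expected = {
                t[:depth] for t in tuples
                if any(x is not None for x in t[depth - 1:])
            }
            assert distinct_count(level, records) == len(expected)
        assert len(records) == 200  # the fifth Tables-style count is the row count

    def test_null_slot_key_distinct_from_real_key(self, store):
        store.insert_value(_rec("P1", None, "D1"))
        store.insert_value(_rec("P1", "E1", "D2"))
        keys = distinct_keys("encounter", store.all_records())
        assert keys == {ScopeKey("encounter", ("P1", None)),
                        ScopeKey("encounter", ("P1", "E1"))}


@st.composite
def _records(draw):
    p = draw(st.sampled_from(["P1", "P2", "P3"]))
    e = draw(st.sampled_from([None, "E1", "E2"]))
    d = draw(st.sampled_from([None, "D1", "D2"]))
    g = draw(st.sampled_from([None, "G1", "G2"])) if d is not None else None
    return _rec(p, e, d, g, concept="RadiologyFinding",
                value=draw(st.sampled_from(["a", "b", "c"])))


@settings(max_examples=60, derandomize=True, deadline=None)
@given(st.lists(_records(), max_size=30))
def test_insert_then_scan_round_trip(records):
    """Any batch of valid rows comes back as the same multiset."""
    store = EAVStore()
    store.register_concept(Concept("RadiologyFinding", value_kind="text"))
    store.insert_values(records)
    def key(r):
        return (tuple(x or "" for x in r.scope_tuple()), r.concept_id, r.value,
                sum(x is None for x in r.scope_tuple()))
    assert sorted(map(key, store.all_records())) == sorted(map(key, records))


def test_file_backed_store_persists_across_reopen(tmp_path):
    path = str(tmp_path / "warehouse.db")
    store = EAVStore(path)
    store.register_concept(Concept("Modality", value_kind="code", domain="imaging"))
    store.insert_value(_rec("P1", "E1", "D1", "G1", "Modality", "MR"))
    store.close()

    reopened = EAVStore(path)
    assert reopened.get_concept("Modality").value_kind == "code"
    assert len(reopened) == 1
    (rec,) = reopened.all_records()
    assert rec.scope_tuple() == ("P1", "E1", "D1", "G1")


def test_csv_dump_load_round_trip(tmp_path, store):
    store.insert_value(_rec("P1", "E1", "D1", None, "RadiologyFinding", "hello, \"world\""))
    store.insert_value(_rec("P1", None, "SD", "SG", "Modality", "MR"))
    store.insert_value(ValueRecord(
        patient_id="P2", encounter_id="E2", concept_id="LVEF", value=35.5,
        observed_at=dt.date(2016, 5, 1),
    ))
    path = str(tmp_path / "dump.csv")
    assert store.dump_csv(path) == 3
    text = open(path).read()
    assert r"\N" in text  # explicit null marker, distinct from empty string

    reloaded = EAVStore()
    assert reloaded.load_csv(path) == 3
    def key(r):
        return (tuple(x or "" for x in r.scope_tuple()), r.concept_id,
                str(r.value), str(r.observed_at))
    assert sorted(map(key, reloaded.all_records())) == sorted(map(key, store.all_records()))
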