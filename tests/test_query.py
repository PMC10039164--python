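"""Query language parsing and multilevel cascade evaluation."""

import datetime as dt
import filecmp
import json

import numpy as np
import pytest

from cdwquery.clinical import ClinicalIngestor, ClinicalObservation, EncounterRecord
from cdwquery.query import (
    And,
    Condition,
    MultilevelQuery,
    Or,
    QueryParseError,
    UnsupportedFormatError,
    eval_expr,
    evaluate,
    export_results,
    parse_query,
    render_query,
    summarize,
)
from cdwquery.store import Concept, EAVStore, ScopeKey, ValueRecord
from cdwquery.synth import STEMI_QUERY, worked_example_stemi

from .reference import random_query


class TestParser:
    def test_group_equality_condition(self):
        q = parse_query('GROUP: Modality == "MR"')
        assert q.group == Condition("Modality", "==", "MR")
        assert q.patient is None and q.document is None

    def test_two_condition_and_at_encounter(self):
        q = parse_query('ENCOUNTER: NT-proBNP > 1000 AND ICD matches "^I50"')
        assert q.encounter == And((
            Condition("NT-proBNP", ">", 1000.0),
            Condition("ICD", "matches", "^I50"),
        ))

    def test_admission_window_and_precedence(self):
        q = parse_query(
            "ADMISSION: [2016-01-01, 2017-12-31]\n"
            'DOCUMENT: RadiologyOrder matches "CMR(A|B)" OR StudyDescription contains "cardiac"\n'
            'GROUP: Modality == "MR" AND (SeriesDescription contains "cine" OR SeriesDescription exists)\n'
        )
        assert q.admission_window == (dt.date(2016, 1, 1), dt.date(2017, 12, 31))
        assert isinstance(q.document, Or)
        assert isinstance(q.group, And)
        assert isinstance(q.group.children[1], Or)

    @pytest.mark.parametrize("text, fragment", [
        ("GROUP: Modality >", "literal"),
        ("GROUP: Modality == \"MR\" AND (X == 1", "expected ')'"),
        ("ADMISSION: [2016-13-99, 2017-01-01]\nGROUP: Modality exists", "date"),
        ("NONSENSE: X == 1", "NONSENSE"),
        ("", "empty"),
        ("GROUP: AND == 1", "concept"),
    ])
    def test_syntax_errors_carry_location(self, text, fragment):
        with pytest.raises(QueryParseError) as err:
            parse_query(text)
        assert "line" in str(err.value)
        assert fragment.lower() in str(err.value).lower()

    def test_unbounded_window_is_normalised_away(self):
        q = parse_query("ADMISSION: [*, *]\nGROUP: Modality exists")
        assert q.admission_window is None

    def test_string_escapes(self):
        q = parse_query(r'DOCUMENT: RadiologyFinding contains "a \"quoted\" word"')
        assert q.document.operand == 'a "quoted" word'

    def test_render_parse_round_trip_on_random_queries(self):
        rng = np.random.default_rng(42)
        for _ in range(200):
            q = random_query(rng)
            assert parse_query(render_query(q)) == q


@pytest.fixture
def stemi_store():
    return worked_example_stemi()


class TestEvalExpr:
    def test_same_document_co_occurrence(self, stemi_store):
        expr = parse_query(STEMI_QUERY).document
        ok, matched = eval_expr(
            expr, ScopeKey("document", ("STEMI-P1", "E-SAME", "LAB-1")), stemi_store
        )
        assert ok
        assert {r.concept_id for r in matched} == {"TroponinT", "CK-MB"}

    def test_split_documents_fail_but_encounter_scope_passes(self, stemi_store):
        expr = parse_query(STEMI_QUERY).document
        for doc in ("LAB-2", "LAB-3"):
            ok, matched = eval_expr(
                expr, ScopeKey("document", ("STEMI-P2", "E-SPLIT", doc)), stemi_store
            )
            assert not ok and matched == []
        ok, _ = eval_expr(
            expr, ScopeKey("encounter", ("STEMI-P2", "E-SPLIT")), stemi_store
        )
        assert ok  # witnesses from two different documents

    def test_empty_scope_is_false(self, stemi_store):
        expr = parse_query(STEMI_QUERY).document
        ok, matched = eval_expr(
            expr, ScopeKey("document", ("STEMI-P1", "E-SAME", "NO-DOC")), stemi_store
        )
        assert (ok, matched) == (False, [])

    def test_regex_error_surfaces_with_pattern(self, stemi_store):
        store = stemi_store
        store.register_concept(Concept("Note", value_kind="text"))
        store.insert_value(ValueRecord(patient_id="STEMI-P1", concept_id="Note",
                                       value="x"))
        with pytest.raises(Exception):
            eval_expr(Condition("Note", "matches", "(unclosed"),
                      ScopeKey("patient", ("STEMI-P1",)), store)


class TestCascade:
    def test_document_only_query_passes_all_upper_levels(self, hospital_store):
        q = parse_query('DOCUMENT: RadiologyOrder matches "CMR(A|B)"')
        result = evaluate(q, hospital_store)
        assert result.levels["patient"].keys == hospital_store.entity_keys("patient")
        assert result.levels["encounter"].keys == hospital_store.entity_keys("encounter")
        assert result.levels["document"].keys < hospital_store.entity_keys("document")

    def test_empty_store_empty_selections(self):
        store = EAVStore()
        store.register_concept(Concept("Modality", value_kind="code"))
        result = evaluate(parse_query("GROUP: Modality exists"), store)
        assert all(sel.keys == set() for sel in result.levels.values())

    def test_group_refinement_excludes_presentation_states(self, hospital_store):
        from cdwquery.synth import RADIOLOGY_QUERY

        q = parse_query(RADIOLOGY_QUERY)
        result = evaluate(q, hospital_store)
        groups = result.levels["group"].keys
        assert groups  # the planted cardiac studies match
        modalities = {
            r.value for r in hospital_store.records_in_scope(
                "group", groups, {"Modality"}
            )
        }
        assert modalities == {"MR"}
        # but PR series exist in those same documents
        docs = result.levels["document"].keys
        all_group_modalities = {
            r.value
            for r in hospital_store.records_in_scope(
                "group", hospital_store.children("document", docs), {"Modality"})
        }
        assert "PR" in all_group_modalities

    def test_cascade_refinement_and_condition_monotonicity(self, hospital_store):
        rng = np.random.default_rng(7)
        for _ in range(20):
            q = random_query(rng)
            result = evaluate(q, hospital_store)
            assert result.levels["encounter"].keys <= hospital_store.children(
                "patient", result.levels["patient"].keys)
            assert result.levels["document"].keys <= hospital_store.children(
                "encounter", result.levels["encounter"].keys)
            assert result.levels["group"].keys <= hospital_store.children(
                "document", result.levels["document"].keys)
            # adding a group condition never enlarges the group selection
            extra = Condition("Modality", "==", "MR")
            group = And((q.group, extra)) if q.group is not None else extra
            tightened = MultilevelQuery(
                patient=q.patient, encounter=q.encounter, document=q.document,
                group=group, admission_window=q.admission_window,
            )
            assert evaluate(tightened, hospital_store).levels["group"].keys \
                <= result.levels["group"].keys

    def test_admission_window_filters_encounters(self):
        store = EAVStore()
        ing = ClinicalIngestor(store)
        ing.ingest_encounter(EncounterRecord("P1", "E-IN", dt.date(2016, 6, 1)))
        ing.ingest_encounter(EncounterRecord("P1", "E-OUT", dt.date(2018, 6, 1)))
        ing.ingest_observation(ClinicalObservation(
            patient_id="P1", encounter_id="E-IN", concept_id="ICD", value="I50"))
        ing.ingest_observation(ClinicalObservation(
            patient_id="P1", encounter_id="E-OUT", concept_id="ICD", value="I50"))
        q = parse_query("ADMISSION: [2016-01-01, 2016-12-31]\nENCOUNTER: ICD exists")
        result = evaluate(q, store)
        assert {k.ids[1] for k in result.levels["encounter"].keys} == {"E-IN"}

    def test_orphan_documents_blocked_by_encounter_constraint(self):
        store = EAVStore()
        ing = ClinicalIngestor(store)
        store.register_concept(Concept("Modality", value_kind="code", domain="imaging"))
        ing.ingest_encounter(EncounterRecord("P1", "E1", dt.date(2016, 6, 1)))
        store.insert_value(ValueRecord(
            patient_id="P1", document_id="STUDY:1", group_id="G1",
            concept_id="Modality", value="MR"))
        free = evaluate(parse_query("GROUP: Modality exists"), store)
        assert {k.ids[2] for k in free.levels["document"].keys} == {"STUDY:1"}
        blocked = evaluate(parse_query(
            "ADMISSION: [2016-01-01, 2016-12-31]\nGROUP: Modality exists"), store)
        assert blocked.levels["document"].keys == set()


class TestStatistics:
    def test_hand_counted_group_row(self, store):
        # 3 matched series across 2 patients / 2 encounters / 2 documents
        rows = [
            ("PA", "E1", "D1", "G1"), ("PA", "E1", "D1", "G2"),
            ("PB", "E2", "D2", "G3"),
        ]
        for p, e, d, g in rows:
            store.insert_value(ValueRecord(
                patient_id=p, encounter_id=e, document_id=d, group_id=g,
                concept_id="Modality", value="MR"))
        result = evaluate(parse_query('GROUP: Modality == "MR"'), store)
        stats = summarize(result, store)
        (row,) = stats.rows
        assert (row.level, row.n_patients, row.n_encounters, row.n_documents,
                row.n_groups) == ("group", 2, 2, 2, 3)
        assert row.n_values == 3
        (attr,) = row.attributes
        assert attr.concept_id == "Modality" and attr.n_unique == 1

    def test_unqueried_levels_are_not_rows(self, hospital_store):
        from cdwquery.synth import RADIOLOGY_QUERY

        result = evaluate(parse_query(RADIOLOGY_QUERY), hospital_store)
        stats = summarize(result, hospital_store)
        assert [r.level for r in stats.rows] == ["document", "group"]
        text = stats.to_text()
        assert "#Patients" in text and "#Groups" in text
        assert stats.to_tsv().count("\n") >= 3


class TestExport:
    def test_sorted_deterministic_export_with_manifest(self, hospital_store, tmp_path):
        from cdwquery.synth import RADIOLOGY_QUERY

        result = evaluate(parse_query(RADIOLOGY_QUERY), hospital_store)
        a, b = str(tmp_path / "a.csv"), str(tmp_path / "b.csv")
        export_results(result, "group", "csv", a)
        export_results(result, "group", "csv", b)
        assert filecmp.cmp(a, b, shallow=False)
        manifest = json.load(open(a + ".manifest.json"))
        uids = manifest["series_instance_uids"]
        assert uids == sorted(uids)
        assert len(uids) == len(result.levels["group"].keys)
        header = open(a).readline().strip().split(",")
        assert header[:4] == ["patient_id", "encounter_id", "document_id", "group_id"]
        assert open(a).read().count("\n") == len(uids) + 1

    def test_jsonl_export(self, hospital_store, tmp_path):
        from cdwquery.synth import RADIOLOGY_QUERY

        result = evaluate(parse_query(RADIOLOGY_QUERY), hospital_store)
        path = str(tmp_path / "docs.jsonl")
        export_results(result, "document", "jsonl", path)
        lines = [json.loads(line) for line in open(path)]
        assert len(lines) == len(result.levels["document"].keys)
        assert all("patient_id" in obj for obj in lines)

    def test_empty_result_header_only(self, store, tmp_path):
        result = evaluate(parse_query('GROUP: Modality == "NOPE"'), store)
        path = str(tmp_path / "empty.csv")
        export_results(result, "group", "csv", path)
        assert open(path).read().strip().count("\n") == 0

    def test_unknown_format_lists_supported(self, store, tmp_path):
        result = evaluate(parse_query("GROUP: Modality exists"), store)
        with pytest.raises(UnsupportedFormatError, match="csv"):
            export_results(result, "group", "xlsx", str(tmp_path / "x"))
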