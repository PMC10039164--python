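"""Ingestion of clinical records: radiology reports, encounters, observations.

Radiology reports are the linchpin between the clinical and imaging
domains: every report row is stored with a (patient, encounter, document)
prefix, and the report's accession number is indexed so that DICOM series
can later adopt the same three identifiers.

Observations cover the rest of the clinical payload used by feasibility
queries: ICD diagnosis codes and narrative letters at encounter scope,
laboratory panel values at document scope (values of one specimen share
one document id, which is what makes same-report co-occurrence queries
meaningful), and echocardiography parameters such as LVEF.
"""

from __future__ import annotations

import datetime as _dt
import json
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional

from .store import Concept, EAVStore, ValidationError, ValueRecord

__all__ = [
    "RadiologyReport",
    "ClinicalObservation",
    "EncounterRecord",
    "ReportIndex",
    "ClinicalIngestor",
    "DuplicateDocumentError",
    "AccessionConflictError",
    "build_report_index",
    "register_clinical_concepts",
    "load_reports",
    "load_observations",
    "load_encounters",
    "REPORT_FIELD_CONCEPTS",
]


class DuplicateDocumentError(ValueError):
    """Two reports claim the same document identifier."""


class AccessionConflictError(ValueError):
    """One accession number maps to two different reports."""


@dataclass(frozen=True)
class RadiologyReport:
    """A narrative radiology report plus its order/linkage identifiers."""

    accession_number: str
    patient_id: str
    encounter_id: str
    document_id: str
    order_identifier: str = ""
    short_finding: str = ""
    finding: str = ""
    assessment: str = ""
    report_date: Optional[_dt.date] = None


@dataclass(frozen=True)
class ClinicalObservation:
    """A single coded/numeric/text clinical fact at an explicit scope."""

    patient_id: str
    concept_id: str
    value: object
    encounter_id: Optional[str] = None
    document_id: Optional[str] = None
    group_id: Optional[str] = None
    observed_at: Optional[_dt.date] = None


@dataclass(frozen=True)
class EncounterRecord:
    """One hospitalization; admission date drives the query date window."""

    patient_id: str
    encounter_id: str
    admission_date: _dt.date
    department: str = ""


#: report field -> concept id; order fixed, one EAV row per non-empty field
REPORT_FIELD_CONCEPTS: tuple[tuple[str, str], ...] = (
    ("order_identifier", "RadiologyOrder"),
    ("short_finding", "RadiologyShortFinding"),
    ("finding", "RadiologyFinding"),
    ("assessment", "RadiologyAssessment"),
)

#: concept id for the admission date row written per encounter
ADMISSION_CONCEPT = "AdmissionDate"
DEPARTMENT_CONCEPT = "Department"

_CLINICAL_CONCEPTS = (
    Concept("RadiologyOrder", "Radiology order", "text"),
    Concept("RadiologyShortFinding", "Radiology short finding", "text"),
    Concept("RadiologyFinding", "Radiology finding", "text"),
    Concept("RadiologyAssessment", "Radiology assessment", "text"),
    Concept(ADMISSION_CONCEPT, "Admission date", "date"),
    Concept(DEPARTMENT_CONCEPT, "Department", "code"),
    Concept("ICD", "ICD diagnosis code", "code"),
    Concept("Sex", "Administrative sex", "code"),
    Concept("BirthYear", "Year of birth", "numeric"),
    Concept("PhysicianLetter", "Physician letter", "text"),
    Concept("LVEF", "Left ventricular ejection fraction", "numeric", unit="%"),
    Concept("NT-proBNP", "NT-proBNP", "numeric", unit="pg/ml"),
    Concept("TroponinT", "Troponin T", "numeric", unit="ng/ml"),
    Concept("CK-MB", "Creatine kinase-MB", "numeric", unit="U/l"),
)


def register_clinical_concepts(store: EAVStore) -> None:
    """Register the built-in clinical concept dictionary (idempotent)."""
    for concept in _CLINICAL_CONCEPTS:
        store.register_concept(concept)


class ReportIndex:
    """Accession number -> (patient, encounter, document) lookup table."""

    def __init__(self) -> None:
        self._map: dict[str, tuple[str, str, str]] = {}

    def add(self, accession: str, ids: tuple[str, str, str]) -> None:
        existing = self._map.get(accession)
        if existing is not None and existing != ids:
            raise AccessionConflictError(
                f"accession {accession!r} maps to both {existing} and {ids}"
            )
        self._map[accession] = ids

    def lookup(self, accession: str) -> Optional[tuple[str, str, str]]:
        """Return (patient_id, encounter_id, document_id) or None."""
        return self._map.get(accession)

    def __len__(self) -> int:
        return len(self._map)

    def __contains__(self, accession: str) -> bool:
        return accession in self._map


def build_report_index(reports: Iterable[RadiologyReport]) -> ReportIndex:
    """Index a report batch by accession number.

    Order-insensitive; duplicate accessions with conflicting identifiers
    raise :class:`AccessionConflictError`.
    """
    index = ReportIndex()
    for report in reports:
        index.add(
            report.accession_number,
            (report.patient_id, report.encounter_id, report.document_id),
        )
    return index


class ClinicalIngestor:
    """Loads clinical records into an :class:`EAVStore`.

    Parameters
    ----------
    store
        Target warehouse; the built-in clinical concepts are registered
        on construction.
    allow_dangling
        When False (default), a report whose encounter was never ingested
        is rejected; set True to accept reports for unknown encounters.
    """

    def __init__(self, store: EAVStore, allow_dangling: bool = False) -> None:
        self.store = store
        self.allow_dangling = allow_dangling
        self.index = ReportIndex()
        self._encounters: set[tuple[str, str]] = set()
        self._documents: set[str] = set()
        register_clinical_concepts(store)

    # ------------------------------------------------------------------
    def ingest_encounter(self, encounter: EncounterRecord) -> None:
        key = (encounter.patient_id, encounter.encounter_id)
        self._encounters.add(key)
        self.store.insert_value(ValueRecord(
            patient_id=encounter.patient_id,
            encounter_id=encounter.encounter_id,
            concept_id=ADMISSION_CONCEPT,
            value=encounter.admission_date,
            observed_at=encounter.admission_date,
        ))
        if encounter.department:
            self.store.insert_value(ValueRecord(
                patient_id=encounter.patient_id,
                encounter_id=encounter.encounter_id,
                concept_id=DEPARTMENT_CONCEPT,
                value=encounter.department,
            ))

    def ingest_report(self, report: RadiologyReport) -> int:
        """Store one row per non-empty report field, all sharing the
        report's (patient, encounter, document) prefix; returns the row
        count.  Empty fields are skipped so value statistics count facts,
        not placeholders.
        """
        if report.document_id in self._documents:
            raise DuplicateDocumentError(
                f"document {report.document_id!r} already ingested"
            )
        key = (report.patient_id, report.encounter_id)
        if not self.allow_dangling and key not in self._encounters:
            raise ValidationError(
                f"report {report.document_id!r} references unknown encounter {key};"
                " ingest the encounter first or set allow_dangling=True"
            )
        n = 0
        for field_name, concept_id in REPORT_FIELD_CONCEPTS:
            text = getattr(report, field_name)
            if not text:
                continue
            self.store.insert_value(ValueRecord(
                patient_id=report.patient_id,
                encounter_id=report.encounter_id,
                document_id=report.document_id,
                concept_id=concept_id,
                value=text,
                observed_at=report.report_date,
            ))
            n += 1
        self._documents.add(report.document_id)
        self.index.add(
            report.accession_number,
            (report.patient_id, report.encounter_id, report.document_id),
        )
        return n

    def ingest_observation(self, obs: ClinicalObservation) -> int:
        """Insert one observation at its stated scope; returns the record id."""
        return self.store.insert_value(ValueRecord(
            patient_id=obs.patient_id,
            encounter_id=obs.encounter_id,
            document_id=obs.document_id,
            group_id=obs.group_id,
            concept_id=obs.concept_id,
            value=obs.value,
            observed_at=obs.observed_at,
        ))

    def ingest(
        self,
        encounters: Iterable[EncounterRecord] = (),
        reports: Iterable[RadiologyReport] = (),
        observations: Iterable[ClinicalObservation] = (),
    ) -> int:
        """Bulk ingest in dependency order; returns total rows inserted."""
        before = len(self.store)
        for enc in encounters:
            self.ingest_encounter(enc)
        for report in reports:
            self.ingest_report(report)
        for obs in observations:
            self.ingest_observation(obs)
        return len(self.store) - before


# ----------------------------------------------------------------------
# file loading (CSV and JSON-lines; keys/columns exactly the field names)
# ----------------------------------------------------------------------

def _iter_rows(path: str) -> Iterable[Mapping[str, str]]:
    if str(path).endswith((".jsonl", ".ndjson")):
        with open(path, encoding="utf-8") as fh:
            for line in fh:
                line = line.strip()
                if line:
                    yield json.loads(line)
    else:
        import csv

        with open(path, newline="", encoding="utf-8") as fh:
            yield from csv.DictReader(fh)


def _opt(row: Mapping[str, str], key: str) -> Optional[str]:
    value = row.get(key)
    return value if value not in (None, "") else None


def load_reports(path: str) -> list[RadiologyReport]:
    reports = []
    for row in _iter_rows(path):
        date = _opt(row, "report_date")
        reports.append(RadiologyReport(
            accession_number=row["accession_number"],
            patient_id=row["patient_id"],
            encounter_id=row["encounter_id"],
            document_id=row["document_id"],
            order_identifier=row.get("order_identifier", "") or "",
            short_finding=row.get("short_finding", "") or "",
            finding=row.get("finding", "") or "",
            assessment=row.get("assessment", "") or "",
            report_date=_dt.date.fromisoformat(date) if date else None,
        ))
    return reports


def load_observations(path: str) -> list[ClinicalObservation]:
    observations = []
    for row in _iter_rows(path):
        date = _opt(row, "observed_at")
        observations.append(ClinicalObservation(
            patient_id=row["patient_id"],
            concept_id=row["concept_id"],
            value=row["value"],
            encounter_id=_opt(row, "encounter_id"),
            document_id=_opt(row, "document_id"),
            group_id=_opt(row, "group_id"),
            observed_at=_dt.date.fromisoformat(date) if date else None,
        ))
    return observations


def load_encounters(path: str) -> list[EncounterRecord]:
    return [
        EncounterRecord(
            patient_id=row["patient_id"],
            encounter_id=row["encounter_id"],
            admission_date=_dt.date.fromisoformat(row["admission_date"]),
            department=row.get("department", "") or "",
        )
        for row in _iter_rows(path)
    ]
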