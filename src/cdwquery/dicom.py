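"""DICOM metadata extraction and mapping into the four-level EAV model.

The DICOM information model nests instance -> series -> study -> patient;
only the series level is modeled here (it is the granularity of interest
for cohort building — a study may mix modalities and examinations, and
per-image rows add bulk without adding query power).

Linkage rules:

* A series whose accession number resolves to an ingested radiology
  report *adopts* the report's patient, encounter and document
  identifiers; the group identifier is the Series Instance UID.  The
  DICOM hierarchy is thereby preserved inside the warehouse: the report
  document's group children are exactly its studies' series.
* A series without a usable accession number (externally transmitted
  images, typically) falls back to an orphan mapping: the DICOM patient
  id, a *null* encounter, and a document id derived deterministically
  from the Study Instance UID.

Each retained header value becomes one EAV row.  Modality, the two UIDs
and the series description are group-scoped; the study description is
document-scoped (one row per document/study pair).
"""

from __future__ import annotations

import csv
import json
import logging
import os
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

from .clinical import ReportIndex
from .store import Concept, EAVStore, ValidationError, ValueRecord

logger = logging.getLogger(__name__)

__all__ = [
    "SeriesMetadata",
    "LinkageResult",
    "SeriesReadResult",
    "IngestSummary",
    "read_series_metadata",
    "write_series_table",
    "link_series",
    "ingest_series",
    "register_imaging_concepts",
    "ORPHAN_DOCUMENT_PREFIX",
]

#: document id prefix for studies that cannot be linked to a report
ORPHAN_DOCUMENT_PREFIX = "STUDY:"

#: SeriesMetadata scalar fields, in the column order of the table dialect
_TABLE_FIELDS = (
    "dicom_patient_id", "accession_number", "study_instance_uid",
    "series_instance_uid", "modality", "study_description",
    "series_description",
)

_IMAGING_CONCEPTS = (
    Concept("Modality", "Modality", "code", "imaging"),
    Concept("StudyInstanceUID", "Study instance UID", "code", "imaging"),
    Concept("SeriesInstanceUID", "Series instance UID", "code", "imaging"),
    Concept("SeriesDescription", "Series description", "text", "imaging"),
    Concept("StudyDescription", "Study description", "text", "imaging"),
)


def register_imaging_concepts(store: EAVStore) -> None:
    for concept in _IMAGING_CONCEPTS:
        store.register_concept(concept)


@dataclass(frozen=True)
class SeriesMetadata:
    """The per-series DICOM tag subset consumed by ingestion."""

    dicom_patient_id: str
    study_instance_uid: str
    series_instance_uid: str
    modality: str
    accession_number: Optional[str] = None
    study_description: str = ""
    series_description: str = ""
    extra_tags: Mapping[str, str] = field(default_factory=dict)

    def validate(self) -> None:
        if not self.series_instance_uid:
            raise ValidationError("SeriesInstanceUID is required")
        if not self.study_instance_uid:
            raise ValidationError(
                f"series {self.series_instance_uid}: StudyInstanceUID is required"
            )
        if not self.modality:
            raise ValidationError(
                f"series {self.series_instance_uid}: Modality must be a non-empty code"
            )


@dataclass(frozen=True)
class LinkageResult:
    """Where one DICOM series lands in the four-level hierarchy."""

    patient_id: str
    document_id: str
    group_id: str
    encounter_id: Optional[str] = None
    linked_via: str = "accession"  # or "orphan_fallback"


class SeriesReadResult(list):
    """List of :class:`SeriesMetadata` plus a skipped-source counter."""

    def __init__(self, series: Iterable[SeriesMetadata] = (), skipped: int = 0):
        super().__init__(series)
        self.skipped = skipped


@dataclass
class IngestSummary:
    """Outcome of one :func:`ingest_series` run."""

    rows: int = 0
    linked: int = 0
    orphans: int = 0
    skipped: int = 0
    errors: list[str] = field(default_factory=list)


# ----------------------------------------------------------------------
# reading series metadata
# ----------------------------------------------------------------------

def _read_dicom_directory(path: str) -> SeriesReadResult:
    import pydicom

    by_series: dict[str, SeriesMetadata] = {}
    skipped = 0
    filenames = []
    for root, _dirs, files in os.walk(path):
        filenames.extend(os.path.join(root, name) for name in files)
    for filename in sorted(filenames):
        try:
            ds = pydicom.dcmread(filename, stop_before_pixels=True)
        except Exception as exc:  # unreadable / non-DICOM file
            logger.warning("skipping unreadable file %s: %s", filename, exc)
            skipped += 1
            continue
        series_uid = str(getattr(ds, "SeriesInstanceUID", "") or "")
        if not series_uid:
            raise ValidationError(f"{filename}: missing SeriesInstanceUID")
        meta = SeriesMetadata(
            dicom_patient_id=str(getattr(ds, "PatientID", "") or ""),
            accession_number=str(getattr(ds, "AccessionNumber", "") or "") or None,
            study_instance_uid=str(getattr(ds, "StudyInstanceUID", "") or ""),
            series_instance_uid=series_uid,
            modality=str(getattr(ds, "Modality", "") or ""),
            study_description=str(getattr(ds, "StudyDescription", "") or ""),
            series_description=str(getattr(ds, "SeriesDescription", "") or ""),
        )
        previous = by_series.get(series_uid)
        if previous is None:
            meta.validate()
            by_series[series_uid] = meta
        elif previous != meta:
            # first file (lexicographic filename order) wins
            logger.warning(
                "series %s: header disagreement in %s ignored (first file wins)",
                series_uid, filename,
            )
    return SeriesReadResult(by_series.values(), skipped=skipped)


def _row_to_series(row: Mapping[str, str]) -> SeriesMetadata:
    extras = {
        key: value
        for key, value in row.items()
        if key not in _TABLE_FIELDS and value not in (None, "")
    }
    meta = SeriesMetadata(
        dicom_patient_id=row.get("dicom_patient_id", "") or "",
        accession_number=(row.get("accession_number") or None),
        study_instance_uid=row.get("study_instance_uid", "") or "",
        series_instance_uid=row.get("series_instance_uid", "") or "",
        modality=row.get("modality", "") or "",
        study_description=row.get("study_description", "") or "",
        series_description=row.get("series_description", "") or "",
        extra_tags=extras,
    )
    meta.validate()
    return meta


def _read_table(path: str) -> SeriesReadResult:
    by_series: dict[str, SeriesMetadata] = {}
    if str(path).endswith((".jsonl", ".ndjson")):
        with open(path, encoding="utf-8") as fh:
            rows: Iterable[Mapping[str, str]] = [
                json.loads(line) for line in fh if line.strip()
            ]
    else:
        with open(path, newline="", encoding="utf-8") as fh:
            rows = list(csv.DictReader(fh))
    for row in rows:
        meta = _row_to_series(row)
        by_series.setdefault(meta.series_instance_uid, meta)
    return SeriesReadResult(by_series.values())


def read_series_metadata(source: str) -> SeriesReadResult:
    """Read per-series metadata from a directory of DICOM Part-10 files
    (header only, pixel data never loaded) or from a C-FIND-style
    CSV/JSON-lines table.

    One :class:`SeriesMetadata` is returned per distinct Series Instance
    UID.  Unreadable files are skipped with a warning and counted in
    ``result.skipped``; a record without a SeriesInstanceUID is a hard
    error.
    """
    if os.path.isdir(source):
        return _read_dicom_directory(source)
    return _read_table(source)


def write_series_table(series: Sequence[SeriesMetadata], path: str) -> None:
    """Write the C-FIND-style metadata dialect (CSV or ``.jsonl``)."""
    extra_names = sorted({name for s in series for name in s.extra_tags})
    if str(path).endswith((".jsonl", ".ndjson")):
        with open(path, "w", encoding="utf-8") as fh:
            for s in series:
                row = {name: getattr(s, name) or "" for name in _TABLE_FIELDS}
                row.update(s.extra_tags)
                fh.write(json.dumps(row, sort_keys=False) + "\n")
        return
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(list(_TABLE_FIELDS) + extra_names)
        for s in series:
            row = [getattr(s, name) or "" for name in _TABLE_FIELDS]
            row += [s.extra_tags.get(name, "") for name in extra_names]
            writer.writerow(row)


# ----------------------------------------------------------------------
# linkage and ingestion
# ----------------------------------------------------------------------

def link_series(series: SeriesMetadata, index: ReportIndex) -> LinkageResult:
    """Resolve one series to its warehouse identifiers.

    An accession number that is present but unknown degrades to the
    orphan fallback with a warning — operationally the same situation as
    externally transmitted images without a local report.
    """
    if series.accession_number:
        hit = index.lookup(series.accession_number)
        if hit is not None:
            patient_id, encounter_id, document_id = hit
            return LinkageResult(
                patient_id=patient_id,
                encounter_id=encounter_id,
                document_id=document_id,
                group_id=series.series_instance_uid,
                linked_via="accession",
            )
        logger.warning(
            "series %s: accession %r not found in report index; using orphan fallback",
            series.series_instance_uid, series.accession_number,
        )
    return LinkageResult(
        patient_id=series.dicom_patient_id,
        encounter_id=None,
        document_id=ORPHAN_DOCUMENT_PREFIX + series.study_instance_uid,
        group_id=series.series_instance_uid,
        linked_via="orphan_fallback",
    )


def _imaging_concept(store: EAVStore, concept_id: str) -> str:
    if not store.has_concept(concept_id):
        store.register_concept(Concept(concept_id, concept_id, "text", "imaging"))
    return concept_id


def ingest_series(
    series_list: Iterable[SeriesMetadata],
    index: ReportIndex,
    store: EAVStore,
) -> IngestSummary:
    """Map series metadata into the store, one EAV row per header value.

    Group-scoped rows: Modality, SeriesInstanceUID, StudyInstanceUID,
    SeriesDescription (when non-empty) and every extra tag.  One
    document-scoped StudyDescription row per (document, study) pair.
    Re-running over identical input inserts nothing (rows are unique on
    scope, concept and value).  Per-record failures are collected in the
    summary, not raised.
    """
    register_imaging_concepts(store)
    summary = IngestSummary()
    study_desc_done: set[tuple[str, str]] = set()

    for series in series_list:
        try:
            series.validate()
            linkage = link_series(series, index)
        except ValidationError as exc:
            summary.skipped += 1
            summary.errors.append(str(exc))
            continue
        if linkage.linked_via == "accession":
            summary.linked += 1
        else:
            summary.orphans += 1

        group_values: list[tuple[str, str]] = [
            ("Modality", series.modality),
            ("SeriesInstanceUID", series.series_instance_uid),
            ("StudyInstanceUID", series.study_instance_uid),
        ]
        if series.series_description:
            group_values.append(("SeriesDescription", series.series_description))
        for tag_name in sorted(series.extra_tags):
            _imaging_concept(store, tag_name)
            group_values.append((tag_name, series.extra_tags[tag_name]))

        for concept_id, value in group_values:
            if store.has_value(linkage.patient_id, linkage.encounter_id,
                               linkage.document_id, linkage.group_id,
                               concept_id, value):
                continue
            store.insert_value(ValueRecord(
                patient_id=linkage.patient_id,
                encounter_id=linkage.encounter_id,
                document_id=linkage.document_id,
                group_id=linkage.group_id,
                concept_id=concept_id,
                value=value,
            ))
            summary.rows += 1

        if series.study_description:
            pair = (linkage.document_id, series.study_instance_uid)
            if pair not in study_desc_done:
                study_desc_done.add(pair)
                if not store.has_value(linkage.patient_id, linkage.encounter_id,
                                       linkage.document_id, None,
                                       "StudyDescription", series.study_description):
                    store.insert_value(ValueRecord(
                        patient_id=linkage.patient_id,
                        encounter_id=linkage.encounter_id,
                        document_id=linkage.document_id,
                        concept_id="StudyDescription",
                        value=series.study_description,
                    ))
                    summary.rows += 1
    return summary
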