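"""Extended entity-attribute-value (EAV) store with four grouping levels.

The warehouse stores every fact as one row of a single relational value
table: entity keys (patient, and optionally encounter, document, group),
a concept identifier, and a typed value.  The four grouping levels form a
strict hierarchy

    patient > encounter > document > group

and a value may be anchored at any depth.  Two irregular shapes occur in
practice and are first-class here:

* a value anchored to a patient only (no encounter/document/group);
* an *orphan* imaging document: a value with a document (and group) but a
  null encounter, which arises when a DICOM study carries no accession
  number that resolves to a radiology report.

Absent levels are stored as SQL NULL, never as an empty string, so that
identifier joins can never accidentally match on "".
"""

from __future__ import annotations

import csv
import datetime as _dt
import sqlite3
from dataclasses import dataclass, field, replace
from typing import Iterable, Iterator, Mapping, Optional, Sequence

__all__ = [
    "LEVELS",
    "Concept",
    "ValueRecord",
    "ScopeKey",
    "EAVStore",
    "ConceptConflictError",
    "UnknownConceptError",
    "ValidationError",
    "distinct_count",
    "distinct_keys",
]

#: Grouping levels ordered from most comprehensive to most restrictive.
LEVELS: tuple[str, ...] = ("patient", "encounter", "document", "group")

_LEVEL_DEPTH: dict[str, int] = {name: i + 1 for i, name in enumerate(LEVELS)}

VALUE_KINDS = ("numeric", "text", "code", "date")
DOMAINS = ("clinical", "imaging")


class ConceptConflictError(ValueError):
    """A concept id is re-registered with a different definition."""


class UnknownConceptError(KeyError):
    """A value references a concept id that was never registered."""


class ValidationError(ValueError):
    """A record violates the EAV model's structural invariants."""


def level_depth(level: str) -> int:
    try:
        return _LEVEL_DEPTH[level]
    except KeyError:
        raise ValueError(f"unknown grouping level {level!r}; expected one of {LEVELS}")


@dataclass(frozen=True)
class Concept:
    """Metadata of one attribute in the concept dictionary."""

    concept_id: str
    name: str = ""
    value_kind: str = "text"
    domain: str = "clinical"
    unit: Optional[str] = None

    def __post_init__(self) -> None:
        if not self.concept_id:
            raise ValidationError("concept_id must be non-empty")
        if self.value_kind not in VALUE_KINDS:
            raise ValidationError(
                f"value_kind {self.value_kind!r} not in {VALUE_KINDS}"
            )
        if self.domain not in DOMAINS:
            raise ValidationError(f"domain {self.domain!r} not in {DOMAINS}")
        if not self.name:
            object.__setattr__(self, "name", self.concept_id)


@dataclass(frozen=True)
class ValueRecord:
    """One EAV row: a concept's value anchored at up to four levels."""

    patient_id: str
    concept_id: str
    value: object
    encounter_id: Optional[str] = None
    document_id: Optional[str] = None
    group_id: Optional[str] = None
    observed_at: Optional[_dt.date] = None
    record_id: Optional[int] = None

    def scope_tuple(self) -> tuple[Optional[str], ...]:
        return (self.patient_id, self.encounter_id, self.document_id, self.group_id)

    def depth(self) -> int:
        """Index (1-based) of the deepest non-null level of this record."""
        t = self.scope_tuple()
        for i in range(4, 0, -1):
            if t[i - 1] is not None:
                return i
        return 1  # unreachable: patient_id is required

    def validate(self) -> None:
        if not self.patient_id:
            raise ValidationError("patient_id is required and must be non-empty")
        if self.group_id is not None and self.document_id is None:
            raise ValidationError(
                "group_id requires a document_id (a group always nests in a document)"
            )


@dataclass(frozen=True, order=True)
class ScopeKey:
    """An entity identifier at one grouping level.

    ``ids`` has exactly as many slots as the level is deep; an absent
    intermediate identifier (the orphan-encounter case) is an explicit
    ``None`` slot, never omitted.
    """

    level: str
    ids: tuple[Optional[str], ...]

    def __post_init__(self) -> None:
        d = level_depth(self.level)
        if len(self.ids) != d:
            raise ValidationError(
                f"ScopeKey at level {self.level!r} needs {d} id slots, got {len(self.ids)}"
            )
        if self.ids[0] is None:
            raise ValidationError("patient slot of a ScopeKey cannot be null")

    @property
    def patient_id(self) -> str:
        return self.ids[0]  # type: ignore[return-value]

    def parent(self) -> "ScopeKey":
        d = level_depth(self.level)
        if d == 1:
            raise ValueError("patient level has no parent")
        return ScopeKey(LEVELS[d - 2], self.ids[:-1])


def _record_key(record: ValueRecord, level: str) -> Optional[ScopeKey]:
    """The record's entity key at ``level``, or None if the record is not
    anchored that deep.

    A null slot forms part of a key only when some deeper slot is non-null
    (e.g. an orphan document yields the encounter key ``(P, None)``); a
    record whose anchoring simply stops above ``level`` has no key there.
    """
    d = level_depth(level)
    if record.depth() < d:
        return None
    return ScopeKey(level, record.scope_tuple()[:d])


def distinct_keys(level: str, records: Iterable[ValueRecord]) -> set[ScopeKey]:
    """Distinct entity keys at ``level`` among ``records``."""
    keys: set[ScopeKey] = set()
    for rec in records:
        key = _record_key(rec, level)
        if key is not None:
            keys.add(key)
    return keys


def distinct_count(level: str, records: Iterable[ValueRecord]) -> int:
    """Number of distinct entities at ``level`` among ``records``.

    This is the counting rule behind the per-level statistics table
    (#Patients, #Encounter, #Documents, #Groups).
    """
    return len(distinct_keys(level, records))


_SCHEMA = """
CREATE TABLE IF NOT EXISTS concept (
    concept_id TEXT PRIMARY KEY,
    name       TEXT NOT NULL,
    value_kind TEXT NOT NULL,
    domain     TEXT NOT NULL,
    unit       TEXT
);
CREATE TABLE IF NOT EXISTS value_row (
    record_id    INTEGER PRIMARY KEY AUTOINCREMENT,
    patient_id   TEXT NOT NULL,
    encounter_id TEXT,
    document_id  TEXT,
    group_id     TEXT,
    concept_id   TEXT NOT NULL REFERENCES concept(concept_id),
    value        BLOB,
    observed_at  TEXT
);
CREATE INDEX IF NOT EXISTS ix_value_patient ON value_row(patient_id);
CREATE INDEX IF NOT EXISTS ix_value_pat_enc ON value_row(patient_id, encounter_id);
CREATE INDEX IF NOT EXISTS ix_value_document ON value_row(document_id);
CREATE INDEX IF NOT EXISTS ix_value_group ON value_row(group_id);
CREATE INDEX IF NOT EXISTS ix_value_concept ON value_row(concept_id);
"""


class EAVStore:
    """Relational EAV warehouse: one value table plus a concept dictionary.

    Parameters
    ----------
    path
        SQLite database file, or ``":memory:"`` (default) for an
        in-memory store.

    Identifier comparison is exact, case-sensitive string equality
    throughout: DICOM UIDs and accession numbers are opaque keys.
    """

    def __init__(self, path: str = ":memory:") -> None:
        self._conn = sqlite3.connect(path)
        self._conn.executescript(_SCHEMA)
        self._concepts: dict[str, Concept] = {}
        for row in self._conn.execute(
            "SELECT concept_id, name, value_kind, domain, unit FROM concept"
        ):
            self._concepts[row[0]] = Concept(*row)

    # ------------------------------------------------------------------
    # concept dictionary
    # ------------------------------------------------------------------
    def register_concept(self, concept: Concept) -> str:
        """Register ``concept``; idempotent for an identical re-registration.

        Raises
        ------
        ConceptConflictError
            if the id exists with a different definition.
        """
        existing = self._concepts.get(concept.concept_id)
        if existing is not None:
            if existing != concept:
                raise ConceptConflictError(
                    f"concept {concept.concept_id!r} already registered as {existing}, "
                    f"conflicting with {concept}"
                )
            return concept.concept_id
        self._conn.execute(
            "INSERT INTO concept VALUES (?,?,?,?,?)",
            (concept.concept_id, concept.name, concept.value_kind,
             concept.domain, concept.unit),
        )
        self._concepts[concept.concept_id] = concept
        return concept.concept_id

    def get_concept(self, concept_id: str) -> Concept:
        try:
            return self._concepts[concept_id]
        except KeyError:
            raise UnknownConceptError(concept_id)

    def has_concept(self, concept_id: str) -> bool:
        return concept_id in self._concepts

    def concepts(self) -> list[Concept]:
        return sorted(self._concepts.values(), key=lambda c: c.concept_id)

    # ------------------------------------------------------------------
    # value rows
    # ------------------------------------------------------------------
    def _coerce_value(self, concept: Concept, value: object) -> object:
        kind = concept.value_kind
        if kind == "numeric":
            try:
                return float(value)  # type: ignore[arg-type]
            except (TypeError, ValueError):
                raise ValidationError(
                    f"concept {concept.concept_id!r} is numeric; got {value!r}"
                )
        if kind == "date":
            if isinstance(value, _dt.date):
                return value.isoformat()
            try:
                return _dt.date.fromisoformat(str(value)).isoformat()
            except ValueError:
                raise ValidationError(
                    f"concept {concept.concept_id!r} is a date; got {value!r}"
                )
        if value is None:
            raise ValidationError(
                f"null value for concept {concept.concept_id!r}"
            )
        return str(value)

    def insert_value(self, record: ValueRecord) -> int:
        """Insert one value row and return its surrogate record id."""
        record.validate()
        concept = self.get_concept(record.concept_id)
        value = self._coerce_value(concept, record.value)
        observed = record.observed_at.isoformat() if record.observed_at else None
        cur = self._conn.execute(
            "INSERT INTO value_row (patient_id, encounter_id, document_id, group_id,"
            " concept_id, value, observed_at) VALUES (?,?,?,?,?,?,?)",
            (record.patient_id, record.encounter_id, record.document_id,
             record.group_id, record.concept_id, value, observed),
        )
        return int(cur.lastrowid)

    def insert_values(self, records: Iterable[ValueRecord]) -> list[int]:
        return [self.insert_value(r) for r in records]

    def __len__(self) -> int:
        (n,) = self._conn.execute("SELECT COUNT(*) FROM value_row").fetchone()
        return int(n)

    def _row_to_record(self, row: Sequence) -> ValueRecord:
        record_id, pid, eid, did, gid, cid, value, observed = row
        concept = self.get_concept(cid)
        if concept.value_kind == "numeric" and value is not None:
            value = float(value)
        elif concept.value_kind == "date" and value is not None:
            value = _dt.date.fromisoformat(value)
        observed_at = _dt.date.fromisoformat(observed) if observed else None
        return ValueRecord(
            patient_id=pid, encounter_id=eid, document_id=did, group_id=gid,
            concept_id=cid, value=value, observed_at=observed_at,
            record_id=int(record_id),
        )

    def _fetch(
        self,
        patient_ids: Optional[set[str]] = None,
        concept_ids: Optional[set[str]] = None,
    ) -> Iterator[ValueRecord]:
        sql = ("SELECT record_id, patient_id, encounter_id, document_id, group_id,"
               " concept_id, value, observed_at FROM value_row")
        clauses, params = [], []
        if patient_ids is not None:
            if not patient_ids:
                return
            ids = sorted(patient_ids)
            clauses.append(f"patient_id IN ({','.join('?' * len(ids))})")
            params.extend(ids)
        if concept_ids is not None:
            if not concept_ids:
                return
            ids = sorted(concept_ids)
            clauses.append(f"concept_id IN ({','.join('?' * len(ids))})")
            params.extend(ids)
        if clauses:
            sql += " WHERE " + " AND ".join(clauses)
        for row in self._conn.execute(sql, params):
            yield self._row_to_record(row)

    def all_records(self) -> list[ValueRecord]:
        return list(self._fetch())

    def records_in_scope(
        self,
        level: str,
        entity_ids: Iterable[ScopeKey],
        concept_ids: Optional[set[str]] = None,
    ) -> Iterator[ValueRecord]:
        """Stream the records whose scope prefix at ``level`` matches one of
        ``entity_ids`` (exact match, so a null slot only matches a key that
        carries a null in that slot), optionally restricted to ``concept_ids``.
        """
        depth = level_depth(level)
        keys = set(entity_ids)
        for key in keys:
            if key.level != level:
                raise ValidationError(
                    f"scope key {key} is not at the requested level {level!r}"
                )
        if not keys:
            return iter(())
        wanted = {key.ids for key in keys}
        patients = {key.patient_id for key in keys}

        def _gen() -> Iterator[ValueRecord]:
            for rec in self._fetch(patient_ids=patients, concept_ids=concept_ids):
                if rec.scope_tuple()[:depth] in wanted:
                    yield rec

        return _gen()

    def children(self, level: str, entity_ids: Iterable[ScopeKey]) -> set[ScopeKey]:
        """Distinct scope keys at the next finer level occurring under
        ``entity_ids``; the cascade's level-to-level hand-off.
        """
        depth = level_depth(level)
        if depth == 4:
            raise ValueError("group is the finest level; it has no children")
        child_level = LEVELS[depth]
        return distinct_keys(child_level, self.records_in_scope(level, entity_ids))

    def entity_keys(self, level: str) -> set[ScopeKey]:
        """All distinct entity keys at ``level`` present in the store."""
        return distinct_keys(level, self._fetch())

    def has_value(
        self,
        patient_id: str,
        encounter_id: Optional[str],
        document_id: Optional[str],
        group_id: Optional[str],
        concept_id: str,
        value: object,
    ) -> bool:
        """True if a row with exactly this (scope, concept, value) exists.

        Used to give imaging ingestion (scope, concept, value) uniqueness,
        which makes a re-run over identical input a no-op.
        """
        concept = self.get_concept(concept_id)
        coerced = self._coerce_value(concept, value)
        clauses = ["patient_id = ?", "concept_id = ?", "value = ?"]
        params: list[object] = [patient_id, concept_id, coerced]
        for col, val in (("encounter_id", encounter_id),
                         ("document_id", document_id),
                         ("group_id", group_id)):
            if val is None:
                clauses.append(f"{col} IS NULL")
            else:
                clauses.append(f"{col} = ?")
                params.append(val)
        sql = "SELECT 1 FROM value_row WHERE " + " AND ".join(clauses) + " LIMIT 1"
        return self._conn.execute(sql, params).fetchone() is not None

    def patient_ids(self) -> set[str]:
        return {
            row[0]
            for row in self._conn.execute("SELECT DISTINCT patient_id FROM value_row")
        }

    # ------------------------------------------------------------------
    # flat-file dump/load
    # ------------------------------------------------------------------
    _CSV_COLUMNS = ("patient_id", "encounter_id", "document_id", "group_id",
                    "concept_id", "value_kind", "value", "observed_at")

    @staticmethod
    def _csv_cell(value: Optional[object]) -> str:
        if value is None:
            return r"\N"
        return str(value)

    @staticmethod
    def _csv_uncell(text: str) -> Optional[str]:
        return None if text == r"\N" else text

    def dump_csv(self, path: str) -> int:
        """Write the value table as CSV; ``\\N`` marks SQL null (distinct
        from an empty string).  Rows are sorted for reproducibility.
        """
        records = sorted(
            self.all_records(),
            key=lambda r: (r.scope_tuple()[0],
                           tuple(x or "" for x in r.scope_tuple()[1:]),
                           r.concept_id, str(r.value)),
        )
        with open(path, "w", newline="", encoding="utf-8") as fh:
            writer = csv.writer(fh, quoting=csv.QUOTE_MINIMAL)
            writer.writerow(self._CSV_COLUMNS)
            for rec in records:
                kind = self.get_concept(rec.concept_id).value_kind
                value = rec.value
                if isinstance(value, float) and value.is_integer():
                    value = int(value)
                writer.writerow([
                    self._csv_cell(rec.patient_id),
                    self._csv_cell(rec.encounter_id),
                    self._csv_cell(rec.document_id),
                    self._csv_cell(rec.group_id),
                    rec.concept_id,
                    kind,
                    self._csv_cell(value),
                    self._csv_cell(rec.observed_at.isoformat() if rec.observed_at else None),
                ])
        return len(records)

    def load_csv(self, path: str, domain: str = "clinical") -> int:
        """Load value rows from a dump produced by :meth:`dump_csv`,
        auto-registering unseen concepts with the dumped value kind.
        """
        n = 0
        with open(path, newline="", encoding="utf-8") as fh:
            reader = csv.DictReader(fh)
            for row in reader:
                cid = row["concept_id"]
                if not self.has_concept(cid):
                    self.register_concept(
                        Concept(cid, value_kind=row["value_kind"], domain=domain)
                    )
                observed = self._csv_uncell(row["observed_at"])
                self.insert_value(ValueRecord(
                    patient_id=self._csv_uncell(row["patient_id"]) or "",
                    encounter_id=self._csv_uncell(row["encounter_id"]),
                    document_id=self._csv_uncell(row["document_id"]),
                    group_id=self._csv_uncell(row["group_id"]),
                    concept_id=cid,
                    value=self._csv_uncell(row["value"]),
                    observed_at=_dt.date.fromisoformat(observed) if observed else None,
                ))
                n += 1
        return n

    def commit(self) -> None:
        """Flush pending writes to a file-backed database."""
        self._conn.commit()

    def close(self) -> None:
        self._conn.commit()
        self._conn.close()
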