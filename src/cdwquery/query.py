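"""Multilevel query language and cascade evaluator.

A single query carries one optional boolean condition tree per grouping
level plus an optional admission-date window, e.g.::

    ADMISSION: [2016-01-01, 2017-12-31]
    ENCOUNTER: NT-proBNP > 1000 AND ICD matches "^I50"
    DOCUMENT:  RadiologyOrder matches "CMR(A|B)" OR StudyDescription contains "cardiac"
    GROUP:     Modality == "MR"

Evaluation runs a cascade from the most comprehensive level (patient) to
the most restrictive (group): each level filters the *children* of the
previous level's selection, and a level without conditions simply passes
all children through.  Within one scope, ``AND`` is existential per
condition — two AND-ed conditions may be witnessed by two different
records of the scope.  Same-record co-occurrence is therefore expressed
by *lowering the level* (e.g. two laboratory values of one specimen are
constrained at the document level), which is the whole point of having
four levels.

Orphan imaging documents (null encounter) flow into the document level
only when the encounter level is completely unconstrained: an encounter
condition or date window can never be satisfied by a document that has
no encounter.
"""

from __future__ import annotations

import datetime as _dt
import json
import re
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Optional, Sequence, Union

from .clinical import ADMISSION_CONCEPT
from .store import (
    LEVELS,
    EAVStore,
    ScopeKey,
    ValueRecord,
    distinct_count,
    level_depth,
)

__all__ = [
    "Condition",
    "And",
    "Or",
    "ConditionExpr",
    "MultilevelQuery",
    "LevelSelection",
    "MultilevelResult",
    "LevelStatistics",
    "QueryParseError",
    "QueryTypeError",
    "UnsupportedFormatError",
    "parse_query",
    "render_query",
    "eval_expr",
    "evaluate",
    "summarize",
    "export_results",
]

OPERATORS = ("contains", "matches", "==", "!=", ">", ">=", "<", "<=", "exists")

_COMPARISONS = {"==", "!=", ">", ">=", "<", "<="}
_ORDERED = {">", ">=", "<", "<="}


class QueryParseError(ValueError):
    """Syntax error in the query language, with source location."""

    def __init__(self, message: str, line: int, column: int) -> None:
        super().__init__(f"line {line}, column {column}: {message}")
        self.line = line
        self.column = column


class QueryTypeError(TypeError):
    """Operator applied to a concept of an incompatible value kind."""


class UnsupportedFormatError(ValueError):
    """Unknown export format."""


# ----------------------------------------------------------------------
# condition trees
# ----------------------------------------------------------------------

@dataclass(frozen=True)
class Condition:
    """One atomic constraint: ``concept operator operand``.

    ``operand`` is a string for text/code/date concepts, a float for
    numeric concepts, and absent for ``exists``.
    """

    concept_id: str
    operator: str
    operand: Optional[object] = None

    def __post_init__(self) -> None:
        if self.operator not in OPERATORS:
            raise ValueError(f"unknown operator {self.operator!r}")
        if self.operator == "exists":
            if self.operand is not None:
                raise ValueError("'exists' takes no operand")
        elif self.operand is None:
            raise ValueError(f"operator {self.operator!r} requires an operand")


@dataclass(frozen=True)
class And:
    children: tuple["ConditionExpr", ...]

    def __post_init__(self) -> None:
        if len(self.children) < 2:
            raise ValueError("AND needs at least two children")


@dataclass(frozen=True)
class Or:
    children: tuple["ConditionExpr", ...]

    def __post_init__(self) -> None:
        if len(self.children) < 2:
            raise ValueError("OR needs at least two children")


ConditionExpr = Union[Condition, And, Or]


def expr_concepts(expr: Optional[ConditionExpr]) -> set[str]:
    if expr is None:
        return set()
    if isinstance(expr, Condition):
        return {expr.concept_id}
    out: set[str] = set()
    for child in expr.children:
        out |= expr_concepts(child)
    return out


@dataclass(frozen=True)
class MultilevelQuery:
    """Per-level condition trees plus an admission-date window."""

    patient: Optional[ConditionExpr] = None
    encounter: Optional[ConditionExpr] = None
    document: Optional[ConditionExpr] = None
    group: Optional[ConditionExpr] = None
    admission_window: Optional[tuple[Optional[_dt.date], Optional[_dt.date]]] = None
    export_level: str = "group"

    def __post_init__(self) -> None:
        level_depth(self.export_level)
        # an unbounded window constrains nothing: normalise it away so
        # that (-inf, +inf) is exactly a no-op
        if self.admission_window == (None, None):
            object.__setattr__(self, "admission_window", None)
        if self.admission_window is None and not any(
            self.expr_for(level) for level in LEVELS
        ):
            raise ValueError(
                "query must constrain at least one level or set an admission window"
            )

    def expr_for(self, level: str) -> Optional[ConditionExpr]:
        return getattr(self, level)


# ----------------------------------------------------------------------
# parser
# ----------------------------------------------------------------------

_LEVEL_KEYWORDS = {name.upper(): name for name in LEVELS}

_TOKEN_RE = re.compile(
    r"""
      (?P<WS>[ \t]+)
    | (?P<COMMENT>\#[^\n]*)
    | (?P<NL>\n)
    | (?P<STRING>"(?:\\.|[^"\\\n])*")
    | (?P<DATE>\d{4}-\d{2}-\d{2})
    | (?P<NUMBER>-?\d+(?:\.\d+)?(?:[eE][+-]?\d+)?)
    | (?P<IDENT>[A-Za-z_][A-Za-z0-9_.\-]*)
    | (?P<OP>==|!=|>=|<=|>|<)
    | (?P<PUNCT>[():\[\],*])
""",
    re.VERBOSE,
)


@dataclass(frozen=True)
class _Token:
    kind: str
    text: str
    line: int
    column: int


def _tokenize(text: str) -> list[_Token]:
    tokens: list[_Token] = []
    line, line_start = 1, 0
    pos = 0
    while pos < len(text):
        match = _TOKEN_RE.match(text, pos)
        if match is None:
            raise QueryParseError(
                f"unexpected character {text[pos]!r}", line, pos - line_start + 1
            )
        kind = match.lastgroup or ""
        column = pos - line_start + 1
        if kind == "NL":
            line += 1
            line_start = match.end()
        elif kind not in ("WS", "COMMENT"):
            tokens.append(_Token(kind, match.group(), line, column))
        pos = match.end()
    tokens.append(_Token("EOF", "", line, len(text) - line_start + 1))
    return tokens


class _Parser:
    def __init__(self, text: str) -> None:
        self.tokens = _tokenize(text)
        self.pos = 0

    def peek(self, offset: int = 0) -> _Token:
        return self.tokens[min(self.pos + offset, len(self.tokens) - 1)]

    def advance(self) -> _Token:
        token = self.tokens[self.pos]
        if token.kind != "EOF":
            self.pos += 1
        return token

    def error(self, message: str, token: Optional[_Token] = None) -> QueryParseError:
        token = token or self.peek()
        return QueryParseError(message, token.line, token.column)

    def expect(self, text: str) -> _Token:
        token = self.peek()
        if token.text != text:
            raise self.error(f"expected {text!r}, found {token.text or 'end of input'!r}")
        return self.advance()

    # -- grammar ----------------------------------------------------
    def parse(self) -> MultilevelQuery:
        window: Optional[tuple[Optional[_dt.date], Optional[_dt.date]]] = None
        exprs: dict[str, ConditionExpr] = {}
        while self.peek().kind != "EOF":
            token = self.peek()
            if token.kind != "IDENT":
                raise self.error(
                    f"expected a level header, found {token.text!r}"
                )
            keyword = token.text.upper()
            if keyword == "ADMISSION":
                if window is not None:
                    raise self.error("duplicate ADMISSION line")
                self.advance()
                self.expect(":")
                window = self._parse_window()
            elif keyword in _LEVEL_KEYWORDS:
                level = _LEVEL_KEYWORDS[keyword]
                if level in exprs:
                    raise self.error(f"duplicate {keyword} block")
                self.advance()
                self.expect(":")
                exprs[level] = self._parse_or()
            else:
                raise self.error(
                    f"expected PATIENT/ENCOUNTER/DOCUMENT/GROUP/ADMISSION, "
                    f"found {token.text!r}"
                )
        try:
            return MultilevelQuery(admission_window=window, **exprs)
        except ValueError as exc:
            raise QueryParseError(str(exc), 1, 1)

    def _parse_window(self) -> tuple[Optional[_dt.date], Optional[_dt.date]]:
        self.expect("[")
        start = self._parse_window_date()
        self.expect(",")
        end = self._parse_window_date()
        self.expect("]")
        return (start, end)

    def _parse_window_date(self) -> Optional[_dt.date]:
        token = self.peek()
        if token.text == "*":
            self.advance()
            return None
        if token.kind != "DATE":
            raise self.error(f"expected YYYY-MM-DD or '*', found {token.text!r}")
        self.advance()
        try:
            return _dt.date.fromisoformat(token.text)
        except ValueError:
            raise self.error(f"invalid calendar date {token.text!r}", token)

    def _parse_or(self) -> ConditionExpr:
        children = [self._parse_and()]
        while self.peek().text == "OR":
            self.advance()
            children.append(self._parse_and())
        if len(children) == 1:
            return children[0]
        flat: list[ConditionExpr] = []
        for child in children:
            flat.extend(child.children if isinstance(child, Or) else [child])
        return Or(tuple(flat))

    def _parse_and(self) -> ConditionExpr:
        children = [self._parse_factor()]
        while self.peek().text == "AND":
            self.advance()
            children.append(self._parse_factor())
        if len(children) == 1:
            return children[0]
        flat: list[ConditionExpr] = []
        for child in children:
            flat.extend(child.children if isinstance(child, And) else [child])
        return And(tuple(flat))

    def _parse_factor(self) -> ConditionExpr:
        if self.peek().text == "(":
            self.advance()
            expr = self._parse_or()
            self.expect(")")
            return expr
        return self._parse_condition()

    def _parse_condition(self) -> Condition:
        token = self.peek()
        if token.kind != "IDENT" or token.text in ("AND", "OR"):
            raise self.error(f"expected a concept identifier, found {token.text!r}")
        concept_id = self.advance().text
        op_token = self.peek()
        if op_token.text == "exists":
            self.advance()
            return Condition(concept_id, "exists")
        if op_token.text not in ("contains", "matches") and op_token.kind != "OP":
            raise self.error(
                f"expected an operator after {concept_id!r}, found {op_token.text!r}"
            )
        operator = self.advance().text
        return Condition(concept_id, operator, self._parse_literal())

    def _parse_literal(self) -> object:
        token = self.peek()
        if token.kind == "STRING":
            self.advance()
            return _unescape(token.text[1:-1])
        if token.kind == "DATE":
            self.advance()
            return token.text
        if token.kind == "NUMBER":
            self.advance()
            return float(token.text)
        raise self.error(
            f"expected a literal operand, found {token.text or 'end of input'!r}"
        )


def _unescape(body: str) -> str:
    out, i = [], 0
    escapes = {"n": "\n", "t": "\t", '"': '"', "\\": "\\"}
    while i < len(body):
        ch = body[i]
        if ch == "\\" and i + 1 < len(body):
            out.append(escapes.get(body[i + 1], body[i + 1]))
            i += 2
        else:
            out.append(ch)
            i += 1
    return "".join(out)


def _escape(text: str) -> str:
    return text.replace("\\", "\\\\").replace('"', '\\"').replace("\n", "\\n").replace("\t", "\\t")


def parse_query(text: str) -> MultilevelQuery:
    """Parse query text into a :class:`MultilevelQuery`.

    Syntax errors raise :class:`QueryParseError` carrying line/column.
    """
    if not text.strip():
        raise QueryParseError("empty query", 1, 1)
    return _Parser(text).parse()


def _render_literal(operand: object) -> str:
    if isinstance(operand, float):
        return str(int(operand)) if operand.is_integer() else repr(operand)
    text = str(operand)
    if re.fullmatch(r"\d{4}-\d{2}-\d{2}", text):
        return text
    return f'"{_escape(text)}"'


def _render_expr(expr: ConditionExpr, parent: str = "") -> str:
    if isinstance(expr, Condition):
        if expr.operator == "exists":
            return f"{expr.concept_id} exists"
        return f"{expr.concept_id} {expr.operator} {_render_literal(expr.operand)}"
    if isinstance(expr, And):
        body = " AND ".join(_render_expr(c, "AND") for c in expr.children)
        return body
    body = " OR ".join(_render_expr(c, "OR") for c in expr.children)
    return f"({body})" if parent == "AND" else body


def render_query(query: MultilevelQuery) -> str:
    """Render a query back to canonical text (reparses to an equal query)."""
    lines = []
    if query.admission_window is not None:
        start, end = query.admission_window
        lines.append(
            "ADMISSION: [%s, %s]"
            % (start.isoformat() if start else "*", end.isoformat() if end else "*")
        )
    for level in LEVELS:
        expr = query.expr_for(level)
        if expr is not None:
            lines.append(f"{level.upper()}: {_render_expr(expr)}")
    return "\n".join(lines) + "\n"


# ----------------------------------------------------------------------
# evaluation
# ----------------------------------------------------------------------

def _value_matches(condition: Condition, record: ValueRecord, kind: str) -> bool:
    op = condition.operator
    if op == "exists":
        return True
    value = record.value
    operand = condition.operand
    if op in ("contains", "matches"):
        if kind not in ("text", "code"):
            raise QueryTypeError(
                f"{op!r} requires a text or code concept; "
                f"{condition.concept_id!r} is {kind}"
            )
        text = str(value)
        if op == "contains":
            return str(operand).lower() in text.lower()
        return re.search(str(operand), text) is not None
    # comparison operators
    if kind == "numeric":
        try:
            left, right = float(value), float(operand)  # type: ignore[arg-type]
        except (TypeError, ValueError):
            return False
    elif kind == "date":
        left = value if isinstance(value, _dt.date) else _dt.date.fromisoformat(str(value))
        try:
            right = _dt.date.fromisoformat(str(operand))
        except ValueError:
            raise QueryTypeError(
                f"operand {operand!r} is not a date for concept {condition.concept_id!r}"
            )
    else:
        if op in _ORDERED:
            raise QueryTypeError(
                f"{op!r} requires a numeric or date concept; "
                f"{condition.concept_id!r} is {kind}"
            )
        left, right = str(value), str(operand)
    if op == "==":
        return left == right
    if op == "!=":
        return left != right
    if op == ">":
        return left > right
    if op == ">=":
        return left >= right
    if op == "<":
        return left < right
    return left <= right  # "<="


def _eval_tree(
    expr: ConditionExpr, records: Sequence[ValueRecord], store: EAVStore
) -> tuple[bool, list[ValueRecord]]:
    if isinstance(expr, Condition):
        kind = store.get_concept(expr.concept_id).value_kind
        witnesses = [
            rec for rec in records
            if rec.concept_id == expr.concept_id and _value_matches(expr, rec, kind)
        ]
        return (bool(witnesses), witnesses)
    results = [_eval_tree(child, records, store) for child in expr.children]
    if isinstance(expr, And):
        ok = all(flag for flag, _ in results)
    else:
        ok = any(flag for flag, _ in results)
    if not ok:
        return (False, [])
    witnesses_by_id: dict[int, ValueRecord] = {}
    for flag, recs in results:
        if flag:
            for rec in recs:
                witnesses_by_id[id(rec)] = rec
    return (True, list(witnesses_by_id.values()))


def eval_expr(
    expr: ConditionExpr, scope: ScopeKey, store: EAVStore
) -> tuple[bool, list[ValueRecord]]:
    """Evaluate a condition tree within one scope.

    A condition is true iff *some* record in the scope satisfies it
    (existential semantics); the returned records are the union of the
    witnesses of the conditions that contributed to the truth value.
    """
    records = list(
        store.records_in_scope(scope.level, [scope], expr_concepts(expr))
    )
    return _eval_tree(expr, records, store)


def _eval_keys(
    expr: Optional[ConditionExpr],
    level: str,
    keys: set[ScopeKey],
    store: EAVStore,
) -> tuple[set[ScopeKey], list[ValueRecord]]:
    """Filter ``keys`` by ``expr``; returns (passing keys, witness union).

    Batched: records for all keys are fetched once and grouped by scope
    prefix, which keeps the cascade linear in store size.
    """
    if expr is None:
        return (set(keys), [])
    depth = level_depth(level)
    by_key: dict[tuple, list[ValueRecord]] = {}
    for rec in store.records_in_scope(level, keys, expr_concepts(expr)):
        by_key.setdefault(rec.scope_tuple()[:depth], []).append(rec)
    selected: set[ScopeKey] = set()
    matched: list[ValueRecord] = []
    for key in keys:
        flag, witnesses = _eval_tree(expr, by_key.get(key.ids, []), store)
        if flag:
            selected.add(key)
            matched.extend(witnesses)
    return (selected, matched)


@dataclass
class LevelSelection:
    """One level's outcome: selected entities and witness records."""

    keys: set[ScopeKey] = field(default_factory=set)
    matched: list[ValueRecord] = field(default_factory=list)
    queried: bool = False


@dataclass
class MultilevelResult:
    """Per-level selections of one cascade run."""

    levels: dict[str, LevelSelection]
    query: MultilevelQuery

    def keys(self, level: str) -> set[ScopeKey]:
        return self.levels[level].keys

    def group_ids(self) -> set[str]:
        return {key.ids[3] for key in self.levels["group"].keys if key.ids[3]}


def _admission_dates(
    store: EAVStore, keys: set[ScopeKey]
) -> dict[tuple, list[_dt.date]]:
    dates: dict[tuple, list[_dt.date]] = {}
    for rec in store.records_in_scope("encounter", keys, {ADMISSION_CONCEPT}):
        value = rec.value
        if not isinstance(value, _dt.date):
            value = _dt.date.fromisoformat(str(value))
        dates.setdefault(rec.scope_tuple()[:2], []).append(value)
    return dates


def _in_window(
    dates: Iterable[_dt.date],
    window: tuple[Optional[_dt.date], Optional[_dt.date]],
) -> bool:
    start, end = window
    for date in dates:
        if (start is None or date >= start) and (end is None or date <= end):
            return True
    return False


def evaluate(query: MultilevelQuery, store: EAVStore) -> MultilevelResult:
    """Run the patient -> encounter -> document -> group cascade."""
    levels: dict[str, LevelSelection] = {}
    window = query.admission_window

    # patient level: all patients, filtered by the patient expression;
    # a date window additionally requires the patient to have an encounter
    patients = {ScopeKey("patient", (pid,)) for pid in store.patient_ids()}
    selected, matched = _eval_keys(query.patient, "patient", patients, store)
    if window is not None:
        with_encounter = {
            key.parent() for key in store.children("patient", selected)
            if key.ids[1] is not None
        }
        selected = {key for key in selected if key in with_encounter}
    levels["patient"] = LevelSelection(selected, matched, query.patient is not None)

    # encounter level: children of the selected patients; the orphan
    # pseudo-encounter (null slot) survives only a fully unconstrained level
    encounters = store.children("patient", levels["patient"].keys)
    constrained = query.encounter is not None or window is not None
    orphan_keys = {key for key in encounters if key.ids[1] is None}
    real_keys = encounters - orphan_keys
    selected, matched = _eval_keys(query.encounter, "encounter", real_keys, store)
    if window is not None:
        dates = _admission_dates(store, selected)
        selected = {
            key for key in selected if _in_window(dates.get(key.ids, ()), window)
        }
    if not constrained:
        selected |= orphan_keys
    levels["encounter"] = LevelSelection(
        selected, matched, query.encounter is not None
    )

    documents = store.children("encounter", levels["encounter"].keys)
    selected, matched = _eval_keys(query.document, "document", documents, store)
    levels["document"] = LevelSelection(
        selected, matched, query.document is not None
    )

    groups = store.children("document", levels["document"].keys)
    selected, matched = _eval_keys(query.group, "group", groups, store)
    levels["group"] = LevelSelection(selected, matched, query.group is not None)

    return MultilevelResult(levels, query)


# ----------------------------------------------------------------------
# statistics
# ----------------------------------------------------------------------

@dataclass
class AttributeStat:
    concept_id: str
    n_records: int
    n_unique: Optional[int]  # unique texts, for text/code attributes only


@dataclass
class LevelRow:
    level: str
    n_patients: int
    n_encounters: int
    n_documents: int
    n_groups: int
    n_values: int
    attributes: list[AttributeStat]


@dataclass
class LevelStatistics:
    """Per-level descriptive statistics of a query result.

    One row per queried level, in cascade order; counts are distinct
    entity counts over that level's matched (witness) records.
    """

    rows: list[LevelRow]

    def to_tsv(self) -> str:
        lines = ["level\tn_patients\tn_encounters\tn_documents\tn_groups\tn_values"
                 "\tattribute\tattr_records\tattr_unique"]
        for row in self.rows:
            base = (f"{row.level}\t{row.n_patients}\t{row.n_encounters}"
                    f"\t{row.n_documents}\t{row.n_groups}\t{row.n_values}")
            if not row.attributes:
                lines.append(base + "\t\t\t")
            for attr in row.attributes:
                unique = "" if attr.n_unique is None else str(attr.n_unique)
                lines.append(base + f"\t{attr.concept_id}\t{attr.n_records}\t{unique}")
        return "\n".join(lines) + "\n"

    def to_text(self) -> str:
        header = ("Level", "#Patients", "#Encounter", "#Documents", "#Groups",
                  "#Values", "#Values per attribute")
        table: list[tuple[str, ...]] = [header]
        for row in self.rows:
            attr_lines = []
            for attr in row.attributes:
                if attr.n_unique is not None:
                    attr_lines.append(f"{attr.concept_id} = {attr.n_unique} unique")
                else:
                    attr_lines.append(f"{attr.concept_id} = {attr.n_records}")
            table.append((
                row.level, str(row.n_patients), str(row.n_encounters),
                str(row.n_documents), str(row.n_groups), str(row.n_values),
                "; ".join(attr_lines),
            ))
        widths = [max(len(r[i]) for r in table) for i in range(len(header))]
        lines = []
        for i, r in enumerate(table):
            lines.append("  ".join(cell.ljust(widths[j]) for j, cell in enumerate(r)).rstrip())
            if i == 0:
                lines.append("  ".join("-" * w for w in widths))
        return "\n".join(lines) + "\n"


def summarize(result: MultilevelResult, store: EAVStore) -> LevelStatistics:
    """Descriptive statistics over the cascade result, one row per
    queried level (an unqueried level is not a row; a date window alone
    makes the encounter level a row).
    """
    query = result.query
    rows: list[LevelRow] = []
    for level in LEVELS:
        selection = result.levels[level]
        window_row = level == "encounter" and query.admission_window is not None
        if not selection.queried and not window_row:
            continue
        matched = selection.matched
        attrs: list[AttributeStat] = []
        for concept_id in sorted(expr_concepts(query.expr_for(level))):
            concept_records = [r for r in matched if r.concept_id == concept_id]
            kind = store.get_concept(concept_id).value_kind
            unique = (
                len({str(r.value) for r in concept_records})
                if kind in ("text", "code") else None
            )
            attrs.append(AttributeStat(concept_id, len(concept_records), unique))
        rows.append(LevelRow(
            level=level,
            n_patients=distinct_count("patient", matched),
            n_encounters=distinct_count("encounter", matched),
            n_documents=distinct_count("document", matched),
            n_groups=distinct_count("group", matched),
            n_values=len(matched),
            attributes=attrs,
        ))
    return LevelStatistics(rows)


def mean_series_per_study(n_series: int, n_studies: int) -> float:
    """Mean number of series per study, as printed in the statistics."""
    if n_studies <= 0:
        raise ValueError("n_studies must be positive")
    return round(n_series / n_studies, 1)


# ----------------------------------------------------------------------
# export
# ----------------------------------------------------------------------

_EXPORT_FORMATS = ("csv", "jsonl")


def _sort_key(ids: tuple) -> tuple:
    return tuple("" if x is None else str(x) for x in ids)


def export_results(
    result: MultilevelResult, level: str, fmt: str, path: str
) -> str:
    """Write the selected entities at ``level`` with their matched
    attribute values; deterministic (sorted) so repeated exports of one
    result are byte-identical.

    For the group level a companion ``<path>.manifest.json`` lists the
    selected Series Instance UIDs — the hand-off for bulk image
    retrieval from the PACS.
    """
    if fmt not in _EXPORT_FORMATS:
        raise UnsupportedFormatError(
            f"unknown format {fmt!r}; supported: {', '.join(_EXPORT_FORMATS)}"
        )
    depth = level_depth(level)
    selection = result.levels[level]
    id_columns = ("patient_id", "encounter_id", "document_id", "group_id")[:depth]

    by_key: dict[tuple, dict[str, set[str]]] = {key.ids: {} for key in selection.keys}
    for rec in selection.matched:
        prefix = rec.scope_tuple()[:depth]
        if prefix in by_key:
            value = rec.value
            if isinstance(value, float) and value.is_integer():
                value = int(value)
            by_key[prefix].setdefault(rec.concept_id, set()).add(str(value))
    concept_columns = sorted({c for attrs in by_key.values() for c in attrs})

    ordered = sorted(by_key, key=_sort_key)
    if fmt == "csv":
        import csv as _csv

        with open(path, "w", newline="", encoding="utf-8") as fh:
            writer = _csv.writer(fh)
            writer.writerow(list(id_columns) + concept_columns)
            for ids in ordered:
                row = ["" if x is None else x for x in ids]
                row += ["|".join(sorted(by_key[ids].get(c, ()))) for c in concept_columns]
                writer.writerow(row)
    else:
        with open(path, "w", encoding="utf-8") as fh:
            for ids in ordered:
                obj: dict[str, object] = dict(zip(id_columns, ids))
                for concept in concept_columns:
                    if concept in by_key[ids]:
                        obj[concept] = sorted(by_key[ids][concept])
                fh.write(json.dumps(obj, sort_keys=False) + "\n")

    if level == "group":
        manifest = {
            "series_instance_uids": sorted(
                key.ids[3] for key in selection.keys if key.ids[3]
            )
        }
        with open(path + ".manifest.json", "w", encoding="utf-8") as fh:
            json.dump(manifest, fh, indent=2, sort_keys=True)
            fh.write("\n")
    return path
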