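"""Independent brute-force reference for the cascade and single-level
joins, plus a random query generator.

The reference materialises every (patient, encounter, document, group)
tuple from the raw record list and filters with plain nested loops; it
shares no evaluation code with the engine it checks.
"""

from __future__ import annotations

import datetime as dt
import re

import numpy as np

from cdwquery.query import And, Condition, MultilevelQuery, Or

_LEVEL_DEPTH = {"patient": 1, "encounter": 2, "document": 3, "group": 4}


def _rows(store):
    return [
        (r.patient_id, r.encounter_id, r.document_id, r.group_id,
         r.concept_id, r.value)
        for r in store.all_records()
    ]


def _kinds(store):
    return {c.concept_id: c.value_kind for c in store.concepts()}


def _depth(row):
    for i in (4, 3, 2):
        if row[i - 1] is not None:
            return i
    return 1


def _as_date(value):
    return value if isinstance(value, dt.date) else dt.date.fromisoformat(str(value))


def _cond_ok(cond, kind, value):
    op = cond.operator
    if op == "exists":
        return True
    if op == "contains":
        return str(cond.operand).lower() in str(value).lower()
    if op == "matches":
        return re.search(str(cond.operand), str(value)) is not None
    if kind == "numeric":
        left, right = float(value), float(cond.operand)
    elif kind == "date":
        left, right = _as_date(value), _as_date(cond.operand)
    else:
        left, right = str(value), str(cond.operand)
    return {
        "==": left == right, "!=": left != right,
        ">": left > right, ">=": left >= right,
        "<": left < right, "<=": left <= right,
    }[op]


def _expr_ok(expr, rows, kinds):
    if isinstance(expr, Condition):
        return any(
            row[4] == expr.concept_id and _cond_ok(expr, kinds[expr.concept_id], row[5])
            for row in rows
        )
    if isinstance(expr, And):
        return all(_expr_ok(child, rows, kinds) for child in expr.children)
    return any(_expr_ok(child, rows, kinds) for child in expr.children)


def _in_window(dates, window):
    lo, hi = window
    return any(
        (lo is None or d >= lo) and (hi is None or d <= hi) for d in dates
    )


def _admissions(rows, p, e):
    return [
        _as_date(row[5]) for row in rows
        if row[0] == p and row[1] == e and row[4] == "AdmissionDate"
    ]


def brute_force_evaluate(query: MultilevelQuery, store):
    """Nested-loop cascade; returns per-level id-tuple selections."""
    rows, kinds = _rows(store), _kinds(store)
    window = query.admission_window

    sel_p = set()
    for p in sorted({row[0] for row in rows}):
        scope = [row for row in rows if row[0] == p]
        if query.patient is not None and not _expr_ok(query.patient, scope, kinds):
            continue
        if window is not None and not any(row[1] is not None for row in scope):
            continue
        sel_p.add((p,))

    sel_e = set()
    for p, e in {row[:2] for row in rows if (row[0],) in sel_p and _depth(row) >= 2}:
        if e is None:
            if query.encounter is None and window is None:
                sel_e.add((p, e))
            continue
        scope = [row for row in rows if row[:2] == (p, e)]
        if query.encounter is not None and not _expr_ok(query.encounter, scope, kinds):
            continue
        if window is not None and not _in_window(_admissions(rows, p, e), window):
            continue
        sel_e.add((p, e))

    sel_d = set()
    for doc in {row[:3] for row in rows if row[:2] in sel_e and _depth(row) >= 3}:
        scope = [row for row in rows if row[:3] == doc]
        if query.document is None or _expr_ok(query.document, scope, kinds):
            sel_d.add(doc)

    sel_g = set()
    for grp in {row[:4] for row in rows if row[:3] in sel_d and _depth(row) >= 4}:
        scope = [row for row in rows if row[:4] == grp]
        if query.group is None or _expr_ok(query.group, scope, kinds):
            sel_g.add(grp)

    return {"patient": sel_p, "encounter": sel_e, "document": sel_d, "group": sel_g}


def brute_force_single_join(query: MultilevelQuery, join_level: str, store):
    """Nested-loop single-level join; returns (entities, group tuples)."""
    rows, kinds = _rows(store), _kinds(store)
    depth = _LEVEL_DEPTH[join_level]
    window = query.admission_window
    exprs = [
        expr for expr in (query.patient, query.encounter, query.document, query.group)
        if expr is not None
    ]

    selected = set()
    for ent in {row[:depth] for row in rows if _depth(row) >= depth}:
        if window is not None:
            if join_level == "patient":
                encounters = {row[1] for row in rows
                              if row[0] == ent[0] and row[1] is not None}
                if not any(
                    _in_window(_admissions(rows, ent[0], e), window)
                    for e in encounters
                ):
                    continue
            else:
                if ent[1] is None or not _in_window(
                    _admissions(rows, ent[0], ent[1]), window
                ):
                    continue
        visible = [
            row for row in rows
            if row[:min(_depth(row), depth)] == ent[:min(_depth(row), depth)]
        ]
        if all(_expr_ok(expr, visible, kinds) for expr in exprs):
            selected.add(ent)

    groups = {row[:4] for row in rows if _depth(row) >= 4 and row[:depth] in selected}
    return selected, groups


# ----------------------------------------------------------------------
# random queries
# ----------------------------------------------------------------------

# concepts by the level their records are anchored at; a condition is
# only generated at (or below) its concept's native level, which is how
# these queries are written in practice
_POOLS = {
    "patient": (
        ("Sex", "code", ["M", "F"]),
        ("BirthYear", "numeric", (1935.0, 1995.0)),
    ),
    "encounter": (
        ("ICD", "code", ["I50", "I11", "I13", "I10", "E11.9"]),
        ("LVEF", "numeric", (25.0, 65.0)),
        ("NT-proBNP", "numeric", (200.0, 3000.0)),
        ("PhysicianLetter", "text", ["Herzinsuffizienz", "unauffaellig", "Aufnahme"]),
    ),
    "document": (
        ("RadiologyOrder", "text", ["CMRA", "CMRB", "CMR(A|B)", "CT20", "XR10"]),
        ("StudyDescription", "text", ["cardiac", "Thorax", "survey", "examination"]),
        ("RadiologyShortFinding", "text", ["abnormality", "recommended", "changes"]),
    ),
    "group": (
        ("Modality", "code", ["MR", "PR", "CT", "XA", "US"]),
        ("SeriesDescription", "text", ["cine", "presentation", "series"]),
    ),
}

_NUMERIC_OPS = (">", ">=", "<", "<=", "exists")
_CODE_OPS = ("==", "!=", "contains", "matches", "exists")
_TEXT_OPS = ("contains", "matches", "exists")


def _random_condition(rng: np.random.Generator, level: str) -> Condition:
    pool = _POOLS[level]
    concept, kind, values = pool[int(rng.integers(len(pool)))]
    if kind == "numeric":
        op = _NUMERIC_OPS[int(rng.integers(len(_NUMERIC_OPS)))]
        if op == "exists":
            return Condition(concept, "exists")
        lo, hi = values
        return Condition(concept, op, float(np.round(rng.uniform(lo, hi), 1)))
    ops = _CODE_OPS if kind == "code" else _TEXT_OPS
    op = ops[int(rng.integers(len(ops)))]
    if op == "exists":
        return Condition(concept, "exists")
    return Condition(concept, op, values[int(rng.integers(len(values)))])


def _random_expr(rng: np.random.Generator, level: str):
    n = 1 + int(rng.integers(3))
    conditions = tuple(_random_condition(rng, level) for _ in range(n))
    if n == 1:
        return conditions[0]
    return And(conditions) if rng.random() < 0.5 else Or(conditions)


def random_query(rng: np.random.Generator) -> MultilevelQuery:
    """A random multilevel query over the synthetic hospital's concepts."""
    exprs = {}
    for level in ("patient", "encounter", "document", "group"):
        if rng.random() < 0.5:
            exprs[level] = _random_expr(rng, level)
    window = None
    if rng.random() < 0.3:
        start = dt.date(2016, 1, 1) + dt.timedelta(days=int(rng.integers(0, 400)))
        end = start + dt.timedelta(days=int(rng.integers(30, 500)))
        window = (
            start if rng.random() < 0.8 else None,
            end if rng.random() < 0.8 else None,
        )
        if window == (None, None):
            window = None
    if not exprs and window is None:
        exprs["group"] = _random_expr(rng, "group")
    return MultilevelQuery(admission_window=window, **exprs)
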