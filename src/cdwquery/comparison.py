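"""Single-level join simulation and inflation reporting.

Systems without a group level (and often without a document level)
answer a combined clinical/imaging question by joining *all* conditions
at one grouping level and then taking every DICOM series that hangs off
the selected entities.  This module re-runs a multilevel query that way
and quantifies how much the coarser join inflates the series count, and
which modalities make up the excess — the evaluation device behind the
headline +45% / +112% / +573% numbers.

Join semantics: an entity at the join level sees every record on its
root-to-leaf path — records anchored above it at their own depth (a
flattened row carries its ancestors' attributes) plus all records below
it.  Every condition of the query, from every level, must hold
existentially over that visible set; the group level is *not* re-filtered
afterwards, which is precisely what a single-level system cannot do.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional

from .store import EAVStore, ScopeKey, distinct_keys, level_depth
from .query import (
    MultilevelQuery,
    MultilevelResult,
    _admission_dates,
    _eval_tree,
    _in_window,
    evaluate,
    expr_concepts,
)

__all__ = [
    "SingleLevelResult",
    "ComparisonReport",
    "UndefinedInflationError",
    "single_level_join",
    "compare",
    "inflation_pct",
]


class UndefinedInflationError(ZeroDivisionError):
    """Inflation is undefined when the multilevel result is empty."""


@dataclass
class SingleLevelResult:
    """Outcome of joining all query conditions at one level."""

    join_level: str
    entities: set[ScopeKey]
    groups: set[ScopeKey]
    modality_histogram: dict[str, int]


@dataclass
class ComparisonReport:
    """Multilevel vs single-level-join group counts and the excess mix."""

    join_level: str
    n_groups_multilevel: int
    n_groups_single: int
    inflation_pct: int
    #: modality -> percentage share of the excess (single minus multilevel)
    excess_modality_distribution: dict[str, float]
    excess_modality_counts: dict[str, int] = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "join_level": self.join_level,
            "n_groups_multilevel": self.n_groups_multilevel,
            "n_groups_single": self.n_groups_single,
            "inflation_pct": self.inflation_pct,
            "excess_modality_distribution": self.excess_modality_distribution,
            "excess_modality_counts": self.excess_modality_counts,
        }

    def to_text(self) -> str:
        lines = [
            f"join level:            {self.join_level}",
            f"groups (multilevel):   {self.n_groups_multilevel}",
            f"groups (single join):  {self.n_groups_single}",
            f"inflation:             +{self.inflation_pct}%",
        ]
        if self.excess_modality_distribution:
            lines.append("excess modality mix:")
            for modality, share in sorted(
                self.excess_modality_distribution.items(),
                key=lambda item: (-item[1], item[0]),
            ):
                count = self.excess_modality_counts.get(modality, 0)
                lines.append(f"  {modality:<8} {share:5.1f}%  ({count})")
        return "\n".join(lines) + "\n"


def inflation_pct(n_multilevel: int, n_single: int) -> int:
    """Percentage by which the single-level count exceeds the multilevel
    count, rounded to the nearest integer (half away from zero).
    """
    if n_multilevel <= 0:
        raise UndefinedInflationError(
            "inflation is undefined for an empty multilevel result"
        )
    raw = 100.0 * (n_single - n_multilevel) / n_multilevel
    return int(math.floor(raw + 0.5))


def _visible_index(records, max_depth: int):
    """Index records by scope prefix of length min(depth, max_depth)."""
    index: dict[int, dict[tuple, list]] = {k: {} for k in range(1, max_depth + 1)}
    for rec in records:
        k = min(rec.depth(), max_depth)
        index[k].setdefault(rec.scope_tuple()[:k], []).append(rec)
    return index


def single_level_join(
    query: MultilevelQuery, join_level: str, store: EAVStore
) -> SingleLevelResult:
    """Evaluate every condition of ``query`` jointly at ``join_level`` and
    return all group-level children of the passing entities.

    The admission window is applied as the encounter-scoped condition it
    is: at encounter/document joins the entity's own encounter must be
    admitted in the window (orphan entities with a null encounter fail);
    at a patient join the patient merely needs *some* encounter in the
    window.
    """
    depth = level_depth(join_level)
    if depth >= 4:
        raise ValueError(
            "joining at the group level is the multilevel query itself; "
            "use patient, encounter or document"
        )
    entities = store.entity_keys(join_level)
    exprs = [
        expr for expr in (query.patient, query.encounter, query.document, query.group)
        if expr is not None
    ]
    concepts: set[str] = set()
    for expr in exprs:
        concepts |= expr_concepts(expr)

    patient_keys = {ScopeKey("patient", (pid,)) for pid in store.patient_ids()}
    relevant = list(store.records_in_scope("patient", patient_keys, concepts))
    index = _visible_index(relevant, depth)

    window = query.admission_window
    window_ok: Optional[set[tuple]] = None
    if window is not None:
        encounter_keys = {
            key for key in store.entity_keys("encounter") if key.ids[1] is not None
        }
        dates = _admission_dates(store, encounter_keys)
        window_ok = {
            ids for ids, ds in dates.items() if _in_window(ds, window)
        }

    selected: set[ScopeKey] = set()
    for entity in entities:
        if window_ok is not None:
            if join_level == "patient":
                if not any(ids[0] == entity.ids[0] for ids in window_ok):
                    continue
            else:
                if entity.ids[1] is None or entity.ids[:2] not in window_ok:
                    continue
        visible: list = []
        for k in range(1, depth + 1):
            visible.extend(index[k].get(entity.ids[:k], ()))
        if all(_eval_tree(expr, visible, store)[0] for expr in exprs):
            selected.add(entity)

    groups = distinct_keys(
        "group", store.records_in_scope(join_level, selected)
    )
    histogram: dict[str, int] = {}
    for modality in _group_modalities(store, groups).values():
        histogram[modality] = histogram.get(modality, 0) + 1
    return SingleLevelResult(join_level, selected, groups, histogram)


def _group_modalities(store: EAVStore, groups: set[ScopeKey]) -> dict[ScopeKey, str]:
    modality: dict[ScopeKey, str] = {key: "UNKNOWN" for key in groups}
    for rec in store.records_in_scope("group", groups, {"Modality"}):
        modality[ScopeKey("group", rec.scope_tuple())] = str(rec.value)
    return modality


def compare(
    query: MultilevelQuery,
    store: EAVStore,
    join_level: str,
    multilevel: Optional[MultilevelResult] = None,
) -> ComparisonReport:
    """Quantify how a single-level join inflates the group-level result.

    ``inflation_pct`` is ``100 x (n_single - n_multilevel) / n_multilevel``
    rounded to the nearest integer; the excess distribution covers the
    groups the coarse join returns beyond the multilevel result and sums
    to 100% (up to float rounding) whenever the excess is non-empty.
    """
    if multilevel is None:
        multilevel = evaluate(query, store)
    multi_groups = multilevel.levels["group"].keys
    single = single_level_join(query, join_level, store)
    n_multi = len(multi_groups)
    n_single = len(single.groups)
    excess = single.groups - multi_groups
    counts: dict[str, int] = {}
    for modality in _group_modalities(store, excess).values():
        counts[modality] = counts.get(modality, 0) + 1
    total = sum(counts.values())
    distribution = {
        modality: 100.0 * n / total for modality, n in sorted(counts.items())
    } if total else {}
    return ComparisonReport(
        join_level=join_level,
        n_groups_multilevel=n_multi,
        n_groups_single=n_single,
        inflation_pct=inflation_pct(n_multi, n_single),
        excess_modality_distribution=distribution,
        excess_modality_counts=counts,
    )
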