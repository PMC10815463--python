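"""Argumentation engine over scenario-table knowledge bases.

Matching a patient's findings against a table yields arguments: one per
(matched row, selected disease) pair.  Within a table, an argument from a
more specific scenario (a strict descendant row) is strictly stronger than
one from an ancestor row; arguments from different tables — or from rows on
different branches of one table — are incomparable.  Arguments for different
diseases are counterarguments of each other, and the dialectic keeps exactly
the diseases still supported at the most specific matched scenarios.

Findings are open-world: a term that is absent is unknown, not false, so
negative findings must be modelled as tokens of their own.

:func:`plausible_diagnoses` computes the surviving set directly from the
maximal matched rows of each table; :func:`oracle_plausible` recomputes it by
exhaustive enumeration of the attack relation and serves as an independent
check on small knowledge bases.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Literal, Union

from .knowledge_base import (
    ConditionTerm,
    DiagnosticTable,
    KnowledgeBase,
)

__all__ = [
    "FindingSet",
    "parse_findings",
    "Argument",
    "MatchResult",
    "Defeat",
    "DiagnosisResult",
    "match_rows",
    "build_arguments",
    "compare_strength",
    "plausible_diagnoses",
    "oracle_plausible",
    "OracleSizeError",
]

FindingSet = frozenset  # of ConditionTerm


def parse_findings(terms: Iterable[Union[str, ConditionTerm]]) -> frozenset[ConditionTerm]:
    """Build a finding set from raw strings and/or terms."""
    return frozenset(
        t if isinstance(t, ConditionTerm) else ConditionTerm.parse(t) for t in terms
    )


@dataclass(frozen=True)
class Argument:
    """A supporting argument: *disease* is selected in a matched row.

    ``lineage`` is the row-id chain from the table root down to the row;
    ``depth`` is its length, the strength rank within the table.
    """

    disease: str
    table_id: str
    row_id: str
    depth: int
    lineage: tuple[str, ...]


Strength = Literal["stronger", "weaker", "equal", "incomparable"]


def compare_strength(a: Argument, b: Argument) -> Strength:
    """Order two arguments by scenario specificity.

    Within one table an argument from a strict descendant row is stronger
    than one from any of that row's ancestors; two arguments from the same
    row are equal.  Rows on different branches, like rows of different
    tables, give incomparable arguments.
    """
    if a.table_id != b.table_id:
        return "incomparable"
    if a.row_id == b.row_id:
        return "equal"
    if b.row_id in a.lineage:
        return "stronger"
    if a.row_id in b.lineage:
        return "weaker"
    return "incomparable"


@dataclass(frozen=True)
class MatchResult:
    matched: frozenset[str]
    maximal: frozenset[str]


def match_rows(table: DiagnosticTable, findings: frozenset[ConditionTerm]) -> MatchResult:
    """Rows whose effective conditions are all satisfied, plus the maximal ones.

    A row matches iff every condition group on its root path is satisfied by
    the findings; since effective conditions accumulate down the tree, an
    unmatched row cannot have matched descendants, so the matched set is an
    ancestor-closed subtree and the maximal rows are its leaves.
    """
    matched: set[str] = set()
    root = table.root
    stack = [root]
    while stack:
        row = stack.pop()
        if all(g.satisfied_by(findings) for g in row.effective_conditions):
            matched.add(row.row_id)
            stack.extend(table.children(row.row_id))
    maximal = {
        rid
        for rid in matched
        if not any(child.row_id in matched for child in table.children(rid))
    }
    return MatchResult(matched=frozenset(matched), maximal=frozenset(maximal))


def build_arguments(
    kb: KnowledgeBase, findings: frozenset[ConditionTerm]
) -> list[Argument]:
    """One argument per (matched row, selected disease) pair, across all tables."""
    args: list[Argument] = []
    for table in sorted(kb.tables, key=lambda t: t.table_id):
        result = match_rows(table, findings)
        for row in table.rows:
            if row.row_id not in result.matched:
                continue
            lineage = table.lineage(row.row_id)
            for disease in sorted(row.selected):
                args.append(
                    Argument(
                        disease=disease,
                        table_id=table.table_id,
                        row_id=row.row_id,
                        depth=row.depth,
                        lineage=lineage,
                    )
                )
    return args


@dataclass(frozen=True)
class Defeat:
    disease: str
    table_id: str
    defeating_row_id: str
    reason: str  # "outranked" | "overridden-elsewhere"


@dataclass(frozen=True)
class DiagnosisResult:
    plausible: frozenset[str]
    winning_arguments: dict[str, tuple[Argument, ...]]
    defeats: tuple[Defeat, ...]
    matched_rows: dict[str, MatchResult]

    def to_dict(self) -> dict:
        return {
            "plausible": sorted(self.plausible),
            "winning_arguments": {
                d: [
                    {"table_id": a.table_id, "row_id": a.row_id, "depth": a.depth}
                    for a in args
                ]
                for d, args in sorted(self.winning_arguments.items())
            },
            "defeats": [
                {
                    "disease": d.disease,
                    "table_id": d.table_id,
                    "defeating_row_id": d.defeating_row_id,
                    "reason": d.reason,
                }
                for d in self.defeats
            ],
            "matched_rows": {
                tid: {"matched": sorted(m.matched), "maximal": sorted(m.maximal)}
                for tid, m in sorted(self.matched_rows.items())
            },
        }


def plausible_diagnoses(
    kb: KnowledgeBase, findings: frozenset[ConditionTerm]
) -> DiagnosisResult:
    """Dialectic selection of the plausible-diagnosis set.

    Each table with at least one matched row delivers a verdict: the union
    of the selected sets of its maximal matched rows.  A disease selected
    only in non-maximal rows of a table is defeated there — a more specific
    scenario dropped it.  Tables are incomparable, so the global plausible
    set is the union of the per-table verdicts; a disease defeated in one
    table but vindicated by another is kept, with its defeat recorded as
    ``overridden-elsewhere`` for transparency.
    """
    verdicts: dict[str, frozenset[str]] = {}
    matched_rows: dict[str, MatchResult] = {}
    table_defeats: list[tuple[str, str, str]] = []  # (disease, table_id, defeating row)
    for table in sorted(kb.tables, key=lambda t: t.table_id):
        result = match_rows(table, findings)
        if not result.matched:
            continue
        matched_rows[table.table_id] = result
        verdict = frozenset().union(
            *(table.row(rid).selected for rid in result.maximal)
        )
        verdicts[table.table_id] = verdict
        for row in table.rows:
            if row.row_id not in result.matched:
                continue
            losers = row.selected - verdict
            if not losers:
                continue
            # The defeating row: the deepest maximal matched descendant.
            beaters = [
                table.row(rid)
                for rid in result.maximal
                if row.row_id in table.lineage(rid) and rid != row.row_id
            ]
            if not beaters:  # row itself maximal: losers impossible here
                continue
            beater = max(beaters, key=lambda r: (r.depth, r.row_id))
            for disease in sorted(losers):
                table_defeats.append((disease, table.table_id, beater.row_id))

    plausible = frozenset().union(*verdicts.values()) if verdicts else frozenset()

    winning: dict[str, tuple[Argument, ...]] = {}
    for disease in sorted(plausible):
        args: list[Argument] = []
        for tid in sorted(verdicts):
            table = kb.table(tid)
            for rid in sorted(matched_rows[tid].maximal):
                row = table.row(rid)
                if disease in row.selected:
                    args.append(
                        Argument(
                            disease=disease,
                            table_id=tid,
                            row_id=rid,
                            depth=row.depth,
                            lineage=table.lineage(rid),
                        )
                    )
        winning[disease] = tuple(args)

    seen: set[tuple[str, str, str]] = set()
    defeats: list[Defeat] = []
    for disease, tid, beater in table_defeats:
        key = (disease, tid, beater)
        if key in seen:
            continue
        seen.add(key)
        reason = "overridden-elsewhere" if disease in plausible else "outranked"
        defeats.append(Defeat(disease, tid, beater, reason))

    return DiagnosisResult(
        plausible=plausible,
        winning_arguments=winning,
        defeats=tuple(defeats),
        matched_rows=matched_rows,
    )


class OracleSizeError(ValueError):
    """The knowledge base exceeds the brute-force oracle's size bound."""


_ORACLE_MAX_TABLES = 8
_ORACLE_MAX_ROWS = 6


def oracle_plausible(
    kb: KnowledgeBase, findings: frozenset[ConditionTerm]
) -> frozenset[str]:
    """Plausible diagnoses by explicit enumeration of the attack relation.

    Builds every argument, then the full attack relation (arguments for
    different diseases attack each other; an attack strictly defeats its
    target iff the attacker is strictly stronger).  A disease is plausible
    iff at least one of its arguments has no strictly stronger attacker.
    Intentionally quadratic and restricted to small knowledge bases.
    """
    if len(kb.tables) > _ORACLE_MAX_TABLES or any(
        len(t.rows) > _ORACLE_MAX_ROWS for t in kb.tables
    ):
        raise OracleSizeError(
            f"oracle accepts at most {_ORACLE_MAX_TABLES} tables of "
            f"{_ORACLE_MAX_ROWS} rows each"
        )
    args = build_arguments(kb, findings)
    survivors: set[str] = set()
    for a in args:
        defeated = any(
            b.disease != a.disease and compare_strength(b, a) == "stronger"
            for b in args
        )
        if not defeated:
            survivors.add(a.disease)
    return frozenset(survivors)
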