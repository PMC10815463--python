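"""Explanations for diagnoses and guidance on what to ask next.

An explanation unravels the argument behind a verdict: for a plausible
disease, the scenario conditions of its winning row plus the deeper, not yet
established conditions that would strengthen it; for a defeated disease, the
more specific matched scenario that dropped it; for a disease no matched
table mentions, an explicit "no evidence" verdict.

Guidance enumerates the condition groups sitting one-or-more levels below
the currently maximal matched rows — the questions whose answers could
refine the differential — and ranks them by how much they could shrink the
plausible set in the worst case over each group's alternatives.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

from .engine import DiagnosisResult, plausible_diagnoses
from .knowledge_base import ConditionGroup, ConditionTerm, KnowledgeBase

__all__ = ["Explanation", "GuidanceItem", "explain", "candidate_queries"]


@dataclass(frozen=True)
class RowRef:
    table_id: str
    row_id: str
    conditions: tuple[ConditionGroup, ...]


@dataclass(frozen=True)
class Strengthener:
    table_id: str
    row_id: str
    condition_group: ConditionGroup


@dataclass(frozen=True)
class Explanation:
    disease: str
    verdict: str  # "plausible" | "defeated" | "no-evidence"
    supporting: Optional[RowRef]
    strengtheners: tuple[Strengthener, ...]
    defeated_by: Optional[RowRef]

    def to_dict(self) -> dict:
        def ref(r: Optional[RowRef]):
            if r is None:
                return None
            return {
                "table_id": r.table_id,
                "row_id": r.row_id,
                "conditions": [g.render() for g in r.conditions],
            }

        return {
            "disease": self.disease,
            "verdict": self.verdict,
            "supporting": ref(self.supporting),
            "strengtheners": [
                {
                    "table_id": s.table_id,
                    "row_id": s.row_id,
                    "condition": s.condition_group.render(),
                }
                for s in self.strengtheners
            ],
            "defeated_by": ref(self.defeated_by),
        }

    def render_text(self) -> str:
        if self.verdict == "plausible":
            assert self.supporting is not None
            conds = ", ".join(g.render() for g in self.supporting.conditions)
            line = (
                f"PLAUSIBLE: {self.disease} because {conds} "
                f"({self.supporting.table_id}/{self.supporting.row_id})"
            )
            if self.strengtheners:
                extra = ", ".join(s.condition_group.render() for s in self.strengtheners)
                line += f"; would be strengthened by {extra}"
            return line
        if self.verdict == "defeated":
            assert self.defeated_by is not None
            conds = ", ".join(g.render() for g in self.defeated_by.conditions)
            return (
                f"DEFEATED: {self.disease} — a more specific scenario applies: {conds} "
                f"({self.defeated_by.table_id}/{self.defeated_by.row_id})"
            )
        return f"NO EVIDENCE: {self.disease} is not mentioned by any matched table"


def explain(
    kb: KnowledgeBase,
    findings: frozenset[ConditionTerm],
    result: DiagnosisResult,
    disease: str,
) -> Explanation:
    """Explain the verdict on one registry disease under the given findings."""
    if disease not in kb.registry_codes:
        raise KeyError(f"unknown disease code {disease!r}")

    if disease in result.plausible:
        args = result.winning_arguments.get(disease, ())
        best = max(args, key=lambda a: (a.depth, a.table_id, a.row_id))
        table = kb.table(best.table_id)
        row = table.row(best.row_id)
        strengtheners: list[Strengthener] = []
        seen: set[tuple[str, ConditionGroup]] = set()
        for arg in args:
            t = kb.table(arg.table_id)
            matched = result.matched_rows[arg.table_id].matched
            for desc in t.descendants(arg.row_id):
                if desc.row_id in matched or disease not in desc.selected:
                    continue
                for g in desc.effective_conditions:
                    if g.satisfied_by(findings):
                        continue
                    key = (arg.table_id, g)
                    if key in seen:
                        continue
                    seen.add(key)
                    strengtheners.append(Strengthener(arg.table_id, desc.row_id, g))
        strengtheners.sort(key=lambda s: (s.table_id, s.row_id, s.condition_group.render()))
        return Explanation(
            disease=disease,
            verdict="plausible",
            supporting=RowRef(best.table_id, best.row_id, row.effective_conditions),
            strengtheners=tuple(strengtheners),
            defeated_by=None,
        )

    defeats = [d for d in result.defeats if d.disease == disease]
    if defeats:
        # Report the strongest defeating scenario.
        def beater_depth(d):
            return kb.table(d.table_id).row(d.defeating_row_id).depth

        top = max(defeats, key=lambda d: (beater_depth(d), d.table_id, d.defeating_row_id))
        row = kb.table(top.table_id).row(top.defeating_row_id)
        return Explanation(
            disease=disease,
            verdict="defeated",
            supporting=None,
            strengtheners=(),
            defeated_by=RowRef(top.table_id, top.defeating_row_id, row.effective_conditions),
        )

    return Explanation(
        disease=disease,
        verdict="no-evidence",
        supporting=None,
        strengtheners=(),
        defeated_by=None,
    )


@dataclass(frozen=True)
class GuidanceItem:
    condition_group: ConditionGroup
    tables_affected: tuple[str, ...]
    discrimination: int
    rank: int

    def to_dict(self) -> dict:
        return {
            "condition": self.condition_group.render(),
            "tables_affected": list(self.tables_affected),
            "discrimination": self.discrimination,
            "rank": self.rank,
        }


def candidate_queries(
    kb: KnowledgeBase, findings: frozenset[ConditionTerm]
) -> list[GuidanceItem]:
    """Unsatisfied conditions worth establishing next, most discriminating first.

    Collects every unsatisfied condition group appearing in an unmatched
    descendant of a maximal matched row.  Discrimination is conservative:
    current plausible-set size minus the worst-case (largest) plausible set
    over the group's alternatives, floored at zero.  Ties are broken by the
    canonical rendering of the group.  Empty when every matched table is
    already matched at a leaf.
    """
    result = plausible_diagnoses(kb, findings)
    now = len(result.plausible)
    candidates: dict[ConditionGroup, set[str]] = {}
    for tid, match in result.matched_rows.items():
        table = kb.table(tid)
        for rid in match.maximal:
            for desc in table.descendants(rid):
                if desc.row_id in match.matched:
                    continue
                for g in desc.effective_conditions:
                    if g.satisfied_by(findings):
                        continue
                    candidates.setdefault(g, set()).add(tid)

    items: list[GuidanceItem] = []
    for group, tables in candidates.items():
        worst = 0
        for alt in group.alternatives:
            size = len(plausible_diagnoses(kb, findings | {alt}).plausible)
            worst = max(worst, size)
        items.append(
            GuidanceItem(
                condition_group=group,
                tables_affected=tuple(sorted(tables)),
                discrimination=max(0, now - worst),
                rank=0,
            )
        )
    items.sort(key=lambda i: (-i.discrimination, i.condition_group.render()))
    return [
        GuidanceItem(i.condition_group, i.tables_affected, i.discrimination, rank)
        for rank, i in enumerate(items, start=1)
    ]
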