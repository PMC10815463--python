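"""Closeness-accuracy metric and phased cohort evaluation.

The system's differential diagnosis is compared with an expert's at three
cumulative information stages of a patient visit — first suspicions, initial
diagnosis, final diagnosis.  With s = |system set|, e = |expert set|,
c = |system ∩ expert| and D = size of the disease universe, the score is

    accuracy = (c / e) * ((D - |s - e|) / D)

i.e. recall against the expert's set, penalized by the size mismatch between
the two differentials relative to the universe.  It is 1 exactly when the
sets coincide, and near zero when the system proposes everything while the
expert proposes one disease.

Cohort input/output uses JSON Lines, one patient case per line.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from enum import IntEnum
from typing import Iterable, Optional, Sequence

from .engine import plausible_diagnoses
from .knowledge_base import ConditionTerm, KnowledgeBase

__all__ = [
    "Phase",
    "PatientCase",
    "AccuracyRecord",
    "CohortSummary",
    "closeness_accuracy",
    "evaluate_case",
    "evaluate_cohort",
    "summarize_cohort",
    "case_to_dict",
    "case_from_dict",
    "read_cohort_jsonl",
    "write_cohort_jsonl",
]


class Phase(IntEnum):
    FIRST_SUSPICIONS = 1
    INITIAL_DIAGNOSIS = 2
    FINAL_DIAGNOSIS = 3


def closeness_accuracy(s: int, e: int, c: int, D: int) -> float:
    """Score a system differential against an expert differential.

    Raises ``ValueError`` if the expert set is empty (the comparison is
    undefined) or the counts are inconsistent.
    """
    if D < 1:
        raise ValueError("disease universe D must be >= 1")
    if e == 0:
        raise ValueError("expert gave no diagnosis: comparison undefined")
    if not (0 <= c <= min(s, e)):
        raise ValueError(f"need 0 <= c <= min(s, e), got s={s}, e={e}, c={c}")
    if s > D or e > D:
        raise ValueError(f"set sizes cannot exceed D={D}, got s={s}, e={e}")
    return (c / e) * ((D - abs(s - e)) / D)


@dataclass(frozen=True)
class PatientCase:
    """Phased findings plus the expert's differential at each phase.

    Findings are cumulative: each phase contains the previous phase's terms.
    ``target`` is the ground-truth disease for synthetic cases.
    """

    case_id: str
    group: str
    findings: tuple[frozenset[ConditionTerm], ...]  # one per phase, cumulative
    expert: tuple[frozenset[str], ...]  # expert diagnosis codes per phase
    target: Optional[str] = None

    def __post_init__(self) -> None:
        if len(self.findings) != len(Phase) or len(self.expert) != len(Phase):
            raise ValueError("a case needs findings and expert sets for all three phases")
        for earlier, later in zip(self.findings, self.findings[1:]):
            if not earlier <= later:
                raise ValueError(
                    f"case {self.case_id!r}: findings must accumulate across phases"
                )


@dataclass(frozen=True)
class AccuracyRecord:
    case_id: str
    phase: Phase
    s: int
    e: int
    c: int
    D: int
    accuracy: float
    group: Optional[str] = None

    def to_dict(self) -> dict:
        return {
            "case_id": self.case_id,
            "phase": int(self.phase),
            "s": self.s,
            "e": self.e,
            "c": self.c,
            "D": self.D,
            "accuracy": self.accuracy,
            "group": self.group,
        }


def evaluate_case(kb: KnowledgeBase, case: PatientCase) -> list[AccuracyRecord]:
    """Run the engine on each phase's findings and score against the expert.

    A phase with an empty expert set is skipped with a warning — the
    comparison is undefined there.
    """
    records: list[AccuracyRecord] = []
    for phase in Phase:
        expert = case.expert[phase - 1]
        if not expert:
            warnings.warn(
                f"case {case.case_id!r}: empty expert set at phase {phase.name}; skipped",
                stacklevel=2,
            )
            continue
        system = plausible_diagnoses(kb, case.findings[phase - 1]).plausible
        s, e, c = len(system), len(expert), len(system & expert)
        records.append(
            AccuracyRecord(
                case_id=case.case_id,
                phase=phase,
                s=s,
                e=e,
                c=c,
                D=kb.D,
                accuracy=closeness_accuracy(s, e, c, kb.D),
                group=case.group,
            )
        )
    return records


def evaluate_cohort(kb: KnowledgeBase, cases: Iterable[PatientCase]) -> list[AccuracyRecord]:
    records: list[AccuracyRecord] = []
    for case in cases:
        records.extend(evaluate_case(kb, case))
    return records


@dataclass(frozen=True)
class CohortSummary:
    n_cases: int
    phase_means: dict[Phase, float]
    group_phase_means: dict[str, dict[Phase, float]]
    frac_all_phases_ge_080: float
    frac_case_avg_gt_050: float
    frac_case_avg_gt_090: float

    def to_dict(self) -> dict:
        return {
            "n_cases": self.n_cases,
            "phase_means": {p.name.lower(): v for p, v in self.phase_means.items()},
            "group_phase_means": {
                g: {p.name.lower(): v for p, v in means.items()}
                for g, means in sorted(self.group_phase_means.items())
            },
            "frac_all_phases_ge_080": self.frac_all_phases_ge_080,
            "frac_case_avg_gt_050": self.frac_case_avg_gt_050,
            "frac_case_avg_gt_090": self.frac_case_avg_gt_090,
        }

    def render_text(self) -> str:
        lines = [f"cases: {self.n_cases}"]
        for p in Phase:
            lines.append(f"mean accuracy, {p.name.lower()}: {self.phase_means[p]:.3f}")
        for g in sorted(self.group_phase_means):
            means = self.group_phase_means[g]
            triple = " / ".join(f"{means[p]:.3f}" for p in Phase)
            lines.append(f"  {g}: {triple}")
        lines.append(f"fraction >= 0.800 in all phases: {self.frac_all_phases_ge_080:.3f}")
        lines.append(f"fraction case-average > 0.500:  {self.frac_case_avg_gt_050:.3f}")
        lines.append(f"fraction case-average > 0.900:  {self.frac_case_avg_gt_090:.3f}")
        return "\n".join(lines)


def summarize_cohort(records: Sequence[AccuracyRecord]) -> CohortSummary:
    """Aggregate per-case records into phase means and threshold fractions.

    Requires a record for every phase of every case.  The 0.8 threshold is
    applied per phase (a case counts if all three phase scores reach it);
    the 0.5 and 0.9 thresholds are applied to the case average.
    """
    if not records:
        raise ValueError("empty cohort")
    by_case: dict[str, dict[Phase, AccuracyRecord]] = {}
    for r in records:
        by_case.setdefault(r.case_id, {})[r.phase] = r
    for cid, per_phase in by_case.items():
        if set(per_phase) != set(Phase):
            raise ValueError(f"case {cid!r} lacks records for all three phases")

    n = len(by_case)
    phase_means = {
        p: sum(by_case[cid][p].accuracy for cid in by_case) / n for p in Phase
    }
    groups: dict[str, list[str]] = {}
    for cid, per_phase in by_case.items():
        group = per_phase[Phase.FIRST_SUSPICIONS].group or "other"
        groups.setdefault(group, []).append(cid)
    group_phase_means = {
        g: {p: sum(by_case[cid][p].accuracy for cid in cids) / len(cids) for p in Phase}
        for g, cids in groups.items()
    }
    all_ge = sum(
        1 for cid in by_case if all(by_case[cid][p].accuracy >= 0.800 for p in Phase)
    )
    avgs = {cid: sum(by_case[cid][p].accuracy for p in Phase) / len(Phase) for cid in by_case}
    return CohortSummary(
        n_cases=n,
        phase_means=phase_means,
        group_phase_means=group_phase_means,
        frac_all_phases_ge_080=all_ge / n,
        frac_case_avg_gt_050=sum(1 for v in avgs.values() if v > 0.500) / n,
        frac_case_avg_gt_090=sum(1 for v in avgs.values() if v > 0.900) / n,
    )


# ---------------------------------------------------------------------------
# JSON Lines cohort IO


def case_to_dict(case: PatientCase) -> dict:
    return {
        "case_id": case.case_id,
        "group": case.group,
        "findings": [sorted(t.render() for t in phase) for phase in case.findings],
        "expert": [sorted(phase) for phase in case.expert],
        "target": case.target,
    }


def case_from_dict(doc: dict) -> PatientCase:
    return PatientCase(
        case_id=str(doc["case_id"]),
        group=str(doc.get("group", "other")),
        findings=tuple(
            frozenset(ConditionTerm.parse(t) for t in phase) for phase in doc["findings"]
        ),
        expert=tuple(frozenset(str(d) for d in phase) for phase in doc["expert"]),
        target=doc.get("target"),
    )


def write_cohort_jsonl(cases: Iterable[PatientCase], path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for case in cases:
            fh.write(json.dumps(case_to_dict(case), sort_keys=True) + "\n")


def read_cohort_jsonl(path) -> list[PatientCase]:
    cases = []
    with open(path, "r", encoding="utf-8") as fh:
        for line in fh:
            line = line.strip()
            if line:
                cases.append(case_from_dict(json.loads(line)))
    return cases
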