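"""Seeded generators for random knowledge bases and phased patient cohorts.

The generators emulate, at desk scale, the structure the evaluation harness
assumes: presenting-complaint tables whose rows refine scenarios down a
tree, and patients whose findings accumulate over three visit phases along a
root-to-leaf scenario path, with a simulated expert derived from the
engine's own output under a controllable disagreement model.

Token namespaces are kept disjoint by construction: condition vocabulary
``c<k>`` (partitioned so no two tables share a token), noise vocabulary
``x<k>``, disease codes ``D<k>``.  Noise terms therefore never interact with
the knowledge base, which makes zero-noise expectations exact.
"""

from __future__ import annotations

import random
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

from .engine import plausible_diagnoses
from .evaluation import PatientCase, Phase
from .knowledge_base import (
    ConditionGroup,
    ConditionTerm,
    DiagnosticTable,
    DiseaseCode,
    KnowledgeBase,
    ScenarioRow,
)

__all__ = [
    "KBGenParams",
    "CohortGenParams",
    "PRESENTATION_GROUPS",
    "generate_kb",
    "generate_case",
    "generate_cohort",
]

PRESENTATION_GROUPS = (
    "bleeding",
    "endocrinology",
    "cancer",
    "pelvic_pain",
    "urogynaecology",
    "sexually_transmitted_infections",
    "vulva_pathology",
)


@dataclass(frozen=True)
class KBGenParams:
    """Parameters for random knowledge bases.

    ``vocab_size`` condition tokens are partitioned evenly across tables, so
    a finding can only ever match rows of one table; each table's first pool
    token is its presenting trigger.  ``group_p`` is the probability that a
    row condition is a two-alternative disjunction.  With
    ``subset_selection`` every child row selects a subset of its parent's
    diseases, as the shipped tables do.
    """

    n_tables: int = 6
    rows_per_table: tuple[int, int] = (3, 5)
    branching_p: float = 0.25
    conditions_per_row: tuple[int, int] = (1, 2)
    vocab_size: int = 72
    n_diseases: int = 20
    diseases_per_table: tuple[int, int] = (3, 6)
    group_p: float = 0.2
    subset_selection: bool = True
    seed: int = 0

    def validate(self) -> None:
        if self.n_tables < 1 or self.n_diseases < 1 or self.vocab_size < 1:
            raise ValueError("n_tables, n_diseases and vocab_size must be positive")
        for lo, hi in (self.rows_per_table, self.conditions_per_row, self.diseases_per_table):
            if not (1 <= lo <= hi):
                raise ValueError("ranges must satisfy 1 <= lo <= hi")
        for p in (self.branching_p, self.group_p):
            if not (0.0 <= p <= 1.0):
                raise ValueError("probabilities must lie in [0, 1]")
        if self.diseases_per_table[1] > self.n_diseases:
            raise ValueError("diseases_per_table exceeds the registry size")
        pool = self.vocab_size // self.n_tables
        needed = 1 + (self.rows_per_table[1] - 1) * self.conditions_per_row[1]
        if pool < needed:
            raise ValueError(
                f"vocabulary too small: each table needs up to {needed} fresh tokens "
                f"but gets a pool of {pool}"
            )


def generate_kb(params: KBGenParams) -> KnowledgeBase:
    """A random knowledge base, reproducible from ``params.seed``.

    Output always passes ``validate_kb`` with zero errors; every row selects
    at least one disease.
    """
    params.validate()
    rng = random.Random(params.seed)
    registry = tuple(
        DiseaseCode(
            code=f"D{k}",
            label=f"synthetic disease {k}",
            group=PRESENTATION_GROUPS[(k - 1) % len(PRESENTATION_GROUPS)],
        )
        for k in range(1, params.n_diseases + 1)
    )
    codes = [d.code for d in registry]
    pool_size = params.vocab_size // params.n_tables

    tables: list[DiagnosticTable] = []
    for t in range(params.n_tables):
        pool = [f"c{t * pool_size + k}" for k in range(1, pool_size + 1)]
        fresh = list(pool)
        trigger_tok = fresh.pop(0)
        trigger = ConditionGroup.of(trigger_tok)

        k_dis = rng.randint(*params.diseases_per_table)
        columns = tuple(sorted(rng.sample(codes, k_dis)))

        def make_group() -> ConditionGroup:
            primary = fresh.pop(rng.randrange(len(fresh)))
            if params.group_p > 0 and rng.random() < params.group_p:
                others = [tok for tok in pool if tok != primary]
                return ConditionGroup.of(primary, rng.choice(others))
            return ConditionGroup.of(primary)

        n_rows = rng.randint(*params.rows_per_table)
        root_k = rng.randint(max(1, len(columns) - 2), len(columns))
        rows: list[dict] = [
            {
                "row_id": "r1",
                "parent": None,
                "adds": (trigger,),
                "selected": frozenset(rng.sample(columns, root_k)),
            }
        ]
        for i in range(2, n_rows + 1):
            if rng.random() < params.branching_p:
                parent = rng.choice(rows)
            else:
                parent = rows[-1]
            n_conds = rng.randint(*params.conditions_per_row)
            adds = tuple(make_group() for _ in range(n_conds))
            if params.subset_selection:
                choices = sorted(parent["selected"])
            else:
                choices = list(columns)
            k_sel = rng.randint(1, len(choices))
            rows.append(
                {
                    "row_id": f"r{i}",
                    "parent": parent["row_id"],
                    "adds": adds,
                    "selected": frozenset(rng.sample(choices, k_sel)),
                }
            )

        # Resolve depths / effective conditions (rows are created parent-first).
        resolved: dict[str, ScenarioRow] = {}
        built: list[ScenarioRow] = []
        for r in rows:
            if r["parent"] is None:
                depth, inherited = 1, ()
            else:
                p = resolved[r["parent"]]
                depth, inherited = p.depth + 1, p.effective_conditions
            effective = list(inherited)
            for g in r["adds"]:
                if g not in effective:
                    effective.append(g)
            row = ScenarioRow(
                row_id=r["row_id"],
                parent_row_id=r["parent"],
                own_conditions=r["adds"],
                effective_conditions=tuple(effective),
                selected=r["selected"],
                depth=depth,
            )
            resolved[row.row_id] = row
            built.append(row)

        tables.append(
            DiagnosticTable(
                table_id=f"t{t + 1}",
                presenting_trigger=trigger,
                disease_columns=columns,
                rows=tuple(built),
            )
        )
    return KnowledgeBase(registry=registry, tables=tuple(tables))


@dataclass(frozen=True)
class CohortGenParams:
    """Parameters for phased synthetic cohorts.

    ``phase_noise`` gives, per phase, the probability of picking up one
    irrelevant extra finding (from the disjoint noise namespace).  The
    expert model is either ``exact`` (expert = system output, the clean
    baseline) or ``perturbed`` (each system disease dropped with
    ``expert_drop_rate``; with ``expert_add_rate`` one disease the system
    did not propose is added).  ``group_weights`` optionally draws the
    case's presentation group at random; by default a case inherits the
    registry group of its target disease.
    """

    n_cases: int = 50
    phase_noise: tuple[float, float, float] = (0.0, 0.0, 0.0)
    expert_model: str = "exact"  # "exact" | "perturbed"
    expert_drop_rate: float = 0.0
    expert_add_rate: float = 0.0
    group_weights: Optional[dict[str, float]] = None
    seed: int = 0

    def validate(self) -> None:
        if self.n_cases < 1:
            raise ValueError("n_cases must be >= 1")
        for r in (*self.phase_noise, self.expert_drop_rate, self.expert_add_rate):
            if not (0.0 <= r <= 1.0):
                raise ValueError("rates must lie in [0, 1]")
        if self.expert_model not in ("exact", "perturbed"):
            raise ValueError(f"unknown expert model {self.expert_model!r}")


def _leaves(table: DiagnosticTable) -> list[ScenarioRow]:
    return [r for r in table.rows if not table.children(r.row_id)]


def generate_case(
    kb: KnowledgeBase,
    params: CohortGenParams,
    target: Optional[str] = None,
    case_id: str = "case",
    rng: Optional[random.Random] = None,
) -> PatientCase:
    """One synthetic patient: a root-to-leaf scenario path, phased.

    Picks a target disease and a leaf selecting it; phase 1 findings satisfy
    the root scenario, phase 2 the mid-path scenario, phase 3 the leaf, plus
    optional noise terms.  Expert sets are derived from the engine's output
    at each phase under the configured expert model.
    """
    params.validate()
    if not kb.tables:
        raise ValueError("knowledge base has no tables")
    if rng is None:
        rng = random.Random(params.seed)

    candidates: list[tuple[DiagnosticTable, ScenarioRow]] = []
    for table in kb.tables:
        for leaf in _leaves(table):
            if leaf.selected and (target is None or target in leaf.selected):
                candidates.append((table, leaf))
    if not candidates:
        raise ValueError(
            f"no table leaf selects target {target!r}" if target else "no selectable leaf"
        )
    table, leaf = candidates[rng.randrange(len(candidates))]
    if target is None:
        target = rng.choice(sorted(leaf.selected))

    path = [table.row(rid) for rid in table.lineage(leaf.row_id)]
    phase_rows = (path[0], path[len(path) // 2], path[-1])

    chosen: dict[ConditionGroup, ConditionTerm] = {}

    def satisfy(groups) -> set[ConditionTerm]:
        terms: set[ConditionTerm] = set()
        for g in groups:
            if g not in chosen:
                chosen[g] = rng.choice(sorted(g.alternatives))
            terms.add(chosen[g])
        return terms

    findings: list[frozenset[ConditionTerm]] = []
    acc: set[ConditionTerm] = set()
    noise_k = 0
    for phase in Phase:
        acc |= satisfy(phase_rows[phase - 1].effective_conditions)
        if rng.random() < params.phase_noise[phase - 1]:
            noise_k += 1
            acc.add(ConditionTerm(value=f"x{rng.randrange(10_000)}"))
        findings.append(frozenset(acc))

    registry_codes = sorted(kb.registry_codes)
    expert_sets: list[frozenset[str]] = []
    for phase in Phase:
        system = plausible_diagnoses(kb, findings[phase - 1]).plausible
        if params.expert_model == "exact":
            expert = set(system)
        else:
            expert = {d for d in system if rng.random() >= params.expert_drop_rate}
            if rng.random() < params.expert_add_rate:
                outside = [d for d in registry_codes if d not in system]
                if outside:
                    expert.add(rng.choice(outside))
        if not expert:
            expert = {target}
        expert_sets.append(frozenset(expert))

    if params.group_weights:
        names = sorted(params.group_weights)
        weights = [params.group_weights[g] for g in names]
        group = rng.choices(names, weights=weights, k=1)[0]
    else:
        group = next((d.group for d in kb.registry if d.code == target), "other")

    return PatientCase(
        case_id=case_id,
        group=group,
        findings=tuple(findings),
        expert=tuple(expert_sets),
        target=target,
    )


def generate_cohort(kb: KnowledgeBase, params: CohortGenParams) -> list[PatientCase]:
    """``n_cases`` independent cases from one seeded stream."""
    params.validate()
    rng = random.Random(params.seed)
    width = len(str(params.n_cases))
    return [
        generate_case(kb, params, case_id=f"case{idx:0{width}d}", rng=rng)
        for idx in range(1, params.n_cases + 1)
    ]
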