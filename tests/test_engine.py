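"""Row matching, argument strength, dialectic selection and the oracle."""

import dataclasses
import random

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from argdx import (
    KnowledgeBase,
    build_arguments,
    compare_strength,
    match_rows,
    oracle_plausible,
    parse_findings,
    plausible_diagnoses,
)
from argdx.engine import OracleSizeError
from argdx.knowledge_base import ConditionTerm
from argdx.synthetic_data import KBGenParams, generate_kb


def _kb_vocab(kb):
    return sorted(
        {
            t
            for table in kb.tables
            for row in table.rows
            for g in row.effective_conditions
            for t in g.alternatives
        }
    )


def _random_findings(kb, rng, extra_noise=False):
    vocab = _kb_vocab(kb)
    n = rng.randint(0, min(len(vocab), 10))
    terms = set(rng.sample(vocab, n))
    if extra_noise:
        terms.add(ConditionTerm(value=f"x{rng.randrange(100)}"))
    return frozenset(terms)


class TestMatchRows:
    def test_presenting_symptom_matches_root_only(self, kb_discharge):
        table = kb_discharge.tables[0]
        result = match_rows(table, parse_findings(["vaginal_discharge"]))
        assert result.matched == result.maximal == frozenset({"r1"})

    def test_empty_findings_match_nothing(self, kb_discharge):
        result = match_rows(kb_discharge.tables[0], frozenset())
        assert result.matched == frozenset()

    def test_full_scenario_matches_whole_chain(self, kb_discharge, discharge_phases):
        result = match_rows(kb_discharge.tables[0], discharge_phases[2])
        assert result.matched == frozenset({"r1", "r2", "r3"})
        assert result.maximal == frozenset({"r3"})

    @settings(max_examples=40, derandomize=True, deadline=None)
    @given(seed=st.integers(0, 5_000))
    def test_matched_set_is_ancestor_closed(self, seed):
        kb = generate_kb(KBGenParams(seed=seed, branching_p=0.5))
        rng = random.Random(seed)
        findings = _random_findings(kb, rng)
        for table in kb.tables:
            result = match_rows(table, findings)
            for rid in result.matched:
                assert set(table.lineage(rid)) <= set(result.matched)


class TestArguments:
    def test_root_match_yields_depth1_arguments(self, kb_discharge):
        args = build_arguments(kb_discharge, parse_findings(["vaginal_discharge"]))
        assert sorted(a.disease for a in args) == ["BV", "CM", "NG", "TM", "VC"]
        assert all(a.depth == 1 for a in args)

    def test_empty_kb_yields_no_arguments(self, kb_registry_default):
        assert build_arguments(kb_registry_default, parse_findings(["anything"])) == []

    def test_deepest_arguments_only_for_surviving_diseases(
        self, kb_discharge, discharge_phases
    ):
        args = build_arguments(kb_discharge, discharge_phases[2])
        assert {a.depth for a in args} == {1, 2, 3}
        assert {a.disease for a in args if a.depth == 3} == {"BV", "TM"}

    def test_strength_examples(self, kb_discharge, discharge_phases):
        args = build_arguments(kb_discharge, discharge_phases[2])
        by_row = {}
        for a in args:
            by_row.setdefault(a.row_id, a)
        assert compare_strength(by_row["r3"], by_row["r1"]) == "stronger"
        assert compare_strength(by_row["r1"], by_row["r3"]) == "weaker"
        same_row = [a for a in args if a.row_id == "r3"]
        assert compare_strength(same_row[0], same_row[1]) == "equal"

    def test_cross_table_arguments_incomparable(self, kb_discharge, kb_burning):
        combined = KnowledgeBase(
            registry=kb_burning.registry,
            tables=kb_burning.tables + kb_discharge.tables,
        )
        args = build_arguments(
            combined, parse_findings(["vaginal_discharge", "burning"])
        )
        a = next(a for a in args if a.table_id == "sti_discharge")
        b = next(a for a in args if a.table_id == "sti_burning")
        assert compare_strength(a, b) == "incomparable"

    @settings(max_examples=30, derandomize=True, deadline=None)
    @given(seed=st.integers(0, 5_000))
    def test_strength_is_antisymmetric_and_transitive(self, seed):
        kb = generate_kb(KBGenParams(seed=seed, branching_p=0.4))
        rng = random.Random(seed)
        args = build_arguments(kb, _random_findings(kb, rng))
        if len(args) < 3:
            return
        flip = {"stronger": "weaker", "weaker": "stronger"}
        for _ in range(100):
            a, b, c = (rng.choice(args) for _ in range(3))
            ab, ba = compare_strength(a, b), compare_strength(b, a)
            assert ba == flip.get(ab, ab)
            if ab == "stronger" and compare_strength(b, c) == "stronger":
                assert compare_strength(a, c) == "stronger"


class TestPlausibleDiagnoses:
    def test_worked_example_progression(self, kb_discharge, discharge_phases):
        expected = [
            {"BV", "TM", "VC", "NG", "CM"},
            {"BV", "TM", "NG"},
            {"BV", "TM"},
        ]
        for findings, want in zip(discharge_phases, expected):
            assert plausible_diagnoses(kb_discharge, findings).plausible == want

    def test_defeats_recorded_for_dropped_diseases(self, kb_discharge, discharge_phases):
        result = plausible_diagnoses(kb_discharge, discharge_phases[1])
        defeated = {d.disease for d in result.defeats}
        assert defeated == {"VC", "CM"}
        for d in result.defeats:
            assert d.defeating_row_id in result.matched_rows["sti_discharge"].maximal
            assert d.reason == "outranked"

    def test_no_matched_table_gives_empty_result(self, kb_discharge):
        result = plausible_diagnoses(kb_discharge, parse_findings(["headache"]))
        assert result.plausible == frozenset()
        assert not result.matched_rows and not result.defeats

    def test_irrelevant_term_leaves_result_unchanged(self, kb_discharge, discharge_phases):
        base = plausible_diagnoses(kb_discharge, discharge_phases[1])
        noisy = plausible_diagnoses(
            kb_discharge, discharge_phases[1] | parse_findings(["left_handed"])
        )
        assert noisy == base

    def test_determinism_under_table_and_row_reordering(self, kb_discharge, kb_burning):
        combined = KnowledgeBase(
            registry=kb_burning.registry,
            tables=kb_burning.tables + kb_discharge.tables,
        )
        reordered = KnowledgeBase(
            registry=combined.registry,
            tables=tuple(
                dataclasses.replace(t, rows=tuple(reversed(t.rows)))
                for t in reversed(combined.tables)
            ),
        )
        findings = parse_findings(["vaginal_discharge", "burning", "intermenstrual_bleeding"])
        a = plausible_diagnoses(combined, findings)
        b = plausible_diagnoses(reordered, findings)
        assert a.plausible == b.plausible
        assert set(a.defeats) == set(b.defeats)

    def test_union_across_tables_with_override_record(self, kb_discharge, kb_burning):
        # burning table refines away BV/TM while the discharge table still
        # supports them: cross-table arguments are incomparable, so both
        # tables' verdicts union and the local defeat is marked overridden.
        combined = KnowledgeBase(
            registry=kb_burning.registry,
            tables=kb_burning.tables + kb_discharge.tables,
        )
        findings = parse_findings(
            ["vaginal_discharge", "burning", "intermenstrual_bleeding"]
        )
        result = plausible_diagnoses(combined, findings)
        assert result.plausible == {"BV", "TM", "VC", "NG", "CM", "AW"}
        overridden = {
            d.disease for d in result.defeats if d.reason == "overridden-elsewhere"
        }
        assert {"BV", "TM"} <= overridden

    @settings(max_examples=40, derandomize=True, deadline=None)
    @given(seed=st.integers(0, 5_000))
    def test_monotone_shrinkage_under_subset_selection(self, seed):
        # Chain tables: on branching trees a sibling scenario that starts
        # matching can legitimately re-introduce diseases a cousin's leaf
        # had dropped, so monotone shrinkage is a chain property.
        kb = generate_kb(KBGenParams(seed=seed, subset_selection=True, branching_p=0.0))
        rng = random.Random(seed)
        table = kb.tables[rng.randrange(len(kb.tables))]
        vocab = sorted(
            {t for r in table.rows for g in r.effective_conditions for t in g.alternatives}
        )
        rng.shuffle(vocab)
        findings: set = set()
        prev = None
        for term in vocab:
            findings.add(term)
            current = plausible_diagnoses(kb, frozenset(findings)).plausible
            if prev is not None and prev:
                assert current <= prev or not current
            if current:
                prev = current

    @settings(max_examples=40, derandomize=True, deadline=None)
    @given(seed=st.integers(0, 5_000))
    def test_intra_table_refinement_on_chains(self, seed):
        # On chain tables the maximal matched row under a finding superset
        # is a descendant-or-self of the one under the subset.
        kb = generate_kb(KBGenParams(seed=seed, branching_p=0.0))
        rng = random.Random(seed)
        table = kb.tables[rng.randrange(len(kb.tables))]
        vocab = sorted(
            {t for r in table.rows for g in r.effective_conditions for t in g.alternatives}
        )
        f1 = frozenset(rng.sample(vocab, rng.randint(0, len(vocab) // 2)))
        f2 = f1 | frozenset(rng.sample(vocab, rng.randint(0, len(vocab) // 2)))
        m1, m2 = match_rows(table, f1), match_rows(table, f2)
        if not m1.matched:
            return
        (top1,) = m1.maximal
        (top2,) = m2.maximal
        assert top1 in table.lineage(top2)


class TestOracle:
    def test_oracle_agrees_on_worked_examples(self, kb_discharge, discharge_phases):
        for findings in discharge_phases:
            assert oracle_plausible(kb_discharge, findings) == plausible_diagnoses(
                kb_discharge, findings
            ).plausible

    def test_empty_findings_give_empty_set(self, kb_discharge):
        assert oracle_plausible(kb_discharge, frozenset()) == frozenset()

    def test_size_bound_enforced(self):
        kb = generate_kb(KBGenParams(seed=0, n_tables=9, vocab_size=108))
        with pytest.raises(OracleSizeError):
            oracle_plausible(kb, frozenset())

    @pytest.mark.parametrize("subset_selection", [True, False])
    def test_oracle_equivalence_on_random_instances(self, subset_selection):
        """Brute-force argumentation semantics matches the table-verdict engine."""
        rng = random.Random(20_000 + subset_selection)
        for trial in range(250):
            kb = generate_kb(
                KBGenParams(
                    seed=rng.randrange(2**31),
                    n_tables=rng.randint(1, 4),
                    rows_per_table=(2, 6),
                    branching_p=rng.choice([0.0, 0.3, 0.6]),
                    vocab_size=44,
                    n_diseases=rng.randint(4, 12),
                    diseases_per_table=(2, 4),
                    subset_selection=subset_selection,
                )
            )
            findings = _random_findings(kb, rng, extra_noise=(trial % 3 == 0))
            assert oracle_plausible(kb, findings) == plausible_diagnoses(
                kb, findings
            ).plausible
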