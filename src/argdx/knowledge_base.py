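"""Data model and textual format for scenario-table knowledge bases.

A knowledge base is a registry of diseases plus a collection of diagnostic
tables.  Each table is rooted at a presenting complaint (e.g. vaginal
discharge) and holds a tree of scenario rows of increasing specificity: a
child row inherits all of its ancestors' conditions and adds its own.  Every
row marks the subset of the table's disease columns that remain supported
under that scenario.

Documents are YAML with top-level ``registry`` and ``tables`` keys; condition
terms use the functional rendering ``predicate(subject, value)`` (or a bare
symptom token) and disjunctive condition groups join alternatives with
``+/``.  Parsing is lossless with respect to :func:`serialize_kb`.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, replace
from importlib import resources
from typing import Iterable, Literal, Optional, Sequence, Union

import yaml

__all__ = [
    "DiseaseCode",
    "ConditionTerm",
    "ConditionGroup",
    "ScenarioRow",
    "DiagnosticTable",
    "KnowledgeBase",
    "ValidationReport",
    "ValidationIssue",
    "KBError",
    "KBParseError",
    "KBStructureError",
    "KBValidationError",
    "RevisionError",
    "AddRow",
    "EditSelection",
    "EditConditions",
    "parse_kb",
    "serialize_kb",
    "load_kb",
    "load_fixture",
    "fixture_path",
    "validate_kb",
    "revise_table",
    "canonical_token",
]


class KBError(Exception):
    """Base class for knowledge-base errors."""


class KBParseError(KBError):
    """The document does not conform to the KB schema."""


class KBStructureError(KBParseError):
    """Row hierarchy is broken (cycles, missing parents, several roots)."""


class KBValidationError(KBParseError):
    """A disease code is used where it is not declared."""


class RevisionError(KBError):
    """A table edit was rejected because it would produce an invalid table."""

    def __init__(self, message: str, report: Optional["ValidationReport"] = None):
        super().__init__(message)
        self.report = report


_WS = re.compile(r"\s+")


def canonical_token(raw: str) -> str:
    """Case-fold a token and replace whitespace runs with underscores."""
    return _WS.sub("_", raw.strip()).casefold()


_TERM2 = re.compile(r"^([^(),\s]+)\s*\(\s*([^(),]*?)\s*,\s*([^(),]*?)\s*\)$")
_TERM1 = re.compile(r"^([^(),\s]+)\s*\(\s*([^(),]+?)\s*\)$")


@dataclass(frozen=True, order=True)
class ConditionTerm:
    """An atomic finding: ``predicate(subject, value)`` or a bare symptom.

    Equality is syntactic on the canonical rendering, so
    ``Texture (VD, thin)`` and ``texture(vd,thin)`` are the same term.
    """

    predicate: str = ""
    subject: str = ""
    value: str = ""

    def __post_init__(self) -> None:
        if not self.value:
            raise ValueError("ConditionTerm requires a non-empty value")

    @classmethod
    def parse(cls, raw: str) -> "ConditionTerm":
        raw = raw.strip()
        m = _TERM2.match(raw)
        if m:
            return cls(
                predicate=canonical_token(m.group(1)),
                subject=canonical_token(m.group(2)),
                value=canonical_token(m.group(3)),
            )
        m = _TERM1.match(raw)
        if m:
            return cls(predicate=canonical_token(m.group(1)), value=canonical_token(m.group(2)))
        return cls(value=canonical_token(raw))

    def render(self) -> str:
        if self.predicate and self.subject:
            return f"{self.predicate}({self.subject},{self.value})"
        if self.predicate:
            return f"{self.predicate}({self.value})"
        return self.value

    def __str__(self) -> str:  # pragma: no cover - convenience
        return self.render()


@dataclass(frozen=True)
class ConditionGroup:
    """A disjunction of condition terms, e.g. ``burning +/ itching``.

    A finding set satisfies the group iff it contains at least one
    alternative; a singleton group behaves exactly like its term.
    """

    alternatives: frozenset[ConditionTerm]

    def __post_init__(self) -> None:
        if not self.alternatives:
            raise ValueError("ConditionGroup requires at least one alternative")

    @classmethod
    def of(cls, *terms: Union[ConditionTerm, str]) -> "ConditionGroup":
        parsed = frozenset(
            t if isinstance(t, ConditionTerm) else ConditionTerm.parse(t) for t in terms
        )
        return cls(parsed)

    @classmethod
    def parse(cls, raw: str) -> "ConditionGroup":
        parts = [p for p in (s.strip() for s in raw.split("+/")) if p]
        if not parts:
            raise KBParseError(f"empty condition group: {raw!r}")
        return cls(frozenset(ConditionTerm.parse(p) for p in parts))

    def satisfied_by(self, findings: frozenset[ConditionTerm]) -> bool:
        return not self.alternatives.isdisjoint(findings)

    def render(self) -> str:
        return " +/ ".join(sorted(t.render() for t in self.alternatives))

    def __str__(self) -> str:  # pragma: no cover - convenience
        return self.render()


@dataclass(frozen=True)
class DiseaseCode:
    """A short uppercase disease token plus label and presentation group."""

    code: str
    label: str = ""
    group: str = "other"

    def __post_init__(self) -> None:
        if not self.code:
            raise ValueError("DiseaseCode requires a non-empty code")


@dataclass(frozen=True)
class ScenarioRow:
    """One row of a diagnostic table.

    ``own_conditions`` are the conditions the row adds to its parent (the
    ``++`` additions); ``effective_conditions`` is the union over the row's
    root path, resolved at parse time.  ``selected`` holds the disease codes
    marked as supported under this scenario.
    """

    row_id: str
    parent_row_id: Optional[str]
    own_conditions: tuple[ConditionGroup, ...]
    effective_conditions: tuple[ConditionGroup, ...]
    selected: frozenset[str]
    depth: int


@dataclass(frozen=True)
class DiagnosticTable:
    table_id: str
    presenting_trigger: ConditionGroup
    disease_columns: tuple[str, ...]
    rows: tuple[ScenarioRow, ...]

    def row(self, row_id: str) -> ScenarioRow:
        for r in self.rows:
            if r.row_id == row_id:
                return r
        raise KeyError(row_id)

    def children(self, row_id: str) -> tuple[ScenarioRow, ...]:
        return tuple(r for r in self.rows if r.parent_row_id == row_id)

    @property
    def root(self) -> ScenarioRow:
        roots = [r for r in self.rows if r.parent_row_id is None]
        if len(roots) != 1:
            raise KBStructureError(f"table {self.table_id!r} has {len(roots)} roots")
        return roots[0]

    def lineage(self, row_id: str) -> tuple[str, ...]:
        """Row ids from the root down to ``row_id`` (inclusive)."""
        chain: list[str] = []
        cur: Optional[str] = row_id
        seen: set[str] = set()
        while cur is not None:
            if cur in seen:
                raise KBStructureError(f"cycle through row {cur!r} in table {self.table_id!r}")
            seen.add(cur)
            chain.append(cur)
            cur = self.row(cur).parent_row_id
        return tuple(reversed(chain))

    def descendants(self, row_id: str) -> tuple[ScenarioRow, ...]:
        out: list[ScenarioRow] = []
        stack = [row_id]
        while stack:
            rid = stack.pop()
            for child in self.children(rid):
                out.append(child)
                stack.append(child.row_id)
        return tuple(out)


@dataclass(frozen=True)
class KnowledgeBase:
    registry: tuple[DiseaseCode, ...]
    tables: tuple[DiagnosticTable, ...]

    @property
    def D(self) -> int:
        """Size of the disease universe (the ``D`` of the accuracy metric)."""
        return len(self.registry)

    @property
    def registry_codes(self) -> frozenset[str]:
        return frozenset(d.code for d in self.registry)

    def table(self, table_id: str) -> DiagnosticTable:
        for t in self.tables:
            if t.table_id == table_id:
                return t
        raise KeyError(table_id)


Severity = Literal["error", "warning"]


@dataclass(frozen=True)
class ValidationIssue:
    severity: Severity
    table_id: Optional[str]
    row_id: Optional[str]
    message: str


@dataclass(frozen=True)
class ValidationReport:
    issues: tuple[ValidationIssue, ...]

    @property
    def ok(self) -> bool:
        return not any(i.severity == "error" for i in self.issues)

    @property
    def errors(self) -> tuple[ValidationIssue, ...]:
        return tuple(i for i in self.issues if i.severity == "error")

    @property
    def warnings(self) -> tuple[ValidationIssue, ...]:
        return tuple(i for i in self.issues if i.severity == "warning")

    def to_dict(self) -> dict:
        return {
            "ok": self.ok,
            "issues": [
                {
                    "severity": i.severity,
                    "table_id": i.table_id,
                    "row_id": i.row_id,
                    "message": i.message,
                }
                for i in self.issues
            ],
        }


# ---------------------------------------------------------------------------
# Parsing


def _parse_groups(raw: Sequence, where: str) -> tuple[ConditionGroup, ...]:
    if not isinstance(raw, list):
        raise KBParseError(f"{where}: 'adds' must be a list of condition strings")
    groups = []
    for item in raw:
        if not isinstance(item, str):
            raise KBParseError(f"{where}: condition entries must be strings, got {item!r}")
        groups.append(ConditionGroup.parse(item))
    return tuple(groups)


def _build_table(doc: dict, registry_codes: frozenset[str]) -> DiagnosticTable:
    if not isinstance(doc, dict):
        raise KBParseError("each table must be a mapping")
    table_id = doc.get("table_id")
    if not isinstance(table_id, str) or not table_id:
        raise KBParseError("table missing 'table_id'")
    where = f"table {table_id!r}"
    presenting = doc.get("presenting")
    if not isinstance(presenting, str) or not presenting.strip():
        raise KBParseError(f"{where}: missing 'presenting' complaint")
    trigger = ConditionGroup.parse(presenting)
    columns = doc.get("diseases")
    if not isinstance(columns, list) or not columns:
        raise KBParseError(f"{where}: 'diseases' must be a non-empty list of codes")
    columns = tuple(str(c) for c in columns)
    for c in columns:
        if c not in registry_codes:
            raise KBValidationError(f"{where}: disease column {c!r} not in registry")
    raw_rows = doc.get("rows")
    if not isinstance(raw_rows, list) or not raw_rows:
        raise KBParseError(f"{where}: 'rows' must be a non-empty list")

    drafts: dict[str, dict] = {}
    order: list[str] = []
    for raw in raw_rows:
        if not isinstance(raw, dict):
            raise KBParseError(f"{where}: each row must be a mapping")
        row_id = raw.get("row_id")
        if not isinstance(row_id, str) or not row_id:
            raise KBParseError(f"{where}: row missing 'row_id'")
        if row_id in drafts:
            raise KBParseError(f"{where}: duplicate row id {row_id!r}")
        rwhere = f"{where}, row {row_id!r}"
        parent = raw.get("parent")
        if parent is not None and not isinstance(parent, str):
            raise KBParseError(f"{rwhere}: 'parent' must be a row id or null")
        adds = _parse_groups(raw.get("adds", []), rwhere)
        select = raw.get("select", [])
        if not isinstance(select, list):
            raise KBParseError(f"{rwhere}: 'select' must be a list of disease codes")
        select = frozenset(str(s) for s in select)
        for code in select:
            if code not in columns:
                raise KBValidationError(
                    f"{rwhere}: selects {code!r} which is not a column of this table"
                )
        drafts[row_id] = {"parent": parent, "adds": adds, "select": select}
        order.append(row_id)

    roots = [rid for rid in order if drafts[rid]["parent"] is None]
    if len(roots) != 1:
        raise KBStructureError(f"{where}: expected exactly one root row, found {len(roots)}")
    for rid in order:
        parent = drafts[rid]["parent"]
        if parent is not None and parent not in drafts:
            raise KBStructureError(f"{where}, row {rid!r}: unknown parent {parent!r}")

    # Resolve depth and effective conditions; detects cycles.
    resolved: dict[str, tuple[int, tuple[ConditionGroup, ...]]] = {}

    def resolve(rid: str, trail: tuple[str, ...]) -> tuple[int, tuple[ConditionGroup, ...]]:
        if rid in resolved:
            return resolved[rid]
        if rid in trail:
            raise KBStructureError(f"{where}: cyclic parent references through row {rid!r}")
        parent = drafts[rid]["parent"]
        if parent is None:
            depth, inherited = 1, ()
        else:
            pdepth, peff = resolve(parent, trail + (rid,))
            depth, inherited = pdepth + 1, peff
        effective = list(inherited)
        for g in drafts[rid]["adds"]:
            if g not in effective:
                effective.append(g)
        resolved[rid] = (depth, tuple(effective))
        return resolved[rid]

    for rid in order:
        resolve(rid, ())

    rows = tuple(
        ScenarioRow(
            row_id=rid,
            parent_row_id=drafts[rid]["parent"],
            own_conditions=drafts[rid]["adds"],
            effective_conditions=resolved[rid][1],
            selected=drafts[rid]["select"],
            depth=resolved[rid][0],
        )
        for rid in order
    )
    return DiagnosticTable(
        table_id=table_id,
        presenting_trigger=trigger,
        disease_columns=columns,
        rows=rows,
    )


def parse_kb(text: str) -> KnowledgeBase:
    """Parse a YAML knowledge-base document.

    Raises :class:`KBParseError` (schema), :class:`KBStructureError`
    (hierarchy) or :class:`KBValidationError` (undeclared disease codes),
    each naming the offending table and row.
    """
    try:
        doc = yaml.safe_load(text)
    except yaml.YAMLError as exc:
        raise KBParseError(f"not valid YAML: {exc}") from exc
    if not isinstance(doc, dict):
        raise KBParseError("KB document must be a mapping with 'registry' and 'tables'")
    raw_registry = doc.get("registry")
    if not isinstance(raw_registry, list) or not raw_registry:
        raise KBParseError("'registry' must be a non-empty list of diseases")
    registry: list[DiseaseCode] = []
    seen: set[str] = set()
    for entry in raw_registry:
        if isinstance(entry, str):
            entry = {"code": entry}
        if not isinstance(entry, dict) or "code" not in entry:
            raise KBParseError(f"registry entries need a 'code': {entry!r}")
        code = str(entry["code"])
        if code in seen:
            raise KBParseError(f"duplicate disease code {code!r} in registry")
        seen.add(code)
        registry.append(
            DiseaseCode(
                code=code,
                label=str(entry.get("label", "")),
                group=str(entry.get("group", "other")),
            )
        )
    codes = frozenset(seen)
    raw_tables = doc.get("tables", [])
    if raw_tables is None:
        raw_tables = []
    if not isinstance(raw_tables, list):
        raise KBParseError("'tables' must be a list")
    tables: list[DiagnosticTable] = []
    table_ids: set[str] = set()
    for tdoc in raw_tables:
        table = _build_table(tdoc, codes)
        if table.table_id in table_ids:
            raise KBParseError(f"duplicate table id {table.table_id!r}")
        table_ids.add(table.table_id)
        tables.append(table)
    return KnowledgeBase(registry=tuple(registry), tables=tuple(tables))


def load_kb(path) -> KnowledgeBase:
    with open(path, "r", encoding="utf-8") as fh:
        return parse_kb(fh.read())


def fixture_path(name: str):
    """Path to a fixture document shipped with the package."""
    return resources.files("argdx") / "fixtures" / name


def load_fixture(name: str) -> KnowledgeBase:
    return parse_kb(fixture_path(name).read_text(encoding="utf-8"))


# ---------------------------------------------------------------------------
# Serialization


def _row_to_dict(row: ScenarioRow) -> dict:
    return {
        "row_id": row.row_id,
        "parent": row.parent_row_id,
        "adds": [g.render() for g in row.own_conditions],
        "select": sorted(row.selected),
    }


def _table_to_dict(table: DiagnosticTable) -> dict:
    return {
        "table_id": table.table_id,
        "presenting": table.presenting_trigger.render(),
        "diseases": list(table.disease_columns),
        "rows": [_row_to_dict(r) for r in table.rows],
    }


def serialize_table(table: DiagnosticTable) -> str:
    """Serialize a single table (used for byte-level locality checks)."""
    return yaml.safe_dump(_table_to_dict(table), sort_keys=False, allow_unicode=True)


def serialize_kb(kb: KnowledgeBase) -> str:
    doc = {
        "registry": [
            {"code": d.code, "label": d.label, "group": d.group} for d in kb.registry
        ],
        "tables": [_table_to_dict(t) for t in kb.tables],
    }
    return yaml.safe_dump(doc, sort_keys=False, allow_unicode=True)


# ---------------------------------------------------------------------------
# Validation


def validate_kb(kb: KnowledgeBase) -> ValidationReport:
    """Mechanical consistency checks; never raises.

    Errors are breaches of the structural invariants (unreachable rows,
    selections outside the declared columns, ...).  A child row whose
    selection is not a subset of its parent's is only a warning: the shipped
    tables shrink monotonically down the hierarchy but nothing forces a KB
    author to.  Rows selecting no disease at all are likewise flagged.
    """
    issues: list[ValidationIssue] = []

    def err(msg: str, table_id=None, row_id=None) -> None:
        issues.append(ValidationIssue("error", table_id, row_id, msg))

    def warn(msg: str, table_id=None, row_id=None) -> None:
        issues.append(ValidationIssue("warning", table_id, row_id, msg))

    if kb.D < 1:
        err("registry must contain at least one disease")
    codes = [d.code for d in kb.registry]
    for code in sorted({c for c in codes if codes.count(c) > 1}):
        err(f"duplicate disease code {code!r} in registry")
    registry_codes = frozenset(codes)

    table_ids = [t.table_id for t in kb.tables]
    for tid in sorted({t for t in table_ids if table_ids.count(t) > 1}):
        err(f"duplicate table id {tid!r}")

    for table in kb.tables:
        tid = table.table_id
        row_ids = [r.row_id for r in table.rows]
        for rid in sorted({r for r in row_ids if row_ids.count(r) > 1}):
            err(f"duplicate row id {rid!r}", tid, rid)
            continue
        for c in table.disease_columns:
            if c not in registry_codes:
                err(f"disease column {c!r} not in registry", tid)
        roots = [r for r in table.rows if r.parent_row_id is None]
        if len(roots) != 1:
            err(f"expected exactly one root row, found {len(roots)}", tid)
            continue
        root = roots[0]
        by_id = {r.row_id: r for r in table.rows}
        # reachability / acyclicity
        reachable: set[str] = set()
        stack = [root.row_id]
        while stack:
            rid = stack.pop()
            if rid in reachable:
                continue
            reachable.add(rid)
            stack.extend(r.row_id for r in table.rows if r.parent_row_id == rid)
        for r in table.rows:
            if r.row_id not in reachable:
                err("row not reachable from the root (cycle or orphan)", tid, r.row_id)
        if table.presenting_trigger not in root.own_conditions:
            err("root row does not include the presenting trigger", tid, root.row_id)
        columns = frozenset(table.disease_columns)
        for r in table.rows:
            if not set(r.selected) <= columns:
                extra = sorted(set(r.selected) - columns)
                err(f"selects codes outside table columns: {extra}", tid, r.row_id)
            if not r.selected:
                warn("row selects no disease", tid, r.row_id)
            parent = by_id.get(r.parent_row_id) if r.parent_row_id else None
            if parent is not None:
                if r.depth != parent.depth + 1:
                    err("depth is not parent depth + 1", tid, r.row_id)
                if not set(r.own_conditions) <= set(r.effective_conditions):
                    err("effective_conditions does not include own_conditions", tid, r.row_id)
                expected = list(parent.effective_conditions)
                for g in r.own_conditions:
                    if g not in expected:
                        expected.append(g)
                if r.row_id in reachable and list(r.effective_conditions) != expected:
                    err("effective_conditions is not the union over the root path", tid, r.row_id)
                if not r.selected <= parent.selected:
                    warn(
                        "selects diseases its parent does not "
                        f"({sorted(r.selected - parent.selected)})",
                        tid,
                        r.row_id,
                    )
            elif r.depth != 1:
                err("root row must have depth 1", tid, r.row_id)
    return ValidationReport(tuple(issues))


# ---------------------------------------------------------------------------
# Modular revision


@dataclass(frozen=True)
class AddRow:
    row_id: str
    parent: str
    adds: tuple[str, ...]
    select: frozenset[str]


@dataclass(frozen=True)
class EditSelection:
    row_id: str
    select: frozenset[str]


@dataclass(frozen=True)
class EditConditions:
    row_id: str
    adds: tuple[str, ...]


Edit = Union[AddRow, EditSelection, EditConditions]


def _recompute(table: DiagnosticTable) -> DiagnosticTable:
    """Rebuild depths and effective conditions after a local edit."""
    doc = _table_to_dict(table)
    return _build_table(doc, frozenset(table.disease_columns))


def revise_table(kb: KnowledgeBase, table_id: str, edit: Edit) -> KnowledgeBase:
    """Apply a local edit to one table, leaving every other table untouched.

    The revised KB is validated before being returned; an edit that would
    break the table's invariants is rejected with :class:`RevisionError`.
    """
    try:
        table = kb.table(table_id)
    except KeyError:
        raise RevisionError(f"unknown table {table_id!r}")

    if isinstance(edit, AddRow):
        if any(r.row_id == edit.row_id for r in table.rows):
            raise RevisionError(f"row id {edit.row_id!r} already exists in {table_id!r}")
        bad = sorted(set(edit.select) - set(table.disease_columns))
        if bad:
            raise RevisionError(f"edit selects unknown disease codes {bad} in {table_id!r}")
        new_row = ScenarioRow(
            row_id=edit.row_id,
            parent_row_id=edit.parent,
            own_conditions=tuple(ConditionGroup.parse(a) for a in edit.adds),
            effective_conditions=(),  # recomputed below
            selected=frozenset(edit.select),
            depth=0,
        )
        new_rows = table.rows + (new_row,)
    elif isinstance(edit, (EditSelection, EditConditions)):
        try:
            table.row(edit.row_id)
        except KeyError:
            raise RevisionError(f"unknown row {edit.row_id!r} in table {table_id!r}")
        new_rows = tuple(
            replace(
                r,
                selected=frozenset(edit.select) if isinstance(edit, EditSelection) else r.selected,
                own_conditions=(
                    tuple(ConditionGroup.parse(a) for a in edit.adds)
                    if isinstance(edit, EditConditions)
                    else r.own_conditions
                ),
            )
            if r.row_id == edit.row_id
            else r
            for r in table.rows
        )
        if isinstance(edit, EditSelection):
            bad = sorted(set(edit.select) - set(table.disease_columns))
            if bad:
                raise RevisionError(f"edit selects unknown disease codes {bad} in {table_id!r}")
    else:  # pragma: no cover - defensive
        raise RevisionError(f"unknown edit type {type(edit).__name__}")

    draft = replace(table, rows=new_rows)
    try:
        rebuilt = _recompute(draft)
    except KBError as exc:
        raise RevisionError(str(exc))
    new_kb = replace(
        kb, tables=tuple(rebuilt if t.table_id == table_id else t for t in kb.tables)
    )
    report = validate_kb(new_kb)
    if not report.ok:
        raise RevisionError(
            f"edit would invalidate table {table_id!r}: "
            + "; ".join(i.message for i in report.errors),
            report,
        )
    return new_kb
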