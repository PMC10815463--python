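# Methods

## Knowledge representation

A knowledge base is a disease registry plus diagnostic tables.  Each table
is triggered by a presenting complaint and holds a tree of scenario rows.
A row's *own* conditions are the additions it makes to its parent; its
*effective* conditions are the union along the root path, resolved at parse
time and revalidated by recomputation.  Conditions are canonicalized
(case-folded, whitespace → underscore) so equality is syntactic:
`Texture (VD, thin)` ≡ `texture(vd,thin)`.  A condition group is a
disjunction (`burning +/ itching`) satisfied by any one alternative;
singleton groups behave as their term.

The printed source tables are chains, but hierarchies of increasing
specificity admit branching, so the parser and all reasoning accept
arbitrary trees.  Two deliberate softenings of the format:

* a child selecting a disease its parent does not is a **warning**, not an
  error — the shipped tables shrink monotonically down the hierarchy, but
  that is an observed regularity, not a law of the format;
* a row selecting no disease at all is a **warning** — it is
  representable, but it has no analogue in the source tables and breaks
  the engine/oracle equivalence argument below, so the generator never
  emits one.

Documents are YAML (see `fixtures/kb_schema.json` for the structural
schema, enforced by the parser itself).  Serialization is lossless:
`parse(serialize(kb)) == kb` structurally, which the tests verify on 1000
generated knowledge bases.  Revision (`revise_table`) rebuilds only the
edited table and validates the result; rejected edits leave the KB
untouched, and untouched tables are byte-identical under per-table
serialization.

## Argumentation semantics

For findings `F`, a row matches iff every effective condition group is
satisfied.  Effective conditions accumulate, so the matched rows of a table
form an ancestor-closed subtree; the *maximal* matched rows are its leaves.
One argument exists per (matched row, selected disease).

**Strength is ancestry, not raw depth.**  An argument is strictly stronger
than another iff it comes from the same table and a strict descendant row;
same-row arguments are equal; everything else — different branches of one
table, different tables — is incomparable.  On chains (all shipped tables)
this coincides with depth ordering.  On branching trees raw depth would let
a depth-3 scenario in one branch defeat an unrelated depth-2 scenario in a
sibling branch, which contradicts the intended reading that only *more
specific versions of the same scenario* override; ancestry is the faithful
generalization, and it is what makes the engine provably equal to the
brute-force oracle.

The engine computes each matched table's verdict as the union of selected
sets over its maximal matched rows.  Diseases selected only in non-maximal
rows of a table are defeated there (the record names the deepest maximal
matched descendant as the defeating row).  Tables are incomparable, so the
global plausible set is the union of verdicts; a disease defeated in one
table but present in another table's verdict stays plausible, with the
local defeat kept and marked `overridden-elsewhere` for transparency.

The oracle enumerates every argument and the full attack relation
(arguments for different diseases attack each other; an attack strictly
defeats its target iff the attacker is strictly stronger) and accepts a
disease iff some argument for it has no strictly stronger attacker.  For
trees whose rows all select at least one disease this is equivalent to the
verdict-union computation: a maximal-row argument has no stronger attacker;
conversely an undefeated argument's maximal matched descendants can select
nothing but its own disease, which therefore appears in the verdict.  The
two code paths share only the primitives (matching, strength) and are
checked against each other on 1000 random instances.  The oracle refuses
knowledge bases beyond 8 tables of 6 rows — it is intentionally quadratic.

Findings are open-world (D3 of the design): absence of a term never counts
against a scenario, and negative findings must be modelled as tokens of
their own.  A term appearing in no table cannot change any verdict.

## Explanations and guidance

An explanation reports one of three verdicts.  *Plausible*: the deepest
winning row (ties broken by table then row id), its effective conditions —
all satisfied by the findings — and the *strengtheners*: unsatisfied
condition groups of deeper, unmatched descendant rows that still select
the disease.  *Defeated*: the strongest defeating scenario with its
conditions.  *No evidence*: the disease is in the registry but no matched
table mentions it.

Guidance enumerates every unsatisfied condition group in an unmatched
descendant of a maximal matched row.  Discrimination is conservative:
current plausible-set size minus the worst-case (largest) plausible set
over the group's alternatives, recomputed exactly by re-running the engine
per alternative.  The value is floored at zero because, without the
subset-selection regularity, establishing a condition can legitimately
enlarge a verdict.  Ranking is by discrimination descending, ties broken
lexicographically by the group's canonical rendering; ranking guidance at
all is this package's choice — the source system displays the changing
diagnosis list rather than a question ranking.

## Evaluation

`closeness_accuracy(s, e, c, D) = (c/e) · ((D − |s − e|)/D)`.  The size
penalty uses the absolute difference: the source formula's `D − s − e`
notation and prose leave the sign open, and the absolute value keeps the
metric in [0, 1] symmetrically while agreeing with the published degenerate
example (`s = D, e = c = 1` → `1/D`).  `e = 0` is an error (the comparison
is undefined), and `D` always comes from the loaded knowledge base — it is
137 only if the user supplies a 137-disease registry.  Exhaustive
enumeration for `D ≤ 12` confirms the range, that 1 is attained only at
`s = e = c`, strict growth in `c` (where the size penalty is not total) and
strict decay in `|s − e|` (for `c ≥ 1`).

A patient case carries cumulative findings and an expert differential for
each of three phases.  `evaluate_case` runs the engine per phase and scores
against the expert; phases with an empty expert set are skipped with a
warning.  Cohort summaries report phase means, group-by-phase means and
three threshold fractions.  The ≥ 0.8 threshold is applied per phase (a
case must clear it in all three), while the 0.5 and 0.9 thresholds apply
to the case average; the source description does not fix the scope of the
latter two, and the case average is the reading consistent with reserving
the "all three stages" wording for the 0.8 rule.

## Synthetic data

`generate_kb` emulates the structure the evaluation assumes, at desk scale
(defaults: 6 tables of 3–5 rows, branching probability 0.25, 1–2 fresh
conditions per row, 20 diseases, 3–6 columns per table, 20 % of conditions
two-way disjunctions, subset selection on).  The condition vocabulary is
partitioned across tables, so a finding matches rows of one table only.
This is a deliberate simplification: real knowledge bases share symptoms
across presentations, which is exactly what the cross-table union semantics
exists for, and the fixture tests cover that path; the partition is what
makes within-table properties (refinement, monotone shrinkage on chains)
exact on generated data.  Every generated row selects at least one disease,
and generated KBs always validate cleanly.

`generate_case` picks a target disease and a root-to-leaf path selecting
it; phase findings satisfy the root, mid-path and leaf scenarios
cumulatively.  Noise terms come from a namespace (`x<k>`) disjoint from the
condition vocabulary (`c<k>`), so noise can never change engine output —
zero-noise and noisy runs differ only through expert perturbation.  The
simulated expert is derived from the engine's own per-phase output:
`exact` (expert = system; the clean baseline, which makes expected values
exact — mean accuracy is provably 1.0) or `perturbed` (each system disease
dropped with a given rate; with a second rate one disease the system did
not propose is added; an empty expert set falls back to the target
disease).  Cohort defaults are 50 cases, zero noise, exact expert.

Two monotonicity facts shape the tests:

* **Chains only:** with subset selection, plausible sets shrink as findings
  grow *within one chain table*.  On branching trees the claim is false —
  a sibling scenario that starts matching can re-introduce diseases a
  cousin's leaf had dropped, with every selection still a subset of its
  parent's — so the property test generates chains.
* **Phase monotonicity:** with the expert fixed at the final-phase verdict
  and subset selection on, per-case accuracy is non-decreasing across
  phases: the system set only shrinks toward the expert set, so `c = e`
  and only the size penalty decays.

What passing these tests shows about real data is limited in the obvious
ways: real tables share vocabulary, experts are not perturbations of the
system, and disease prevalence is not uniform.  The harness measures the
mechanics of the method — matching, dialectic, metric — not clinical
performance.

## Problem sizes and determinism

The test suite and the acceptance script use 1000-instance samples for the
oracle and round-trip equivalences (knowledge bases of 1–4 tables, 2–6
rows), 200-case cohorts for the expert-model experiments and 150 cases for
phase monotonicity; the full run takes well under a minute on one core.
All randomness flows through explicit seeds (`random.Random`); results are
identical across runs and independent of table/row iteration order, which
the engine guarantees by sorting on ids.
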