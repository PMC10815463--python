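# argdx — argumentation-based differential diagnosis over scenario tables

`argdx` is a knowledge-based diagnostic engine for clinicians' workflows in
which information arrives incrementally: presenting complaint first, then
detailed symptoms, then examination findings.  Knowledge lives in
*diagnostic tables*: each table is rooted at a presenting complaint and its
rows form a hierarchy of increasingly specific scenarios, every row marking
(√) the diseases still supported under that scenario.  The engine matches a
patient's findings against these tables, forms one *argument* per matched
row and selected disease, and runs a dialectic comparison in which an
argument from a more specific scenario defeats arguments for diseases that
the deeper row no longer selects.  The result is a *spectrum* of plausible
diagnoses — not a single winner — each with a traceable explanation, plus
ranked guidance on which unobserved condition is worth establishing next.

The package is aimed at people building or studying explainable diagnostic
decision support: it provides the knowledge-base format and editor
operations, the reasoning engine with a brute-force verification oracle, an
evaluation harness that scores the system against an expert's differential,
and seeded generators for synthetic knowledge bases and patient cohorts.

## The model in brief

A table `T` has disease columns `d₁ … dₖ` and scenario rows arranged in a
tree; a child row inherits its ancestors' conditions and adds its own
(`++`).  Conditions are terms `predicate(subject, value)` or bare symptoms,
optionally grouped disjunctively (`burning +/ itching`).  For a finding set
`F` (open-world: absent means unknown), a row matches iff every condition
group on its root path is satisfied.  Within a table, arguments from a
strict descendant row are strictly stronger than those from its ancestors;
arguments from different tables are incomparable.  Each matched table's
verdict is the union of the selected sets of its *maximal* matched rows,
and the plausible set is the union of verdicts across tables.

The evaluation metric compares the system set `S` with an expert set `E`
over a universe of `D` diseases.  With `s = |S|`, `e = |E|`, `c = |S ∩ E|`:

```
accuracy = (c / e) · ( (D − |s − e|) / D )
```

It equals 1 exactly when `S = E`, and is near zero when the system proposes
every disease while the expert proposes one (e.g. `s = D = 137, e = c = 1`
gives `1/137 ≈ 0.0073`).  A patient case is scored at three cumulative
phases — first suspicions, initial diagnosis, final diagnosis — and cohorts
are summarized by phase means, group-by-phase means, and threshold
fractions (≥ 0.8 in all phases; case average > 0.5 and > 0.9).

## Worked example

The package ships the two sexually-transmitted-infection tables as
fixtures.  With profuse, thin, green vaginal discharge:

```sh
argdx diagnose --kb sti_discharge.yaml \
  --find vaginal_discharge --find "quantity(vd,profuse)" \
  --find "texture(vd,thin)" --find "colour(vd,green)"
```

prints (abridged):

```json
{
  "plausible": ["BV", "NG", "TM"],
  "defeats": [
    {"disease": "CM", "table_id": "sti_discharge", "defeating_row_id": "r2", "reason": "outranked"},
    {"disease": "VC", "table_id": "sti_discharge", "defeating_row_id": "r2", "reason": "outranked"}
  ],
  "matched_rows": {"sti_discharge": {"matched": ["r1", "r2"], "maximal": ["r2"]}}
}
```

Bacterial vaginosis, gonorrhoea and trichomoniasis remain plausible;
candidiasis and chlamydia were selected at the root scenario but dropped by
the deeper matched row `r2`, so they are reported as defeated.  Asking what
to check next:

```sh
argdx guide --kb sti_discharge.yaml --find vaginal_discharge \
  --find "quantity(vd,profuse)" --find "texture(vd,thin)" --find "colour(vd,green)" --text
# 1. texture(vd,frothy) (discrimination 1; sti_discharge)
```

Establishing frothy texture shrinks the differential from three diseases to
two (`BV`, `TM`).  Explanations are symmetrical:

```sh
argdx explain --kb sti_discharge.yaml ... --disease VC --text
# DEFEATED: VC — a more specific scenario applies: vaginal_discharge,
#   quantity(vd,profuse), texture(vd,thin), colour(vd,green) (sti_discharge/r2)
```

The same API is available in Python (`argdx.plausible_diagnoses`,
`argdx.explain`, `argdx.candidate_queries`, `argdx.evaluate_case`, ...),
and `argdx simulate` emits seeded synthetic knowledge bases (YAML) and
phased cohorts (JSON Lines) for experiments.

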