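# adaptiveq

**Adaptive questionnaires from rule-based clinical guidelines.**

Guideline-based clinical decision support — the motivating case is
STOPP/START-style medication review for elderly patients with polypharmacy —
needs patient data that electronic records rarely provide in coded form:
diagnoses, symptoms, histories. Asking a clinician to fill a static form with
every condition any rule might need is slow and noisy. `adaptiveq` turns a
production-rule base into an **unordered, exhaustive adaptive questionnaire**:
checkboxes appear only while they can still influence a recommendation, they
can be answered in any order, and every decision-relevant question is
eventually shown — so the rules fire exactly as they would under full
knowledge.

The package is for health-informatics developers and researchers building or
studying rule-based CDSS front-ends: it contains the compiler, the evaluation
engine, the question-ordering optimisers, a synthetic test-bed, and a CLI.

## The method

A clinical rule over clinical conditions `C` and non-clinical conditions `D`
(drugs, labs — assumed already known and coded) is a 6-element tuple

```
R = (Cᵖ, Dᵖ, Cᵃ, Dᵃ, U = [(Cᵘ¹, Dᵘ¹), ...], A)
```

read as ⋀Cᵖ ∧ ⋀Dᵖ ∧ ⋀¬Cᵃ ∧ ⋀¬Dᵃ ∧ ⋀ᵤ(⋁Cᵘ ∨ ⋁Dᵘ) → A. Given a strict total
priority order `≺` over the clinical conditions, each rule is compiled into
*display rules* concluding `display(x)` for each clinical condition x it
mentions — five generator schemes (`p`, `a1`, `a2`, `u1`, `u2`) for present
conditions, absent conditions, and union members respectively. The
questionnaire shows the union of targets of all satisfied display rules,
recomputed under the closed-world assumption after every change. Present
conditions are asked before absent ones (a condition is a priori more likely
false than true), and within `Cᵖ` only the `≺`-first unchecked condition is
shown.

Choosing `≺` to minimise the number of conditions on the *initial* screen is
NP-hard (it embeds a Generalized Traveling Salesman Problem over the 2ⁿ
subsets of `C`). The package ships the occurrence-count heuristic (sort by
decreasing number of rules mentioning a condition), an exact brute-force
optimiser, a seeded random-restart hill-climbing search, and the GTSP
formulation as an independent oracle.

## Worked example

The packaged fixture `stoppstart_d2d6` holds two real guideline rules:

* START D2 — *start fibre supplements for diverticulosis with a history of
  constipation*: `constipation ∧ diverticulosis ∧ ¬fibre → start(fibre)`
* STOPP D6 — *stop antipsychotics in those with parkinsonism or Lewy body
  disease*: `antipsychotic ∧ (parkinsonism ∨ lewy_body) → stop(antipsychotic)`

```python
from adaptiveq import (ConditionOrder, PatientProfile, compile_all,
                       displayed_conditions, load_fixture)

rb = load_fixture("stoppstart_d2d6")
rules = compile_all(rb, ConditionOrder(rb.clinical_ids))
len(rules)                                           # 6 display rules
displayed_conditions(rules, PatientProfile())        # {'constipation'}
displayed_conditions(rules, PatientProfile(
    nonclinical_true=frozenset({"fibre"})))          # set()
displayed_conditions(rules, PatientProfile(
    clinical_checked=frozenset({"constipation"})))   # {'constipation', 'diverticulosis'}
```

With no drugs, a single checkbox is shown out of four clinical conditions;
checking it reveals the second D2 condition; a prescribed fibre supplement
suppresses the D2 questions entirely (the rule can no longer fire). With an
antipsychotic on the drug list, both union members of D6 appear, and checking
one hides the other.

The same pipeline from the shell:

```sh
$ adaptiveq compile d2d6.yaml --order declaration
{ "total": 6,
  "per_generator": {"p": 2, "a1": 0, "a2": 0, "u1": 2, "u2": 2}, ... }

$ adaptiveq simulate d2d6.yaml --patients 3 --seed 1
{ ...,
  "patients": [
    {"patient": 0, "n_drugs": 2, "questions_asked": 2,
     "displayed_fraction": 0.5, "rules_triggered": ["D6"]},
    {"patient": 1, "n_drugs": 0, "questions_asked": 1,
     "displayed_fraction": 0.25, "rules_triggered": []},
    {"patient": 2, "n_drugs": 2, "questions_asked": 2,
     "displayed_fraction": 0.5, "rules_triggered": []}],
  "mean_questions_asked": 1.6666666666666667,
  "mean_displayed_fraction": 0.4166666666666667 }
```

`questions_asked` counts the distinct clinical conditions ever displayed
during a truthful data-entry session; `rules_triggered` are the guideline
rules firing on the final profile. Subcommands: `validate`, `compile`,
`order`, `simulate`, `gen` (see `adaptiveq --help`).

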