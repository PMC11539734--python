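# Methods

## Rule model

A rule base is a catalogue of conditions plus `m` production rules. Clinical
conditions (`C`, size `n`) are unknown at session start and must be asked;
non-clinical conditions (`D`: drug prescriptions, lab results) are assumed
already known and coded. Each rule is the 6-tuple
`(Cᵖ, Dᵖ, Cᵃ, Dᵃ, U, A)`: conditions required present, required absent, a
list of disjunctive unions (each a pair of clinical/non-clinical member
sets), and an opaque action. Terminology codes (ICD10/ATC/LOINC) are display
metadata only — evaluation matches ids, which keeps the semantics independent
of any terminology service. Identity of a union is its list index, not its
member sets, so two unions with equal clinical members remain distinct.
Validation rejects a condition appearing in two roles of one rule, empty
premises, and empty unions; the file format is YAML/JSON with a JSON-Schema
description shipped under `src/adaptiveq/schema/` (enforced structurally by
the parser itself).

Lab-test conditions may be modelled as either kind; the package default is
non-clinical (already coded), but a user who wants labs asked in the
questionnaire simply declares them clinical.

## Display-rule compilation

Design assumptions: (a) fewer visible questions is better; (b) non-clinical
conditions are known up front and are evaluated first; (c) a clinical
condition is a priori more likely false than true, so present-requirements
are asked before absent-requirements. A strict total order `≺` on `C` breaks
ties inside a rule.

Five generators per rule (all premises are 6-tuples again, so one evaluator
serves both rule kinds):

| kind | target | premise |
|------|--------|---------|
| `p`  | x ∈ Cᵖ | {c ∈ Cᵖ | c ≺ x}, Dᵖ, Cᵃ, Dᵃ, unions whose clinical members all ≺ x |
| `a1` | x ∈ Cᵃ | Cᵖ, Dᵖ, Cᵃ∖{x}, Dᵃ, U |
| `a2` | x ∈ Cᵃ | {x}, Dᵖ, {c ∈ Cᵃ | c ≺ x}, Dᵃ, ∅ |
| `u1` | x ∈ Cᵘᵏ | {c ∈ Cᵖ | c ≺ x}, Dᵖ, Cᵃ ∪ (Cᵘᵏ∖{x}), Dᵃ ∪ Dᵘᵏ, other gated unions |
| `u2` | x ∈ Cᵘᵏ | {c ∈ Cᵖ | c ≺ x} ∪ {x}, Dᵖ, Cᵃ, Dᵃ, other gated unions |

"Gated" unions are those whose clinical members all precede x — vacuously
true for drug-only unions, which are therefore always retained. In `u1` the
target's own union contributes its *other* members to the absent slots; the
target is never negated in its own premise (its visibility while checked is
`u2`'s job, and the displayed set is identical either way). `a2`/`u2` exist
solely so a condition set outside the questionnaire (e.g. imported from an
EHR) stays visible and can be retracted.

Compilation is eager: the set `R^d` (size `Σ(|Cᵖ| + 2|Cᵃ| + 2Σₖ|Cᵘᵏ|)`) is
materialized once per order; only evaluation is repeated when the profile
changes. Duplicate display rules from different sources are kept with
provenance (`generator`, `source_rule`) — the displayed set is a union, so
duplicates are harmless, and provenance supports explanation. Whether
duplicates should instead be merged is an open design point; we favour
explainability.

## Engine semantics

Evaluation is two-valued and closed-world: unanswered means false. The
displayed set is `{x | some display rule with target x is satisfied}` — a
pure function of (display rules, profile), no fixpoint, since display
conclusions never feed premises. `step` applies one event (check, uncheck,
set/unset drug, choose code) and reports appear/disappear diffs for UI
highlighting; check/uncheck are only accepted for currently displayed
conditions, while hidden conditions silently retain their value (explicit
profile edits model EHR imports). Unchecking a gating condition does *not*
clear dependent checked conditions: the dependent value is retained and
merely hidden, and reappears intact when the gate is re-checked. A checked
but hidden condition does count toward rule triggering — it is part of the
profile. Code choices never affect evaluation.

`simulate_session` drives a whole session against a complete ground-truth
patient. The default greedy-truthful policy checks, per round, every
displayed unchecked condition that is true in the ground truth, applied as
one batch (every member of the round was visible when the round began; the
checked set grows monotonically, so the session terminates). A
one-condition-per-step policy probes order sensitivity; arbitrary callable
policies are capped at 10·|C| events to guard against non-termination.

The central correctness property — exhaustiveness — is that after a truthful
session the triggered rules equal `triggered_rules(ground truth)`. The test
suite and the acceptance script verify this over ≥1000 seeded random
(rule base, patient) pairs.

## Ordering

The objective is the number of distinct clinical conditions displayed when no
clinical condition has been entered yet (drugs/labs known). Implemented
routes:

* `occurrence_order` — sort by decreasing number of rules mentioning the
  condition (counting rules, not slots); ties and unmentioned conditions keep
  catalogue declaration order. Patient-independent, the production choice.
* `brute_force_order` — exact enumeration over the conditions that occur in
  rules (others cannot affect the objective and are appended); deterministic
  tie-break to the lexicographically smallest optimal permutation by
  declaration index. Capped at 9 occurring conditions (9! permutations of a
  cheap objective; the suite uses ≤ 7).
* `stochastic_order` — random-restart hill climbing over adjacent
  transpositions, first restart seeded at the heuristic order (so its value
  never exceeds the heuristic's), remaining restarts random, all driven by a
  single seed. The optimizer is a pluggable callable so other permutation
  metaheuristics can be swapped in; hill climbing was chosen as a simple,
  reproducible default.

Inside the search loops the objective uses a specialized evaluator: with no
clinical condition entered only `p`, `a1` and `u1` rules can fire, and their
premises reduce to drug-set membership plus priority comparisons. The tests
check this evaluator against the compile-and-run route and against a literal
transcription of the formulas (three independent routes).

### GTSP formulation

On restricted rule bases (only `Cᵖ` non-empty, all patient conditions false)
the ordering problem is a Generalized TSP: towns are the 2ⁿ subsets of `C`
(the set already placed in the order under construction), area `A_k` holds
the size-k subsets, and the asymmetric distance matrix is

```
M(i, j) = 0   if |i| = n and |j| = 0          (closing edge)
          +∞  if |j| ≠ |i| + 1                 (areas visited in order)
          1   if ∃r: j∖i ⊆ Cᵖᵣ and i ∩ Cᵖᵣ = ∅ (the move displays a condition)
          0   otherwise
```

Because a town stands for a *growing* order, consecutive towns in a valid
tour are nested — each adds exactly one condition — and `gtsp_bruteforce`
searches exactly those tours. The area constraint alone would also admit
finite-cost moves between non-nested sets of consecutive sizes, and such
tours can undercut the true objective (three single-condition rules give a
non-nested tour of cost 2 versus a true optimum of 3), so they are excluded
as inconsistent with the town semantics. The optimal order is recovered from
successive tour differences, and on every restricted instance in the suite
the tour cost equals the direct brute-force optimum. Town materialization is
capped at n = 6 (64 towns); larger instances are refused rather than
approximated.

## Synthetic test-bed

`gen_rulebase` draws per-rule slot sizes uniformly from configurable ranges
(defaults: |Cᵖ| 0–3, |Cᵃ| 0–2, 0–2 unions of 1–3 clinical members, |Dᵃ| 0–1)
over a catalogue of 8 clinical and 6 non-clinical conditions, with roles
disjoint by construction and premises never empty; every generated base is
round-tripped through the parser so it satisfies the same contract as
user-supplied files. `drug_gated_fraction` is the probability that a rule
requires a present drug (|Dᵖ| 1–2): 1.0 emulates STOPP-style bases, where
every rule is gated by a prescription, 0.0 START-style ones. A union gains a
non-clinical member with probability 0.3 so drug-bearing unions are exercised.
`gen_independent_rulebase` builds rules over pairwise-disjoint private
condition sets — the regime where every order yields the same objective and
the occurrence heuristic is already optimal. `gen_patient` draws each
clinical condition true with probability `p` = 0.2 (conditions are more
often false than true) and each drug with `q` = 0.5 (0.15 where a sparse
polypharmacy-like profile is contrasted).

What the generator does **not** emulate: real guideline structure
(hierarchical drug classes, correlated comorbidities, shared conditions
across many rules at realistic frequencies), terminology subsumption, or the
size of a full guideline encoding (~124 rules, 73 conditions). Passing tests
therefore establish the algorithmic guarantees — exhaustiveness, count closed
forms, reduction equivalence, heuristic dominance — not clinical performance
figures on any real guideline.

## Problem sizes and numerical choices

The acceptance run uses 1000 rule-base/patient pairs for exhaustiveness,
15 restricted bases (n = 5) for the GTSP oracle, 15 general bases (n = 7)
for heuristic dominance, 100 bases for the count closed form, 25 independent
bases for heuristic parity, and 2 × 30 bases for the STOPP/START contrast —
all sizes chosen so that exact enumeration stays comfortable on one CPU while
the stochastic checks remain well-powered. All randomness flows from one
`--seed`. Ties everywhere break by catalogue declaration order; orders are
plain permutations, so there is no floating-point tolerance anywhere in the
core (the only float arithmetic is the +∞ entries of the GTSP matrix and
reported fractions).

## Known limitations

* No cardinality premises ("at least x of y conditions").
* No "is-a" subsumption between conditions; every condition is independent.
* Mid-session re-ordering is not implemented: `≺` is fixed when the form
  opens (the objective is defined on the empty initial form).
* The AFB-style metaheuristic itself is not bundled; the pluggable optimizer
  interface accepts one.
* The questionnaire state model covers grouping and appear/disappear diffs;
  rendering is out of scope.
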