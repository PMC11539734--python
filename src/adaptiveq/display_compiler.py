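"""Compile clinical rules into display rules.

A *display rule* concludes ``display(x)`` for a clinical condition x: it
decides whether the questionnaire should currently show the checkbox for x.
The questionnaire shows exactly the conditions concluded by at least one
satisfied display rule, and the set is recomputed after every change to the
patient profile — that re-execution, not re-compilation, is what adapts the
form.

Compilation assumes that (a) fewer visible questions is better, (b)
non-clinical conditions (drugs, labs) are already known and therefore
evaluated first, and (c) a clinical condition is a priori more likely false
than true, so conditions required *present* are asked before conditions
required *absent*.  A strict total priority order ``≺`` over the clinical
conditions breaks the remaining ties: when a rule needs several present
conditions, only the ≺-first is shown until it is checked.

Five generators produce display rules from one clinical rule
(C^p, D^p, C^a, D^a, U, A):

* ``p``  — one rule per x ∈ C^p: show x once every present condition with
  higher priority is true (and the rest of the premise holds);
* ``a1`` — per x ∈ C^a: show x once everything else in the premise holds,
  so the user can deny/confirm the contra-indication last;
* ``a2`` — per x ∈ C^a: keep x visible when it is already true (e.g. set by
  an EHR import) so the user can still uncheck it;
* ``u1`` — per clinical member x of a union: show x while no member of that
  union is true yet;
* ``u2`` — per clinical member x of a union: keep x visible when x itself is
  true, the union analogue of ``a2``.
"""

from __future__ import annotations

from dataclasses import dataclass

from .rule_model import ClinicalRule, Premise, RuleBase, UnionGroup

__all__ = [
    "ConditionOrder",
    "DisplayRule",
    "compile_present",
    "compile_absent",
    "compile_union_member",
    "compile_all",
    "display_rule_count",
]


@dataclass(frozen=True)
class ConditionOrder:
    """A strict total priority order over clinical condition ids.

    ``sequence[0]`` has the highest priority; ``c1 ≺ c2`` iff c1 precedes c2.
    """

    sequence: tuple[str, ...]

    def __post_init__(self) -> None:
        if len(set(self.sequence)) != len(self.sequence):
            raise ValueError("order contains duplicate condition ids")
        object.__setattr__(
            self, "_rank", {c: i for i, c in enumerate(self.sequence)}
        )

    @property
    def rank(self) -> dict[str, int]:
        return self._rank  # type: ignore[attr-defined]

    def precedes(self, a: str, b: str) -> bool:
        """True iff a ≺ b."""
        return self.rank[a] < self.rank[b]

    def covers(self, ids) -> bool:
        return set(ids) <= set(self.sequence)


@dataclass(frozen=True)
class DisplayRule:
    """A compiled rule concluding display(target).

    ``generator`` records which of the five schemes produced it and
    ``source_rule`` the clinical rule it came from, for provenance and
    explanation.
    """

    premise: Premise
    target: str
    generator: str  # one of p, a1, a2, u1, u2
    source_rule: str


def _preceding(ids: frozenset[str], x: str, order: ConditionOrder) -> frozenset[str]:
    rank = order.rank
    rx = rank[x]
    return frozenset(c for c in ids if rank[c] < rx)


def _gated_unions(
    unions: tuple[UnionGroup, ...],
    x: str,
    order: ConditionOrder,
    skip_index: int | None = None,
) -> tuple[UnionGroup, ...]:
    """Unions retained in a compiled premise: those whose clinical members all
    precede x.  A union with no clinical member is always retained (the
    quantifier is vacuously true).  ``skip_index`` drops the union the target
    itself belongs to."""
    rank = order.rank
    rx = rank[x]
    kept = []
    for k, u in enumerate(unions):
        if k == skip_index:
            continue
        if all(rank[c] < rx for c in u.clinical):
            kept.append(u)
    return tuple(kept)


def compile_present(
    rule: ClinicalRule, x: str, order: ConditionOrder
) -> DisplayRule:
    """Display rule for x ∈ C^p: show x once the premise holds restricted to
    higher-priority clinical conditions."""
    if x not in rule.present_clinical:
        raise ValueError(f"{x!r} is not a present clinical condition of rule {rule.id}")
    premise = Premise(
        present_clinical=_preceding(rule.present_clinical, x, order),
        present_nonclinical=rule.present_nonclinical,
        absent_clinical=rule.absent_clinical,
        absent_nonclinical=rule.absent_nonclinical,
        unions=_gated_unions(rule.unions, x, order),
    )
    return DisplayRule(premise, x, "p", rule.id)


def compile_absent(
    rule: ClinicalRule, x: str, order: ConditionOrder
) -> tuple[DisplayRule, DisplayRule]:
    """Display rules (a1, a2) for x ∈ C^a.

    a1 shows x when every other part of the premise is satisfied; a2 keeps x
    visible whenever x is already true and the non-clinical context plus
    higher-priority absent conditions still hold, so a value set outside the
    questionnaire can be retracted.
    """
    if x not in rule.absent_clinical:
        raise ValueError(f"{x!r} is not an absent clinical condition of rule {rule.id}")
    a1 = DisplayRule(
        Premise(
            present_clinical=rule.present_clinical,
            present_nonclinical=rule.present_nonclinical,
            absent_clinical=rule.absent_clinical - {x},
            absent_nonclinical=rule.absent_nonclinical,
            unions=rule.unions,
        ),
        x,
        "a1",
        rule.id,
    )
    a2 = DisplayRule(
        Premise(
            present_clinical=frozenset({x}),
            present_nonclinical=rule.present_nonclinical,
            absent_clinical=_preceding(rule.absent_clinical, x, order),
            absent_nonclinical=rule.absent_nonclinical,
            unions=(),
        ),
        x,
        "a2",
        rule.id,
    )
    return a1, a2


def compile_union_member(
    rule: ClinicalRule, k: int, x: str, order: ConditionOrder
) -> tuple[DisplayRule, DisplayRule]:
    """Display rules (u1, u2) for clinical member x of union k.

    u1 shows x while no member of union k is true (the other members move to
    the absent slots); u2 keeps x visible when x itself is true.  Other unions
    are identified by index and retained only when all their clinical members
    precede x (vacuously for drug-only unions).
    """
    union = rule.unions[k]
    if x not in union.clinical:
        raise ValueError(f"{x!r} is not a clinical member of union {k} of rule {rule.id}")
    others = _gated_unions(rule.unions, x, order, skip_index=k)
    preceding_p = _preceding(rule.present_clinical, x, order)
    u1 = DisplayRule(
        Premise(
            present_clinical=preceding_p,
            present_nonclinical=rule.present_nonclinical,
            absent_clinical=rule.absent_clinical | (union.clinical - {x}),
            absent_nonclinical=rule.absent_nonclinical | union.nonclinical,
            unions=others,
        ),
        x,
        "u1",
        rule.id,
    )
    u2 = DisplayRule(
        Premise(
            present_clinical=preceding_p | {x},
            present_nonclinical=rule.present_nonclinical,
            absent_clinical=rule.absent_clinical,
            absent_nonclinical=rule.absent_nonclinical,
            unions=others,
        ),
        x,
        "u2",
        rule.id,
    )
    return u1, u2


def compile_all(rb: RuleBase, order: ConditionOrder) -> list[DisplayRule]:
    """Compile the whole display-rule set R^d.

    For every rule: one ``p`` rule per present clinical condition, an
    (``a1``, ``a2``) pair per absent clinical condition, and a (``u1``,
    ``u2``) pair per clinical union member, hence

        |R^d| = Σ_rules ( |C^p| + 2·|C^a| + 2·Σ_k |C^uk| ).

    Rules whose premise mentions no clinical condition yield nothing.
    Duplicate premises from different sources are kept — displayed-set
    computation is a union, and provenance aids explanation.
    """
    if not order.covers(rb.clinical_ids):
        missing = set(rb.clinical_ids) - set(order.sequence)
        raise ValueError(f"order does not cover clinical conditions: {sorted(missing)}")
    out: list[DisplayRule] = []
    for rule in rb.rules:
        for x in sorted(rule.present_clinical, key=order.rank.__getitem__):
            out.append(compile_present(rule, x, order))
        for x in sorted(rule.absent_clinical, key=order.rank.__getitem__):
            out.extend(compile_absent(rule, x, order))
        for k, union in enumerate(rule.unions):
            for x in sorted(union.clinical, key=order.rank.__getitem__):
                out.extend(compile_union_member(rule, k, x, order))
    return out


def display_rule_count(rb: RuleBase) -> int:
    """Closed-form size of R^d, independent of the order."""
    return sum(
        len(r.present_clinical)
        + 2 * len(r.absent_clinical)
        + 2 * sum(len(u.clinical) for u in r.unions)
        for r in rb.rules
    )
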