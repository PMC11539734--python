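"""Seeded generators for rule bases and ground-truth patients, plus fixtures.

The generators emulate the structural features of screening guidelines such
as STOPP/START: short conjunctive premises over a modest condition catalogue,
occasional disjunctive unions, and — for STOPP-style rules — a drug that must
be present, which is what lets the questionnaire hide most clinical questions
for patients not taking the drug.  ``drug_gated_fraction`` controls the
probability that a generated rule carries such a present-drug gate (1.0
emulates a pure STOPP-style base, 0.0 a START-style one).

Patients are drawn condition-wise independently: clinical conditions are true
with probability ``p`` (default 0.2 — clinical conditions are a priori more
likely false than true) and drugs/labs with probability ``q`` (default 0.5).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources

import numpy as np

from .engine import PatientProfile
from .rule_model import (
    CLINICAL,
    DEFAULT_CATEGORIES,
    NONCLINICAL,
    ClinicalRule,
    Condition,
    Premise,
    RuleBase,
    UnionGroup,
    parse_rulebase,
    serialize_rulebase,
)

__all__ = [
    "RuleBaseSpec",
    "PatientSpec",
    "gen_rulebase",
    "gen_patient",
    "gen_independent_rulebase",
    "load_fixture",
    "FIXTURES",
]

FIXTURES = ("stoppstart_d2d6", "stoppstart_demo")


@dataclass(frozen=True)
class RuleBaseSpec:
    """Shape parameters for a synthetic rule base.

    Per-rule slot sizes are drawn uniformly from the inclusive ranges below;
    roles are disjoint by construction and a premise is never left empty.
    """

    n_clinical: int = 8
    n_nonclinical: int = 6
    m: int = 6
    present_clinical_size: tuple[int, int] = (0, 3)
    absent_clinical_size: tuple[int, int] = (0, 2)
    union_count: tuple[int, int] = (0, 2)
    union_clinical_size: tuple[int, int] = (1, 3)
    present_nonclinical_size: tuple[int, int] = (1, 2)  # applies when drug-gated
    absent_nonclinical_size: tuple[int, int] = (0, 1)
    drug_gated_fraction: float = 0.5
    union_nonclinical_prob: float = 0.3
    seed: int = 0


@dataclass(frozen=True)
class PatientSpec:
    """Prevalence parameters for a synthetic ground-truth patient."""

    p: float = 0.2  # clinical condition prevalence
    q: float = 0.5  # drug/lab prevalence
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 <= self.p <= 1.0 and 0.0 <= self.q <= 1.0):
            raise ValueError("prevalences must lie in [0, 1]")


def _catalogue(n_clinical: int, n_nonclinical: int) -> tuple[Condition, ...]:
    conditions = [
        Condition(
            id=f"c{i + 1:03d}",
            kind=CLINICAL,
            label=f"Clinical condition {i + 1}",
            category=DEFAULT_CATEGORIES[i % len(DEFAULT_CATEGORIES)],
        )
        for i in range(n_clinical)
    ]
    conditions += [
        Condition(
            id=f"d{i + 1:03d}",
            kind=NONCLINICAL,
            label=f"Drug/lab {i + 1}",
        )
        for i in range(n_nonclinical)
    ]
    return tuple(conditions)


def _draw(rng: np.random.Generator, lo_hi: tuple[int, int]) -> int:
    lo, hi = lo_hi
    return int(rng.integers(lo, hi + 1))


def gen_rulebase(spec: RuleBaseSpec) -> RuleBase:
    """Generate a valid rule base; identical spec (incl. seed) ⇒ identical output."""
    if spec.n_clinical < 1:
        raise ValueError("need at least one clinical condition")
    if spec.m < 0 or spec.n_nonclinical < 0:
        raise ValueError("infeasible spec")
    rng = np.random.default_rng(spec.seed)
    catalogue = _catalogue(spec.n_clinical, spec.n_nonclinical)
    clinical = [c.id for c in catalogue if c.kind == CLINICAL]
    nonclinical = [c.id for c in catalogue if c.kind == NONCLINICAL]

    rules = []
    for r in range(spec.m):
        # disjoint roles: consume from per-rule shuffled pools
        cpool = list(rng.permutation(np.array(clinical, dtype=object)))
        dpool = list(rng.permutation(np.array(nonclinical, dtype=object)))

        def take(pool: list, k: int) -> frozenset[str]:
            taken = pool[:k]
            del pool[:k]
            return frozenset(str(x) for x in taken)

        cp = take(cpool, _draw(rng, spec.present_clinical_size))
        ca = take(cpool, _draw(rng, spec.absent_clinical_size))
        unions = []
        for _ in range(_draw(rng, spec.union_count)):
            uc = take(cpool, min(_draw(rng, spec.union_clinical_size), len(cpool)))
            ud = (
                take(dpool, 1)
                if rng.random() < spec.union_nonclinical_prob and dpool
                else frozenset()
            )
            if uc or ud:
                unions.append(UnionGroup(uc, ud))
        if rng.random() < spec.drug_gated_fraction:
            dp = take(dpool, min(_draw(rng, spec.present_nonclinical_size), len(dpool)))
        else:
            dp = frozenset()
        da = take(dpool, min(_draw(rng, spec.absent_nonclinical_size), len(dpool)))

        if not (cp or ca or unions or dp or da):
            cp = take(cpool, 1)  # never emit an empty premise

        rules.append(
            ClinicalRule(
                id=f"r{r + 1:03d}",
                premise=Premise(
                    present_clinical=cp,
                    present_nonclinical=dp,
                    absent_clinical=ca,
                    absent_nonclinical=da,
                    unions=tuple(unions),
                ),
                action=f"act(r{r + 1:03d})",
            )
        )
    rb = RuleBase(catalogue=catalogue, rules=tuple(rules))
    # generated bases must satisfy the same contract as parsed ones
    return parse_rulebase(serialize_rulebase(rb))


def gen_independent_rulebase(
    m: int = 6, conditions_per_rule: tuple[int, int] = (1, 3), seed: int = 0
) -> RuleBase:
    """Rule base whose rules share no conditions (each rule owns its own).

    Every rule is a pure present-clinical conjunction over private conditions,
    so the initial-display objective is the same for every priority order —
    the regime in which the occurrence heuristic is already optimal.
    """
    rng = np.random.default_rng(seed)
    sizes = [_draw(rng, conditions_per_rule) for _ in range(m)]
    n = sum(sizes)
    catalogue = _catalogue(n, 0)
    clinical = [c.id for c in catalogue]
    rules = []
    start = 0
    for r, size in enumerate(sizes):
        cp = frozenset(clinical[start : start + size])
        start += size
        rules.append(
            ClinicalRule(
                id=f"r{r + 1:03d}",
                premise=Premise(present_clinical=cp),
                action=f"act(r{r + 1:03d})",
            )
        )
    return RuleBase(catalogue=catalogue, rules=tuple(rules))


def gen_patient(rb: RuleBase, spec: PatientSpec) -> PatientProfile:
    """Complete ground-truth profile: independent Bernoulli draws per condition."""
    rng = np.random.default_rng(spec.seed)
    clinical = frozenset(
        cid for cid in rb.clinical_ids if rng.random() < spec.p
    )
    drugs = frozenset(
        cid for cid in rb.nonclinical_ids if rng.random() < spec.q
    )
    return PatientProfile(nonclinical_true=drugs, clinical_checked=clinical)


def load_fixture(name: str) -> RuleBase:
    """Load a packaged rule-base fixture by name.

    ``stoppstart_d2d6`` holds exactly the START D2 and STOPP D6 rules;
    ``stoppstart_demo`` adds eight illustrative (non-normative) rules
    exercising every display-rule generator.
    """
    if name not in FIXTURES:
        raise ValueError(f"unknown fixture {name!r}; available: {FIXTURES}")
    text = (
        resources.files("adaptiveq") / "fixtures" / f"{name}.yaml"
    ).read_text()
    return parse_rulebase(text)
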