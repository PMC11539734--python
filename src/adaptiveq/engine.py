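"""Closed-world rule evaluation and interactive questionnaire sessions.

The engine evaluates premises under the closed-world assumption: a condition
absent from the profile's truth sets is false.  Unanswered questionnaire items
are therefore "no", matching how checkbox forms are read in practice.

Two rule sets are evaluated against the same profile:

* the clinical rules themselves (``triggered_rules``) — the guideline
  recommendations that fire for the patient;
* the compiled display rules (``displayed_conditions``) — which clinical
  conditions the questionnaire currently shows.  This is a pure recomputation
  (display conclusions never feed premises), so no fixpoint is needed.

``step`` applies one user event (check/uncheck a condition, edit the drug
list, pick a terminology code) and reports which checkboxes appeared or
disappeared; ``simulate_session`` drives a whole session against a
ground-truth patient, the harness behind the exhaustiveness guarantee: after
a truthful session, exactly the rules that hold under full knowledge have
fired.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from typing import Callable, Iterable, Mapping, Sequence

from .display_compiler import DisplayRule
from .rule_model import CLINICAL, NONCLINICAL, Condition, Premise, RuleBase

__all__ = [
    "PatientProfile",
    "QuestionnaireState",
    "SessionTrace",
    "Check",
    "Uncheck",
    "SetDrug",
    "UnsetDrug",
    "ChooseCode",
    "EngineError",
    "UnknownEventTargetError",
    "NotDisplayedError",
    "premise_satisfied",
    "triggered_rules",
    "displayed_conditions",
    "initial_state",
    "step",
    "simulate_session",
]


class EngineError(ValueError):
    """Base class for session errors."""


class UnknownEventTargetError(EngineError):
    """An event references an id absent from the catalogue (or of wrong kind)."""


class NotDisplayedError(EngineError):
    """Check/uncheck of a condition that is not currently displayed.

    Hidden conditions keep their value; they may only change through explicit
    profile edits (e.g. an EHR import), not through questionnaire events.
    """


@dataclass(frozen=True)
class PatientProfile:
    """A closed-world truth assignment over the catalogue.

    ``nonclinical_true`` holds the drugs/lab facts present; ``clinical_checked``
    the clinical conditions currently asserted true.  Anything else is false.
    ``code_choice`` maps a clinical id to the terminology code the user picked;
    it never affects rule evaluation, which matches ids only.
    """

    nonclinical_true: frozenset[str] = frozenset()
    clinical_checked: frozenset[str] = frozenset()
    code_choice: tuple[tuple[str, str], ...] = ()

    @property
    def truths(self) -> frozenset[str]:
        return self.nonclinical_true | self.clinical_checked

    def to_json(self) -> str:
        return json.dumps(
            {
                "nonclinical_true": sorted(self.nonclinical_true),
                "clinical_checked": sorted(self.clinical_checked),
                **(
                    {"code_choice": dict(sorted(self.code_choice))}
                    if self.code_choice
                    else {}
                ),
            }
        )

    @classmethod
    def from_json(cls, text: str) -> "PatientProfile":
        doc = json.loads(text)
        return cls(
            nonclinical_true=frozenset(doc.get("nonclinical_true", [])),
            clinical_checked=frozenset(doc.get("clinical_checked", [])),
            code_choice=tuple(sorted(doc.get("code_choice", {}).items())),
        )


@dataclass(frozen=True)
class QuestionnaireState:
    """The visible face of the questionnaire after the latest recomputation."""

    displayed: frozenset[str]
    newly_appeared: frozenset[str] = frozenset()
    disappeared_last_step: frozenset[str] = frozenset()
    by_category: tuple[tuple[str, tuple[str, ...]], ...] = ()

    def grouped(self) -> dict[str, tuple[str, ...]]:
        """Displayed conditions grouped by catalogue category."""
        return dict(self.by_category)


# user events --------------------------------------------------------------


@dataclass(frozen=True)
class Check:
    condition: str


@dataclass(frozen=True)
class Uncheck:
    condition: str


@dataclass(frozen=True)
class SetDrug:
    drug: str


@dataclass(frozen=True)
class UnsetDrug:
    drug: str


@dataclass(frozen=True)
class ChooseCode:
    condition: str
    code: str


Event = Check | Uncheck | SetDrug | UnsetDrug | ChooseCode


@dataclass(frozen=True)
class SessionTrace:
    """Record of a simulated data-entry session."""

    steps: tuple[tuple[Event, frozenset[str]], ...]
    initial_displayed: frozenset[str]
    ever_displayed: frozenset[str]
    final_profile: PatientProfile
    triggered: frozenset[str]

    @property
    def questions_asked(self) -> int:
        """Number of distinct clinical conditions ever displayed."""
        return len(self.ever_displayed)


# evaluation ---------------------------------------------------------------


def premise_satisfied(premise: Premise, profile: PatientProfile) -> bool:
    """Closed-world evaluation of a six-slot premise.

    True iff all present conditions are in the profile's truths, no absent
    condition is, and every union has at least one true member.  The empty
    premise is vacuously true.
    """
    truths = profile.truths
    if not premise.present_clinical <= truths:
        return False
    if not premise.present_nonclinical <= truths:
        return False
    if premise.absent_clinical & truths or premise.absent_nonclinical & truths:
        return False
    for u in premise.unions:
        if not (u.clinical & truths or u.nonclinical & truths):
            return False
    return True


def triggered_rules(rb: RuleBase, profile: PatientProfile) -> frozenset[str]:
    """Ids of the clinical rules whose premise holds for the profile."""
    return frozenset(
        r.id for r in rb.rules if premise_satisfied(r.premise, profile)
    )


def displayed_conditions(
    display_rules: Sequence[DisplayRule], profile: PatientProfile
) -> frozenset[str]:
    """Clinical conditions with at least one satisfied display rule."""
    return frozenset(
        dr.target for dr in display_rules if premise_satisfied(dr.premise, profile)
    )


def _group(
    displayed: frozenset[str], catalogue: Sequence[Condition]
) -> tuple[tuple[str, tuple[str, ...]], ...]:
    groups: dict[str, list[str]] = {}
    for c in catalogue:
        if c.id in displayed:
            groups.setdefault(c.category, []).append(c.id)
    return tuple((cat, tuple(ids)) for cat, ids in sorted(groups.items()))


def initial_state(
    rb: RuleBase,
    display_rules: Sequence[DisplayRule],
    profile: PatientProfile,
) -> QuestionnaireState:
    """Questionnaire state when the form is first opened (nothing flagged new)."""
    displayed = displayed_conditions(display_rules, profile)
    return QuestionnaireState(
        displayed=displayed, by_category=_group(displayed, rb.catalogue)
    )


# interaction --------------------------------------------------------------


def _apply_event(
    rb: RuleBase, profile: PatientProfile, state: QuestionnaireState, event: Event
) -> PatientProfile:
    by_id = rb.conditions_by_id

    def _known(cid: str, kind: str) -> Condition:
        cond = by_id.get(cid)
        if cond is None:
            raise UnknownEventTargetError(f"unknown condition id {cid!r}")
        if cond.kind != kind:
            raise UnknownEventTargetError(
                f"{cid!r} is {cond.kind}, expected {kind}"
            )
        return cond

    if isinstance(event, (Check, Uncheck)):
        _known(event.condition, CLINICAL)
        if event.condition not in state.displayed:
            raise NotDisplayedError(
                f"{event.condition!r} is not currently displayed"
            )
        if isinstance(event, Check):
            return replace(
                profile, clinical_checked=profile.clinical_checked | {event.condition}
            )
        return replace(
            profile, clinical_checked=profile.clinical_checked - {event.condition}
        )
    if isinstance(event, SetDrug):
        _known(event.drug, NONCLINICAL)
        return replace(
            profile, nonclinical_true=profile.nonclinical_true | {event.drug}
        )
    if isinstance(event, UnsetDrug):
        _known(event.drug, NONCLINICAL)
        return replace(
            profile, nonclinical_true=profile.nonclinical_true - {event.drug}
        )
    if isinstance(event, ChooseCode):
        cond = _known(event.condition, CLINICAL)
        if event.code not in cond.codes:
            raise UnknownEventTargetError(
                f"{event.code!r} is not a code of {event.condition!r}"
            )
        choices = dict(profile.code_choice)
        choices[event.condition] = event.code
        return replace(profile, code_choice=tuple(sorted(choices.items())))
    raise UnknownEventTargetError(f"unsupported event {event!r}")


def step(
    rb: RuleBase,
    display_rules: Sequence[DisplayRule],
    profile: PatientProfile,
    state: QuestionnaireState,
    event: Event,
) -> tuple[PatientProfile, QuestionnaireState]:
    """Apply one user event and recompute the visible questionnaire.

    Conditions that just appeared are reported in ``newly_appeared`` (the
    UI highlights them); conditions that vanished in ``disappeared_last_step``.
    A condition hidden by the change silently retains its checked value.
    """
    new_profile = _apply_event(rb, profile, state, event)
    displayed = displayed_conditions(display_rules, new_profile)
    new_state = QuestionnaireState(
        displayed=displayed,
        newly_appeared=displayed - state.displayed,
        disappeared_last_step=state.displayed - displayed,
        by_category=_group(displayed, rb.catalogue),
    )
    return new_profile, new_state


# simulation ---------------------------------------------------------------

Policy = Callable[
    [QuestionnaireState, PatientProfile, PatientProfile], Iterable[Event]
]


def simulate_session(
    rb: RuleBase,
    display_rules: Sequence[DisplayRule],
    ground_truth: PatientProfile,
    policy: str | Policy = "greedy",
) -> SessionTrace:
    """Simulate a data-entry session against a complete ground-truth patient.

    ``ground_truth.clinical_checked`` is read as the set of clinical
    conditions that are actually true; the session starts from the patient's
    known drugs/labs and an empty questionnaire.

    Policies:

    * ``"greedy"`` (default, truthful): each round, check every displayed,
      unchecked condition that is true in the ground truth; stop when a round
      changes nothing.  The checked set grows monotonically, so the session
      terminates.
    * ``"single"``: same, but one condition per step (lowest catalogue
      declaration order first) — useful to probe order sensitivity.
    * a callable ``policy(state, profile, ground_truth) -> events``; custom
      policies are guarded by a cap of 10·|C| events.
    """
    true_clinical = ground_truth.clinical_checked
    profile = PatientProfile(nonclinical_true=ground_truth.nonclinical_true)
    state = initial_state(rb, display_rules, profile)
    ever = set(state.displayed)
    initial_displayed = state.displayed
    steps: list[tuple[Event, frozenset[str]]] = []
    declaration_rank = {cid: i for i, cid in enumerate(rb.clinical_ids)}

    if callable(policy):
        cap = 10 * max(rb.n, 1)
        count = 0
        while True:
            events = list(policy(state, profile, ground_truth))
            if not events:
                break
            for ev in events:
                count += 1
                if count > cap:
                    raise EngineError(
                        f"custom policy exceeded the step cap of {cap} events"
                    )
                profile, state = step(rb, display_rules, profile, state, ev)
                ever |= state.displayed
                steps.append((ev, state.displayed))
    else:
        if policy not in ("greedy", "single"):
            raise ValueError(f"unknown policy {policy!r}")
        one_per_round = policy == "single"
        while True:
            todo = sorted(
                (state.displayed & true_clinical) - profile.clinical_checked,
                key=declaration_rank.__getitem__,
            )
            if not todo:
                break
            if one_per_round:
                profile, state = step(rb, display_rules, profile, state, Check(todo[0]))
                ever |= state.displayed
                steps.append((Check(todo[0]), state.displayed))
                continue
            # whole round applied as one batch: every condition in `todo` was
            # displayed when the round started, even if an earlier check in the
            # same round would have hidden it
            before = state.displayed
            profile = replace(
                profile, clinical_checked=profile.clinical_checked | set(todo)
            )
            displayed = displayed_conditions(display_rules, profile)
            state = QuestionnaireState(
                displayed=displayed,
                newly_appeared=displayed - before,
                disappeared_last_step=before - displayed,
                by_category=_group(displayed, rb.catalogue),
            )
            ever |= displayed
            steps.extend((Check(x), displayed) for x in todo)

    return SessionTrace(
        steps=tuple(steps),
        initial_displayed=initial_displayed,
        ever_displayed=frozenset(ever),
        final_profile=profile,
        triggered=triggered_rules(rb, profile),
    )
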