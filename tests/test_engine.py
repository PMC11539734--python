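"""Closed-world evaluation, stepping, simulation, and exhaustiveness."""

import pytest

from adaptiveq import (
    Check,
    ChooseCode,
    ConditionOrder,
    PatientProfile,
    PatientSpec,
    RuleBaseSpec,
    SetDrug,
    Uncheck,
    compile_all,
    displayed_conditions,
    gen_patient,
    gen_rulebase,
    initial_state,
    occurrence_order,
    premise_satisfied,
    simulate_session,
    step,
    triggered_rules,
)
from adaptiveq.engine import EngineError, NotDisplayedError, UnknownEventTargetError


def _profile(drugs=(), checked=()):
    return PatientProfile(
        nonclinical_true=frozenset(drugs), clinical_checked=frozenset(checked)
    )


# --- premise evaluation ----------------------------------------------------


def test_premise_satisfied_examples(d2d6):
    d2, d6 = d2d6.rule("D2").premise, d2d6.rule("D6").premise
    # fibre already prescribed violates ¬fibre even with both conditions true
    assert not premise_satisfied(
        d2, _profile(drugs={"fibre"}, checked={"constipation", "diverticulosis"})
    )
    assert premise_satisfied(d2, _profile(checked={"constipation", "diverticulosis"}))
    # a union is satisfied by any single member
    assert premise_satisfied(d6, _profile(drugs={"antipsychotic"}, checked={"lewy_body"}))
    assert not premise_satisfied(d6, _profile(drugs={"antipsychotic"}))
    # the empty premise is vacuously true
    from adaptiveq.rule_model import Premise

    assert premise_satisfied(Premise(), _profile())


def test_triggered_rules(d2d6):
    assert triggered_rules(d2d6, _profile(checked={"constipation", "diverticulosis"})) == {
        "D2"
    }
    assert triggered_rules(d2d6, _profile()) == set()
    assert triggered_rules(
        d2d6, _profile(drugs={"antipsychotic"}, checked={"parkinsonism"})
    ) == {"D6"}


def test_displayed_conditions_printed_behavior(d2d6_rules):
    assert displayed_conditions(d2d6_rules, _profile()) == {"constipation"}
    assert displayed_conditions(d2d6_rules, _profile(checked={"constipation"})) == {
        "constipation",
        "diverticulosis",
    }
    assert displayed_conditions(d2d6_rules, _profile(drugs={"antipsychotic"})) == {
        "constipation",
        "parkinsonism",
        "lewy_body",
    }
    assert displayed_conditions(d2d6_rules, _profile(drugs={"fibre"})) == set()


def test_displayed_equals_per_rule_bruteforce(d2d6, d2d6_rules):
    """The displayed set is the union over independently evaluated display rules."""
    import itertools

    clin = d2d6.clinical_ids
    for drugs in ({}, {"fibre"}, {"antipsychotic"}, {"fibre", "antipsychotic"}):
        for k in range(len(clin) + 1):
            for checked in itertools.combinations(clin, k):
                prof = _profile(drugs=drugs, checked=checked)
                expected = {
                    dr.target
                    for dr in d2d6_rules
                    if premise_satisfied(dr.premise, prof)
                }
                assert displayed_conditions(d2d6_rules, prof) == expected


# --- stepping --------------------------------------------------------------


def test_check_reveals_gated_condition(d2d6, d2d6_rules):
    profile = _profile()
    state = initial_state(d2d6, d2d6_rules, profile)
    assert state.displayed == {"constipation"}
    assert state.newly_appeared == set()
    profile, state = step(d2d6, d2d6_rules, profile, state, Check("constipation"))
    assert state.newly_appeared == {"diverticulosis"}
    assert state.displayed == {"constipation", "diverticulosis"}


def test_union_member_check_hides_the_other(d2d6, d2d6_rules):
    profile = _profile(drugs={"antipsychotic"})
    state = initial_state(d2d6, d2d6_rules, profile)
    assert {"parkinsonism", "lewy_body"} <= state.displayed
    profile, state = step(d2d6, d2d6_rules, profile, state, Check("parkinsonism"))
    assert "lewy_body" in state.disappeared_last_step
    assert "parkinsonism" in state.displayed  # kept visible by its u2 rule


def test_uncheck_is_inverse(d2d6, d2d6_rules):
    profile = _profile()
    state = initial_state(d2d6, d2d6_rules, profile)
    profile, state = step(d2d6, d2d6_rules, profile, state, Check("constipation"))
    profile, state = step(d2d6, d2d6_rules, profile, state, Uncheck("constipation"))
    assert state.displayed == {"constipation"}
    assert state.disappeared_last_step == {"diverticulosis"}
    profile, state = step(d2d6, d2d6_rules, profile, state, Check("constipation"))
    assert state.displayed == {"constipation", "diverticulosis"}


def test_hidden_conditions_retain_their_value(d2d6, d2d6_rules):
    profile = _profile()
    state = initial_state(d2d6, d2d6_rules, profile)
    profile, state = step(d2d6, d2d6_rules, profile, state, Check("constipation"))
    profile, state = step(d2d6, d2d6_rules, profile, state, Check("diverticulosis"))
    profile, state = step(d2d6, d2d6_rules, profile, state, Uncheck("constipation"))
    # diverticulosis is hidden but silently keeps its checked value
    assert "diverticulosis" not in state.displayed
    assert "diverticulosis" in profile.clinical_checked
    profile, state = step(d2d6, d2d6_rules, profile, state, Check("constipation"))
    assert "diverticulosis" in state.displayed
    assert triggered_rules(d2d6, profile) == {"D2"}


def test_event_errors(d2d6, d2d6_rules):
    profile = _profile()
    state = initial_state(d2d6, d2d6_rules, profile)
    with pytest.raises(NotDisplayedError):
        step(d2d6, d2d6_rules, profile, state, Check("parkinsonism"))
    with pytest.raises(UnknownEventTargetError):
        step(d2d6, d2d6_rules, profile, state, Check("ghost"))
    with pytest.raises(UnknownEventTargetError):
        step(d2d6, d2d6_rules, profile, state, SetDrug("constipation"))


def test_drug_event_and_code_choice(demo):
    order = ConditionOrder(demo.clinical_ids)
    rules = compile_all(demo, order)
    profile = _profile()
    state = initial_state(demo, rules, profile)
    profile, state = step(demo, rules, profile, state, SetDrug("antipsychotic"))
    assert {"parkinsonism", "lewy_body"} <= state.newly_appeared
    # picking a terminology code never changes the displayed set
    assert "diabetes" in state.displayed
    profile, state = step(demo, rules, profile, state, Check("diabetes"))
    before = state.displayed
    profile, state = step(demo, rules, profile, state, ChooseCode("diabetes", "E10"))
    assert state.displayed == before
    assert dict(profile.code_choice)["diabetes"] == "E10"
    with pytest.raises(UnknownEventTargetError):
        step(demo, rules, profile, state, ChooseCode("diabetes", "Z99"))


def test_sticky_visibility_of_ehr_imported_absent_condition():
    """a2: a condition set outside the questionnaire stays visible (so it can
    be retracted) while its drug context holds, and vanishes once unchecked."""
    from adaptiveq.rule_model import ClinicalRule, Condition, Premise, RuleBase

    rb = RuleBase(
        (
            Condition(id="ankle_edema", kind="clinical"),
            Condition(id="heart_failure", kind="clinical"),
            Condition(id="loop_diuretic", kind="nonclinical"),
        ),
        (
            ClinicalRule(
                "r",
                Premise(
                    present_clinical=frozenset({"ankle_edema"}),
                    absent_clinical=frozenset({"heart_failure"}),
                    present_nonclinical=frozenset({"loop_diuretic"}),
                ),
                "review(loop_diuretic)",
            ),
        ),
    )
    rules = compile_all(rb, ConditionOrder(rb.clinical_ids))
    profile = _profile(drugs={"loop_diuretic"}, checked={"heart_failure"})
    state = initial_state(rb, rules, profile)
    assert "heart_failure" in state.displayed
    profile, state = step(rb, rules, profile, state, Uncheck("heart_failure"))
    assert "heart_failure" not in state.displayed  # a1 still gated by ankle edema


def test_category_grouping(demo):
    rules = compile_all(demo, ConditionOrder(demo.clinical_ids))
    state = initial_state(demo, rules, _profile(drugs={"antipsychotic"}))
    groups = state.grouped()
    assert "parkinsonism" in groups["neurology"]
    assert set(groups) <= {c.category for c in demo.catalogue}
    assert sorted(x for ids in groups.values() for x in ids) == sorted(state.displayed)


# --- simulation ------------------------------------------------------------


def test_simulated_sessions_match_printed_outcomes(d2d6, d2d6_rules):
    tr = simulate_session(
        d2d6, d2d6_rules, _profile(checked={"constipation", "diverticulosis"})
    )
    assert (tr.questions_asked, tr.triggered) == (2, {"D2"})
    tr = simulate_session(d2d6, d2d6_rules, _profile())
    assert (tr.questions_asked, tr.triggered) == (1, frozenset())
    tr = simulate_session(d2d6, d2d6_rules, _profile(drugs={"fibre"}))
    assert (tr.questions_asked, tr.triggered) == (0, frozenset())


def test_session_determinism(demo):
    rules = compile_all(demo, occurrence_order(demo))
    truth = gen_patient(demo, PatientSpec(p=0.4, seed=7))
    t1 = simulate_session(demo, rules, truth)
    t2 = simulate_session(demo, rules, truth)
    assert t1 == t2


def test_single_condition_policy_reaches_same_triggered_set(demo):
    rules = compile_all(demo, occurrence_order(demo))
    for seed in range(20):
        truth = gen_patient(demo, PatientSpec(p=0.4, seed=seed))
        greedy = simulate_session(demo, rules, truth)
        single = simulate_session(demo, rules, truth, policy="single")
        assert greedy.triggered == triggered_rules(demo, truth)
        assert single.triggered == triggered_rules(demo, truth)


def test_custom_policy_step_cap(d2d6, d2d6_rules):
    def flip_flop(state, profile, truth):
        if "constipation" in profile.clinical_checked:
            return [Uncheck("constipation")]
        return [Check("constipation")]

    with pytest.raises(EngineError, match="cap"):
        simulate_session(d2d6, d2d6_rules, _profile(), policy=flip_flop)


def test_questions_asked_bounds(demo):
    rules = compile_all(demo, occurrence_order(demo))
    truth = gen_patient(demo, PatientSpec(p=0.5, seed=3))
    tr = simulate_session(demo, rules, truth)
    assert tr.questions_asked >= len(
        tr.final_profile.clinical_checked & tr.ever_displayed
    )
    assert tr.questions_asked <= demo.n


def test_exhaustiveness_smoke():
    """Triggered rules after a truthful session equal those under full
    knowledge (the acceptance suite runs the 1000-pair version)."""
    for seed in range(200):
        rb = gen_rulebase(RuleBaseSpec(seed=seed))
        rules = compile_all(rb, occurrence_order(rb))
        truth = gen_patient(rb, PatientSpec(seed=seed + 10_000))
        trace = simulate_session(rb, rules, truth)
        assert trace.triggered == triggered_rules(rb, truth)


def test_reordering_never_changes_triggered_rules():
    """The priority order changes what is shown along the way, never which
    clinical rules fire at the end of a truthful session."""
    import numpy as np

    for seed in range(30):
        rb = gen_rulebase(RuleBaseSpec(seed=seed))
        truth = gen_patient(rb, PatientSpec(seed=seed + 20_000))
        expected = triggered_rules(rb, truth)
        rng = np.random.default_rng(seed)
        for _ in range(3):
            perm = tuple(rng.permutation(np.array(rb.clinical_ids, dtype=object)))
            rules = compile_all(rb, ConditionOrder(perm))
            assert simulate_session(rb, rules, truth).triggered == expected


def test_profile_json_roundtrip():
    prof = PatientProfile(
        nonclinical_true=frozenset({"fibre"}),
        clinical_checked=frozenset({"constipation"}),
        code_choice=(("constipation", "K59.0"),),
    )
    assert PatientProfile.from_json(prof.to_json()) == prof
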