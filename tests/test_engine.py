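"""Conversation state machine: flow, branching, back-navigation, expiry."""

from __future__ import annotations

from datetime import timedelta

import pytest

from checkup import (
    AnswerValidationError,
    CheckupScript,
    ConsentError,
    Instrument,
    RegistrationError,
    Section,
    StateError,
    check_expiry,
    evaluate_branches,
    go_back,
    included_sections,
    next_prompt,
    progress,
    start_session,
    submit_answer,
)
from checkup.engine import BranchRule
from checkup.instruments import PHQ9_SLEEP_ITEM
from checkup.persistence import ENCOURAGEMENT_MESSAGE

from conftest import T0, answers_for_total, run_scripted_session


def _min_vectors(script):
    """Lowest legal answer everywhere (sleep item 0: no insomnia)."""
    return {
        ins.id: [item.min_value for item in ins.items]
        for ins in script.instruments
    }


def _sleepy_vectors(script):
    vectors = _min_vectors(script)
    instrument = script.instrument("phq9")
    idx = instrument.item_index(PHQ9_SLEEP_ITEM)
    phq = list(vectors["phq9"])
    phq[idx] = 2
    vectors["phq9"] = phq
    return vectors


# ---------------------------------------------------------------------------
# registration
# ---------------------------------------------------------------------------

def test_start_session_opens_at_first_section(script):
    session = start_session(script, "ACME", True, T0)
    assert session.status == "in_progress"
    assert session.cursor_section == script.sections[0].id == "stress"
    assert session.cursor_item == 0
    assert session.started_at == T0


def test_declined_consent_creates_no_session(script):
    with pytest.raises(ConsentError) as err:
        start_session(script, "ACME", False, T0)
    # the refusal re-displays the terms
    assert err.value.terms_text == script.terms_text


def test_empty_company_code_is_registration_error(script):
    with pytest.raises(RegistrationError):
        start_session(script, "   ", True, T0)


# ---------------------------------------------------------------------------
# prompts
# ---------------------------------------------------------------------------

def test_fresh_session_prompt_bundles_section_intro(script):
    session = start_session(script, "ACME", True, T0)
    prompt = next_prompt(session, script)
    assert prompt.kind == "question"
    assert prompt.messages == script.sections[0].intro_messages
    first_item = script.instrument("dass21_stress").items[0]
    assert prompt.item_id == first_item.id
    assert prompt.options == [(o.value, o.label) for o in first_item.options]


def test_mid_instrument_prompt_has_full_option_list(script):
    session = start_session(script, "ACME", True, T0)
    submit_answer(session, script, 0, T0)
    prompt = next_prompt(session, script)
    assert prompt.kind == "question"
    assert prompt.messages == []  # no intro mid-section
    assert len(prompt.options) == 4


def test_encouragement_shown_at_configured_midpoint(script):
    vectors = _min_vectors(script)
    session = start_session(script, "ACME", True, T0)
    seen = []
    while session.status == "in_progress":
        prompt = next_prompt(session, script)
        seen.extend(prompt.messages)
        section = script.section(session.cursor_section)
        submit_answer(
            session, script,
            vectors[section.instrument_id][session.cursor_item], T0,
        )
    assert ENCOURAGEMENT_MESSAGE in seen


def test_completed_session_yields_feedback_then_stays_terminal(script):
    session = run_scripted_session(script, _min_vectors(script))
    prompt = next_prompt(session, script)
    assert prompt.kind == "feedback"
    assert prompt.messages  # feedback plus disclaimer
    # idempotent: asking again yields the same feedback
    assert next_prompt(session, script).messages == prompt.messages


# ---------------------------------------------------------------------------
# answering
# ---------------------------------------------------------------------------

def test_illegal_value_rejected_without_moving_cursor(script):
    session = start_session(script, "ACME", True, T0)
    with pytest.raises(AnswerValidationError):
        submit_answer(session, script, 9, T0)
    assert session.cursor_item == 0
    assert session.answer_count() == 0


def test_no_skip_every_included_item_answered(script):
    for vectors in (_min_vectors(script), _sleepy_vectors(script)):
        if vectors["phq9"][2] > 0:
            vectors = dict(vectors)
        session = run_scripted_session(script, vectors)
        for section in included_sections(script, session.answers):
            instrument = script.instrument(section.instrument_id)
            answered = session.answers.get(section.id, {})
            assert set(answered) == {i.id for i in instrument.items}


def test_final_answer_completes_session(script):
    session = run_scripted_session(script, _min_vectors(script))
    assert session.status == "completed"
    assert session.cursor_section is None


# ---------------------------------------------------------------------------
# branching
# ---------------------------------------------------------------------------

@pytest.mark.parametrize("sleep_value, included",
                         [(0, False), (1, True), (3, True)])
def test_sleep_item_gates_insomnia_section(script, sleep_value, included):
    answers = {"depression": {PHQ9_SLEEP_ITEM: sleep_value}}
    assert ("insomnia" in evaluate_branches(script, answers)) is included


def test_unanswered_branch_source_defers_inclusion(script):
    assert evaluate_branches(script, {}) == set()


def test_sleepy_session_takes_isi_and_minimal_does_not(script):
    sleepy = run_scripted_session(script, _sleepy_vectors(script))
    minimal = run_scripted_session(script, _min_vectors(script))
    assert "insomnia" in sleepy.answers and sleepy.answer_count() == 61
    assert "insomnia" not in minimal.answers and minimal.answer_count() == 54


# ---------------------------------------------------------------------------
# back-navigation
# ---------------------------------------------------------------------------

def test_go_back_clears_exactly_the_previous_answer(script):
    session = start_session(script, "ACME", True, T0)
    submit_answer(session, script, 1, T0)
    submit_answer(session, script, 2, T0)
    assert session.cursor_item == 2
    go_back(session, script)
    assert session.cursor_item == 1
    item_id = script.instrument("dass21_stress").items[1].id
    assert item_id not in session.answers["stress"]
    assert session.answer_count() == 1


def test_second_consecutive_go_back_is_noop(script):
    session = start_session(script, "ACME", True, T0)
    submit_answer(session, script, 1, T0)
    submit_answer(session, script, 2, T0)
    go_back(session, script)
    cursor = (session.cursor_section, session.cursor_item)
    go_back(session, script)
    assert (session.cursor_section, session.cursor_item) == cursor
    assert session.answer_count() == 1


def test_go_back_at_first_prompt_is_noop(script):
    session = start_session(script, "ACME", True, T0)
    go_back(session, script)
    assert session.cursor_item == 0
    assert session.cursor_section == "stress"


def test_go_back_crosses_section_boundary(script):
    session = start_session(script, "ACME", True, T0)
    for _ in range(7):  # finish the stress section
        submit_answer(session, script, 0, T0)
    assert session.cursor_section == "anxiety"
    go_back(session, script)
    assert session.cursor_section == "stress"
    assert session.cursor_item == 6


def test_changing_sleep_answer_drops_pending_insomnia(script):
    """Brute-force re-evaluation of the branch predicate after re-answer."""
    session = start_session(script, "ACME", True, T0)
    vectors = _sleepy_vectors(script)
    instrument = script.instrument("phq9")
    sleep_idx = instrument.item_index(PHQ9_SLEEP_ITEM)
    # answer stress + anxiety + depression up to and including sleep item
    while not (
        session.cursor_section == "depression"
        and session.cursor_item == sleep_idx + 1
    ):
        section = script.section(session.cursor_section)
        submit_answer(
            session, script,
            vectors[section.instrument_id][session.cursor_item], T0,
        )
    assert "insomnia" in evaluate_branches(script, session.answers)
    go_back(session, script)  # back onto the sleep item
    submit_answer(session, script, 0, T0)  # change 2 -> 0
    assert "insomnia" not in evaluate_branches(script, session.answers)
    # finishing now skips insomnia entirely
    while session.status == "in_progress":
        section = script.section(session.cursor_section)
        submit_answer(
            session, script,
            vectors[section.instrument_id][session.cursor_item], T0,
        )
    assert "insomnia" not in session.answers
    assert session.answer_count() == 54


# ---------------------------------------------------------------------------
# expiry
# ---------------------------------------------------------------------------

@pytest.mark.parametrize(
    "elapsed, expired",
    [
        (timedelta(hours=23, minutes=59), False),
        (timedelta(hours=24), False),  # boundary is strict
        (timedelta(hours=24, minutes=1), True),
    ],
)
def test_24h_reset_boundary(script, elapsed, expired):
    session = start_session(script, "ACME", True, T0)
    submit_answer(session, script, 1, T0)
    check_expiry(session, T0 + elapsed)
    if expired:
        assert session.status == "expired"
        assert session.answers == {}
    else:
        assert session.status == "in_progress"
        assert session.answer_count() == 1


def test_completed_sessions_are_immune_to_expiry(script):
    session = run_scripted_session(script, _min_vectors(script))
    check_expiry(session, T0 + timedelta(days=30))
    assert session.status == "completed"
    assert session.answer_count() == 54


def test_expired_session_refuses_further_operations(script):
    session = start_session(script, "ACME", True, T0)
    check_expiry(session, T0 + timedelta(hours=25))
    with pytest.raises(StateError):
        next_prompt(session, script)
    with pytest.raises(StateError):
        submit_answer(session, script, 0, T0 + timedelta(hours=25))


# ---------------------------------------------------------------------------
# progress
# ---------------------------------------------------------------------------

def test_progress_zero_then_one_with_revealed_flags(script):
    session = start_session(script, "ACME", True, T0)
    info = progress(session, script)
    assert info.fraction == 0.0
    assert not any(info.revealed.values())
    done = run_scripted_session(script, _sleepy_vectors(script))
    info = progress(done, script)
    assert info.fraction == 1.0
    assert all(info.revealed.values())


def test_progress_never_decreases_on_forward_moves(script):
    for vectors in (_min_vectors(script), _sleepy_vectors(script)):
        session = start_session(script, "ACME", True, T0)
        fractions = [progress(session, script).fraction]
        while session.status == "in_progress":
            section = script.section(session.cursor_section)
            submit_answer(
                session, script,
                vectors[section.instrument_id][session.cursor_item], T0,
            )
            fractions.append(progress(session, script).fraction)
        assert all(b >= a for a, b in zip(fractions, fractions[1:]))
        assert fractions[-1] == 1.0


def _toy_script() -> CheckupScript:
    """Five two-item sections with equal weights (no conditional path)."""
    def toy(iid):
        from checkup import CategoryBand, Item, ResponseOption

        options = [ResponseOption(label=str(v), value=v) for v in (0, 1)]
        return Instrument(
            id=iid,
            items=[Item(id=f"{iid}_{k}", text="t", options=options)
                   for k in (1, 2)],
            bands=[CategoryBand(label="any", lower=0, upper=2)],
        )

    ids = ["dass21_stress", "gad7", "phq9", "olbi", "jss"]
    sections = [
        Section(id=sid, instrument_id=iid)
        for sid, iid in zip(
            ["stress", "anxiety", "depression", "burnout", "work_stress"], ids
        )
    ]
    return CheckupScript(
        sections=sections, instruments=[toy(i) for i in ids]
    )


def test_progress_is_item_ratio_over_included_sections():
    script = _toy_script()
    session = start_session(script, "ACME", True, T0)
    for _ in range(4):  # finish 2 of 5 equally weighted sections
        submit_answer(session, script, 0, T0)
    assert progress(session, script).fraction == pytest.approx(0.4)


def test_progress_zero_after_expiry(script):
    session = start_session(script, "ACME", True, T0)
    for _ in range(10):
        submit_answer(session, script, 1, T0)
    check_expiry(session, T0 + timedelta(hours=25))
    assert progress(session, script).fraction == 0.0


# ---------------------------------------------------------------------------
# determinism
# ---------------------------------------------------------------------------

def test_identical_inputs_give_identical_sessions(script):
    a = run_scripted_session(script, _sleepy_vectors(script), token="same")
    b = run_scripted_session(script, _sleepy_vectors(script), token="same")
    assert a.model_dump() == b.model_dump()


def test_branch_rule_must_target_conditional_section(script):
    bad = script.model_copy(deep=True)
    bad.branch_rules.append(
        BranchRule(
            target_section="burnout",
            source_instrument="phq9",
            source_item=PHQ9_SLEEP_ITEM,
        )
    )
    assert any(
        "non-conditional" in v.message for v in bad.validate_script()
    )
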