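"""Scripted checkup conversation: a deterministic session state machine.

The checkup is a fixed tour through story sections (stress, anxiety,
depression, optionally insomnia, burnout, work-related stress), each binding
one instrument.  Questions are delivered one at a time; there is no way to
skip a question, and the user may step back exactly one answer.  The
insomnia section is conditional: it is included if and only if the sleep
item of the depression screener is endorsed above "not at all".  Sessions
not completed within 24 hours expire and their answers are erased.

Everything here is a pure function of (script, answer sequence,
timestamps): no randomness, so identical inputs yield identical
transcripts, scores and statuses.
"""

from __future__ import annotations

import uuid
from dataclasses import dataclass, field
from datetime import datetime, timedelta, timezone
from typing import Literal, Optional, Union

from pydantic import BaseModel, ConfigDict, Field

from . import risk as risk_mod
from .errors import (
    AnswerValidationError,
    ConsentError,
    RegistrationError,
    ScriptValidationError,
    StateError,
)
from .instruments import (
    Instrument,
    Item,
    ScoreResult,
    Violation,
    score_instrument,
    validate_instrument,
)
from .risk import RiskConfig, RiskEvent, assess_risk, safety_flow, scan_free_text

#: sessions not completed within this window are reset and overwritten
EXPIRY = timedelta(hours=24)

SectionId = Literal[
    "stress", "anxiety", "depression", "burnout", "work_stress", "insomnia"
]
Status = Literal["registered", "in_progress", "completed", "expired"]


# ---------------------------------------------------------------------------
# script types
# ---------------------------------------------------------------------------

class Section(BaseModel):
    """One story section: intro messages plus exactly one instrument."""

    model_config = ConfigDict(extra="forbid")

    id: SectionId
    intro_messages: list[str] = Field(default_factory=list)
    instrument_id: str
    conditional: bool = False


class BranchRule(BaseModel):
    """Include ``target_section`` iff a prior answer differs from a value.

    The predicate is (source instrument, item id, excluded option value):
    the target is included when the item's answer is anything other than
    the excluded value, deferred while the item is unanswered.
    """

    model_config = ConfigDict(extra="forbid")

    target_section: SectionId
    source_instrument: str
    source_item: str
    excluded_value: int = 0


class EncouragementRule(BaseModel):
    """Show ``message`` just before item ``item_index`` of a section."""

    model_config = ConfigDict(extra="forbid")

    section_id: SectionId
    item_index: int
    message: str


class FeedbackTemplates(BaseModel):
    """Per-instrument, per-category feedback blocks plus the disclaimer.

    ``per_instrument[iid]`` maps category labels to message templates;
    a ``"default"`` key is a fallback for categories without an explicit
    template.  Templates may use ``{name}``, ``{category}`` and ``{total}``
    placeholders.  Coverage is checked at script load, not at runtime.
    """

    model_config = ConfigDict(extra="forbid")

    per_instrument: dict[str, dict[str, str]] = Field(default_factory=dict)
    disclaimer: str = (
        "Remember: these results do not offer a diagnosis, but they may "
        "indicate the presence of an emotional difficulty worth discussing "
        "with a professional."
    )
    completion_message: str = "You finished the whole expedition - thank you!"


class ReportConfig(BaseModel):
    """Reporting knobs carried by the script."""

    model_config = ConfigDict(extra="forbid")

    k_anonymity: int = 8
    rate_decimals: int = 1


class CheckupScript(BaseModel):
    """Ordered sections, instrument definitions, branch rules and messages."""

    model_config = ConfigDict(extra="forbid")

    version: int = 1
    sections: list[Section]
    instruments: list[Instrument]
    branch_rules: list[BranchRule] = Field(default_factory=list)
    encouragement: list[EncouragementRule] = Field(default_factory=list)
    terms_text: str = (
        "Your answers are anonymous and will be shared with your "
        "organization only in aggregated form. Do you agree to the terms "
        "and conditions?"
    )
    feedback: FeedbackTemplates = Field(default_factory=FeedbackTemplates)
    risk: RiskConfig = Field(default_factory=RiskConfig)
    report: ReportConfig = Field(default_factory=ReportConfig)

    # -- lookups ------------------------------------------------------------

    def instrument(self, instrument_id: str) -> Instrument:
        for ins in self.instruments:
            if ins.id == instrument_id:
                return ins
        raise KeyError(instrument_id)

    def section(self, section_id: str) -> Section:
        for sec in self.sections:
            if sec.id == section_id:
                return sec
        raise KeyError(section_id)

    def section_of_instrument(self, instrument_id: str) -> Section:
        for sec in self.sections:
            if sec.instrument_id == instrument_id:
                return sec
        raise KeyError(instrument_id)

    def section_instrument(self, section_id: str) -> Instrument:
        return self.instrument(self.section(section_id).instrument_id)

    def encouragements_at(self, section_id: str, item_index: int) -> list[str]:
        return [
            r.message
            for r in self.encouragement
            if r.section_id == section_id and r.item_index == item_index
        ]

    # -- validation ---------------------------------------------------------

    def validate_script(self) -> list[Violation]:
        """Cross-reference and instrument checks; errors block loading."""
        out: list[Violation] = []
        ids = [ins.id for ins in self.instruments]
        if len(set(ids)) != len(ids):
            out.append(Violation("duplicate instrument ids"))
        sec_ids = [s.id for s in self.sections]
        if len(set(sec_ids)) != len(sec_ids):
            out.append(Violation("duplicate section ids"))
        for sec in self.sections:
            if sec.instrument_id not in ids:
                out.append(
                    Violation(
                        f"section {sec.id} binds unknown instrument "
                        f"{sec.instrument_id!r}"
                    )
                )
        conditional = [s.id for s in self.sections if s.conditional]
        targeted = {r.target_section for r in self.branch_rules}
        for rule in self.branch_rules:
            if rule.target_section not in conditional:
                out.append(
                    Violation(
                        f"branch targets non-conditional section "
                        f"{rule.target_section!r}"
                    )
                )
            try:
                src = self.section_of_instrument(rule.source_instrument)
                self.instrument(rule.source_instrument).item_index(
                    rule.source_item
                )
            except KeyError as missing:
                out.append(Violation(f"branch source {missing} not in script"))
                continue
            order = [s.id for s in self.sections]
            if rule.target_section in order and (
                order.index(src.id) >= order.index(rule.target_section)
            ):
                out.append(
                    Violation(
                        f"branch source section {src.id} does not precede "
                        f"target {rule.target_section}"
                    )
                )
        for sec_id in conditional:
            if sec_id not in targeted:
                out.append(
                    Violation(
                        f"conditional section {sec_id} has no branch rule",
                        severity="warning",
                    )
                )
        for ins in self.instruments:
            out.extend(validate_instrument(ins))
        # feedback coverage: every band of every sectioned instrument
        for ins in self.instruments:
            templates = self.feedback.per_instrument.get(ins.id, {})
            if "default" in templates:
                continue
            for band in ins.bands:
                if band.label not in templates:
                    out.append(
                        Violation(
                            f"no feedback template for {ins.id} category "
                            f"{band.label!r} and no default"
                        )
                    )
        for rule in self.encouragement:
            ins = self.section_instrument(rule.section_id)
            if not 0 <= rule.item_index < len(ins.items):
                out.append(
                    Violation(
                        f"encouragement at {rule.section_id}[{rule.item_index}] "
                        "is outside the instrument"
                    )
                )
        return out

    def raise_for_errors(self) -> None:
        errors = [v for v in self.validate_script() if v.severity == "error"]
        if errors:
            raise ScriptValidationError(
                "; ".join(v.message for v in errors), location="script"
            )


# ---------------------------------------------------------------------------
# session types
# ---------------------------------------------------------------------------

class TranscriptEvent(BaseModel):
    model_config = ConfigDict(extra="forbid")

    timestamp: datetime
    actor: Literal["bot", "user"]
    kind: Literal["message", "question", "answer", "free_text", "risk_referral"]
    payload: Union[str, dict]


class Session(BaseModel):
    """One user's traversal of the script.

    ``answers`` is a section-id -> (item-id -> option value) map holding
    only visited items; ``cursor_section``/``cursor_item`` point at the next
    unanswered question.  No name or other personal identification data is
    stored — the token is an opaque anonymous key.
    """

    model_config = ConfigDict(extra="forbid")

    token: str
    company_code: str
    group: Optional[str] = None
    consented: bool = True
    started_at: datetime
    answers: dict[str, dict[str, int]] = Field(default_factory=dict)
    cursor_section: Optional[str] = None
    cursor_item: int = 0
    status: Status = "in_progress"
    risk_events: list[RiskEvent] = Field(default_factory=list)
    transcript: list[TranscriptEvent] = Field(default_factory=list)
    last_action: str = "start"

    def answer_count(self) -> int:
        return sum(len(v) for v in self.answers.values())

    def flat_answers(self) -> dict[str, int]:
        """Item-id -> value across all sections (item ids are unique)."""
        flat: dict[str, int] = {}
        for per_section in self.answers.values():
            flat.update(per_section)
        return flat

    def _stamp(self, now: datetime) -> datetime:
        """Next transcript timestamp, strictly after the previous one."""
        if self.transcript:
            floor = self.transcript[-1].timestamp + timedelta(microseconds=1)
            if now < floor:
                return floor
        return now

    def log(
        self,
        now: datetime,
        actor: Literal["bot", "user"],
        kind: str,
        payload: Union[str, dict],
    ) -> None:
        self.transcript.append(
            TranscriptEvent(
                timestamp=self._stamp(now), actor=actor, kind=kind,
                payload=payload,
            )
        )


@dataclass(frozen=True)
class Prompt:
    """What the bot says next: zero or more messages, then maybe a question."""

    kind: Literal["question", "feedback"]
    messages: list[str] = field(default_factory=list)
    section_id: Optional[str] = None
    item_id: Optional[str] = None
    question: Optional[str] = None
    options: Optional[list[tuple[int, str]]] = None


@dataclass(frozen=True)
class ProgressInfo:
    fraction: float
    revealed: dict[str, bool]


# ---------------------------------------------------------------------------
# branch evaluation
# ---------------------------------------------------------------------------

def evaluate_branches(
    script: CheckupScript, answers: dict[str, dict[str, int]]
) -> set[str]:
    """Conditional sections currently included, as a pure function of answers.

    A rule whose source item is unanswered is deferred: the target is not
    (yet) included.
    """
    included: set[str] = set()
    for rule in script.branch_rules:
        src_section = script.section_of_instrument(rule.source_instrument)
        value = answers.get(src_section.id, {}).get(rule.source_item)
        if value is not None and value != rule.excluded_value:
            included.add(rule.target_section)
    return included


def _definitively_excluded(
    script: CheckupScript, answers: dict[str, dict[str, int]]
) -> set[str]:
    """Conditional sections whose every rule has resolved to 'excluded'."""
    excluded: set[str] = set()
    for sec in script.sections:
        if not sec.conditional:
            continue
        rules = [r for r in script.branch_rules if r.target_section == sec.id]
        if not rules:
            continue
        resolved_out = True
        for rule in rules:
            src_section = script.section_of_instrument(rule.source_instrument)
            value = answers.get(src_section.id, {}).get(rule.source_item)
            if value is None or value != rule.excluded_value:
                resolved_out = False
        if resolved_out:
            excluded.add(sec.id)
    return excluded


def included_sections(
    script: CheckupScript, answers: dict[str, dict[str, int]]
) -> list[Section]:
    """Script-ordered sections on the current traversal path."""
    included = evaluate_branches(script, answers)
    return [
        s for s in script.sections if not s.conditional or s.id in included
    ]


# ---------------------------------------------------------------------------
# lifecycle operations
# ---------------------------------------------------------------------------

def start_session(
    script: CheckupScript,
    company_code: str,
    consent: bool,
    now: datetime,
    token: Optional[str] = None,
    group: Optional[str] = None,
) -> Session:
    """Register a user and open an in-progress session at the first prompt.

    Declining the terms raises :class:`ConsentError` (carrying the terms
    text for re-display) and creates no session; an empty company code is a
    registration error.  Duplicate-token rejection is enforced by the
    session store, which owns the campaign's token namespace.
    """
    if not consent:
        raise ConsentError(script.terms_text)
    if not company_code or not company_code.strip():
        raise RegistrationError("a non-empty company code is required")
    if not script.sections:
        raise ScriptValidationError("script has no sections")
    session = Session(
        token=token or uuid.uuid4().hex,
        company_code=company_code.strip(),
        group=group,
        consented=True,
        started_at=now,
        cursor_section=script.sections[0].id,
        cursor_item=0,
        status="in_progress",
    )
    session.log(now, "bot", "message", "registration complete")
    return session


def check_expiry(session: Session, now: datetime) -> Session:
    """Apply the 24-hour reset: expire and erase an overdue session.

    Strictly more than 24 h after ``started_at`` an in-progress session
    expires and its answers (and answer-bearing transcript) are destroyed;
    token and company code survive so a fresh restart is possible.
    Completed sessions are immune.
    """
    if session.status == "in_progress" and now - session.started_at > EXPIRY:
        session.status = "expired"
        session.answers = {}
        session.risk_events = []
        session.transcript = []
        session.cursor_section = None
        session.cursor_item = 0
        session.log(now, "bot", "message", "session expired; data erased")
    return session


def _current_item(session: Session, script: CheckupScript) -> tuple[Section, Item]:
    assert session.cursor_section is not None
    section = script.section(session.cursor_section)
    instrument = script.instrument(section.instrument_id)
    return section, instrument.items[session.cursor_item]


def next_prompt(session: Session, script: CheckupScript) -> Prompt:
    """The next thing the bot shows, as a pure function of session state.

    Section intros and configured encouragement messages are bundled with
    the question they precede.  A completed session yields the feedback
    prompt (idempotently); an expired one is a state error.
    """
    if session.status == "expired":
        raise StateError("session has expired; restart to begin again")
    if session.status == "completed":
        results = session_scores(script, session)
        from .report import personal_feedback  # local import, avoids a cycle

        messages = personal_feedback(results, script.feedback, script)
        messages.append(script.feedback.completion_message)
        return Prompt(kind="feedback", messages=messages)
    if session.status != "in_progress":
        raise StateError(f"cannot prompt a {session.status} session")

    section, item = _current_item(session, script)
    messages: list[str] = []
    if session.cursor_item == 0:
        messages.extend(section.intro_messages)
    messages.extend(script.encouragements_at(section.id, session.cursor_item))
    return Prompt(
        kind="question",
        messages=messages,
        section_id=section.id,
        item_id=item.id,
        question=item.text,
        options=[(o.value, o.label) for o in item.options],
    )


def deliver_prompt(session: Session, script: CheckupScript, now: datetime) -> Prompt:
    """Compute the next prompt and record it on the transcript."""
    prompt = next_prompt(session, script)
    for message in prompt.messages:
        session.log(now, "bot", "message", message)
    if prompt.kind == "question":
        session.log(
            now, "bot", "question",
            {"section": prompt.section_id, "item": prompt.item_id},
        )
    return prompt


def _drop_excluded_answers(session: Session, script: CheckupScript) -> None:
    """Discard answers of conditional sections no longer on the path."""
    included = {s.id for s in included_sections(script, session.answers)}
    for sec in script.sections:
        if sec.conditional and sec.id not in included:
            session.answers.pop(sec.id, None)


def _score_section(
    session: Session, script: CheckupScript, section: Section, now: datetime
) -> ScoreResult:
    instrument = script.instrument(section.instrument_id)
    vector = [
        session.answers[section.id][item.id] for item in instrument.items
    ]
    return score_instrument(instrument, vector)


def _run_risk_checks(session: Session, script: CheckupScript, now: datetime) -> None:
    results = session_scores(script, session)
    events = assess_risk(results, session.flat_answers(), script.risk, now)
    new = [
        e
        for e in events
        if not any(
            e.trigger == have.trigger and e.source == have.source
            for have in session.risk_events
        )
    ]
    if not new:
        return
    session.risk_events.extend(new)
    for message in safety_flow(new, script.risk):
        session.log(now, "bot", "risk_referral", message)


def _advance(session: Session, script: CheckupScript, now: datetime) -> None:
    """Move the cursor forward after an accepted answer."""
    section = script.section(session.cursor_section)  # type: ignore[arg-type]
    instrument = script.instrument(section.instrument_id)
    _drop_excluded_answers(session, script)
    if session.cursor_item + 1 < len(instrument.items):
        session.cursor_item += 1
        return
    # section finished: score, run the safety protocol, move on
    _run_risk_checks(session, script, now)
    path = included_sections(script, session.answers)
    ids = [s.id for s in path]
    idx = ids.index(section.id)
    if idx + 1 < len(path):
        session.cursor_section = path[idx + 1].id
        session.cursor_item = 0
    else:
        session.cursor_section = None
        session.cursor_item = 0
        session.status = "completed"


def submit_answer(
    session: Session, script: CheckupScript, option_value: int, now: datetime
) -> Session:
    """Record the answer to the current question and advance.

    The expiry rule is applied first; an illegal value is rejected without
    moving the cursor (the question is simply re-presented — there is no
    path that skips it).  Finishing a section triggers scoring and the
    risk checks; finishing the last section completes the session.
    """
    check_expiry(session, now)
    if session.status == "expired":
        raise StateError("session has expired; restart to begin again")
    if session.status != "in_progress":
        raise StateError(f"cannot answer in a {session.status} session")
    section, item = _current_item(session, script)
    if option_value not in {o.value for o in item.options}:
        raise AnswerValidationError(
            f"{option_value} is not one of the offered options for "
            f"item {item.id}",
            item_id=item.id,
        )
    session.answers.setdefault(section.id, {})[item.id] = option_value
    session.log(
        now, "user", "answer",
        {"section": section.id, "item": item.id, "value": option_value},
    )
    session.last_action = "answer"
    _advance(session, script, now)
    return session


def go_back(session: Session, script: CheckupScript) -> Session:
    """Step back to the immediately preceding answer and clear it.

    Only a single step is permitted: a second consecutive ``go_back`` (and
    a ``go_back`` at the very first prompt) is a no-op with a notice.  If
    the cleared answer fed a branch rule, the rule re-resolves once the
    item is re-answered, and answers in sections whose inclusion changed
    are dropped.
    """
    if session.status != "in_progress":
        raise StateError(f"cannot go back in a {session.status} session")
    if session.last_action == "go_back" or session.answer_count() == 0:
        # no-op notice: nothing to undo (or one step already taken)
        session.log(
            session.transcript[-1].timestamp if session.transcript
            else session.started_at,
            "bot", "message", "cannot go further back",
        )
        return session
    if session.cursor_item > 0:
        target_section = session.cursor_section
        target_index = session.cursor_item - 1
    else:
        path = included_sections(script, session.answers)
        ids = [s.id for s in path]
        if session.cursor_section is None:
            # completed sessions never reach here (guarded above)
            raise StateError("no cursor to step back from")
        idx = ids.index(session.cursor_section)
        if idx == 0:
            session.log(
                session.transcript[-1].timestamp if session.transcript
                else session.started_at,
                "bot", "message", "cannot go further back",
            )
            return session
        target_section = ids[idx - 1]
        target_index = len(script.section_instrument(target_section).items) - 1
    instrument = script.section_instrument(target_section)  # type: ignore[arg-type]
    item = instrument.items[target_index]
    session.answers.get(target_section, {}).pop(item.id, None)
    if target_section in session.answers and not session.answers[target_section]:
        del session.answers[target_section]
    session.cursor_section = target_section
    session.cursor_item = target_index
    session.last_action = "go_back"
    _drop_excluded_answers(session, script)
    return session


def submit_free_text(
    session: Session, script: CheckupScript, text: str, now: datetime
) -> list[str]:
    """Handle an out-of-band typed message: keyword scan, then resume.

    Returns the bot messages to display (referral flow on a lexicon match,
    empty otherwise); the current question is re-presented unchanged by the
    next :func:`next_prompt` call.
    """
    check_expiry(session, now)
    if session.status != "in_progress":
        raise StateError(f"cannot accept input in a {session.status} session")
    session.log(now, "user", "free_text", {"length": len(text)})
    if not script.risk.keyword_scanning:
        return []
    lexicon = script.risk.lexicon or risk_mod.DEFAULT_LEXICON
    event = scan_free_text(text, lexicon, now)
    if event is None:
        return []
    if not any(
        event.trigger == have.trigger and event.source == have.source
        for have in session.risk_events
    ):
        session.risk_events.append(event)
    messages = safety_flow(event, script.risk)
    for message in messages:
        session.log(now, "bot", "risk_referral", message)
    if script.risk.halt_on_urgent:
        session.status = "expired"
        session.answers = {}
        session.cursor_section = None
    return messages


def progress(session: Session, script: CheckupScript) -> ProgressInfo:
    """Completed fraction of the tour plus per-section revealed flags.

    The denominator counts items of every section still on the path:
    conditional sections count until their branch rules resolve to
    "excluded", so forward moves never lower the fraction (only go_back
    can).  The fraction is exactly 1.0 at completion.
    """
    if session.status == "expired":
        return ProgressInfo(0.0, {s.id: False for s in script.sections})
    excluded = _definitively_excluded(script, session.answers)
    path = [
        s for s in script.sections
        if not s.conditional or s.id not in excluded
    ]
    total = sum(len(script.instrument(s.instrument_id).items) for s in path)
    answered = sum(
        len(session.answers.get(s.id, {})) for s in path
    )
    revealed = {}
    for s in script.sections:
        n_items = len(script.instrument(s.instrument_id).items)
        revealed[s.id] = len(session.answers.get(s.id, {})) == n_items
    fraction = answered / total if total else 0.0
    if session.status == "completed":
        fraction = 1.0
    return ProgressInfo(fraction, revealed)


# ---------------------------------------------------------------------------
# scoring a whole session
# ---------------------------------------------------------------------------

def session_scores(
    script: CheckupScript, session: Session
) -> dict[str, ScoreResult]:
    """Score every fully answered section; keyed by instrument id."""
    results: dict[str, ScoreResult] = {}
    for sec in script.sections:
        instrument = script.instrument(sec.instrument_id)
        answered = session.answers.get(sec.id, {})
        if len(answered) == len(instrument.items):
            vector = [answered[item.id] for item in instrument.items]
            results[instrument.id] = score_instrument(instrument, vector)
    return results
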