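"""Safety protocol: detect serious-risk conditions and build referral flows.

Three in-assessment triggers are monitored after each instrument completes:

* ``severe_anxiety`` — the anxiety screener categorizes in its top band;
* ``severe_depression`` — the depression screener categorizes in its top band;
* ``suicide_item`` — any non-zero endorsement of the depression screener's
  self-harm ideation item, regardless of the total score.

A fourth trigger, ``keyword``, fires on free text typed by the user when a
normalized lexicon phrase occurs as a substring.  Self-harm and keyword
triggers are urgent (emergency services first, then the care network);
severity triggers are elevated (care-network referral) unless they co-occur
with a suicide-item trigger, in which case they escalate to urgent.

Risk events never alter scores or category assignments; by default the
assessment resumes after the referral messages.
"""

from __future__ import annotations

import hashlib
import unicodedata
from datetime import datetime
from typing import Literal, Mapping, Optional, Sequence

from pydantic import BaseModel, ConfigDict, Field

from .instruments import PHQ9_SUICIDE_ITEM, ScoreResult

Trigger = Literal["severe_anxiety", "severe_depression", "suicide_item", "keyword"]
Tier = Literal["urgent", "elevated"]

#: tier precedence for merging simultaneous events
_TIER_RANK = {"elevated": 0, "urgent": 1}


def normalize_text(text: str) -> str:
    """Case-fold and strip diacritics (NFD decomposition, drop combining)."""
    decomposed = unicodedata.normalize("NFD", text.casefold())
    return "".join(c for c in decomposed if not unicodedata.combining(c))


class RiskEvent(BaseModel):
    model_config = ConfigDict(extra="forbid")

    trigger: Trigger
    source: str
    severity_tier: Tier
    timestamp: datetime


class RiskLexicon(BaseModel):
    """Normalized phrase list for free-text scanning."""

    model_config = ConfigDict(extra="forbid")

    phrases: list[str] = Field(min_length=1)
    normalization: str = "casefold+strip-diacritics"

    def normalized_phrases(self) -> list[str]:
        return [normalize_text(p) for p in self.phrases]


class RiskConfig(BaseModel):
    """Script-level safety configuration."""

    model_config = ConfigDict(extra="forbid")

    #: instrument id -> category labels that count as "very high risk"
    severe_categories: dict[str, list[str]] = Field(
        default_factory=lambda: {"gad7": ["severe"], "phq9": ["severe"]}
    )
    suicide_item: str = PHQ9_SUICIDE_ITEM
    lexicon: Optional[RiskLexicon] = None
    keyword_scanning: bool = True
    halt_on_urgent: bool = False
    emergency_message: str = (
        "If you are in immediate danger, please contact emergency services "
        "(SAMU 192 / CVV 188) right now."
    )
    care_message: str = (
        "Based on your answers, we recommend reaching out to the care "
        "network available to you for professional support."
    )


#: shipped placeholder lexicon (the deployed list is configuration)
DEFAULT_LEXICON = RiskLexicon(
    phrases=[
        "suicidio",
        "me matar",
        "quero morrer",
        "nao aguento mais viver",
        "me machucar",
        "suicide",
        "kill myself",
        "want to die",
        "hurt myself",
        "end my life",
    ]
)


_TRIGGER_OF_INSTRUMENT = {"gad7": "severe_anxiety", "phq9": "severe_depression"}


def assess_risk(
    score_results: Mapping[str, ScoreResult],
    answers: Mapping[str, int],
    config: RiskConfig,
    now: datetime,
) -> list[RiskEvent]:
    """Evaluate in-assessment triggers after instruments complete.

    ``answers`` maps item ids to option values (only the suicide item is
    consulted).  Severity events are elevated unless a suicide-item event
    co-occurs, which escalates them to urgent.
    """
    events: list[RiskEvent] = []
    suicide_value = answers.get(config.suicide_item, 0)
    suicide = suicide_value is not None and suicide_value > 0
    if suicide:
        events.append(
            RiskEvent(
                trigger="suicide_item",
                source=config.suicide_item,
                severity_tier="urgent",
                timestamp=now,
            )
        )
    for instrument_id, labels in config.severe_categories.items():
        result = score_results.get(instrument_id)
        if result is not None and result.category in labels:
            trigger = _TRIGGER_OF_INSTRUMENT.get(instrument_id)
            if trigger is None:
                continue
            events.append(
                RiskEvent(
                    trigger=trigger,
                    source=f"{instrument_id}:{result.category}",
                    severity_tier="urgent" if suicide else "elevated",
                    timestamp=now,
                )
            )
    return events


def scan_free_text(
    text: str, lexicon: RiskLexicon, now: Optional[datetime] = None
) -> Optional[RiskEvent]:
    """Substring-match normalized free text against the lexicon.

    Matching is invariant under case and diacritic changes.  The event
    source carries a snippet hash, never the text itself.
    """
    if not text:
        return None
    normalized = normalize_text(text)
    for phrase in lexicon.normalized_phrases():
        if phrase and phrase in normalized:
            digest = hashlib.sha256(text.encode("utf-8")).hexdigest()[:12]
            return RiskEvent(
                trigger="keyword",
                source=f"free_text:{digest}",
                severity_tier="urgent",
                timestamp=now or datetime.now().astimezone(),
            )
    return None


def safety_flow(
    events: RiskEvent | Sequence[RiskEvent], config: RiskConfig
) -> list[str]:
    """Ordered referral messages for one or more simultaneous events.

    Simultaneous events merge into a single flow at the highest tier:
    urgent puts the emergency-services message first, then the care
    network; elevated refers to the care network only.
    """
    if isinstance(events, RiskEvent):
        events = [events]
    if not events:
        return []
    tier = max((e.severity_tier for e in events), key=_TIER_RANK.__getitem__)
    if tier == "urgent":
        return [config.emergency_message, config.care_message]
    return [config.care_message]
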