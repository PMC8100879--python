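"""Shared fixtures: the default script and engineered synthetic cohorts."""

from __future__ import annotations

from datetime import datetime, timedelta, timezone
from typing import Optional, Sequence

import pytest

from checkup import (
    CheckupScript,
    Instrument,
    Session,
    start_session,
    submit_answer,
)
from checkup.instruments import PHQ9_SLEEP_ITEM, PHQ9_SUICIDE_ITEM
from checkup.persistence import default_script

T0 = datetime(2019, 10, 7, 9, 0, tzinfo=timezone.utc)


@pytest.fixture(scope="session")
def script() -> CheckupScript:
    return default_script()


# ---------------------------------------------------------------------------
# deterministic answer construction
# ---------------------------------------------------------------------------

def answers_for_total(
    instrument: Instrument,
    transformed_total: int,
    overrides: Optional[dict[str, int]] = None,
) -> list[int]:
    """An answer vector whose transformed total hits a target exactly.

    ``overrides`` pins raw option values for specific items (e.g. the
    sleep or self-harm item); the remaining keyed contributions are filled
    greedily front-to-back.
    """
    overrides = overrides or {}
    if instrument.transform == "double":
        assert transformed_total % 2 == 0, "doubled totals are even"
        target = transformed_total // 2
    else:
        target = transformed_total
    fixed = {
        item.id: item.keyed_value(overrides[item.id])
        for item in instrument.items
        if item.id in overrides
    }
    free = [item for item in instrument.items if item.id not in fixed]
    budget = target - sum(fixed.values()) - sum(i.min_value for i in free)
    assert budget >= 0, "target below minimum achievable"
    contrib: dict[str, int] = {}
    for item in free:
        add = min(budget, item.max_value - item.min_value)
        contrib[item.id] = item.min_value + add
        budget -= add
    assert budget == 0, "target above maximum achievable"
    vector = []
    for item in instrument.items:
        keyed = fixed.get(item.id, contrib.get(item.id))
        raw = (
            item.min_value + item.max_value - keyed
            if item.reverse_keyed
            else keyed
        )
        vector.append(raw)
    return vector


def run_scripted_session(
    script: CheckupScript,
    vectors: dict[str, Sequence[int]],
    start: datetime = T0,
    token: Optional[str] = None,
    group: Optional[str] = None,
    company_code: str = "ACME",
) -> Session:
    """Drive a session through the engine with per-instrument answers."""
    session = start_session(
        script, company_code, True, start, token=token, group=group
    )
    now = start
    while session.status == "in_progress":
        section = script.section(session.cursor_section)
        vector = vectors[section.instrument_id]
        submit_answer(session, script, vector[session.cursor_item], now)
        now += timedelta(seconds=5)
    return session


# ---------------------------------------------------------------------------
# an engineered cohort matching the pilot's printed category counts
# ---------------------------------------------------------------------------

#: representative transformed totals per category label
REPRESENTATIVE_TOTALS = {
    "gad7": {"none": 2, "mild": 6, "moderate": 12, "severe": 16},
    "phq9": {"none": 2, "mild": 6, "moderate": 12, "moderately severe": 16,
             "severe": 21},
    "dass21_stress": {"normal": 8, "mild": 16, "moderate": 20, "severe": 28},
    "isi": {"absence": 4, "subthreshold": 10, "moderate": 16, "severe": 23},
    "olbi": {"low": 25, "high": 35, "very high": 50},
    "jss": {"normal": 15, "slightly increased": 25, "increased": 35},
}

#: per-instrument category sequences for the 77 completers; the first 34
#: endorse the sleep item (and hence take the insomnia section); among the
#: first 74 respondents exactly 50 score in the low burnout band
PILOT_CATEGORIES = {
    "gad7": ["none"] * 37 + ["mild"] * 20 + ["moderate"] * 13 + ["severe"] * 7,
    "phq9": ["none"] * 49 + ["mild"] * 16 + ["moderate"] * 8
    + ["moderately severe"] * 3 + ["severe"] * 1,
    "dass21_stress": ["normal"] * 55 + ["mild"] * 8 + ["moderate"] * 10
    + ["severe"] * 4,
    "olbi": ["low"] * 50 + ["high"] * 27,
    "jss": ["normal"] * 4 + ["slightly increased"] * 20 + ["increased"] * 53,
}
PILOT_SLEEP_POSITIVE = 34
PILOT_ISI_CATEGORIES = (
    ["absence"] * 14 + ["subthreshold"] * 14 + ["moderate"] * 4
    + ["severe"] * 2
)


def build_pilot_cohort(script: CheckupScript) -> list[Session]:
    """77 completed sessions engineered to the pilot's category counts."""
    instruments = {i.id: i for i in script.instruments}
    sessions = []
    isi_iter = iter(PILOT_ISI_CATEGORIES)
    for r in range(77):
        sleep = 1 if r < PILOT_SLEEP_POSITIVE else 0
        vectors = {}
        for iid in ("gad7", "dass21_stress", "olbi", "jss"):
            label = PILOT_CATEGORIES[iid][r]
            vectors[iid] = answers_for_total(
                instruments[iid], REPRESENTATIVE_TOTALS[iid][label]
            )
        vectors["phq9"] = answers_for_total(
            instruments["phq9"],
            REPRESENTATIVE_TOTALS["phq9"][PILOT_CATEGORIES["phq9"][r]],
            overrides={PHQ9_SLEEP_ITEM: sleep, PHQ9_SUICIDE_ITEM: 0},
        )
        if sleep:
            label = next(isi_iter)
            vectors["isi"] = answers_for_total(
                instruments["isi"], REPRESENTATIVE_TOTALS["isi"][label]
            )
        group = "recycling" if r < 34 else ("logistics" if r < 60 else "office")
        sessions.append(
            run_scripted_session(
                script, vectors, token=f"pilot-{r:03d}", group=group
            )
        )
    return sessions


@pytest.fixture(scope="session")
def pilot_cohort(script: CheckupScript) -> list[Session]:
    sessions = build_pilot_cohort(script)
    assert all(s.status == "completed" for s in sessions)
    return sessions
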