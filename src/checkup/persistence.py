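"""Checkup-script files, the session store, and report exports.

The script file is human-editable YAML that loads into a fully validated
:class:`~checkup.engine.CheckupScript`; unknown fields are rejected with
their location.  A campaign's session store is a directory with one JSON
record per session, named by its anonymous token — no names or other
personal identifiers are ever stored.  Reports export as comma-separated
tables (one row per instrument x group x category) plus a structured JSON
summary; timestamps are timezone-aware UTC throughout.
"""

from __future__ import annotations

import json
from importlib import resources
from pathlib import Path
from typing import Iterable, Optional, Union

import pandas as pd
import pydantic
import yaml

from .engine import (
    BranchRule,
    CheckupScript,
    EncouragementRule,
    FeedbackTemplates,
    Section,
    Session,
    start_session,
)
from .errors import RegistrationError, ScriptValidationError
from .instruments import PHQ9_SLEEP_ITEM, Instrument, default_instruments
from .report import GroupedDistribution
from .risk import RiskLexicon

PathLike = Union[str, Path]


# ---------------------------------------------------------------------------
# default script
# ---------------------------------------------------------------------------

#: default section order: the insomnia section sits right after depression
#: because its trigger is a depression-screener item
_SECTION_PLAN = [
    ("stress", "dass21_stress", False,
     "First stop: stress. A few statements about the past week."),
    ("anxiety", "gad7", False,
     "Next part of the iceberg: anxiety over the past two weeks."),
    ("depression", "phq9", False,
     "Now some questions about your mood over the past two weeks."),
    ("insomnia", "isi", True,
     "You mentioned sleep difficulties, so let's look at your sleep."),
    ("burnout", "olbi", False,
     "Almost around the iceberg: how you relate to your work."),
    ("work_stress", "jss", False,
     "Last section: demands, control and support at your workplace."),
]

ENCOURAGEMENT_MESSAGE = "We are almost done, you are doing very well!"
_MIDPOINT_MESSAGE = "You are doing great - keep going!"

_CARE_NOTE = (
    " Given this result we recommend getting in touch with the care "
    "network available to you."
)


def _default_feedback(instruments: dict[str, Instrument]) -> FeedbackTemplates:
    base = "Your {name} result falls in the '{category}' range (score {total})."
    per: dict[str, dict[str, str]] = {}
    for iid, instrument in instruments.items():
        per[iid] = {"default": base}
        # top two bands carry a care recommendation block
        for band in instrument.bands[-2:]:
            per[iid][band.label] = base + _CARE_NOTE
    return FeedbackTemplates(per_instrument=per)


def default_script() -> CheckupScript:
    """The bundled six-section checkup with canonical instruments."""
    instruments = default_instruments()
    sections = [
        Section(
            id=sid,
            instrument_id=iid,
            conditional=conditional,
            intro_messages=[intro],
        )
        for sid, iid, conditional, intro in _SECTION_PLAN
    ]
    encouragement = []
    for sid, iid, _, _ in _SECTION_PLAN:
        n = len(instruments[iid].items)
        if n >= 9:
            message = (
                ENCOURAGEMENT_MESSAGE if sid == "work_stress"
                else _MIDPOINT_MESSAGE
            )
            encouragement.append(
                EncouragementRule(
                    section_id=sid, item_index=n // 2, message=message
                )
            )
    script = CheckupScript(
        sections=sections,
        instruments=list(instruments.values()),
        branch_rules=[
            BranchRule(
                target_section="insomnia",
                source_instrument="phq9",
                source_item=PHQ9_SLEEP_ITEM,
                excluded_value=0,
            )
        ],
        encouragement=encouragement,
        feedback=_default_feedback(instruments),
    )
    script.raise_for_errors()
    return script


def bundled_script_path() -> Path:
    """Path of the installed copy of the default script YAML."""
    return Path(str(resources.files("checkup").joinpath(
        "data/default_checkup.yaml")))


# ---------------------------------------------------------------------------
# script files
# ---------------------------------------------------------------------------

def load_script(path: PathLike) -> CheckupScript:
    """Parse and fully validate a checkup script file.

    Parse errors carry line information; unknown or invalid fields are
    reported with their location; instrument validators run and any
    error-severity violation rejects the script (warnings are kept on the
    returned script's behalf only in :meth:`CheckupScript.validate_script`).
    """
    path = Path(path)
    try:
        raw = yaml.safe_load(path.read_text(encoding="utf-8"))
    except yaml.YAMLError as exc:
        mark = getattr(exc, "problem_mark", None)
        where = f"{path}:{mark.line + 1}" if mark else str(path)
        raise ScriptValidationError(f"not valid YAML ({exc})", location=where)
    if not isinstance(raw, dict):
        raise ScriptValidationError("script file must be a mapping",
                                    location=str(path))
    try:
        script = CheckupScript.model_validate(raw)
    except pydantic.ValidationError as exc:
        first = exc.errors()[0]
        loc = ".".join(str(p) for p in first["loc"])
        raise ScriptValidationError(
            f"{first['msg']} (field {loc})", location=str(path)
        ) from exc
    script.raise_for_errors()
    return script


def save_script(script: CheckupScript, path: PathLike) -> Path:
    """Write a script as round-trippable YAML."""
    path = Path(path)
    payload = script.model_dump(mode="json")
    path.write_text(
        yaml.safe_dump(payload, sort_keys=False, allow_unicode=True,
                       width=88),
        encoding="utf-8",
    )
    return path


def load_lexicon(path: PathLike) -> RiskLexicon:
    """Read a risk lexicon: one phrase per line, ``#`` comments, UTF-8."""
    phrases = []
    for line in Path(path).read_text(encoding="utf-8").splitlines():
        line = line.strip()
        if line and not line.startswith("#"):
            phrases.append(line)
    return RiskLexicon(phrases=phrases)


# ---------------------------------------------------------------------------
# session store
# ---------------------------------------------------------------------------

class SessionStore:
    """One flat JSON record per session in a directory (the campaign unit).

    ``stats.json`` is reserved for campaign-level metadata and is never
    interpreted as a session record.
    """

    RESERVED = {"stats"}

    def __init__(self, directory: PathLike):
        self.directory = Path(directory)
        self.directory.mkdir(parents=True, exist_ok=True)

    def _path(self, token: str) -> Path:
        return self.directory / f"{token}.json"

    def save(self, session: Session) -> Path:
        path = self._path(session.token)
        path.write_text(session.model_dump_json(indent=2), encoding="utf-8")
        return path

    def load(self, token: str) -> Session:
        path = self._path(token)
        if not path.exists():
            raise RegistrationError(f"no session for token {token!r}")
        return Session.model_validate_json(path.read_text(encoding="utf-8"))

    def tokens(self) -> list[str]:
        return sorted(
            p.stem
            for p in self.directory.glob("*.json")
            if p.stem not in self.RESERVED
        )

    def sessions(self) -> list[Session]:
        return [self.load(token) for token in self.tokens()]

    def start_session(
        self,
        script: CheckupScript,
        company_code: str,
        consent: bool,
        now,
        token: Optional[str] = None,
        group: Optional[str] = None,
    ) -> Session:
        """Register against the store: duplicate tokens are rejected.

        A token whose previous session expired may register afresh (the
        24-hour reset overwrites the old, already-erased record).
        """
        if token is not None and self._path(token).exists():
            previous = self.load(token)
            if previous.status != "expired":
                raise RegistrationError(
                    f"token {token!r} is already registered"
                )
        session = start_session(script, company_code, consent, now,
                                token=token, group=group)
        self.save(session)
        return session


# ---------------------------------------------------------------------------
# report exports
# ---------------------------------------------------------------------------

def distributions_frame(
    distributions: Iterable[GroupedDistribution],
) -> pd.DataFrame:
    rows = [
        {
            "instrument_id": dist.instrument_id,
            "group": group,
            "category": category,
            "count": count,
        }
        for dist in distributions
        for group, cats in sorted(dist.distribution.items())
        for category, count in cats.items()
    ]
    return pd.DataFrame(
        rows, columns=["instrument_id", "group", "category", "count"]
    )


def write_distributions_csv(
    distributions: Iterable[GroupedDistribution], path: PathLike
) -> Path:
    path = Path(path)
    distributions_frame(distributions).to_csv(path, index=False)
    return path


def read_distributions_csv(path: PathLike) -> list[GroupedDistribution]:
    frame = pd.read_csv(path)
    out: list[GroupedDistribution] = []
    for iid, sub in frame.groupby("instrument_id", sort=False):
        dist: dict[str, dict[str, int]] = {}
        for record in sub.to_dict("records"):
            dist.setdefault(str(record["group"]), {})[
                str(record["category"])
            ] = int(record["count"])
        out.append(GroupedDistribution(instrument_id=str(iid),
                                       distribution=dist))
    return out


def write_json(payload: dict, path: PathLike) -> Path:
    path = Path(path)
    path.write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n",
                    encoding="utf-8")
    return path
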