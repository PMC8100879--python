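"""Exception hierarchy shared across the checkup engine.

Exit-code mapping for the CLI lives in :mod:`checkup.cli`; the split here
mirrors it: usage problems (bad flags, missing files) are click's domain,
``ScriptValidationError``/``AnswerValidationError`` are validation failures,
and ``StateError``/``RegistrationError`` are session-state failures.
"""

from __future__ import annotations


class CheckupError(Exception):
    """Base class for all errors raised by this package."""


class AnswerValidationError(CheckupError, ValueError):
    """An answer value is illegal for the item it was given to."""

    def __init__(self, message: str, item_id: str | None = None):
        super().__init__(message)
        self.item_id = item_id


class ScriptValidationError(CheckupError, ValueError):
    """A checkup script (or an instrument inside it) fails validation."""

    def __init__(self, message: str, location: str | None = None):
        super().__init__(message if location is None else f"{location}: {message}")
        self.location = location


class CoverageError(CheckupError, LookupError):
    """A total falls outside every configured category band.

    Signals a misconfigured script: bands must jointly cover every
    achievable transformed total.
    """


class StateError(CheckupError, RuntimeError):
    """An operation was applied to a session in the wrong lifecycle state."""


class RegistrationError(CheckupError, ValueError):
    """Registration failed (empty company code, duplicate token)."""


class ConsentError(CheckupError):
    """The user declined the terms; carries the terms text for re-display."""

    def __init__(self, terms_text: str):
        super().__init__("consent is required before the checkup can start")
        self.terms_text = terms_text


class ConfigError(CheckupError, ValueError):
    """A configuration object (population, report, templates) is invalid."""
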