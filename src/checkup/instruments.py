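"""Standardized screening instruments: definition, scoring, categorization.

Six self-report questionnaires are modelled:

========== ===== ======= ============ ==========================================
id         items scale   transform    severity bands (transformed total)
========== ===== ======= ============ ==========================================
gad7         7   0-3     identity     none 0-4, mild 5-9, moderate 10-14, severe 15+
phq9         9   0-3     identity     none 0-4, mild 5-9, moderate 10-14,
                                      moderately severe 15-19, severe 20+
dass21_stress 7  0-3     double       normal 0-14, mild 15-18, moderate 19-25,
                                      severe 26-33, extremely severe 34+
isi          7   0-4     identity     absence 0-7, subthreshold 8-14,
                                      moderate 15-21, severe 22+
olbi        16   1-4     identity     very low 0-15, low 16-30, high 31-45,
                                      very high 46+
jss         15   1-4     identity     normal 0-15, slightly increased 16-30,
                                      increased 31-45, extremely increased 46+
========== ===== ======= ============ ==========================================

The DASS-21 stress subscale total is doubled before banding so the bands of
the 42-item parent scale apply.  Reverse-keyed items contribute
``min + max - value`` of their option scale, so that higher totals uniformly
mean higher risk.  Note the OLBI "very low" band (0-15) is unreachable when
all 16 items score 1-4 (minimum keyed sum 16); :func:`validate_instrument`
reports this as a warning, not an error, because the published bands are
applied to the raw 1-4 sum as printed.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Literal, Optional, Sequence

from pydantic import BaseModel, Field, model_validator

from .errors import AnswerValidationError, CoverageError

InstrumentId = Literal["gad7", "phq9", "dass21_stress", "isi", "olbi", "jss"]

#: canonical item counts per instrument id
EXPECTED_ITEM_COUNTS: dict[str, int] = {
    "gad7": 7,
    "phq9": 9,
    "dass21_stress": 7,
    "isi": 7,
    "olbi": 16,
    "jss": 15,
}

#: instruments whose total is doubled before banding
EXPECTED_TRANSFORMS: dict[str, str] = {i: "identity" for i in EXPECTED_ITEM_COUNTS}
EXPECTED_TRANSFORMS["dass21_stress"] = "double"


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

class ResponseOption(BaseModel):
    """One selectable answer: display text plus its integer score value."""

    label: str
    value: int


class Item(BaseModel):
    """A single question with its ordered option scale.

    ``reverse_keyed`` items contribute ``min + max - value``; ``subscale``
    tags items of multidimensional instruments (OLBI, JSS).
    """

    id: str
    text: str
    options: list[ResponseOption] = Field(min_length=2)
    reverse_keyed: bool = False
    subscale: Optional[str] = None

    @model_validator(mode="after")
    def _check_scale(self) -> "Item":
        values = [o.value for o in self.options]
        if len(set(values)) != len(values):
            raise ValueError(f"item {self.id}: option values must be distinct")
        lo, hi = min(values), max(values)
        if sorted(values) != list(range(lo, hi + 1)):
            raise ValueError(f"item {self.id}: option values must be contiguous")
        return self

    @property
    def min_value(self) -> int:
        return min(o.value for o in self.options)

    @property
    def max_value(self) -> int:
        return max(o.value for o in self.options)

    def keyed_value(self, value: int) -> int:
        """Score contribution of ``value`` after reverse-keying."""
        if value not in {o.value for o in self.options}:
            raise AnswerValidationError(
                f"value {value} is not a legal option for item {self.id} "
                f"(legal: {self.min_value}..{self.max_value})",
                item_id=self.id,
            )
        if self.reverse_keyed:
            return self.min_value + self.max_value - value
        return value


class CategoryBand(BaseModel):
    """Inclusive score interval mapped to a severity label.

    ``upper=None`` means unbounded above (the printed "15+" style band).
    """

    label: str
    lower: int
    upper: Optional[int] = None

    def contains(self, total: int) -> bool:
        return total >= self.lower and (self.upper is None or total <= self.upper)

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        hi = "+" if self.upper is None else f"-{self.upper}"
        return f"{self.label} ({self.lower}{hi})"


class Instrument(BaseModel):
    """A questionnaire definition: items, transform, category bands."""

    id: str
    name: str = ""
    items: list[Item]
    transform: Literal["identity", "double"] = "identity"
    subscales: Optional[list[str]] = None
    bands: list[CategoryBand]
    subscale_bands: Optional[dict[str, list[CategoryBand]]] = None

    @model_validator(mode="after")
    def _default_name(self) -> "Instrument":
        if not self.name:
            self.name = self.id
        return self

    # -- score arithmetic ---------------------------------------------------

    def apply_transform(self, raw_total: int) -> int:
        return 2 * raw_total if self.transform == "double" else raw_total

    @property
    def min_raw_total(self) -> int:
        return sum(i.min_value for i in self.items)

    @property
    def max_raw_total(self) -> int:
        return sum(i.max_value for i in self.items)

    def achievable_totals(self) -> list[int]:
        """All achievable transformed totals (contiguous raw sums)."""
        return [
            self.apply_transform(t)
            for t in range(self.min_raw_total, self.max_raw_total + 1)
        ]

    def item_index(self, item_id: str) -> int:
        for k, item in enumerate(self.items):
            if item.id == item_id:
                return k
        raise KeyError(item_id)


@dataclass(frozen=True)
class ScoreResult:
    """Scored outcome for one instrument on one answer vector."""

    instrument_id: str
    raw_total: int
    transformed_total: int
    subscale_totals: dict[str, int]
    category: str
    subscale_categories: Optional[dict[str, str]] = None

    def as_dict(self) -> dict:
        return {
            "instrument_id": self.instrument_id,
            "raw_total": self.raw_total,
            "transformed_total": self.transformed_total,
            "subscale_totals": dict(self.subscale_totals),
            "category": self.category,
            "subscale_categories": (
                dict(self.subscale_categories) if self.subscale_categories else None
            ),
        }


@dataclass(frozen=True)
class Violation:
    """One validation finding; warnings do not block script loading."""

    message: str
    severity: str = "error"  # "error" | "warning"


# ---------------------------------------------------------------------------
# operations
# ---------------------------------------------------------------------------

def categorize(total: int, bands: Sequence[CategoryBand]) -> str:
    """Map a transformed total to the unique band containing it."""
    matches = [b for b in bands if b.contains(total)]
    if not matches:
        raise CoverageError(
            f"total {total} falls outside every band "
            f"({', '.join(str(b) for b in bands)}); the script is misconfigured"
        )
    return matches[0].label


def score_instrument(instrument: Instrument, answers: Sequence[int]) -> ScoreResult:
    """Score an ordered vector of option values against an instrument.

    Reverse-keyed items contribute ``min + max - value``; the raw sum is
    transformed (identity or doubled) and mapped onto the category bands.
    """
    if len(answers) != len(instrument.items):
        raise AnswerValidationError(
            f"{instrument.id}: expected {len(instrument.items)} answers, "
            f"got {len(answers)}"
        )
    keyed = [item.keyed_value(v) for item, v in zip(instrument.items, answers)]
    raw_total = sum(keyed)
    transformed = instrument.apply_transform(raw_total)
    sub_totals: dict[str, int] = {}
    sub_categories: Optional[dict[str, str]] = None
    if instrument.subscales:
        sub_totals = subscale_totals(instrument, answers)
        if instrument.subscale_bands:
            sub_categories = {
                tag: categorize(t, instrument.subscale_bands[tag])
                for tag, t in sub_totals.items()
                if tag in instrument.subscale_bands
            }
    return ScoreResult(
        instrument_id=instrument.id,
        raw_total=raw_total,
        transformed_total=transformed,
        subscale_totals=sub_totals,
        category=categorize(transformed, instrument.bands),
        subscale_categories=sub_categories,
    )


def subscale_totals(instrument: Instrument, answers: Sequence[int]) -> dict[str, int]:
    """Per-subscale keyed sums; together they partition the raw total."""
    if not instrument.subscales:
        raise AnswerValidationError(f"{instrument.id} defines no subscales")
    if len(answers) != len(instrument.items):
        raise AnswerValidationError(
            f"{instrument.id}: expected {len(instrument.items)} answers, "
            f"got {len(answers)}"
        )
    totals = {tag: 0 for tag in instrument.subscales}
    for item, v in zip(instrument.items, answers):
        if item.subscale is None:
            raise AnswerValidationError(
                f"item {item.id} carries no subscale tag but {instrument.id} "
                "defines subscales",
                item_id=item.id,
            )
        totals[item.subscale] += item.keyed_value(v)
    return totals


def validate_instrument(instrument: Instrument) -> list[Violation]:
    """Check an instrument against its declared id and internal invariants.

    Returns a list of findings; empty means fully canonical.  Unreachable
    bands (like the OLBI 0-15 band under 1-4 item scoring) are warnings.
    """
    out: list[Violation] = []
    expected_n = EXPECTED_ITEM_COUNTS.get(instrument.id)
    if expected_n is None:
        out.append(Violation(f"unknown instrument id {instrument.id!r}"))
    elif len(instrument.items) != expected_n:
        out.append(
            Violation(
                f"{instrument.id}: expected {expected_n} items, "
                f"found {len(instrument.items)}"
            )
        )
    expected_t = EXPECTED_TRANSFORMS.get(instrument.id)
    if expected_t is not None and instrument.transform != expected_t:
        out.append(
            Violation(
                f"{instrument.id}: transform must be {expected_t!r}, "
                f"found {instrument.transform!r}"
            )
        )

    # band ordering / overlap / coverage over achievable transformed totals
    bands = instrument.bands
    for a, b in zip(bands, bands[1:]):
        if a.upper is None:
            out.append(Violation(f"band {a} is unbounded but not last"))
        elif b.lower <= a.upper:
            out.append(Violation(f"bands {a} and {b} overlap or are unsorted"))
    achievable = instrument.achievable_totals()
    uncovered = [t for t in achievable if not any(b.contains(t) for b in bands)]
    if uncovered:
        out.append(
            Violation(
                f"{instrument.id}: achievable totals {uncovered[:5]}"
                f"{'...' if len(uncovered) > 5 else ''} fall in a band gap"
            )
        )
    reachable = set(achievable)
    for band in bands:
        hi = band.upper if band.upper is not None else max(achievable)
        if not any(t in reachable for t in range(band.lower, hi + 1)):
            out.append(
                Violation(
                    f"{instrument.id}: band {band} is unreachable "
                    f"(achievable totals span {min(achievable)}-{max(achievable)})",
                    severity="warning",
                )
            )

    # subscale tagging
    if instrument.subscales:
        for item in instrument.items:
            if item.subscale is None:
                out.append(
                    Violation(f"item {item.id} is untagged in subscale instrument")
                )
            elif item.subscale not in instrument.subscales:
                out.append(
                    Violation(
                        f"item {item.id} tagged {item.subscale!r}, not a "
                        f"declared subscale of {instrument.id}"
                    )
                )
    return out


# ---------------------------------------------------------------------------
# canonical definitions
# ---------------------------------------------------------------------------

_FREQ_0_3 = ["Not at all", "Several days", "More than half the days",
             "Nearly every day"]
_APPLIED_0_3 = ["Did not apply to me", "Applied to some degree",
                "Applied a good part of the time",
                "Applied very much or most of the time"]
_SEVERITY_0_4 = ["None", "Mild", "Moderate", "Severe", "Very severe"]
_AGREE_1_4 = ["Strongly agree", "Agree", "Disagree", "Strongly disagree"]
_OFTEN_1_4 = ["Almost never", "Rarely", "Sometimes", "Frequently"]


def _scale(labels: Sequence[str], start: int = 0) -> list[ResponseOption]:
    return [
        ResponseOption(label=lab, value=start + k) for k, lab in enumerate(labels)
    ]


def _items(
    prefix: str,
    texts: Sequence[str],
    labels: Sequence[str],
    start: int = 0,
    reverse: Iterable[int] = (),
    subscale_of: Optional[dict[int, str]] = None,
) -> list[Item]:
    rev = set(reverse)
    return [
        Item(
            id=f"{prefix}_{k + 1}",
            text=text,
            options=_scale(labels, start),
            reverse_keyed=(k + 1) in rev,
            subscale=(subscale_of or {}).get(k + 1),
        )
        for k, text in enumerate(texts)
    ]


def _bands(spec: Sequence[tuple[str, int, Optional[int]]]) -> list[CategoryBand]:
    return [CategoryBand(label=l, lower=lo, upper=hi) for l, lo, hi in spec]


def build_gad7() -> Instrument:
    """7-item anxiety screener, two-week window, scored 0-21."""
    texts = [
        "Feeling nervous, anxious, or on edge",
        "Not being able to stop or control worrying",
        "Worrying too much about different things",
        "Trouble relaxing",
        "Being so restless that it is hard to sit still",
        "Becoming easily annoyed or irritable",
        "Feeling afraid as if something awful might happen",
    ]
    return Instrument(
        id="gad7",
        name="Generalized Anxiety Disorder-7",
        items=_items("gad7", texts, _FREQ_0_3),
        bands=_bands(
            [("none", 0, 4), ("mild", 5, 9), ("moderate", 10, 14),
             ("severe", 15, None)]
        ),
    )


#: PHQ-9 sleep-difficulty item id: gates the insomnia section of the checkup
PHQ9_SLEEP_ITEM = "phq9_3"
#: PHQ-9 self-harm ideation item id: any endorsement triggers the safety flow
PHQ9_SUICIDE_ITEM = "phq9_9"


def build_phq9() -> Instrument:
    """9-item depression screener, scored 0-27; item 9 probes self-harm."""
    texts = [
        "Little interest or pleasure in doing things",
        "Feeling down, depressed, or hopeless",
        "Trouble falling or staying asleep, or sleeping too much",
        "Feeling tired or having little energy",
        "Poor appetite or overeating",
        "Feeling bad about yourself, or that you are a failure",
        "Trouble concentrating on things",
        "Moving or speaking noticeably slowly, or being fidgety or restless",
        "Thoughts that you would be better off dead or of hurting yourself",
    ]
    return Instrument(
        id="phq9",
        name="Patient Health Questionnaire-9",
        items=_items("phq9", texts, _FREQ_0_3),
        bands=_bands(
            [("none", 0, 4), ("mild", 5, 9), ("moderate", 10, 14),
             ("moderately severe", 15, 19), ("severe", 20, None)]
        ),
    )


def build_dass21_stress() -> Instrument:
    """DASS-21 stress subscale: 7 items 0-3; total doubled before banding."""
    texts = [
        "I found it hard to wind down",
        "I tended to overreact to situations",
        "I felt that I was using a lot of nervous energy",
        "I found myself getting agitated",
        "I found it difficult to relax",
        "I was intolerant of anything that kept me from getting on with "
        "what I was doing",
        "I felt that I was rather touchy",
    ]
    return Instrument(
        id="dass21_stress",
        name="DASS-21 stress subscale",
        items=_items("dass", texts, _APPLIED_0_3),
        transform="double",
        bands=_bands(
            [("normal", 0, 14), ("mild", 15, 18), ("moderate", 19, 25),
             ("severe", 26, 33), ("extremely severe", 34, None)]
        ),
    )


def build_isi() -> Instrument:
    """Insomnia Severity Index: 7 items 0-4, scored 0-28."""
    texts = [
        "Difficulty falling asleep",
        "Difficulty staying asleep",
        "Problems waking up too early",
        "How satisfied are you with your current sleep pattern?",
        "How noticeable to others is your sleep problem?",
        "How worried are you about your current sleep problem?",
        "To what extent does your sleep problem interfere with your daily "
        "functioning?",
    ]
    return Instrument(
        id="isi",
        name="Insomnia Severity Index",
        items=_items("isi", texts, _SEVERITY_0_4),
        bands=_bands(
            [("absence", 0, 7), ("subthreshold", 8, 14), ("moderate", 15, 21),
             ("severe", 22, None)]
        ),
    )


def build_olbi() -> Instrument:
    """Oldenburg Burnout Inventory: 16 items 1-4 over two dimensions.

    Response scale runs 1 (strongly agree) to 4 (strongly disagree).  Items
    where agreement endorses burnout (negatively worded) are reverse-keyed
    so that higher keyed totals uniformly mean higher burnout risk; the
    positively worded half already points risk-ward (disagreeing with an
    engagement statement scores high).
    """
    exhaustion = [
        ("There are days when I feel tired before I arrive at work", True),
        ("After work, I usually feel worn out and weary", True),
        ("After working, I have enough energy for my leisure activities", False),
        ("After my work, I usually feel totally fit for my leisure "
         "activities", False),
        ("During my work, I often feel emotionally drained", True),
        ("When I work, I usually feel energized", False),
        ("I can tolerate the pressure of my work very well", False),
        ("Over time, one can become disconnected from this type of work",
         True),
    ]
    disengagement = [
        ("I always find new and interesting aspects in my work", False),
        ("It happens more and more often that I talk about my work in a "
         "negative way", True),
        ("Lately, I tend to think less at work and do my job almost "
         "mechanically", True),
        ("I find my work to be a positive challenge", False),
        ("I feel more and more engaged in my work", False),
        ("Sometimes I feel sickened by my work tasks", True),
        ("This is the only type of work that I can imagine myself doing",
         False),
        ("I feel disillusioned with my work", True),
    ]
    items = []
    for k, (text, negative) in enumerate(exhaustion + disengagement):
        items.append(
            Item(
                id=f"olbi_{k + 1}",
                text=text,
                options=_scale(_AGREE_1_4, start=1),
                reverse_keyed=negative,
                subscale="exhaustion" if k < 8 else "disengagement",
            )
        )
    return Instrument(
        id="olbi",
        name="Oldenburg Burnout Inventory",
        items=items,
        subscales=["exhaustion", "disengagement"],
        bands=_bands(
            [("very low", 0, 15), ("low", 16, 30), ("high", 31, 45),
             ("very high", 46, None)]
        ),
    )


def build_jss() -> Instrument:
    """15-item demand-control-support job stress short form, items 1-4.

    Demand items use a frequency scale pointing risk-ward; control items are
    reverse-keyed (having choice is protective); support items use an
    agreement scale where disagreement (low support) scores high, so all
    three subscale totals and the overall total point toward higher risk.
    """
    demand = [
        "Do you have to work very fast?",
        "Do you have to work very intensively?",
        "Does your work demand too much effort?",
        "Do you have enough time to do everything?",
        "Does your work often involve conflicting demands?",
    ]
    control = [
        "Do you have the possibility of learning new things in your work?",
        "Does your work demand a high level of skill or expertise?",
        "Does your work require you to take initiative?",
        "In your work, do you have to do the same thing over and over again?",
        "Do you have a choice in deciding how you do your work?",
    ]
    support = [
        "There is a calm and pleasant atmosphere where I work",
        "We get along well with each other where I work",
        "My coworkers are supportive of me",
        "People understand if I have a bad day at work",
        "I get along well with my supervisors",
    ]
    items: list[Item] = []
    n = 0
    for k, text in enumerate(demand):
        n += 1
        # "enough time" endorses low demand; reverse so high keyed = high risk
        items.append(
            Item(id=f"jss_{n}", text=text, options=_scale(_OFTEN_1_4, 1),
                 reverse_keyed=(k == 3), subscale="demand")
        )
    for k, text in enumerate(control):
        n += 1
        # "same thing over and over" endorses low control, already risk-ward
        items.append(
            Item(id=f"jss_{n}", text=text, options=_scale(_OFTEN_1_4, 1),
                 reverse_keyed=(k != 3), subscale="control")
        )
    for text in support:
        n += 1
        items.append(
            Item(id=f"jss_{n}", text=text,
                 options=_scale(["Totally agree", "Agree", "Disagree",
                                 "Totally disagree"], 1),
                 subscale="support")
        )
    return Instrument(
        id="jss",
        name="Job Stress Scale (demand-control-support short form)",
        items=items,
        subscales=["demand", "control", "support"],
        bands=_bands(
            [("normal", 0, 15), ("slightly increased", 16, 30),
             ("increased", 31, 45), ("extremely increased", 46, None)]
        ),
    )


def default_instruments() -> dict[str, Instrument]:
    """The six canonical instrument definitions keyed by id."""
    builders = [build_gad7, build_phq9, build_dass21_stress, build_isi,
                build_olbi, build_jss]
    return {ins.id: ins for ins in (b() for b in builders)}
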