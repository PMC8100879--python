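"""End-of-checkup feedback and anonymized organization-level reporting.

Campaign metrics follow the usual survey definitions: initiation =
started/eligible, completion = completed/started, response =
completed/eligible (so response = initiation x completion at full
precision).  Rates are computed at full precision and rendered half-up —
one decimal for campaign rates, whole percent for breakdown percentages.

Group-level category distributions apply small-cell pooling: any reporting
group with fewer than k members (k defaults to 8) is merged greedily,
smallest group into the smallest other group with ties broken by label
order, until every reported group has at least k members; if everything
collapses into one undersized group it is reported as "all".  Serialized
reports carry no session tokens.

Only completed sessions enter any distribution; expired sessions hold no
answers at all, so they cannot leak into a report.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from typing import Callable, Iterable, Mapping, Optional, Sequence

import pandas as pd

from .engine import CheckupScript, FeedbackTemplates, Session, session_scores
from .errors import ConfigError
from .instruments import Instrument, ScoreResult, categorize


def round_half_up(x: float, ndigits: int = 0) -> float:
    """Decimal half-up rounding (the convention used for printed rates)."""
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


# ---------------------------------------------------------------------------
# personalized feedback
# ---------------------------------------------------------------------------

def personal_feedback(
    score_results: Mapping[str, ScoreResult],
    templates: FeedbackTemplates,
    script: Optional[CheckupScript] = None,
) -> list[str]:
    """One feedback block per scored instrument, plus the disclaimer.

    Blocks follow the script's section order when a script is given.
    Template coverage is validated at script load; a missing category here
    (hand-built templates) is a configuration error.
    """
    ordered = list(score_results.values())
    if script is not None:
        by_id = {r.instrument_id: r for r in ordered}
        ordered = [
            by_id[sec.instrument_id]
            for sec in script.sections
            if sec.instrument_id in by_id
        ]
    messages: list[str] = []
    for result in ordered:
        per = templates.per_instrument.get(result.instrument_id, {})
        template = per.get(result.category, per.get("default"))
        if template is None:
            raise ConfigError(
                f"no feedback template for {result.instrument_id} "
                f"category {result.category!r}"
            )
        name = result.instrument_id
        if script is not None:
            name = script.instrument(result.instrument_id).name
        messages.append(
            template.format(
                name=name,
                category=result.category,
                total=result.transformed_total,
            )
        )
    messages.append(templates.disclaimer)
    return messages


# ---------------------------------------------------------------------------
# campaign metrics
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CampaignStats:
    """Counts plus derived rates (percent, full precision)."""

    eligible_n: int
    started_n: int
    completed_n: int

    def __post_init__(self) -> None:
        if self.eligible_n <= 0:
            raise ConfigError("eligible_n must be positive: rates undefined")
        if not self.completed_n <= self.started_n <= self.eligible_n:
            raise ConfigError(
                "expected completed <= started <= eligible, got "
                f"{self.completed_n}/{self.started_n}/{self.eligible_n}"
            )

    @property
    def initiation_rate(self) -> float:
        return 100.0 * self.started_n / self.eligible_n

    @property
    def completion_rate(self) -> float:
        if self.started_n == 0:
            return 0.0
        return 100.0 * self.completed_n / self.started_n

    @property
    def response_rate(self) -> float:
        return 100.0 * self.completed_n / self.eligible_n

    def rounded(self, decimals: int = 1) -> dict[str, float]:
        return {
            "initiation_rate": round_half_up(self.initiation_rate, decimals),
            "completion_rate": round_half_up(self.completion_rate, decimals),
            "response_rate": round_half_up(self.response_rate, decimals),
        }

    def as_dict(self, decimals: int = 1) -> dict:
        return {
            "eligible_n": self.eligible_n,
            "started_n": self.started_n,
            "completed_n": self.completed_n,
            **self.rounded(decimals),
        }


def campaign_stats(eligible_n: int, sessions: Iterable[Session]) -> CampaignStats:
    """Initiation/completion/response rates for a campaign's session store.

    Every session in the store counts as started (registration created
    it); only status ``completed`` counts as completed.
    """
    sessions = list(sessions)
    started = len(sessions)
    completed = sum(1 for s in sessions if s.status == "completed")
    return CampaignStats(
        eligible_n=eligible_n, started_n=started, completed_n=completed
    )


# ---------------------------------------------------------------------------
# pooled category distributions
# ---------------------------------------------------------------------------

def pool_groups(sizes: Mapping[str, int], k: int) -> dict[str, str]:
    """Map original group labels to pooled labels, every pool >= k.

    Greedy: repeatedly merge the smallest undersized group into the
    smallest other group (ties broken by label order).  A single leftover
    group below k — or a pool formed from every group — is labelled "all".
    """
    if k < 1:
        raise ConfigError("k must be >= 1")
    # each pool is a sorted tuple of original labels
    pools: dict[tuple[str, ...], int] = {
        (label,): size for label, size in sizes.items()
    }

    def pool_label(members: tuple[str, ...]) -> str:
        if len(members) == len(sizes) and len(sizes) > 1:
            return "all"
        return "+".join(members)

    while len(pools) > 1:
        undersized = [p for p, n in pools.items() if n < k]
        if not undersized:
            break
        smallest = min(undersized, key=lambda p: (pools[p], p))
        others = [p for p in pools if p != smallest]
        target = min(others, key=lambda p: (pools[p], p))
        merged = tuple(sorted(smallest + target))
        n = pools.pop(smallest) + pools.pop(target)
        pools[merged] = n

    mapping: dict[str, str] = {}
    for members, n in pools.items():
        label = pool_label(members)
        if len(pools) == 1 and n < k:
            label = "all"
        for original in members:
            mapping[original] = label
    return mapping


@dataclass(frozen=True)
class GroupedDistribution:
    """Per-instrument category counts by (pooled) reporting group."""

    instrument_id: str
    distribution: dict[str, dict[str, int]]
    pooled_from: dict[str, str] = field(default_factory=dict)

    def total(self) -> int:
        return sum(sum(cats.values()) for cats in self.distribution.values())


def aggregate_distributions(
    script: CheckupScript,
    sessions: Iterable[Session],
    group_of: Callable[[Session], str],
    k: int = 8,
) -> list[GroupedDistribution]:
    """Anonymized per-instrument category distributions by pooled group.

    Only completed sessions contribute; pooling is decided once, on
    completed-session head-counts, and applied to every instrument so a
    group's identity cannot be narrowed by comparing instruments.  The
    output carries no session tokens.
    """
    completed = [s for s in sessions if s.status == "completed"]
    sizes: dict[str, int] = {}
    labelled: list[tuple[str, dict[str, ScoreResult]]] = []
    for session in completed:
        label = group_of(session)
        sizes[label] = sizes.get(label, 0) + 1
        labelled.append((label, session_scores(script, session)))
    if not completed:
        return []
    mapping = pool_groups(sizes, k)

    out: list[GroupedDistribution] = []
    for instrument in script.instruments:
        dist: dict[str, dict[str, int]] = {}
        for label, results in labelled:
            result = results.get(instrument.id)
            if result is None:
                continue  # instrument not administered (unbranched section)
            pooled = mapping[label]
            cats = dist.setdefault(pooled, {})
            cats[result.category] = cats.get(result.category, 0) + 1
        out.append(
            GroupedDistribution(
                instrument_id=instrument.id,
                distribution=dist,
                pooled_from=dict(mapping),
            )
        )
    return out


# ---------------------------------------------------------------------------
# symptomatic breakdown
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SymptomaticBreakdown:
    """Severity-band distribution among respondents above the baseline band.

    ``baseline_label=None`` means no band is excluded (the convention used
    for the burnout and job-stress measures, whose distributions are
    reported over all respondents).
    """

    instrument_id: str
    baseline_label: Optional[str]
    symptomatic_n: int
    counts: dict[str, int]
    percentages: dict[str, int]


_DEFAULT_BASELINE = object()


def symptomatic_breakdown(
    script: CheckupScript,
    sessions: Iterable[Session],
    instrument_id: str,
    baseline_label: object = _DEFAULT_BASELINE,
) -> SymptomaticBreakdown:
    """Band counts and whole-percent shares among symptomatic respondents.

    The baseline (no-symptom) band defaults to the instrument's lowest
    band; pass ``baseline_label=None`` to count every respondent.
    Percentages are count/symptomatic_n rendered half-up to whole percent.
    """
    instrument = script.instrument(instrument_id)
    if baseline_label is _DEFAULT_BASELINE:
        baseline = instrument.bands[0].label
    else:
        baseline = baseline_label  # type: ignore[assignment]
    counts: dict[str, int] = {}
    for session in sessions:
        if session.status != "completed":
            continue
        result = session_scores(script, session).get(instrument_id)
        if result is None or result.category == baseline:
            continue
        counts[result.category] = counts.get(result.category, 0) + 1
    n = sum(counts.values())
    order = [b.label for b in instrument.bands if b.label in counts]
    counts = {label: counts[label] for label in order}
    percentages = {
        label: int(round_half_up(100.0 * c / n)) for label, c in counts.items()
    } if n else {}
    return SymptomaticBreakdown(
        instrument_id=instrument_id,
        baseline_label=baseline,
        symptomatic_n=n,
        counts=counts,
        percentages=percentages,
    )


# ---------------------------------------------------------------------------
# summary table
# ---------------------------------------------------------------------------

def summary_table(
    script: CheckupScript, sessions: Iterable[Session]
) -> pd.DataFrame:
    """Per-instrument n, mean, SD and the category of the rounded mean.

    Means and SDs are of transformed totals over completed sessions that
    answered the instrument (the insomnia count covers branch-triggered
    sessions only).  SD uses n-1 degrees of freedom; with a single
    respondent it is reported as 0.0 with ``sd_degenerate`` set.  Subscale
    rows are appended for multidimensional instruments; they carry a
    category only where subscale bands are configured.
    """
    completed = [s for s in sessions if s.status == "completed"]
    scored = [session_scores(script, s) for s in completed]
    rows = []

    def _row(measure: str, values: list[int],
             bands: Optional[list] = None) -> None:
        n = len(values)
        if n == 0:
            return
        series = pd.Series(values, dtype="float64")
        mean = float(series.mean())
        degenerate = n == 1
        sd = 0.0 if degenerate else float(series.std(ddof=1))
        category = ""
        if bands:
            category = categorize(int(round_half_up(mean)), bands)
        rows.append(
            {
                "measure": measure,
                "n": n,
                "mean": mean,
                "sd": sd,
                "category": category,
                "sd_degenerate": degenerate,
            }
        )

    for instrument in script.instruments:
        totals = [
            r[instrument.id].transformed_total
            for r in scored
            if instrument.id in r
        ]
        _row(instrument.id, totals, instrument.bands)
        if instrument.subscales:
            for tag in instrument.subscales:
                sub = [
                    r[instrument.id].subscale_totals[tag]
                    for r in scored
                    if instrument.id in r
                ]
                bands = (instrument.subscale_bands or {}).get(tag)
                _row(f"{instrument.id}:{tag}", sub, bands)
    return pd.DataFrame(
        rows, columns=["measure", "n", "mean", "sd", "category", "sd_degenerate"]
    )
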