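"""Synthetic respondents: latent-severity ordinal responses and campaigns.

Each simulated employee carries one real-valued latent severity per
construct (stress, anxiety, depression, insomnia, burnout, work stress),
drawn from a correlated multivariate normal.  An item response follows a
graded-threshold (cumulative probit) model: the keyed response level is the
interval of ``latent + noise`` among equally spaced cutpoints, with
standard-normal noise independent across items.  Reverse-keyed items emit
the mirrored raw option value, so the engine's reverse-keying at scoring
recovers the keyed level — the expected keyed total is therefore
non-decreasing in severity for every item.

Because levels are conditionally independent given the latent, the exact
distribution of an instrument total is a convolution, and population band
probabilities are a Gauss-Hermite integral over the latent distribution;
:func:`band_probabilities` computes them analytically, which is what the
parameter-recovery tests compare simulations against.

Campaign behaviour is two Bernoulli mechanisms: a start probability per
invited employee, and a memoryless per-prompt dropout hazard (geometric
survival across the question prompts); abandoned sessions later cross the
24-hour boundary and expire.  Defaults reproduce the pilot campaign's
conditions: start probability 98/120 and a hazard solved so that geometric
survival over the expected number of question prompts equals the observed
77/98 completion.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass
from datetime import datetime, timedelta, timezone
from typing import Optional, Sequence

import numpy as np
from pydantic import BaseModel, ConfigDict, Field, model_validator
from scipy.stats import norm

from .engine import (
    CheckupScript,
    Session,
    check_expiry,
    deliver_prompt,
    next_prompt,
    start_session,
    submit_answer,
)
from .errors import ConfigError
from .instruments import Instrument, Item
from .report import CampaignStats, campaign_stats

#: construct order used for correlation matrices
CONSTRUCTS = ["stress", "anxiety", "depression", "insomnia", "burnout",
              "work_stress"]

#: instrument id -> latent construct
CONSTRUCT_OF_INSTRUMENT = {
    "gad7": "anxiety",
    "phq9": "depression",
    "dass21_stress": "stress",
    "isi": "insomnia",
    "olbi": "burnout",
    "jss": "work_stress",
}

#: default latent locations, moment-matched (Gauss-Hermite) so that the
#: expected transformed instrument totals under spread 1.0 equal the pilot
#: cohort means (anxiety 6.21, depression 4.40, stress 11.09, insomnia 9.26,
#: burnout 27.68, work stress 32.38); see docs/methods.md
DEFAULT_LOCATIONS: dict[str, float] = {
    "stress": -1.043699,
    "anxiety": -0.888613,
    "depression": -1.619170,
    "insomnia": -0.817550,
    "burnout": -1.150078,
    "work_stress": -0.479414,
}

#: default latent correlation: anxiety-depression and depression-insomnia
#: co-vary (the insomnia branch conditions on a depression item), the rest
#: are independent
DEFAULT_CORRELATION: list[list[float]] = [
    [1.0, 0.0, 0.0, 0.0, 0.0, 0.0],
    [0.0, 1.0, 0.5, 0.0, 0.0, 0.0],
    [0.0, 0.5, 1.0, 0.5, 0.0, 0.0],
    [0.0, 0.0, 0.5, 1.0, 0.0, 0.0],
    [0.0, 0.0, 0.0, 0.0, 1.0, 0.0],
    [0.0, 0.0, 0.0, 0.0, 0.0, 1.0],
]

#: pilot campaign engagement conditions
DEFAULT_START_PROBABILITY = 98 / 120
DEFAULT_COMPLETION_TARGET = 77 / 98

#: default reporting-group head-count weights (an industrial plant's
#: recycling / reverse-logistics / office split)
DEFAULT_GROUP_WEIGHTS: dict[str, float] = {
    "recycling": 52.0,
    "logistics": 40.0,
    "office": 28.0,
}


# ---------------------------------------------------------------------------
# configuration and profiles
# ---------------------------------------------------------------------------

class SeverityParams(BaseModel):
    model_config = ConfigDict(extra="forbid")

    location: float = 0.0
    spread: float = Field(default=1.0, ge=0.0)


class PopulationConfig(BaseModel):
    """Parameters of a simulated employee population."""

    model_config = ConfigDict(extra="forbid")

    n: int = Field(default=120, ge=1)
    severity: dict[str, SeverityParams] = Field(default_factory=dict)
    correlation: Optional[list[list[float]]] = None
    start_probability: float = Field(
        default=DEFAULT_START_PROBABILITY, ge=0.0, le=1.0
    )
    dropout_hazard: Optional[float] = Field(default=None, ge=0.0, le=1.0)
    groups: dict[str, float] = Field(
        default_factory=lambda: dict(DEFAULT_GROUP_WEIGHTS)
    )
    threshold_spacing: float = Field(default=1.0, gt=0.0)
    seed: int = 0

    @model_validator(mode="after")
    def _fill_and_check(self) -> "PopulationConfig":
        for construct in CONSTRUCTS:
            self.severity.setdefault(
                construct,
                SeverityParams(location=DEFAULT_LOCATIONS[construct]),
            )
        unknown = set(self.severity) - set(CONSTRUCTS)
        if unknown:
            raise ValueError(f"unknown constructs {sorted(unknown)}")
        if self.correlation is not None:
            self.correlation_matrix()  # raises on invalid input
        return self

    def correlation_matrix(self) -> np.ndarray:
        if self.correlation is None:
            mat = np.asarray(DEFAULT_CORRELATION, dtype=float)
        else:
            mat = np.asarray(self.correlation, dtype=float)
        if mat.shape != (len(CONSTRUCTS), len(CONSTRUCTS)):
            raise ConfigError(
                f"correlation must be {len(CONSTRUCTS)}x{len(CONSTRUCTS)} "
                f"in construct order {CONSTRUCTS}"
            )
        if not np.allclose(mat, mat.T):
            raise ConfigError("correlation matrix must be symmetric")
        if not np.allclose(np.diag(mat), 1.0):
            raise ConfigError("correlation matrix needs a unit diagonal")
        if np.linalg.eigvalsh(mat).min() < -1e-8:
            raise ConfigError("correlation matrix is not positive semi-definite")
        return mat


@dataclass(frozen=True)
class RespondentProfile:
    """One simulated employee: latent severities plus behaviour parameters."""

    latent: dict[str, float]
    dropout_hazard: float
    start_probability: float
    seed: int
    group: Optional[str] = None


def _assign_groups(n: int, weights: dict[str, float]) -> list[Optional[str]]:
    """Deterministic proportional assignment (largest remainder)."""
    if not weights:
        return [None] * n
    labels = sorted(weights)
    total = sum(weights.values())
    exact = {g: n * weights[g] / total for g in labels}
    counts = {g: int(exact[g]) for g in labels}
    leftovers = sorted(
        labels, key=lambda g: (counts[g] and 0, exact[g] - counts[g], g),
        reverse=True,
    )
    for g in leftovers[: n - sum(counts.values())]:
        counts[g] += 1
    out: list[Optional[str]] = []
    for g in labels:
        out.extend([g] * counts[g])
    return out[:n]


def generate_population(config: PopulationConfig) -> list[RespondentProfile]:
    """Draw a reproducible population of respondent profiles.

    Latent severities use the configured correlation structure (a possibly
    singular PSD matrix is handled by an eigenvalue square root, so perfect
    correlation is allowed).
    """
    rng = np.random.default_rng(config.seed)
    corr = config.correlation_matrix()
    eigval, eigvec = np.linalg.eigh(corr)
    transform = eigvec @ np.diag(np.sqrt(np.clip(eigval, 0.0, None)))
    z = rng.standard_normal((config.n, len(CONSTRUCTS)))
    unit = z @ transform.T
    locations = np.array(
        [config.severity[c].location for c in CONSTRUCTS]
    )
    spreads = np.array([config.severity[c].spread for c in CONSTRUCTS])
    latents = locations + spreads * unit
    seeds = rng.integers(0, 2**31, size=config.n)
    hazard = (
        config.dropout_hazard
        if config.dropout_hazard is not None
        else default_dropout_hazard()
    )
    groups = _assign_groups(config.n, config.groups)
    return [
        RespondentProfile(
            latent={c: float(latents[i, j]) for j, c in enumerate(CONSTRUCTS)},
            dropout_hazard=hazard,
            start_probability=config.start_probability,
            seed=int(seeds[i]),
            group=groups[i],
        )
        for i in range(config.n)
    ]


# ---------------------------------------------------------------------------
# graded-threshold response model
# ---------------------------------------------------------------------------

def item_thresholds(n_options: int, spacing: float = 1.0) -> np.ndarray:
    """Equally spaced cutpoints centred on zero for an m-option item."""
    m = n_options
    return spacing * (np.arange(1, m) - m / 2.0)


def level_probabilities(
    theta: float, n_options: int, spacing: float = 1.0
) -> np.ndarray:
    """P(keyed level = r | latent theta) under the cumulative probit model."""
    cuts = item_thresholds(n_options, spacing)
    upper = np.append(norm.cdf(cuts - theta), 1.0)
    lower = np.insert(norm.cdf(cuts - theta), 0, 0.0)
    return upper - lower


def simulate_item_response(
    profile: RespondentProfile,
    item: Item,
    construct: str,
    spacing: float = 1.0,
) -> int:
    """Draw one option value for an item, deterministic per (seed, item).

    The latent plus standard-normal noise is cut at the item's thresholds
    to give the keyed level; a reverse-keyed item emits the mirrored raw
    option value so that scoring's reverse-keying recovers the level.
    """
    theta = profile.latent[construct]
    rng = np.random.default_rng([profile.seed, zlib.crc32(item.id.encode())])
    x = theta + rng.standard_normal()
    cuts = item_thresholds(len(item.options), spacing)
    level = int(np.searchsorted(cuts, x))
    if item.reverse_keyed:
        level = len(item.options) - 1 - level
    return item.options[level].value


def instrument_responses(
    profile: RespondentProfile,
    instrument: Instrument,
    construct: Optional[str] = None,
    spacing: float = 1.0,
) -> list[int]:
    """Option-value vector for a whole instrument."""
    construct = construct or CONSTRUCT_OF_INSTRUMENT[instrument.id]
    return [
        simulate_item_response(profile, item, construct, spacing)
        for item in instrument.items
    ]


# ---------------------------------------------------------------------------
# analytic band probabilities (the simulator's closed-form counterpart)
# ---------------------------------------------------------------------------

def total_pmf_given_theta(
    instrument: Instrument, theta: float, spacing: float = 1.0
) -> np.ndarray:
    """Exact pmf of the keyed raw total given the latent, by convolution.

    Index 0 corresponds to the minimum achievable raw total.
    """
    pmf = np.array([1.0])
    for item in instrument.items:
        pmf = np.convolve(pmf, level_probabilities(
            theta, len(item.options), spacing))
    return pmf


def band_probabilities(
    instrument: Instrument,
    location: float,
    spread: float,
    spacing: float = 1.0,
    n_quadrature: int = 81,
) -> dict[str, float]:
    """Population probability of each category band under the model.

    Integrates the conditional total pmf over the latent N(location,
    spread^2) with Gauss-Hermite quadrature (exact conditional pmf at each
    node).  With zero spread the single-node conditional pmf is used.
    """
    if spread == 0.0:
        nodes, weights = np.array([0.0]), np.array([1.0])
    else:
        nodes, weights = np.polynomial.hermite_e.hermegauss(n_quadrature)
        weights = weights / weights.sum()
    min_raw = instrument.min_raw_total
    pmf = np.zeros(instrument.max_raw_total - min_raw + 1)
    for node, weight in zip(nodes, weights):
        theta = location + spread * node
        pmf += weight * total_pmf_given_theta(instrument, theta, spacing)
    out: dict[str, float] = {}
    for band in instrument.bands:
        mass = 0.0
        for offset, p in enumerate(pmf):
            transformed = instrument.apply_transform(min_raw + offset)
            if band.contains(transformed):
                mass += p
        out[band.label] = float(mass)
    return out


def expected_total(
    instrument: Instrument,
    location: float,
    spread: float,
    spacing: float = 1.0,
    n_quadrature: int = 81,
) -> float:
    """Analytic expectation of the transformed instrument total."""
    if spread == 0.0:
        nodes, weights = np.array([0.0]), np.array([1.0])
    else:
        nodes, weights = np.polynomial.hermite_e.hermegauss(n_quadrature)
        weights = weights / weights.sum()
    min_raw = instrument.min_raw_total
    value = 0.0
    for node, weight in zip(nodes, weights):
        pmf = total_pmf_given_theta(instrument, location + spread * node,
                                    spacing)
        totals = np.array(
            [instrument.apply_transform(min_raw + i) for i in range(len(pmf))]
        )
        value += weight * float(pmf @ totals)
    return value


def match_location(
    instrument: Instrument,
    target_mean: float,
    spread: float = 1.0,
    spacing: float = 1.0,
) -> float:
    """Latent location whose expected transformed total equals the target."""
    from scipy.optimize import brentq

    lo, hi = -8.0, 8.0
    return float(
        brentq(
            lambda mu: expected_total(instrument, mu, spread, spacing)
            - target_mean,
            lo,
            hi,
        )
    )


def sleep_item_positive_probability(
    script: CheckupScript,
    location: float,
    spread: float,
    spacing: float = 1.0,
    n_quadrature: int = 81,
) -> float:
    """P(depression sleep item > 0): the insomnia-branch trigger rate."""
    from .instruments import PHQ9_SLEEP_ITEM

    instrument = script.instrument("phq9")
    item = instrument.items[instrument.item_index(PHQ9_SLEEP_ITEM)]
    if spread == 0.0:
        nodes, weights = np.array([0.0]), np.array([1.0])
    else:
        nodes, weights = np.polynomial.hermite_e.hermegauss(n_quadrature)
        weights = weights / weights.sum()
    p0 = 0.0
    for node, weight in zip(nodes, weights):
        probs = level_probabilities(
            location + spread * node, len(item.options), spacing
        )
        p0 += weight * probs[0]
    return 1.0 - p0


# ---------------------------------------------------------------------------
# campaign simulation
# ---------------------------------------------------------------------------

def calibrate_dropout(
    target_completion: float, n_prompts: int
) -> float:
    """Per-prompt hazard whose geometric survival hits a completion rate.

    Root of ``(1 - h)**n_prompts == target_completion`` in closed form.
    """
    if not 0.0 < target_completion <= 1.0:
        raise ConfigError("target completion must be in (0, 1]")
    if n_prompts < 1:
        raise ConfigError("n_prompts must be >= 1")
    return 1.0 - target_completion ** (1.0 / n_prompts)


def default_dropout_hazard() -> float:
    """Hazard reproducing the pilot's 77/98 completion over the default tour.

    The expected number of question prompts accounts for the insomnia
    branch firing at its analytic trigger rate under the default
    depression severity distribution.
    """
    from .persistence import default_script

    script = default_script()
    base = sum(
        len(script.instrument(s.instrument_id).items)
        for s in script.sections
        if not s.conditional
    )
    conditional = sum(
        len(script.instrument(s.instrument_id).items)
        for s in script.sections
        if s.conditional
    )
    p_branch = sleep_item_positive_probability(
        script, DEFAULT_LOCATIONS["depression"], 1.0
    )
    expected_prompts = base + p_branch * conditional
    return calibrate_dropout(
        DEFAULT_COMPLETION_TARGET, int(round(expected_prompts))
    )


@dataclass(frozen=True)
class ClockModel:
    """Timing of a simulated session: answer cadence and abandonment."""

    start: datetime = datetime(2019, 10, 7, 9, 0, tzinfo=timezone.utc)
    stagger_seconds: float = 60.0
    per_prompt_seconds: float = 10.0
    abandon_delay_hours: float = 25.0


def run_campaign(
    population: Sequence[RespondentProfile],
    script: CheckupScript,
    clock: Optional[ClockModel] = None,
    company_code: str = "SIM",
) -> tuple[list[Session], CampaignStats]:
    """Drive a population through the engine; return sessions plus stats.

    Each profile starts with its start probability; before every question
    prompt it abandons with its dropout hazard, in which case the session
    is left idle past the 24-hour boundary and expires.  Campaign stats
    count every created session as started.
    """
    clock = clock or ClockModel()
    sessions: list[Session] = []
    for i, profile in enumerate(population):
        rng = np.random.default_rng([profile.seed, 0x5E55])
        if rng.random() >= profile.start_probability:
            continue
        now = clock.start + timedelta(seconds=i * clock.stagger_seconds)
        session = start_session(
            script,
            company_code,
            consent=True,
            now=now,
            token=f"sim-{i:05d}",
            group=profile.group,
        )
        while session.status == "in_progress":
            prompt = deliver_prompt(session, script, now)
            if rng.random() < profile.dropout_hazard:
                check_expiry(
                    session,
                    now + timedelta(hours=clock.abandon_delay_hours),
                )
                break
            section = script.section(prompt.section_id)
            instrument = script.instrument(section.instrument_id)
            item = instrument.items[session.cursor_item]
            construct = CONSTRUCT_OF_INSTRUMENT[instrument.id]
            value = simulate_item_response(profile, item, construct)
            now = now + timedelta(seconds=clock.per_prompt_seconds)
            submit_answer(session, script, value, now)
        sessions.append(session)
    stats = campaign_stats(len(population), sessions)
    return sessions, stats
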