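# Methods

`checkup` re-implements, as a reusable engine, a chatbot-style workplace
mental-health checkup: a scripted, branching conversation that delivers six
standardized screening instruments, applies a safety protocol, and feeds an
anonymized organization-level report.  A synthetic-respondent simulator
makes the whole pipeline testable end to end without any real respondent
data.  This note records the models, the parameter choices, and the design
decisions that were genuinely open.

## Instruments and scoring

Six self-report instruments are bundled with their published scoring rules:

| id             | items | item scale | transform | bands (transformed total) |
|----------------|-------|-----------|-----------|---------------------------|
| `gad7`         | 7     | 0–3       | identity  | none 0–4, mild 5–9, moderate 10–14, severe 15+ |
| `phq9`         | 9     | 0–3       | identity  | none 0–4, mild 5–9, moderate 10–14, moderately severe 15–19, severe 20+ |
| `dass21_stress`| 7     | 0–3       | ×2        | normal 0–14, mild 15–18, moderate 19–25, severe 26–33, extremely severe 34+ |
| `isi`          | 7     | 0–4       | identity  | absence 0–7, subthreshold 8–14, moderate 15–21, severe 22+ |
| `olbi`         | 16    | 1–4       | identity  | very low 0–15, low 16–30, high 31–45, very high 46+ |
| `jss`          | 15    | 1–4       | identity  | normal 0–15, slightly increased 16–30, increased 31–45, extremely increased 46+ |

Scoring is a keyed sum: a reverse-keyed item contributes
`min + max − value` of its option scale, the raw sum is transformed
(identity everywhere except the DASS-21 stress subscale, whose total is
doubled so the 42-item parent scale's bands apply), and the transformed
total is mapped to the unique band containing it.  Bands must partition
every achievable transformed total; a total outside all bands raises a
coverage error, which always indicates a misconfigured script rather than
a user error.

Two scale quirks deserve note.  The OLBI is administered on a
1 (strongly agree) – 4 (strongly disagree) scale while its bands start at
0, so the "very low (0–15)" band is unreachable (the minimum keyed sum of
16 items scoring 1–4 is 16).  We keep the bands as published and have the
validator emit a warning, not an error.  We reverse-key the *negatively
worded* OLBI items: on this scale direction, agreeing with an exhaustion
statement scores 1, so without reversal high totals would mean
*engagement* while the band labels call 46+ "very high risk".  Reversing
the negative half makes higher keyed totals uniformly mean higher risk,
which is also what the monotonicity invariant and the simulator assume.
The item-level reverse set remains script-configurable.

The 15-item demand–control–support job-stress short form does not come
with a published item-to-subscale split; the bundled default uses
5 demand / 5 control / 5 support with the protective directions
(control, support, and the "enough time" demand item) reverse-keyed so
all three subscale totals point toward higher risk.  Subscale bands are
optional configuration and absent by default; the total-score bands are
always applied.

## Conversation engine

The checkup is a deterministic state machine over an ordered list of story
sections — stress, anxiety, depression, (insomnia), burnout, work-related
stress — each binding exactly one instrument.  The default order places
insomnia immediately after depression because its branch rule conditions
on the depression screener's sleep item: the insomnia section is included
if and only if that item is endorsed above "not at all".  Branch rules are
pure functions of the answer map, so inclusion is re-derived rather than
stored.

Questions are delivered one at a time; there is no skip path — an illegal
answer is rejected without moving the cursor.  Back-navigation is a single
step: the immediately preceding answer is cleared and re-asked, and a
second consecutive back is a no-op.  (A rolling chat interface shows only
the latest exchange, so deeper history editing is out of scope.)  When a
re-answer flips a branch decision, answers in sections that left the path
are dropped.

Sessions not completed within 24 hours expire: status flips to `expired`
and the answers *and* the answer-bearing transcript are erased, so no
reporting operation can expose an expired session's data.  The boundary is
strict (`> 24 h`), the clock anchors at registration, and the token and
company code survive so the same token can restart fresh.  All timestamps
are timezone-aware; transcript timestamps are forced strictly increasing.

Progress (the "how much of the iceberg is visible" fraction) is answered
items over items on the current path.  A conditional section counts in the
denominator until its branch rules definitively resolve to "excluded";
this keeps the fraction non-decreasing under forward moves (resolving the
sleep item to 0 shrinks the denominator, which can only raise the
fraction), reaches exactly 1.0 at completion, and lets only back-steps
lower it.

Encouragement messages are configurable (section, item-index) pairs; the
default script places one at the midpoint of every instrument with at
least nine items, plus per-section intros at section boundaries.

## Safety protocol

After each instrument completes, three triggers are evaluated: top-band
anxiety (severe, 15+), top-band depression (severe, 20+), and any non-zero
endorsement of the depression screener's self-harm item — the last fires
regardless of the total score.  Free text typed at any prompt is scanned
against a lexicon under case-folding and diacritic-stripping; the shipped
list is a small placeholder since any deployed list is configuration, and
event records carry only a hash of the text.  Self-harm and keyword events
are urgent (emergency-services message first, then care network);
top-band events are elevated (care network) unless co-occurring with a
self-harm event, which escalates them.  Simultaneous events merge into one
flow at the highest tier.  Risk handling never alters scores, and by
default the assessment resumes after the referral messages (a halt flag
exists): the pilot this models reported completed assessments from
high-scoring respondents.  "Moderately severe" depression does not trigger
by default; the trigger categories are configurable.

## Reporting

Campaign metrics use the standard survey definitions — initiation =
started/eligible, completion = completed/started, response =
completed/eligible — computed at full precision and rendered half-up, one
decimal for rates and whole percent for breakdown shares (the mixed
precision the pilot published).  Category distributions by reporting group
apply small-cell pooling with k = 8 by default: the smallest undersized
group merges into the smallest other group (ties broken by label order)
until every reported group has at least k members; a universal pool, or a
single leftover undersized group, is labelled "all".  Pooling is decided
once on completed-session head-counts and applied to every instrument, so
group identity cannot be narrowed by comparing instruments.  The
"symptomatic" breakdown excludes each instrument's lowest band —
an inference from the published denominators — except for burnout and job
stress, whose published distributions cover all respondents
(`baseline_label=None`).  The summary table reports n, mean, SD (n−1
denominator; flagged and zeroed at n = 1) and the category of the
half-up-rounded mean; the insomnia row counts only branch-triggered
sessions.

## Synthetic respondents

Each simulated employee has one latent severity per construct, drawn from
a multivariate normal with configurable per-construct location and spread
and a correlation matrix (validated PSD; singular matrices are allowed via
an eigenvalue square root, so perfect correlation works).  An item
response follows a graded-threshold (cumulative probit) model: keyed level
= interval of `latent + standard-normal noise` among m−1 equally spaced
cutpoints `spacing · (j − m/2)`; reverse-keyed items emit the mirrored raw
option value so scoring recovers the keyed level and expected totals are
monotone in severity.  Item noise is independent given the latent, so the
conditional total is an exact convolution and population band
probabilities are a Gauss–Hermite integral (81 nodes) over the latent —
`band_probabilities` is the closed-form counterpart the parameter-recovery
tests compare simulations against.  Responses are deterministic given
(profile seed, item id), via a per-item generator seeded by
`[seed, crc32(item id)]`.

Defaults are the pilot study's conditions.  The six latent locations were
moment-matched offline (root-finding on the analytic expected total at
spread 1.0) so the default population's expected instrument totals equal
the pilot cohort means — anxiety 6.21, depression 4.40, stress 11.09
(transformed), insomnia 9.26, burnout 27.68, work stress 32.38 — giving
locations (−0.889, −1.619, −1.044, −0.818, −1.150, −0.479).  Latent spread
is fixed at 1.0 (no individual-level data exists to fit it) and the
default correlation links only anxiety–depression and depression–insomnia
at 0.5.  Campaign behaviour is two Bernoulli mechanisms: start probability
98/120, and a memoryless per-prompt dropout hazard solved from the
geometric survival curve `(1 − h)^n = 77/98` with n the expected number of
question prompts (54 unconditional items plus 7 × the analytic
sleep-endorsement probability, ≈ 0.33 under the default depression
severity).  Abandoned sessions idle past the 24-hour boundary and expire.
The default reporting-group weights mirror the pilot site's
recycling/logistics/office head-counts (52/40/28), assigned by largest
remainder.

What the simulator does *not* emulate: real item-level dependence beyond a
single latent per construct (no method factors, no item-specific
difficulty), response styles (acquiescence, straight-lining), the true
in-flow location of dropout (only its aggregate rate), and demographics.
Passing tests therefore show internal consistency of the pipeline and
faithfulness to the published aggregates, not psychometric validity on
real respondents.

## Numerical choices

- Printed-rate rounding is decimal half-up (`round_half_up`), never
  banker's rounding.
- Band probabilities and expected totals use 81-node probabilists'
  Gauss–Hermite quadrature; zero spread degenerates to a single node.
- Greedy answer construction in tests fills keyed contributions
  front-to-back, which reaches every achievable total exactly because
  option values are contiguous.
- Pooling ties break by label sort order, making reports reproducible.
- Session stores reserve the filename `stats.json` for campaign metadata.

## Problem sizes

The test suite exercises the scoring oracle at 1,000 random vectors per
instrument, branch soundness over 500 fully simulated sessions, the
pooling guarantee exhaustively over all partitions of n ≤ 20 into ≤ 4
groups, and simulator parameter recovery at 10,000 respondents against the
analytic band probabilities (within 3 Monte-Carlo standard errors).  The
acceptance script replays the engineered 120/98/77 campaign store, the
77-respondent category-count cohort, and 40 replicated synthetic campaigns
of 120 employees.

## Known limitations

- The engine forces complete data (no skips), so denominators that differ
  across instruments in real deployments (e.g. a 74 vs 77 discrepancy)
  cannot arise internally; reports over subsets must be taken explicitly.
- Free-text handling is a keyword scan, not natural-language
  understanding.
- The interactive CLI is a development harness, not a production chat
  transport; messaging-platform delivery, avatars and the iceberg
  rendering are out of scope.
- Published subscale thresholds for the job-stress short form do not
  exist; subscale categories appear only if a script configures bands.
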