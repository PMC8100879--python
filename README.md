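# checkup

A scripted, chatbot-style **workplace mental-health checkup engine**: six
standardized screening instruments delivered as a branching conversation,
with exact scoring and severity categorization, a safety protocol, a
24-hour session reset, anonymized organization-level reporting with
small-cell pooling, and a synthetic-respondent simulator so the entire
pipeline can be exercised without any real respondent data.

It is aimed at teams building or studying conversational survey tools for
occupational mental-health screening: the deliverable is a library (plus a
thin CLI) that makes the *logic* of such a deployment — scoring rules,
branch rules, risk routing, anonymization — explicit, testable and
reproducible.

## What it implements

**Instruments.** GAD-7 (anxiety, 7 items, 0–21), PHQ-9 (depression,
9 items, 0–27, item 9 probes self-harm ideation), the DASS-21 stress
subscale (7 items, total doubled to 0–42), the Insomnia Severity Index
(7 items, 0–28), the Oldenburg Burnout Inventory (16 items over
exhaustion/disengagement, mixed keying) and a 15-item
demand–control–support job-stress short form.  Scoring is a reverse-keyed
sum `∑ᵢ kᵢ(xᵢ)` with `kᵢ(x) = min+max−x` for reverse-keyed items, an
instrument-level transform, and severity bands that partition every
achievable total (e.g. GAD-7: none 0–4, mild 5–9, moderate 10–14,
severe 15+).

**Conversation.** A deterministic state machine walks ordered story
sections (stress → anxiety → depression → insomnia* → burnout →
work-related stress), one question at a time, no skips, single-step
back-navigation, encouragement messages at configured positions, and a
progress fraction.  *Insomnia is conditional: included iff the PHQ-9
sleep item is endorsed above "not at all".  Sessions idle for more than
24 h expire and their answers are erased.

**Safety.** Top-band anxiety/depression, any endorsement of the PHQ-9
self-harm item, and free-text keyword matches (case- and
diacritic-insensitive) trigger referral flows — emergency services first
for urgent tiers, care network otherwise — without ever altering scores.

**Reporting.** Initiation/completion/response rates; per-group category
distributions with k-anonymity pooling (groups < k merged, k = 8 by
default); symptomatic breakdowns (shares above the no-symptom band); a
per-instrument summary table with the category of the mean.

**Simulation.** Respondents carry correlated latent severities; item
responses follow a graded-threshold (cumulative probit) model whose band
probabilities also exist in closed form, so simulations are checked
against exact analytics.  Campaign behaviour (start probability,
memoryless per-prompt dropout) is calibrated to a published pilot's
engagement figures.

## Worked example

Score a PHQ-9 answer vector:

```python
>>> from checkup import default_instruments, score_instrument
>>> phq9 = default_instruments()["phq9"]
>>> result = score_instrument(phq9, [1, 2, 2, 1, 0, 1, 2, 0, 1])
>>> result.transformed_total, result.category
(10, 'moderate')
```

A total of 10 falls in the moderate band (10–14); item 3 (sleep) answered
2 would route this respondent to the insomnia section, and item 9
answered 1 raises an urgent risk event even though the total is modest.

Simulate a campaign of 120 employees and report on it:

```bash
$ checkup simulate --seed 11 --out demo/store
wrote 93 sessions (70 completed) to demo/store
$ checkup stats --store demo/store --eligible-n 120
eligible_n: 120
started_n: 93
completed_n: 70
initiation_rate: 77.5
completion_rate: 75.3
response_rate: 58.3
$ checkup report --store demo/store --eligible-n 120 --out demo/report
report written to demo/report
```

Here 93 of 120 invited employees started (77.5% initiation), 70 finished
(75.3% completion), so responses cover 58.3% of the workforce — single
draws scatter around the calibrated targets (81.7%, ≈78.6%, 64.2%).  The
report directory contains `distributions.csv` (instrument × pooled group
× category counts), `summary_table.csv` and `summary.json`; with the
default three-site population no group is below k = 8, so no pooling is
needed.  The first lines of `summary_table.csv` from the run above:

```
measure,n,mean,sd,category,sd_degenerate
gad7,70,5.657...,4.705...,mild,False
phq9,70,4.457...,4.113...,none,False
dass21_stress,70,11.171...,9.871...,normal,False
isi,22,11.909...,6.293...,subthreshold,False
```

The `isi` row counts only the 22 completers routed to the insomnia
section.  `checkup run --store ... --code ...` runs an interactive
checkup in the terminal, and `checkup validate-script --script ...`
checks a script file (the bundled default lives at
`src/checkup/data/default_checkup.yaml`).

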