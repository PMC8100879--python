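"""Feedback, campaign rates, pooling, breakdowns and the summary table."""

from __future__ import annotations

from datetime import timedelta

import pytest

from checkup import (
    CampaignStats,
    ConfigError,
    FeedbackTemplates,
    aggregate_distributions,
    campaign_stats,
    check_expiry,
    personal_feedback,
    pool_groups,
    round_half_up,
    score_instrument,
    session_scores,
    start_session,
    submit_answer,
    summary_table,
    symptomatic_breakdown,
)
from checkup.instruments import default_instruments
from checkup.persistence import _CARE_NOTE

from conftest import T0, answers_for_total, run_scripted_session

INSTRUMENTS = default_instruments()


def _cohort(script, totals_list, **kwargs):
    """Completed sessions with the given per-instrument transformed totals."""
    sessions = []
    for r, totals in enumerate(totals_list):
        vectors = {
            iid: answers_for_total(INSTRUMENTS[iid], t)
            for iid, t in totals.items()
        }
        for ins in script.instruments:
            vectors.setdefault(
                ins.id, [item.min_value for item in ins.items]
            )
        if "phq9" not in totals:
            vectors["phq9"] = answers_for_total(
                INSTRUMENTS["phq9"], 0, overrides={"phq9_3": 0}
            )
        sessions.append(
            run_scripted_session(
                script, vectors, token=f"c{r:03d}",
                group=kwargs.get("group_of", lambda i: "all")(r),
            )
        )
    return sessions


# ---------------------------------------------------------------------------
# personal feedback
# ---------------------------------------------------------------------------

def test_feedback_has_block_per_instrument_plus_disclaimer(script):
    vectors = {
        ins.id: [item.min_value for item in ins.items]
        for ins in script.instruments
    }
    session = run_scripted_session(script, vectors)
    results = session_scores(script, session)
    messages = personal_feedback(results, script.feedback, script)
    assert len(messages) == len(results) + 1
    assert messages[-1] == script.feedback.disclaimer
    assert "'normal'" in messages[0]  # stress section comes first


def test_severe_depression_feedback_includes_care_recommendation(script):
    result = score_instrument(
        INSTRUMENTS["phq9"], answers_for_total(INSTRUMENTS["phq9"], 21)
    )
    messages = personal_feedback({"phq9": result}, script.feedback, script)
    assert any(_CARE_NOTE.strip() in m for m in messages)


def test_missing_template_without_default_is_config_error(script):
    templates = FeedbackTemplates(per_instrument={"gad7": {"none": "ok"}})
    result = score_instrument(INSTRUMENTS["gad7"], [1, 1, 1, 1, 1, 0, 0])
    with pytest.raises(ConfigError):
        personal_feedback({"gad7": result}, templates)


def test_template_coverage_checked_at_script_validation(script):
    broken = script.model_copy(deep=True)
    broken.feedback = FeedbackTemplates(per_instrument={})
    assert any("feedback template" in v.message
               for v in broken.validate_script())


# ---------------------------------------------------------------------------
# campaign stats
# ---------------------------------------------------------------------------

def test_pilot_campaign_rates_under_stated_rounding():
    stats = CampaignStats(eligible_n=120, started_n=98, completed_n=77)
    assert round_half_up(stats.initiation_rate, 1) == 81.7
    assert round_half_up(stats.response_rate, 1) == 64.2
    assert round_half_up(stats.completion_rate, 1) == 78.6
    assert round_half_up(stats.completion_rate) == 79.0


def test_rate_identity_response_equals_product():
    stats = CampaignStats(eligible_n=200, started_n=137, completed_n=91)
    assert stats.response_rate == pytest.approx(
        stats.initiation_rate * stats.completion_rate / 100.0
    )


def test_zero_started_gives_zero_rates():
    stats = CampaignStats(eligible_n=50, started_n=0, completed_n=0)
    assert stats.initiation_rate == 0.0
    assert stats.completion_rate == 0.0
    assert stats.response_rate == 0.0


def test_zero_eligible_is_undefined_rate_error():
    with pytest.raises(ConfigError):
        CampaignStats(eligible_n=0, started_n=0, completed_n=0)


def test_campaign_stats_counts_statuses(script):
    sessions = []
    for k in range(5):
        s = start_session(script, "ACME", True, T0, token=f"s{k}")
        submit_answer(s, script, 0, T0)
        sessions.append(s)
    done = _cohort(script, [{"gad7": 3}] * 2)
    check_expiry(sessions[0], T0 + timedelta(hours=25))
    stats = campaign_stats(10, sessions + done)
    assert (stats.started_n, stats.completed_n) == (7, 2)


# ---------------------------------------------------------------------------
# pooling
# ---------------------------------------------------------------------------

def test_groups_at_or_above_k_are_untouched():
    mapping = pool_groups({"a": 9, "b": 12}, k=8)
    assert mapping == {"a": "a", "b": "b"}


def test_small_group_merges_until_all_reported_groups_reach_k():
    mapping = pool_groups({"a": 5, "b": 9, "c": 12}, k=8)
    assert mapping["a"] == mapping["b"] == "a+b"
    assert mapping["c"] == "c"


def test_everything_below_k_collapses_to_all():
    mapping = pool_groups({"a": 3, "b": 4}, k=8)
    assert set(mapping.values()) == {"all"}


def test_single_undersized_group_reported_as_all():
    assert pool_groups({"only": 3}, k=8) == {"only": "all"}


def test_distributions_conserve_counts_and_hide_tokens(script, pilot_cohort):
    dists = aggregate_distributions(
        script, pilot_cohort, lambda s: s.group or "all", k=8
    )
    by_id = {d.instrument_id: d for d in dists}
    for iid, expected_n in [("gad7", 77), ("phq9", 77), ("dass21_stress", 77),
                            ("olbi", 77), ("jss", 77), ("isi", 34)]:
        assert by_id[iid].total() == expected_n
    tokens = {s.token for s in pilot_cohort}
    import json

    from checkup.persistence import distributions_frame

    serialized = distributions_frame(dists).to_csv(index=False) + json.dumps(
        [d.pooled_from for d in dists]
    )
    assert not any(token in serialized for token in tokens)


def test_distribution_groups_respect_k(script, pilot_cohort):
    dists = aggregate_distributions(
        script, pilot_cohort, lambda s: s.group or "all", k=30
    )
    sizes: dict[str, int] = {}
    for s in pilot_cohort:
        label = dists[0].pooled_from[s.group]
        sizes[label] = sizes.get(label, 0) + 1
    assert all(n >= 30 for n in sizes.values()) or len(sizes) == 1


def test_expired_sessions_never_reach_reports(script):
    s = start_session(script, "ACME", True, T0, token="gone")
    for _ in range(20):
        submit_answer(s, script, 1, T0)
    check_expiry(s, T0 + timedelta(hours=25))
    done = _cohort(script, [{"gad7": 3}] * 9)
    dists = aggregate_distributions(script, done + [s], lambda x: "all", k=1)
    assert all(d.total() <= 9 for d in dists)
    table = summary_table(script, done + [s])
    assert int(table.set_index("measure").loc["gad7", "n"]) == 9


# ---------------------------------------------------------------------------
# symptomatic breakdown
# ---------------------------------------------------------------------------

def test_breakdown_excludes_baseline_and_rounds_to_whole_percent(script):
    totals = [{"gad7": 2}] * 37 + [{"gad7": 6}] * 20 + [{"gad7": 12}] * 20
    sessions = _cohort(script, totals)
    b = symptomatic_breakdown(script, sessions, "gad7")
    assert b.baseline_label == "none"
    assert b.symptomatic_n == 40
    assert b.counts == {"mild": 20, "moderate": 20}
    assert b.percentages == {"mild": 50, "moderate": 50}


def test_breakdown_empty_when_everyone_is_baseline(script):
    sessions = _cohort(script, [{"gad7": 1}] * 5)
    b = symptomatic_breakdown(script, sessions, "gad7")
    assert b.symptomatic_n == 0
    assert b.counts == {} and b.percentages == {}


def test_breakdown_with_no_baseline_counts_everyone(script):
    sessions = _cohort(script, [{"olbi": 25}] * 6 + [{"olbi": 35}] * 4)
    b = symptomatic_breakdown(script, sessions, "olbi", baseline_label=None)
    assert b.symptomatic_n == 10
    assert b.percentages == {"low": 60, "high": 40}


# ---------------------------------------------------------------------------
# summary table
# ---------------------------------------------------------------------------

def test_single_session_sd_degenerate_flag(script):
    sessions = _cohort(script, [{"gad7": 6}])
    table = summary_table(script, sessions).set_index("measure")
    row = table.loc["gad7"]
    assert row["n"] == 1 and row["sd"] == 0.0 and bool(row["sd_degenerate"])


def test_uniform_cohort_mean_and_category(script):
    sessions = _cohort(script, [{"gad7": 6}] * 12)
    table = summary_table(script, sessions).set_index("measure")
    row = table.loc["gad7"]
    assert row["mean"] == pytest.approx(6.0)
    assert row["sd"] == pytest.approx(0.0)
    assert row["category"] == "mild"


def test_isi_row_counts_only_branch_triggered_sessions(script, pilot_cohort):
    table = summary_table(script, pilot_cohort).set_index("measure")
    assert int(table.loc["isi", "n"]) == 34
    assert int(table.loc["gad7", "n"]) == 77
    # subscale rows exist for the multidimensional instruments
    assert "jss:demand" in table.index and "olbi:exhaustion" in table.index
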