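import datetime as dt

import pytest

from conftest import REG, make_history, make_version
from retroregistry.changes import (
    ChangeTiming,
    decisive_flip,
    displacement_summary,
    extract_changes,
    launch_to_followup_delta,
    time_relative_to_completion,
)
from retroregistry.classify import AuditConfig, Category, classify_trial
from retroregistry.model import CompletionType, OverallStatus, PartialDate
from retroregistry.synth import CohortSpec, generate_stochastic


def test_single_change_with_day_precision_delta(config):
    h = make_history(
        [
            make_version(1, 2, start="2015-01-15"),
            make_version(2, 100, start="2015-01-15"),
            make_version(3, 300, start="2015-06-01"),
        ]
    )
    events = extract_changes(h, config)
    assert len(events) == 1
    assert events[0].version_number == 3
    assert events[0].delta_days == 137  # 2015-01-15 -> 2015-06-01


def test_constant_start_date_yields_no_events(config):
    h = make_history([make_version(i + 1, 2 + 50 * i, start="2015-02-01") for i in range(5)])
    assert extract_changes(h, config) == []


def test_month_precision_delta_anchors_to_first_of_month(config):
    h = make_history(
        [make_version(1, 2, start="2015-01"), make_version(2, 100, start="2015-03")]
    )
    (event,) = extract_changes(h, config)
    assert event.delta_days == 59  # Jan 1 -> Mar 1, 2015


def test_missing_start_dates_are_skipped_and_comparison_resumes(config):
    h = make_history(
        [
            make_version(1, 2, start="2015-01-15"),
            make_version(2, 100, start=None),
            make_version(3, 300, start="2015-06-01"),
        ]
    )
    (event,) = extract_changes(h, config)
    assert event.version_number == 3
    assert event.from_date == PartialDate(2015, 1, 15)


def test_events_reconstruct_the_start_date_sequence(config):
    histories, _ = generate_stochastic(CohortSpec(n_trials=60, seed=9))
    for h in histories:
        starts = [v.start_date for v in h.versions if v.start_date is not None]
        events = extract_changes(h, config)
        rebuilt = [starts[0]]
        for event in events:
            assert event.from_date == rebuilt[-1]
            rebuilt.append(event.to_date)
        # distinct consecutive values must match the rebuilt chain
        collapsed = [starts[0]]
        for s in starts[1:]:
            if s != collapsed[-1]:
                collapsed.append(s)
        assert rebuilt == collapsed


def test_delta_sum_equals_launch_to_followup_displacement(config):
    histories, _ = generate_stochastic(CohortSpec(n_trials=60, seed=13))
    for h in histories:
        events = extract_changes(h, config)
        total = sum(e.delta_days for e in events)
        assert total == launch_to_followup_delta(h, config)


def _flip_history(assessment_pattern, reg=REG):
    """Build a history whose per-version verdicts follow the given R/P string."""
    retro = "2014-11-01"
    prosp = "2015-02-01"
    versions = []
    for i, char in enumerate(assessment_pattern):
        versions.append(
            make_version(
                i + 1,
                2 + 60 * i,
                OverallStatus.COMPLETED if i == len(assessment_pattern) - 1
                else OverallStatus.RECRUITING,
                start=retro if char == "R" else prosp,
            )
        )
    return make_history(versions, reg=reg)


def test_decisive_flip_is_the_lasting_flip_under_oscillation(config):
    h = _flip_history("RRPRPP")
    classification = classify_trial(h, config)
    assert classification.category is Category.RETROACTIVELY_PROSPECTIVE
    assert decisive_flip(h, classification, config).version_number == 5


def test_decisive_flip_simple_two_version_case(config):
    h = _flip_history("RP")
    flip = decisive_flip(h, classify_trial(h, config), config)
    assert flip.version_number == 2


def test_decisive_flip_rejects_non_flipping_trials(config):
    h = _flip_history("RR")
    with pytest.raises(ValueError, match="retroactively"):
        decisive_flip(h, classify_trial(h, config), config)


def test_change_after_actual_completion_is_post_completion(config):
    h = make_history(
        [
            make_version(1, 2, start="2014-11-01"),
            make_version(2, 1300, OverallStatus.COMPLETED, start="2014-11-01",
                         completion="2018-12-31"),
            make_version(3, 1511, OverallStatus.COMPLETED, start="2015-02-01",
                         completion="2018-12-31"),  # posted 2019-03-01
        ]
    )
    (event,) = extract_changes(h, config)
    assert event.version_date == dt.date(2019, 3, 1)
    assert event.timing is ChangeTiming.POST_COMPLETION
    assert time_relative_to_completion(event, h, config) is ChangeTiming.POST_COMPLETION


def test_change_before_anticipated_completion_is_pre_completion(config):
    h = make_history(
        [
            make_version(1, 2, start="2014-11-01", completion="2018-12-31",
                         completion_type=CompletionType.ANTICIPATED),
            make_version(2, 720, start="2015-02-01", completion="2018-12-31",
                         completion_type=CompletionType.ANTICIPATED),
        ]
    )
    (event,) = extract_changes(h, config)
    assert event.timing is ChangeTiming.PRE_COMPLETION


def test_timing_undetermined_without_any_completion_date(config):
    h = make_history(
        [make_version(1, 2, start="2014-11-01"), make_version(2, 720, start="2015-02-01")]
    )
    (event,) = extract_changes(h, config)
    assert event.timing is ChangeTiming.UNDETERMINED


def test_month_precision_completion_compares_at_month_level(config):
    # change posted 2016-12-20, completion known only as 2016-12: same month,
    # hence not strictly later -> pre-completion
    h = make_history(
        [
            make_version(1, 2, start="2014-11-01", completion="2016-12",
                         completion_type=CompletionType.ACTUAL),
            make_version(2, 710, OverallStatus.COMPLETED, start="2015-02-01",
                         completion="2016-12", completion_type=CompletionType.ACTUAL),
        ]
    )
    (event,) = extract_changes(h, config)
    assert event.version_date == dt.date(2016, 12, 20)
    assert event.timing is ChangeTiming.PRE_COMPLETION


def test_post_completion_fraction_invariant_under_noop_versions(config):
    histories, _ = generate_stochastic(CohortSpec(n_trials=80, seed=21))

    def post_fraction(cohort):
        n_post = n_events = 0
        for h in cohort:
            for e in extract_changes(h, config):
                n_events += 1
                n_post += e.timing is ChangeTiming.POST_COMPLETION
        return n_post, n_events

    import dataclasses

    padded = []
    for h in histories:
        last = h.versions[-1]
        noop = dataclasses.replace(
            last,
            version_number=last.version_number + 1,
            version_date=last.version_date + dt.timedelta(days=1),
        )
        padded.append(
            dataclasses.replace(h, versions=h.versions + (noop,))
            if noop.version_date <= h.registration_date + dt.timedelta(days=1800)
            else h
        )
    assert post_fraction(histories) == post_fraction(padded)


def test_displacement_summary_examples(config):
    def trial(tid, start0, start1):
        return make_history(
            [
                make_version(1, 2, start=start0),
                make_version(2, 700, OverallStatus.COMPLETED, start=start1),
            ],
            trial_id=tid,
        )

    histories = [
        trial("NCT00000001", "2015-02-01", "2015-02-01"),
        trial("NCT00000002", "2015-02-01", "2015-03-02"),
        trial("NCT00000003", "2015-02-01", "2015-03-02"),
    ]
    classifications = {h.trial_id: classify_trial(h, config) for h in histories}
    summary = displacement_summary(histories, classifications, config)
    assert summary.n_trials_with_change == 2
    assert summary.n_total == 3
    assert summary.median_delta_days == 29.0

    symmetric = [
        trial("NCT00000001", "2015-02-11", "2015-02-21"),
        trial("NCT00000002", "2015-02-11", "2015-02-01"),
    ]
    classifications = {h.trial_id: classify_trial(h, config) for h in symmetric}
    summary = displacement_summary(symmetric, classifications, config)
    assert summary.n_trials_with_change == 2
    assert summary.mean_delta_days == 0.0
    assert summary.median_delta_days == 0.0


def test_displacement_summary_empty_subset_flagged(config):
    summary = displacement_summary([], {}, config)
    assert summary.n_trials_with_change == 0
    assert summary.median_delta_days is None
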