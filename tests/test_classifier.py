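import dataclasses
import datetime as dt

import pytest
from hypothesis import given
from hypothesis import strategies as st

from retroregistry.classify import (
    AuditConfig,
    Category,
    RegistrationStatus,
    assign_subgroups,
    classify_trial,
    compare_registration,
    filter_eligible,
    find_followup_version,
    find_launch_version,
    followup_cutoff,
)
from retroregistry.model import OverallStatus, PartialDate, TrialHistory
from retroregistry.synth import CohortSpec, generate_stochastic

from conftest import REG, make_history, make_version

P = RegistrationStatus.PROSPECTIVE
R = RegistrationStatus.RETROSPECTIVE


@pytest.mark.parametrize(
    "start, reg, grace, expected",
    [
        # day precision: one day late is retrospective, equality prospective
        (PartialDate(2014, 12, 1), dt.date(2015, 1, 10), 0, R),
        (PartialDate(2015, 1, 10), dt.date(2015, 1, 10), 0, P),
        (PartialDate(2015, 1, 9), dt.date(2015, 1, 10), 0, R),
        # month precision: both sides truncated to (year, month)
        (PartialDate(2015, 1), dt.date(2015, 1, 28), 0, P),
        (PartialDate(2014, 12), dt.date(2015, 1, 2), 0, R),
        # grace period shifts the registration reference back
        (PartialDate(2015, 1, 5), dt.date(2015, 1, 20), 21, P),
        (PartialDate(2015, 1, 5), dt.date(2015, 1, 20), 0, R),
        (PartialDate(2014, 12), dt.date(2015, 1, 10), 21, P),
    ],
)
def test_compare_registration(start, reg, grace, expected):
    assert compare_registration(start, reg, grace) is expected


@given(
    start=st.dates(dt.date(2013, 1, 1), dt.date(2017, 12, 31)),
    reg=st.dates(dt.date(2015, 1, 1), dt.date(2015, 12, 31)),
    month_only=st.booleans(),
    grace_small=st.integers(0, 60),
    grace_extra=st.integers(0, 60),
)
def test_grace_monotonicity(start, reg, month_only, grace_small, grace_extra):
    """Enlarging the grace period never turns prospective into retrospective."""
    pdate = PartialDate(start.year, start.month) if month_only else PartialDate.from_date(start)
    narrow = compare_registration(pdate, reg, grace_small)
    wide = compare_registration(pdate, reg, grace_small + grace_extra)
    assert not (narrow is P and wide is R)


@given(
    day=st.integers(1, 28),
    reg=st.dates(dt.date(2015, 2, 1), dt.date(2015, 12, 31)),
)
def test_month_retrospective_implies_day_retrospective_for_later_month_registration(day, reg):
    """If the month-level verdict is retrospective against a registration in a
    later month, every day-level refinement within that month agrees."""
    month_start = PartialDate(2015, 1)
    if compare_registration(month_start, reg, 0) is R:
        assert compare_registration(PartialDate(2015, 1, day), reg, 0) is R


def test_launch_version_is_first_with_launched_status(config):
    h = make_history(
        [
            make_version(1, 2, OverallStatus.NOT_YET_RECRUITING, start="2015-03-01"),
            make_version(2, 40, OverallStatus.RECRUITING, start="2015-03-01"),
            make_version(3, 400, OverallStatus.COMPLETED, start="2015-03-01"),
        ]
    )
    assert find_launch_version(h, config).version_number == 2


def test_launch_version_can_be_first_and_can_be_absent(config):
    launched = make_history([make_version(1, 2, OverallStatus.RECRUITING, start="2015-03-01")])
    assert find_launch_version(launched, config).version_number == 1
    never = make_history(
        [
            make_version(1, 2, OverallStatus.NOT_YET_RECRUITING),
            make_version(2, 40, OverallStatus.WITHDRAWN),
        ]
    )
    assert find_launch_version(never, config) is None


def test_followup_version_latest_within_five_years(config):
    h = make_history(
        [
            make_version(1, 2, start="2015-03-01"),
            make_version(2, 842, start="2015-03-01"),
            make_version(3, 1825, start="2015-03-01"),  # 2020-01-09
            make_version(4, 1970, start="2015-03-01"),  # past the window
        ]
    )
    assert find_followup_version(h, config).version_number == 3


def test_followup_boundary_date_inclusive(config):
    # REG is 2015-01-10; the five-year anniversary 2020-01-10 is in-window
    anniversary = (dt.date(2020, 1, 10) - REG).days
    h = make_history([make_version(1, 2, start="2015-03-01"),
                      make_version(2, anniversary, start="2015-03-01")])
    assert find_followup_version(h, config).version_number == 2


def test_leap_day_anniversary_maps_to_feb_28():
    assert followup_cutoff(dt.date(2016, 2, 29), 5) == dt.date(2021, 2, 28)


def test_retroactively_prospective_classification(config):
    h = make_history(
        [
            make_version(1, 2, start="2014-11-01"),
            make_version(2, 700, OverallStatus.COMPLETED, start="2015-02-01",
                         completion="2016-10-01"),
        ]
    )
    c = classify_trial(h, config)
    assert c.launch.status is R
    assert c.followup.status is P
    assert c.category is Category.RETROACTIVELY_PROSPECTIVE


def test_retroactively_retrospective_and_stable_categories(config):
    flip_back = make_history(
        [
            make_version(1, 2, start="2015-02-01"),
            make_version(2, 700, OverallStatus.COMPLETED, start="2014-11-01"),
        ]
    )
    assert classify_trial(flip_back, config).category is Category.RETROACTIVELY_RETROSPECTIVE
    stable = make_history(
        [
            make_version(1, 2, start="2015-02-01"),
            make_version(2, 700, OverallStatus.COMPLETED, start="2015-02-01"),
        ]
    )
    assert classify_trial(stable, config).category is Category.STABLE_PROSPECTIVE


def test_missing_start_date_yields_unclassifiable_not_imputed(config):
    h = make_history(
        [
            make_version(1, 2, start=None),
            make_version(2, 700, OverallStatus.COMPLETED, start="2015-02-01"),
        ]
    )
    c = classify_trial(h, config)
    assert c.launch.status is RegistrationStatus.UNDETERMINED
    assert c.category is Category.UNCLASSIFIABLE


def test_duplicating_a_version_never_changes_the_category(config):
    histories, _ = generate_stochastic(CohortSpec(n_trials=30, seed=11))
    for h in histories:
        base = classify_trial(h, config).category
        last = h.versions[-1]
        dup = dataclasses.replace(last, version_number=last.version_number + 1)
        extended = TrialHistory(h.trial_id, h.registration_date, h.versions + (dup,))
        assert classify_trial(extended, config).category is base


@pytest.mark.parametrize(
    "label, expected",
    [
        ("Phase 1", "PHASE1"),
        ("Early Phase 1", "PHASE1"),
        ("Phase 1 | Phase 2", "PHASE1"),
        ("Phase 2", "PHASE2PLUS"),
        ("Phase 3", "PHASE2PLUS"),
        ("Phase 4", "PHASE2PLUS"),
        ("N/A", "UNREPORTED"),
        ("", "UNREPORTED"),
    ],
)
def test_phase_grouping(label, expected, config):
    h = make_history([make_version(1, 2, start="2015-02-01", phase_label=label)])
    assert assign_subgroups(h, config).phase_group.value == expected


def test_field_tagging_by_condition_keywords(config):
    h = make_history(
        [make_version(1, 2, start="2015-02-01",
                      conditions=("Breast Carcinoma", "Chronic Pain"))]
    )
    labels = assign_subgroups(h, config, keyword_map={"CANCER": ("carcinoma",),
                                                      "PAIN": ("pain",),
                                                      "NEUROLOGICAL": ("parkinson",)})
    assert labels.fields == frozenset({"CANCER", "PAIN"})


def test_eligibility_requires_completion_and_registration_window(audit_2015_config):
    completed = make_history(
        [make_version(1, 2, start="2015-02-01"),
         make_version(2, 700, OverallStatus.COMPLETED, start="2015-02-01")]
    )
    recruiting = make_history(
        [make_version(1, 2, OverallStatus.RECRUITING, start="2015-02-01")],
        trial_id="NCT01234568",
    )
    out_of_window = make_history(
        [make_version(1, 2, OverallStatus.COMPLETED, start="2016-03-01",
                      reg=dt.date(2016, 2, 1))],
        trial_id="NCT01234569",
        reg=dt.date(2016, 2, 1),
    )
    eligible, excluded = filter_eligible(
        [completed, recruiting, out_of_window], audit_2015_config
    )
    assert [h.trial_id for h in eligible] == ["NCT01234567"]
    reasons = dict(excluded)
    assert "status" in reasons["NCT01234568"]
    assert "window" in reasons["NCT01234569"]


def test_categories_partition_the_cohort(config):
    histories, _ = generate_stochastic(CohortSpec(n_trials=300, seed=5))
    classifications = [classify_trial(h, config) for h in histories]
    counts = {cat: 0 for cat in Category}
    for c in classifications:
        counts[c.category] += 1
    assert sum(counts.values()) == len(histories)


# ---------------------------------------------------------------------------
# Brute-force oracle
# ---------------------------------------------------------------------------

LAUNCHED = {
    OverallStatus.RECRUITING,
    OverallStatus.ENROLLING_BY_INVITATION,
    OverallStatus.ACTIVE_NOT_RECRUITING,
    OverallStatus.COMPLETED,
    OverallStatus.TERMINATED,
}


def _brute_force_category(history, followup_years=5, grace=0):
    """Independent re-derivation scanning the raw version list."""
    reg = history.registration_date
    try:
        cutoff = reg.replace(year=reg.year + followup_years)
    except ValueError:  # Feb 29 anchor
        cutoff = reg.replace(year=reg.year + followup_years, day=28)
    window = [v for v in history.versions if v.version_date <= cutoff]

    def verdict(version):
        if version is None or version.start_date is None:
            return None
        s = version.start_date
        ref = reg - dt.timedelta(days=grace)
        if s.day is not None:
            prospective = dt.date(s.year, s.month, s.day) >= ref
        else:
            prospective = (s.year, s.month) >= (ref.year, ref.month)
        return "P" if prospective else "R"

    launch = next((v for v in window if v.overall_status in LAUNCHED), None)
    followup = window[-1] if window else None
    pair = (verdict(launch), verdict(followup))
    return {
        ("R", "P"): Category.RETROACTIVELY_PROSPECTIVE,
        ("P", "R"): Category.RETROACTIVELY_RETROSPECTIVE,
        ("P", "P"): Category.STABLE_PROSPECTIVE,
        ("R", "R"): Category.STABLE_RETROSPECTIVE,
    }.get(pair, Category.UNCLASSIFIABLE)


def test_classifier_agrees_with_brute_force_on_small_cohorts(config):
    histories, _ = generate_stochastic(
        CohortSpec(n_trials=50, seed=23, month_precision_probability=0.5)
    )
    for h in histories:
        assert classify_trial(h, config).category is _brute_force_category(h)
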