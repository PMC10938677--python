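import datetime as dt

import pytest
from hypothesis import settings

from retroregistry.classify import AuditConfig
from retroregistry.model import (
    CompletionType,
    OverallStatus,
    PartialDate,
    SponsorClass,
    TrialHistory,
    VersionRecord,
)
from retroregistry.synth import CompositionSpec

settings.register_profile("ci", deadline=None, derandomize=True)
settings.load_profile("ci")

REG = dt.date(2015, 1, 10)


def make_version(
    number,
    offset_days,
    status=OverallStatus.RECRUITING,
    start=None,
    completion=None,
    completion_type=None,
    reg=REG,
    **kwargs,
):
    """Terse version builder: offsets are days after the registration date,
    start/completion accept ISO partial-date strings."""
    from retroregistry.model import parse_partial_date

    if isinstance(start, str):
        start = parse_partial_date(start)
    if isinstance(completion, str):
        completion = parse_partial_date(completion)
    if completion is not None and completion_type is None:
        completion_type = CompletionType.ACTUAL
    return VersionRecord(
        version_number=number,
        version_date=reg + dt.timedelta(days=offset_days),
        overall_status=status,
        start_date=start,
        completion_date=completion,
        completion_type=completion_type,
        phase_label=kwargs.pop("phase_label", "Phase 2"),
        sponsor_class=kwargs.pop("sponsor_class", SponsorClass.OTHER),
        conditions=tuple(kwargs.pop("conditions", ())),
        **kwargs,
    )


def make_history(versions, trial_id="NCT01234567", reg=REG):
    return TrialHistory(trial_id=trial_id, registration_date=reg, versions=tuple(versions))


@pytest.fixture
def config():
    return AuditConfig()


@pytest.fixture
def small_composition():
    """A consistent small composition exercising every fixture template."""
    return CompositionSpec(
        n_total=120,
        n_originally_retrospective=60,
        n_retroactively_prospective=10,
        n_retroactively_prospective_post_completion=7,
        n_originally_retrospective_with_change=30,
        n_control_latest_change_post_completion=8,
        n_phase1_total=20,
        n_phase1_retroactively_prospective=4,
        n_published_retroactively_prospective=6,
        n_published_claims_prospective=2,
        n_published_flips_concordant=1,
        n_published_controls=5,
        n_published_controls_concordant=3,
    )


@pytest.fixture
def audit_2015_config():
    return AuditConfig(
        registration_year_window=(dt.date(2015, 1, 1), dt.date(2015, 12, 31))
    )
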