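"""Registration-status classification at launch and at follow-up.

A trial is *prospectively* registered when its start date is equal to or
after the date the registration was submitted, and *retrospectively*
registered otherwise.  Because the registry reports some start dates only to
the month, the comparison is performed at the precision of the start date:
day-precision starts compare exact dates, month-precision starts compare
``(year, month)`` pairs for both sides.  Equality counts as prospective in
both modes.

Each trial is assessed twice — at *launch* (the first archived version in
which the overall status shows recruitment has begun or the trial is past
recruitment) and at *follow-up* (the latest archived version within the
follow-up window, five years by default) — and the pair of assessments
yields one of four determinate categories or UNCLASSIFIABLE.
"""

from __future__ import annotations

import dataclasses
import datetime as dt
import enum
from importlib import resources
from typing import Iterable, Mapping

import yaml
from dateutil.relativedelta import relativedelta

from .model import (
    OverallStatus,
    PartialDate,
    PhaseGroup,
    Precision,
    SponsorClass,
    SubgroupLabels,
    TrialHistory,
    VersionRecord,
)


class RegistrationStatus(enum.Enum):
    PROSPECTIVE = "PROSPECTIVE"
    RETROSPECTIVE = "RETROSPECTIVE"
    UNDETERMINED = "UNDETERMINED"


class Category(enum.Enum):
    RETROACTIVELY_PROSPECTIVE = "RETROACTIVELY_PROSPECTIVE"
    RETROACTIVELY_RETROSPECTIVE = "RETROACTIVELY_RETROSPECTIVE"
    STABLE_PROSPECTIVE = "STABLE_PROSPECTIVE"
    STABLE_RETROSPECTIVE = "STABLE_RETROSPECTIVE"
    UNCLASSIFIABLE = "UNCLASSIFIABLE"


#: Statuses indicating the trial has launched (recruitment begun or past).
DEFAULT_LAUNCH_STATUSES = frozenset(
    {
        OverallStatus.RECRUITING,
        OverallStatus.ENROLLING_BY_INVITATION,
        OverallStatus.ACTIVE_NOT_RECRUITING,
        OverallStatus.COMPLETED,
        OverallStatus.TERMINATED,
    }
)

ELIGIBLE_FINAL_STATUSES = frozenset({OverallStatus.COMPLETED, OverallStatus.TERMINATED})


@dataclasses.dataclass(frozen=True)
class AuditConfig:
    """Tunable parameters of the audit.

    followup_years
        Length of the follow-up window after registration; versions posted
        later are invisible to the audit.  Default 5.
    grace_days
        Days of allowance between trial start and registration submission
        within which registration still counts as timely (US law allows 21);
        default 0, i.e. a single day late is retrospective.
    launch_statuses
        Overall statuses that mark a version as "launched".
    registration_year_window
        Optional ``(first, last)`` registration dates for cohort eligibility.
    """

    followup_years: int = 5
    grace_days: int = 0
    launch_statuses: frozenset[OverallStatus] = DEFAULT_LAUNCH_STATUSES
    registration_year_window: tuple[dt.date, dt.date] | None = None
    field_keywords: Mapping[str, tuple[str, ...]] | None = None

    def __post_init__(self) -> None:
        if self.followup_years < 1:
            raise ValueError("followup_years must be >= 1")
        if self.grace_days < 0:
            raise ValueError("grace_days must be >= 0")
        if not self.launch_statuses:
            raise ValueError("launch_statuses must be non-empty")

    @classmethod
    def from_yaml(cls, path) -> "AuditConfig":
        with open(path, "r", encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
        kwargs: dict = {}
        if "followup_years" in raw:
            kwargs["followup_years"] = int(raw["followup_years"])
        if "grace_days" in raw:
            kwargs["grace_days"] = int(raw["grace_days"])
        if "launch_statuses" in raw:
            kwargs["launch_statuses"] = frozenset(
                OverallStatus(s) for s in raw["launch_statuses"]
            )
        if raw.get("registration_year_window"):
            lo, hi = raw["registration_year_window"]
            kwargs["registration_year_window"] = (
                dt.date.fromisoformat(str(lo)),
                dt.date.fromisoformat(str(hi)),
            )
        if raw.get("field_keyword_file"):
            kwargs["field_keywords"] = load_field_keywords(raw["field_keyword_file"])
        return cls(**kwargs)


def load_field_keywords(path=None) -> dict[str, tuple[str, ...]]:
    """Load the medical-field keyword map (field name -> lowercase substrings).

    Without a path, the packaged default list covering cancer, cardiovascular,
    neurological and pain indications is used.
    """
    if path is None:
        source = resources.files("retroregistry.data").joinpath("field_keywords.yaml")
        raw = yaml.safe_load(source.read_text(encoding="utf-8"))
    else:
        with open(path, "r", encoding="utf-8") as fh:
            raw = yaml.safe_load(fh)
    return {str(k).upper(): tuple(str(w).lower() for w in v) for k, v in raw.items()}


@dataclasses.dataclass(frozen=True)
class RegistrationStatusAssessment:
    status: RegistrationStatus
    basis_version_number: int | None = None
    start_date_used: PartialDate | None = None
    comparison_precision: Precision | None = None

    def __post_init__(self) -> None:
        if self.status is not RegistrationStatus.UNDETERMINED:
            if self.basis_version_number is None or self.start_date_used is None:
                raise ValueError("determinate assessment requires basis version and start date")


@dataclasses.dataclass(frozen=True)
class TrialClassification:
    trial_id: str
    launch: RegistrationStatusAssessment
    followup: RegistrationStatusAssessment
    category: Category
    subgroups: SubgroupLabels


def followup_cutoff(registration_date: dt.date, followup_years: int) -> dt.date:
    """Last version date inside the follow-up window (inclusive).

    Calendar-year addition; a Feb 29 registration anchors to Feb 28 in a
    non-leap target year.
    """
    return registration_date + relativedelta(years=followup_years)


def in_window_versions(history: TrialHistory, config: AuditConfig) -> list[VersionRecord]:
    cutoff = followup_cutoff(history.registration_date, config.followup_years)
    return [v for v in history.versions if v.version_date <= cutoff]


def compare_registration(
    start: PartialDate, registration: dt.date, grace_days: int = 0
) -> RegistrationStatus:
    """Prospective/retrospective comparison at the start date's precision.

    The grace period shifts the registration reference back ``grace_days``
    before comparing; with month precision both sides are truncated to
    ``(year, month)`` after the shift.  Equality is prospective.
    """
    reference = registration - dt.timedelta(days=grace_days)
    if start.precision is Precision.DAY:
        prospective = start.anchor() >= reference
    else:
        prospective = start.year_month() >= (reference.year, reference.month)
    return RegistrationStatus.PROSPECTIVE if prospective else RegistrationStatus.RETROSPECTIVE


def find_launch_version(history: TrialHistory, config: AuditConfig) -> VersionRecord | None:
    """Earliest in-window version whose status is in the launch set."""
    for v in in_window_versions(history, config):
        if v.overall_status in config.launch_statuses:
            return v
    return None


def find_followup_version(history: TrialHistory, config: AuditConfig) -> VersionRecord | None:
    """Latest version posted within the follow-up window (boundary inclusive)."""
    window = in_window_versions(history, config)
    return window[-1] if window else None


def _assess(version: VersionRecord | None, history: TrialHistory, config: AuditConfig):
    if version is None or version.start_date is None:
        return RegistrationStatusAssessment(RegistrationStatus.UNDETERMINED)
    status = compare_registration(
        version.start_date, history.registration_date, config.grace_days
    )
    return RegistrationStatusAssessment(
        status=status,
        basis_version_number=version.version_number,
        start_date_used=version.start_date,
        comparison_precision=version.start_date.precision,
    )


_CATEGORY_TABLE = {
    (RegistrationStatus.RETROSPECTIVE, RegistrationStatus.PROSPECTIVE):
        Category.RETROACTIVELY_PROSPECTIVE,
    (RegistrationStatus.PROSPECTIVE, RegistrationStatus.RETROSPECTIVE):
        Category.RETROACTIVELY_RETROSPECTIVE,
    (RegistrationStatus.PROSPECTIVE, RegistrationStatus.PROSPECTIVE):
        Category.STABLE_PROSPECTIVE,
    (RegistrationStatus.RETROSPECTIVE, RegistrationStatus.RETROSPECTIVE):
        Category.STABLE_RETROSPECTIVE,
}


def classify_trial(history: TrialHistory, config: AuditConfig) -> TrialClassification:
    """Assess registration status at launch and follow-up and derive the category.

    A missing launch version, or a missing start date at either decisive
    version, makes that assessment UNDETERMINED and the trial UNCLASSIFIABLE;
    start dates are never imputed from other versions.
    """
    launch = _assess(find_launch_version(history, config), history, config)
    followup = _assess(find_followup_version(history, config), history, config)
    category = _CATEGORY_TABLE.get((launch.status, followup.status), Category.UNCLASSIFIABLE)
    return TrialClassification(
        trial_id=history.trial_id,
        launch=launch,
        followup=followup,
        category=category,
        subgroups=assign_subgroups(history, config),
    )


_PHASE1_LABELS = {"early phase 1", "phase 1", "phase 1 | phase 2"}


def phase_group_from_label(label: str) -> PhaseGroup:
    norm = " ".join(label.strip().lower().split())
    if not norm or norm in {"n/a", "na", "not applicable"}:
        return PhaseGroup.UNREPORTED
    return PhaseGroup.PHASE1 if norm in _PHASE1_LABELS else PhaseGroup.PHASE2PLUS


def assign_subgroups(
    history: TrialHistory,
    config: AuditConfig,
    keyword_map: Mapping[str, tuple[str, ...]] | None = None,
) -> SubgroupLabels:
    """Phase/sponsor/field labels from the latest in-window version.

    Phase 1 covers "Early Phase 1", "Phase 1" and "Phase 1 | Phase 2"; all
    other reported phases fall in Phase 2 and later.  Field membership is a
    case-insensitive substring match of the keyword list against any
    condition string.
    """
    version = find_followup_version(history, config) or history.versions[-1]
    if keyword_map is None:
        keyword_map = config.field_keywords or load_field_keywords()
    conditions = " ; ".join(c.lower() for c in version.conditions)
    fields = frozenset(
        field
        for field, keywords in keyword_map.items()
        if any(kw in conditions for kw in keywords)
    )
    return SubgroupLabels(
        phase_group=phase_group_from_label(version.phase_label),
        sponsor_group=version.sponsor_class,
        fields=fields,
    )


def filter_eligible(
    histories: Iterable[TrialHistory], config: AuditConfig
) -> tuple[list[TrialHistory], list[tuple[str, str]]]:
    """Apply cohort eligibility: registration window and completion by follow-up.

    A trial is kept when its registration date falls inside the configured
    window (when one is set) and its follow-up version's overall status is
    COMPLETED or TERMINATED.  Returns the eligible list and an exclusion log
    of ``(trial_id, reason)`` pairs.
    """
    eligible: list[TrialHistory] = []
    excluded: list[tuple[str, str]] = []
    for history in histories:
        window = config.registration_year_window
        if window is not None and not (window[0] <= history.registration_date <= window[1]):
            excluded.append(
                (history.trial_id,
                 f"registration date {history.registration_date} outside window")
            )
            continue
        followup = find_followup_version(history, config)
        if followup is None:
            excluded.append((history.trial_id, "no version within follow-up window"))
            continue
        if followup.overall_status not in ELIGIBLE_FINAL_STATUSES:
            excluded.append(
                (history.trial_id,
                 f"not completed/terminated by follow-up "
                 f"(status {followup.overall_status.value})")
            )
            continue
        eligible.append(history)
    return eligible, excluded
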