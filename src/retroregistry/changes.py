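"""Start-date change events and their timing relative to trial completion.

A change event is one edit of the start date between consecutive archived
versions inside the follow-up window.  Versions without a start date are
skipped: the comparison resumes at the next version that carries one, so an
edit is still detected across a gap.  Day deltas anchor month-precision
dates to the first of the month, the only convention under which month-level
differences are well defined and order-preserving.

For retroactively prospective trials the *decisive flip* is the change at
the earliest version whose registration assessment is prospective and stays
prospective through every later in-window version — the lasting flip, not
the first transient one when the status oscillates.
"""

from __future__ import annotations

import dataclasses
import datetime as dt
import enum
import logging
import statistics
from typing import Iterable, Sequence

from .classify import (
    AuditConfig,
    Category,
    RegistrationStatus,
    TrialClassification,
    compare_registration,
    find_followup_version,
    find_launch_version,
    in_window_versions,
)
from .model import CompletionType, PartialDate, Precision, TrialHistory, VersionRecord

logger = logging.getLogger(__name__)


class ChangeTiming(enum.Enum):
    PRE_COMPLETION = "PRE_COMPLETION"
    POST_COMPLETION = "POST_COMPLETION"
    UNDETERMINED = "UNDETERMINED"


@dataclasses.dataclass(frozen=True)
class StartDateChange:
    """One start-date edit: the version that introduced the new value."""

    trial_id: str
    from_date: PartialDate
    to_date: PartialDate
    version_number: int
    version_date: dt.date
    delta_days: int
    timing: ChangeTiming = ChangeTiming.UNDETERMINED

    def __post_init__(self) -> None:
        if self.from_date == self.to_date:
            raise ValueError("change event requires from_date != to_date")


@dataclasses.dataclass(frozen=True)
class DisplacementSummary:
    """Launch-to-follow-up start-date displacement over a trial subset."""

    n_trials_with_change: int
    n_total: int
    median_delta_days: float | None
    mean_delta_days: float | None


def delta_days(from_date: PartialDate, to_date: PartialDate) -> int:
    return (to_date.anchor() - from_date.anchor()).days


def extract_changes(history: TrialHistory, config: AuditConfig) -> list[StartDateChange]:
    """All start-date edits between consecutive in-window versions."""
    events: list[StartDateChange] = []
    previous: PartialDate | None = None
    window = in_window_versions(history, config)
    for version in window:
        current = version.start_date
        if current is None:
            continue
        if previous is not None and current != previous:
            events.append(
                StartDateChange(
                    trial_id=history.trial_id,
                    from_date=previous,
                    to_date=current,
                    version_number=version.version_number,
                    version_date=version.version_date,
                    delta_days=delta_days(previous, current),
                    timing=_timing(version, window),
                )
            )
        previous = current
    return events


def _reference_completion(
    change_version: VersionRecord, window: Sequence[VersionRecord]
) -> PartialDate | None:
    """Completion date in force when the change was made.

    Uses only versions up to and including the change version (no
    look-ahead); an ACTUAL completion date is preferred over an ANTICIPATED
    one, and within each kind the latest reported value wins.
    """
    actual: PartialDate | None = None
    anticipated: PartialDate | None = None
    for v in window:
        if v.version_number > change_version.version_number:
            break
        if v.completion_date is None:
            continue
        if v.completion_type is CompletionType.ACTUAL:
            actual = v.completion_date
        else:
            anticipated = v.completion_date
    return actual if actual is not None else anticipated


def _timing(change_version: VersionRecord, window: Sequence[VersionRecord]) -> ChangeTiming:
    completion = _reference_completion(change_version, window)
    if completion is None:
        return ChangeTiming.UNDETERMINED
    when = change_version.version_date
    if completion.precision is Precision.MONTH:
        later = (when.year, when.month) > completion.year_month()
    else:
        later = when > completion.anchor()
    return ChangeTiming.POST_COMPLETION if later else ChangeTiming.PRE_COMPLETION


def time_relative_to_completion(
    change: StartDateChange, history: TrialHistory, config: AuditConfig | None = None
) -> ChangeTiming:
    """Timing of one change against the completion date known at change time.

    The comparison runs at the coarser of the two precisions; strictly later
    than completion counts as post-completion.
    """
    config = config or AuditConfig()
    window = in_window_versions(history, config)
    version = next((v for v in window if v.version_number == change.version_number), None)
    if version is None:
        raise ValueError(
            f"change at version {change.version_number} does not belong to "
            f"{history.trial_id}'s in-window history"
        )
    return _timing(version, window)


def per_version_assessments(
    history: TrialHistory, config: AuditConfig
) -> list[tuple[int, RegistrationStatus]]:
    """(version_number, prospective/retrospective) for every in-window version
    that carries a start date."""
    return [
        (
            v.version_number,
            compare_registration(v.start_date, history.registration_date, config.grace_days),
        )
        for v in in_window_versions(history, config)
        if v.start_date is not None
    ]


def decisive_flip(
    history: TrialHistory,
    classification: TrialClassification,
    config: AuditConfig,
    changes: Sequence[StartDateChange] | None = None,
) -> StartDateChange:
    """The change event that lastingly turned the trial prospective.

    Only defined for RETROACTIVELY_PROSPECTIVE trials; calling it on any
    other category is a contract violation.
    """
    if classification.category is not Category.RETROACTIVELY_PROSPECTIVE:
        raise ValueError(
            f"{history.trial_id}: decisive_flip requires a retroactively "
            f"prospective trial, got {classification.category.value}"
        )
    assessments = per_version_assessments(history, config)
    flip_version = None
    # walk backwards: the lasting run of PROSPECTIVE at the tail
    for number, status in reversed(assessments):
        if status is RegistrationStatus.PROSPECTIVE:
            flip_version = number
        else:
            break
    if flip_version == assessments[0][0]:
        raise ValueError(f"{history.trial_id}: no retrospective assessment precedes the flip")
    if any(s is RegistrationStatus.PROSPECTIVE for n, s in assessments if n < flip_version):
        logger.info("%s: assessment oscillated before the lasting flip", history.trial_id)
    if changes is None:
        changes = extract_changes(history, config)
    for event in changes:
        if event.version_number == flip_version:
            return event
    raise ValueError(
        f"{history.trial_id}: no change event at flip version {flip_version}"
    )


def launch_to_followup_delta(
    history: TrialHistory, config: AuditConfig
) -> int | None:
    """Follow-up start date minus launch start date, in days (month-precision
    values anchored to day 1); None when either start date is missing."""
    launch = find_launch_version(history, config)
    followup = find_followup_version(history, config)
    if (
        launch is None
        or followup is None
        or launch.start_date is None
        or followup.start_date is None
    ):
        return None
    return delta_days(launch.start_date, followup.start_date)


def displacement_summary(
    histories: Iterable[TrialHistory],
    classifications: dict[str, TrialClassification],
    config: AuditConfig,
    categories: set[Category] | None = None,
) -> DisplacementSummary:
    """Summary of nonzero launch-to-follow-up displacements over a subset.

    ``categories`` restricts the subset (None means every classified trial);
    the median and mean run over trials whose displacement is nonzero.
    """
    deltas: list[int] = []
    n_total = 0
    for history in histories:
        classification = classifications.get(history.trial_id)
        if classification is None:
            continue
        if categories is not None and classification.category not in categories:
            continue
        delta = launch_to_followup_delta(history, config)
        if delta is None:
            continue
        n_total += 1
        if delta != 0:
            deltas.append(delta)
    if deltas:
        return DisplacementSummary(
            n_trials_with_change=len(deltas),
            n_total=n_total,
            median_delta_days=float(statistics.median(deltas)),
            mean_delta_days=float(statistics.fmean(deltas)),
        )
    return DisplacementSummary(0, n_total, None, None)
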