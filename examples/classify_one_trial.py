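"""Classify a single trial history by hand.

Builds one registry history whose start date is edited after completion so
that the record flips from retrospective to prospective, then classifies it
and locates the decisive flip.
"""

import datetime as dt

from retroregistry import (
    AuditConfig,
    CompletionType,
    OverallStatus,
    PartialDate,
    TrialHistory,
    VersionRecord,
    classify_trial,
    decisive_flip,
)

reg = dt.date(2015, 1, 10)  # submission date of the registration


def version(number, offset_days, status, start, completion=None, ctype=None):
    return VersionRecord(
        version_number=number,
        version_date=reg + dt.timedelta(days=offset_days),
        overall_status=status,
        start_date=start,
        completion_date=completion,
        completion_type=ctype,
        phase_label="Phase 2",
    )


history = TrialHistory(
    trial_id="NCT01234567",
    registration_date=reg,
    versions=(
        # registered two months after the trial started: retrospective
        version(1, 3, OverallStatus.RECRUITING, PartialDate(2014, 11, 1)),
        version(2, 500, OverallStatus.COMPLETED, PartialDate(2014, 11, 1),
                PartialDate.from_date(reg + dt.timedelta(days=450)),
                CompletionType.ACTUAL),
        # after completion, the start date is pushed past the registration date
        version(3, 700, OverallStatus.COMPLETED, PartialDate(2015, 2, 1),
                PartialDate.from_date(reg + dt.timedelta(days=450)),
                CompletionType.ACTUAL),
    ),
)

config = AuditConfig()  # 5-year follow-up, no grace period
classification = classify_trial(history, config)
flip = decisive_flip(history, classification, config)

print(f"launch assessment:    {classification.launch.status.value} "
      f"(start {classification.launch.start_date_used})")
print(f"follow-up assessment: {classification.followup.status.value} "
      f"(start {classification.followup.start_date_used})")
print(f"category:             {classification.category.value}")
print(f"decisive flip:        version {flip.version_number}, "
      f"{flip.from_date} -> {flip.to_date} ({flip.delta_days:+d} days), "
      f"timing {flip.timing.value}")

# The trial looked retrospectively registered when it launched; by the
# 5-year follow-up its record claims a start date after registration, and the
# edit that achieved this was made after the trial had already completed.
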