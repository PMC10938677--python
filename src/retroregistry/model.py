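"""Domain types for registry trial histories and their file formats.

A trial's audit trail is represented as a :class:`TrialHistory`: the date the
record was first submitted to the registry plus the ordered list of archived
versions.  Start and completion dates carry explicit precision, because
registries report some of them rounded to the month and the
prospective/retrospective comparison must respect that.

Serialization conventions: MONTH-precision dates are written ``YYYY-MM``,
DAY-precision dates ``YYYY-MM-DD``; the JSON Lines dialect relies on this to
round-trip precision, while the version-per-row CSV dialect carries explicit
``*_precision`` columns.
"""

from __future__ import annotations

import calendar
import dataclasses
import datetime as dt
import enum
import io
import json
import logging
import re
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

logger = logging.getLogger(__name__)

NCT_PATTERN = re.compile(r"NCT\d{8}")

_MONTH_NAMES = {name.lower(): i for i, name in enumerate(calendar.month_name) if name}
_MONTH_ABBRS = {name.lower(): i for i, name in enumerate(calendar.month_abbr) if name}


class FormatError(ValueError):
    """Raised for unparseable or invalid input values."""


class LoadError(ValueError):
    """Raised when an input file violates the history schema or invariants."""


class Precision(enum.Enum):
    DAY = "DAY"
    MONTH = "MONTH"


class OverallStatus(enum.Enum):
    NOT_YET_RECRUITING = "NOT_YET_RECRUITING"
    RECRUITING = "RECRUITING"
    ENROLLING_BY_INVITATION = "ENROLLING_BY_INVITATION"
    ACTIVE_NOT_RECRUITING = "ACTIVE_NOT_RECRUITING"
    SUSPENDED = "SUSPENDED"
    COMPLETED = "COMPLETED"
    TERMINATED = "TERMINATED"
    WITHDRAWN = "WITHDRAWN"
    UNKNOWN = "UNKNOWN"


class CompletionType(enum.Enum):
    ACTUAL = "ACTUAL"
    ANTICIPATED = "ANTICIPATED"


class PhaseGroup(enum.Enum):
    PHASE1 = "PHASE1"
    PHASE2PLUS = "PHASE2PLUS"
    UNREPORTED = "UNREPORTED"


class SponsorClass(enum.Enum):
    INDUSTRY = "INDUSTRY"
    OTHER = "OTHER"


#: Registry-style status labels as they appear in exports, mapped to the enum.
_STATUS_ALIASES = {
    "NOT YET RECRUITING": OverallStatus.NOT_YET_RECRUITING,
    "RECRUITING": OverallStatus.RECRUITING,
    "ENROLLING BY INVITATION": OverallStatus.ENROLLING_BY_INVITATION,
    "ACTIVE, NOT RECRUITING": OverallStatus.ACTIVE_NOT_RECRUITING,
    "ACTIVE NOT RECRUITING": OverallStatus.ACTIVE_NOT_RECRUITING,
    "SUSPENDED": OverallStatus.SUSPENDED,
    "COMPLETED": OverallStatus.COMPLETED,
    "TERMINATED": OverallStatus.TERMINATED,
    "WITHDRAWN": OverallStatus.WITHDRAWN,
    "UNKNOWN": OverallStatus.UNKNOWN,
    "UNKNOWN STATUS": OverallStatus.UNKNOWN,
}


def parse_overall_status(text: str) -> OverallStatus:
    """Map a status string to the closed enum; unknown labels become UNKNOWN.

    Real registry exports contain legacy labels, so an unrecognized string is
    logged as a warning rather than rejected.
    """
    key = text.strip().upper().replace("_", " ")
    status = _STATUS_ALIASES.get(key)
    if status is None:
        logger.warning("unrecognized overall status %r mapped to UNKNOWN", text)
        return OverallStatus.UNKNOWN
    return status


@dataclasses.dataclass(frozen=True)
class PartialDate:
    """A calendar date known either to the day or only to the month.

    Ordering is lexicographic on ``(year, month, day or 1)``; use
    :meth:`anchor` for explicit day arithmetic (MONTH-precision values anchor
    to the first of the month) and :meth:`year_month` for month-level
    comparisons.
    """

    year: int
    month: int
    day: int | None = None

    def __post_init__(self) -> None:
        if not 1 <= self.month <= 12:
            raise FormatError(f"month out of range in partial date: {self.month}")
        if self.day is not None:
            # raises ValueError for invalid calendar combinations
            try:
                dt.date(self.year, self.month, self.day)
            except ValueError as exc:
                raise FormatError(
                    f"invalid calendar date {self.year}-{self.month:02d}-{self.day:02d}"
                ) from exc

    def _key(self) -> tuple[int, int, int]:
        return (self.year, self.month, self.day if self.day is not None else 1)

    def __lt__(self, other: "PartialDate") -> bool:
        return self._key() < other._key()

    def __le__(self, other: "PartialDate") -> bool:
        return self._key() <= other._key()

    def __gt__(self, other: "PartialDate") -> bool:
        return self._key() > other._key()

    def __ge__(self, other: "PartialDate") -> bool:
        return self._key() >= other._key()

    @property
    def precision(self) -> Precision:
        return Precision.DAY if self.day is not None else Precision.MONTH

    @classmethod
    def from_date(cls, d: dt.date) -> "PartialDate":
        return cls(d.year, d.month, d.day)

    def anchor(self) -> dt.date:
        """Full date used for day arithmetic; MONTH anchors to day 1."""
        return dt.date(self.year, self.month, self.day if self.day is not None else 1)

    def year_month(self) -> tuple[int, int]:
        return (self.year, self.month)

    def truncate(self, precision: Precision) -> "PartialDate":
        if precision is Precision.MONTH:
            return PartialDate(self.year, self.month)
        if self.day is None:
            raise ValueError("cannot refine a MONTH-precision date to DAY")
        return self

    def isoformat(self) -> str:
        if self.day is not None:
            return f"{self.year:04d}-{self.month:02d}-{self.day:02d}"
        return f"{self.year:04d}-{self.month:02d}"

    def __str__(self) -> str:  # pragma: no cover - convenience
        return self.isoformat()


def parse_partial_date(text: str) -> PartialDate:
    """Parse ``YYYY-MM-DD`` (day precision) or ``YYYY-MM`` / ``Month YYYY``
    (month precision).

    Any other dialect is rejected with a :class:`FormatError` naming the
    offending value — silently guessing between day-first and month-first
    numeric forms would corrupt the audit.
    """
    if not isinstance(text, str) or not text.strip():
        raise FormatError(f"empty or non-string date value: {text!r}")
    s = text.strip()
    m = re.fullmatch(r"(\d{4})-(\d{2})-(\d{2})", s)
    if m:
        return PartialDate(int(m.group(1)), int(m.group(2)), int(m.group(3)))
    m = re.fullmatch(r"(\d{4})-(\d{2})", s)
    if m:
        return PartialDate(int(m.group(1)), int(m.group(2)))
    m = re.fullmatch(r"([A-Za-z]+)\s+(\d{4})", s)
    if m:
        month = _MONTH_NAMES.get(m.group(1).lower()) or _MONTH_ABBRS.get(m.group(1).lower())
        if month is not None:
            return PartialDate(int(m.group(2)), month)
    raise FormatError(f"unparseable partial date: {text!r}")


def parse_full_date(text: str) -> dt.date:
    """Parse a complete ISO date, rejecting anything coarser."""
    pd_ = parse_partial_date(text)
    if pd_.day is None:
        raise FormatError(f"full calendar date required, got month precision: {text!r}")
    return pd_.anchor()


@dataclasses.dataclass(frozen=True)
class VersionRecord:
    """One archived snapshot of a registry record."""

    version_number: int
    version_date: dt.date
    overall_status: OverallStatus
    start_date: PartialDate | None = None
    completion_date: PartialDate | None = None
    completion_type: CompletionType | None = None
    phase_label: str = ""
    sponsor_class: SponsorClass = SponsorClass.OTHER
    enrollment: int | None = None
    conditions: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.version_number < 1:
            raise LoadError(f"version_number must be >= 1, got {self.version_number}")
        if self.enrollment is not None and self.enrollment < 0:
            raise LoadError(f"negative enrollment: {self.enrollment}")


@dataclasses.dataclass(frozen=True)
class TrialHistory:
    """Registration (submission) date plus the ordered archived versions.

    ``registration_date`` is the date the record was first submitted to the
    registry, which is the reference the prospective/retrospective comparison
    uses; it is carried per trial and never inferred from version 1's posting
    date.
    """

    trial_id: str
    registration_date: dt.date
    versions: tuple[VersionRecord, ...]

    def __post_init__(self) -> None:
        if not NCT_PATTERN.fullmatch(self.trial_id):
            raise LoadError(f"trial_id {self.trial_id!r} does not match NCT + 8 digits")
        if not self.versions:
            raise LoadError(f"{self.trial_id}: history has no versions")
        numbers = [v.version_number for v in self.versions]
        if any(b <= a for a, b in zip(numbers, numbers[1:])):
            raise LoadError(f"{self.trial_id}: version numbers not strictly increasing")
        keys = [(v.version_date, v.version_number) for v in self.versions]
        if keys != sorted(keys):
            raise LoadError(f"{self.trial_id}: versions not sorted by (date, number)")
        if self.versions[0].version_date < self.registration_date:
            raise LoadError(
                f"{self.trial_id}: first version date {self.versions[0].version_date} "
                f"precedes registration date {self.registration_date}"
            )


@dataclasses.dataclass(frozen=True)
class SubgroupLabels:
    """Phase / sponsorship / medical-field grouping for one trial."""

    phase_group: PhaseGroup
    sponsor_group: SponsorClass
    fields: frozenset[str] = frozenset()


# ---------------------------------------------------------------------------
# Readers
# ---------------------------------------------------------------------------

CSV_COLUMNS = [
    "trial_id",
    "registration_date",
    "version_number",
    "version_date",
    "overall_status",
    "start_date",
    "start_date_precision",
    "completion_date",
    "completion_date_precision",
    "completion_type",
    "phase_label",
    "sponsor_class",
    "enrollment",
    "conditions",
]


def _opt_partial(value, precision: str | None = None) -> PartialDate | None:
    if value is None or value == "" or (isinstance(value, float) and pd.isna(value)):
        return None
    parsed = parse_partial_date(str(value))
    if precision == "MONTH" and parsed.day is not None:
        parsed = PartialDate(parsed.year, parsed.month)
    return parsed


def _version_from_obj(obj: dict, trial_id: str, where: str) -> VersionRecord:
    try:
        start = _opt_partial(obj.get("start_date"))
        completion = _opt_partial(obj.get("completion_date"))
        ctype = obj.get("completion_type")
        conditions = obj.get("conditions") or []
        if isinstance(conditions, str):
            conditions = [c for c in conditions.split(";") if c]
        enrollment = obj.get("enrollment")
        return VersionRecord(
            version_number=int(obj["version_number"]),
            version_date=parse_full_date(str(obj["version_date"])),
            overall_status=parse_overall_status(str(obj["overall_status"])),
            start_date=start,
            completion_date=completion,
            completion_type=CompletionType(ctype) if ctype else None,
            phase_label=str(obj.get("phase_label") or ""),
            sponsor_class=SponsorClass(obj.get("sponsor_class") or "OTHER"),
            enrollment=int(enrollment) if enrollment not in (None, "") else None,
            conditions=tuple(str(c).strip() for c in conditions),
        )
    except (KeyError, ValueError, FormatError) as exc:
        raise LoadError(f"{trial_id} ({where}): {exc}") from exc


def _check_duplicates(trial_id: str, versions: Sequence[VersionRecord]) -> None:
    seen: set[int] = set()
    for v in versions:
        if v.version_number in seen:
            raise LoadError(f"{trial_id}: duplicate version_number {v.version_number}")
        seen.add(v.version_number)


def read_histories_jsonl(stream: io.TextIOBase | Iterable[str]) -> list[TrialHistory]:
    histories = []
    for lineno, line in enumerate(stream, start=1):
        line = line.strip()
        if not line:
            continue
        try:
            obj = json.loads(line)
        except json.JSONDecodeError as exc:
            raise LoadError(f"line {lineno}: invalid JSON ({exc})") from exc
        trial_id = str(obj.get("trial_id", f"<line {lineno}>"))
        versions = [
            _version_from_obj(v, trial_id, f"line {lineno}") for v in obj.get("versions", [])
        ]
        _check_duplicates(trial_id, versions)
        try:
            histories.append(
                TrialHistory(
                    trial_id=trial_id,
                    registration_date=parse_full_date(str(obj["registration_date"])),
                    versions=tuple(versions),
                )
            )
        except (KeyError, FormatError, LoadError) as exc:
            raise LoadError(f"line {lineno}: {exc}") from exc
    return histories


def read_histories_csv(stream) -> list[TrialHistory]:
    frame = pd.read_csv(stream, dtype=str, keep_default_na=False)
    missing = [c for c in CSV_COLUMNS if c not in frame.columns]
    if missing:
        raise LoadError(f"missing required column(s): {', '.join(missing)}")
    histories = []
    for trial_id, group in frame.groupby("trial_id", sort=True):
        rows = group.to_dict("records")
        versions = []
        registration = None
        for row in rows:
            registration = parse_full_date(row["registration_date"])
            obj = dict(row)
            obj["start_date"] = row["start_date"] or None
            obj["completion_date"] = row["completion_date"] or None
            obj["completion_type"] = row["completion_type"] or None
            version = _version_from_obj(obj, str(trial_id), "csv row")
            if row.get("start_date_precision") == "MONTH" and version.start_date is not None:
                version = dataclasses.replace(
                    version, start_date=version.start_date.truncate(Precision.MONTH)
                )
            if (
                row.get("completion_date_precision") == "MONTH"
                and version.completion_date is not None
            ):
                version = dataclasses.replace(
                    version, completion_date=version.completion_date.truncate(Precision.MONTH)
                )
            versions.append(version)
        versions.sort(key=lambda v: (v.version_date, v.version_number))
        _check_duplicates(str(trial_id), versions)
        histories.append(
            TrialHistory(
                trial_id=str(trial_id),
                registration_date=registration,
                versions=tuple(versions),
            )
        )
    return histories


def read_histories(source, format: str = "jsonl") -> list[TrialHistory]:
    """Read trial histories from a path or open text stream.

    Parameters
    ----------
    source
        Path or open text stream.
    format
        ``"jsonl"`` (one trial object per line) or ``"csv"``
        (version-per-row dialect; rows sharing a trial_id are grouped and
        sorted, so row order does not matter).
    """
    fmt = format.lower()
    if fmt not in ("jsonl", "csv"):
        raise ValueError(f"unknown format {format!r}")
    if isinstance(source, (str, Path)):
        with open(source, "r", encoding="utf-8") as fh:
            return read_histories(fh, format=fmt)
    if fmt == "jsonl":
        return read_histories_jsonl(source)
    return read_histories_csv(source)


# ---------------------------------------------------------------------------
# Writers
# ---------------------------------------------------------------------------


def history_to_obj(history: TrialHistory) -> dict:
    return {
        "trial_id": history.trial_id,
        "registration_date": history.registration_date.isoformat(),
        "versions": [
            {
                "version_number": v.version_number,
                "version_date": v.version_date.isoformat(),
                "overall_status": v.overall_status.value,
                "start_date": v.start_date.isoformat() if v.start_date else None,
                "completion_date": v.completion_date.isoformat() if v.completion_date else None,
                "completion_type": v.completion_type.value if v.completion_type else None,
                "phase_label": v.phase_label,
                "sponsor_class": v.sponsor_class.value,
                "enrollment": v.enrollment,
                "conditions": list(v.conditions),
            }
            for v in history.versions
        ],
    }


def write_histories_jsonl(histories: Iterable[TrialHistory], path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for history in histories:
            fh.write(json.dumps(history_to_obj(history), separators=(",", ":")) + "\n")


def write_histories_csv(histories: Iterable[TrialHistory], path) -> None:
    rows = []
    for history in histories:
        for v in history.versions:
            rows.append(
                {
                    "trial_id": history.trial_id,
                    "registration_date": history.registration_date.isoformat(),
                    "version_number": v.version_number,
                    "version_date": v.version_date.isoformat(),
                    "overall_status": v.overall_status.value,
                    "start_date": v.start_date.isoformat() if v.start_date else "",
                    "start_date_precision": v.start_date.precision.value if v.start_date else "",
                    "completion_date": (
                        v.completion_date.isoformat() if v.completion_date else ""
                    ),
                    "completion_date_precision": (
                        v.completion_date.precision.value if v.completion_date else ""
                    ),
                    "completion_type": v.completion_type.value if v.completion_type else "",
                    "phase_label": v.phase_label,
                    "sponsor_class": v.sponsor_class.value,
                    "enrollment": v.enrollment if v.enrollment is not None else "",
                    "conditions": ";".join(v.conditions),
                }
            )
    pd.DataFrame(rows, columns=CSV_COLUMNS).to_csv(path, index=False)
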