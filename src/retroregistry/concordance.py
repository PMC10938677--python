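"""Matching trials to publications and comparing registered vs published
start dates.

A publication matches a trial when the trial's NCT number appears in its
secondary-identifier list or anywhere in the title/abstract text.  The
"original" start date of a trial is the first one the registry record ever
reported for retrospectively registered trials, and the one in force at
launch for prospectively registered trials.  Concordance truncates both
dates to the coarser of their two precisions before comparing, so a
day-precision registry date and a month-only published date can still agree.
"""

from __future__ import annotations

import dataclasses
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .classify import (
    AuditConfig,
    RegistrationStatus,
    TrialClassification,
    find_launch_version,
    in_window_versions,
)
from .model import NCT_PATTERN, PartialDate, Precision, TrialHistory, _opt_partial
from .stats import percent


@dataclasses.dataclass(frozen=True)
class PublicationRecord:
    publication_id: str
    secondary_ids: tuple[str, ...] = ()
    title_abstract_text: str = ""


@dataclasses.dataclass(frozen=True)
class ExtractionRecord:
    """Consensus manual extraction from one trial's results publication."""

    trial_id: str
    publication_id: str
    is_results_publication: bool = True
    published_start_date: PartialDate | None = None
    published_end_date: PartialDate | None = None
    claims_prospective: bool = False
    claims_retrospective: bool = False
    mentions_start_date_change: bool = False

    def __post_init__(self) -> None:
        if self.claims_prospective and self.claims_retrospective:
            raise ValueError(
                f"{self.trial_id}/{self.publication_id}: publication cannot claim both "
                "prospective and retrospective registration"
            )


@dataclasses.dataclass(frozen=True)
class ConcordanceResult:
    trial_id: str
    original_start: PartialDate
    published_start: PartialDate | None
    concordant: bool | None

    def __post_init__(self) -> None:
        if (self.published_start is None) != (self.concordant is None):
            raise ValueError("concordant must be present exactly when published_start is")


def match_by_nct(
    trial_ids: Iterable[str], publications: Sequence[PublicationRecord]
) -> dict[str, list[str]]:
    """Map each trial to the publications that carry its NCT number.

    Matching is by exact secondary-identifier equality or by an NCT token in
    the title/abstract text; only trials with at least one match appear in
    the result, and duplicate publication records do not duplicate matches.
    """
    ids = set(trial_ids)
    matches: dict[str, list[str]] = {}
    seen: set[tuple[str, str]] = set()
    for pub in publications:
        tokens = set(pub.secondary_ids) | set(NCT_PATTERN.findall(pub.title_abstract_text))
        for token in tokens & ids:
            if (token, pub.publication_id) in seen:
                continue
            seen.add((token, pub.publication_id))
            matches.setdefault(token, []).append(pub.publication_id)
    for pubs in matches.values():
        pubs.sort()
    return matches


def original_start_date(
    history: TrialHistory, classification: TrialClassification, config: AuditConfig
) -> PartialDate:
    """The registry's "original" start date for the concordance comparison.

    Retrospectively registered at launch: the first start date the record
    ever reported.  Prospectively registered: the start date of the launch
    version itself (the value in force once recruiting began).
    """
    if classification.launch.status is RegistrationStatus.UNDETERMINED:
        raise ValueError(f"{history.trial_id}: launch status undetermined")
    if classification.launch.status is RegistrationStatus.RETROSPECTIVE:
        for version in in_window_versions(history, config):
            if version.start_date is not None:
                return version.start_date
        raise ValueError(f"{history.trial_id}: no reported start date")
    launch = find_launch_version(history, config)
    if launch is None or launch.start_date is None:
        raise ValueError(f"{history.trial_id}: launch version lacks a start date")
    return launch.start_date


def assess_concordance(
    original: PartialDate, extraction: ExtractionRecord
) -> ConcordanceResult:
    """Compare registry and published start dates at the coarser precision.

    Publications reporting no start date yield an undefined verdict and are
    excluded from concordance denominators downstream.
    """
    published = extraction.published_start_date
    if published is None:
        return ConcordanceResult(extraction.trial_id, original, None, None)
    if Precision.MONTH in (original.precision, published.precision):
        concordant = original.year_month() == published.year_month()
    else:
        concordant = original == published
    return ConcordanceResult(extraction.trial_id, original, published, concordant)


def tally_reporting(
    extractions: Sequence[ExtractionRecord],
    concordance: Sequence[ConcordanceResult] = (),
) -> dict:
    """Counts and percentages of registration claims, change mentions and
    start-date concordance over a set of consensus extraction records."""
    n = len(extractions)
    n_claim_prosp = sum(e.claims_prospective for e in extractions)
    n_claim_retro = sum(e.claims_retrospective for e in extractions)
    n_mention_change = sum(e.mentions_start_date_change for e in extractions)
    assessed = [c for c in concordance if c.concordant is not None]
    n_concordant = sum(c.concordant for c in assessed)
    return {
        "n_extractions": n,
        "claims_prospective": {"count": n_claim_prosp, "percent": percent(n_claim_prosp, n)},
        "claims_retrospective": {"count": n_claim_retro, "percent": percent(n_claim_retro, n)},
        "mentions_start_date_change": {
            "count": n_mention_change,
            "percent": percent(n_mention_change, n),
        },
        "concordance": {
            "n_assessed": len(assessed),
            "n_excluded_no_published_date": len(concordance) - len(assessed),
            "count": n_concordant,
            "percent": percent(n_concordant, len(assessed)) if assessed else None,
        },
    }


# ---------------------------------------------------------------------------
# File formats
# ---------------------------------------------------------------------------


def read_publications_csv(path) -> list[PublicationRecord]:
    frame = pd.read_csv(path, dtype=str, keep_default_na=False)
    return [
        PublicationRecord(
            publication_id=row["publication_id"],
            secondary_ids=tuple(s for s in row.get("secondary_ids", "").split(";") if s),
            title_abstract_text=row.get("title_abstract_text", ""),
        )
        for row in frame.to_dict("records")
    ]


_TRUE = {"true", "1", "yes"}


def read_extractions_csv(path) -> list[ExtractionRecord]:
    frame = pd.read_csv(path, dtype=str, keep_default_na=False)
    records = []
    for row in frame.to_dict("records"):
        records.append(
            ExtractionRecord(
                trial_id=row["trial_id"],
                publication_id=row["publication_id"],
                is_results_publication=row.get("is_results_publication", "true").lower()
                in _TRUE,
                published_start_date=_opt_partial(row.get("published_start_date") or None),
                published_end_date=_opt_partial(row.get("published_end_date") or None),
                claims_prospective=row.get("claims_prospective", "").lower() in _TRUE,
                claims_retrospective=row.get("claims_retrospective", "").lower() in _TRUE,
                mentions_start_date_change=row.get("mentions_start_date_change", "").lower()
                in _TRUE,
            )
        )
    return records


def write_publications_csv(publications: Sequence[PublicationRecord], path) -> None:
    pd.DataFrame(
        [
            {
                "publication_id": p.publication_id,
                "secondary_ids": ";".join(p.secondary_ids),
                "title_abstract_text": p.title_abstract_text,
            }
            for p in publications
        ],
        columns=["publication_id", "secondary_ids", "title_abstract_text"],
    ).to_csv(path, index=False)


def write_extractions_csv(extractions: Sequence[ExtractionRecord], path) -> None:
    pd.DataFrame(
        [
            {
                "trial_id": e.trial_id,
                "publication_id": e.publication_id,
                "is_results_publication": str(e.is_results_publication).lower(),
                "published_start_date": (
                    e.published_start_date.isoformat() if e.published_start_date else ""
                ),
                "published_end_date": (
                    e.published_end_date.isoformat() if e.published_end_date else ""
                ),
                "claims_prospective": str(e.claims_prospective).lower(),
                "claims_retrospective": str(e.claims_retrospective).lower(),
                "mentions_start_date_change": str(e.mentions_start_date_change).lower(),
            }
            for e in extractions
        ],
        columns=[
            "trial_id",
            "publication_id",
            "is_results_publication",
            "published_start_date",
            "published_end_date",
            "claims_prospective",
            "claims_retrospective",
            "mentions_start_date_change",
        ],
    ).to_csv(path, index=False)
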