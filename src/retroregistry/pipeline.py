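"""End-to-end audit: ingest -> eligibility -> classification -> change
analysis -> statistics -> publication concordance -> report files.

The pipeline is fully deterministic: rows are ordered by trial id and
version number, output JSON is key-sorted, and no timestamps enter the data
files, so two runs on identical inputs are byte-identical.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path
from typing import Sequence

import pandas as pd

from . import changes as ch
from . import classify as cl
from . import concordance as cc
from .model import TrialHistory, read_histories
from .stats import summarize_cohort


@dataclasses.dataclass
class PipelineRun:
    """Stage counts and artifact paths of one pipeline execution."""

    config: cl.AuditConfig
    out_dir: Path
    n_ingested: int
    n_eligible: int
    n_classified: int
    n_unclassifiable: int
    summary: dict
    paths: dict[str, Path]


def audit_cohort(
    histories: Sequence[TrialHistory],
    config: cl.AuditConfig,
    publications: Sequence[cc.PublicationRecord] | None = None,
    extractions: Sequence[cc.ExtractionRecord] | None = None,
):
    """Run the in-memory audit; returns (classifications, changes, flips,
    summary, exclusion log)."""
    eligible, excluded = cl.filter_eligible(histories, config)
    eligible = sorted(eligible, key=lambda h: h.trial_id)
    classifications = [cl.classify_trial(h, config) for h in eligible]
    by_id = {c.trial_id: c for c in classifications}

    changes_by_trial: dict[str, list[ch.StartDateChange]] = {}
    flips: dict[str, ch.StartDateChange] = {}
    for history in eligible:
        events = ch.extract_changes(history, config)
        changes_by_trial[history.trial_id] = events
        classification = by_id[history.trial_id]
        if classification.category is cl.Category.RETROACTIVELY_PROSPECTIVE:
            flips[history.trial_id] = ch.decisive_flip(
                history, classification, config, events
            )

    displacement = ch.displacement_summary(
        eligible,
        by_id,
        config,
        categories={
            cl.Category.RETROACTIVELY_PROSPECTIVE,
            cl.Category.STABLE_RETROSPECTIVE,
        },
    )

    reporting = None
    if publications is not None and extractions is not None:
        reporting = _concordance_stage(
            eligible, by_id, config, publications, extractions
        )

    version_counts = {
        h.trial_id: len(cl.in_window_versions(h, config)) for h in eligible
    }
    summary = summarize_cohort(
        classifications,
        changes_by_trial,
        flips,
        version_counts,
        reporting=reporting,
        displacement=displacement,
    )
    return classifications, changes_by_trial, flips, summary, excluded


def _concordance_stage(histories, by_id, config, publications, extractions):
    matched = cc.match_by_nct([h.trial_id for h in histories], publications)
    history_by_id = {h.trial_id: h for h in histories}
    groups: dict[str, tuple[list, list]] = {
        "retroactively_prospective": ([], []),
        "controls": ([], []),
    }
    for record in extractions:
        if not record.is_results_publication:
            continue
        classification = by_id.get(record.trial_id)
        if classification is None or record.trial_id not in matched:
            continue
        if classification.category is cl.Category.UNCLASSIFIABLE:
            continue
        group = (
            "retroactively_prospective"
            if classification.category is cl.Category.RETROACTIVELY_PROSPECTIVE
            else "controls"
        )
        original = cc.original_start_date(
            history_by_id[record.trial_id], classification, config
        )
        groups[group][0].append(record)
        groups[group][1].append(cc.assess_concordance(original, record))
    return {
        name: cc.tally_reporting(records, results)
        for name, (records, results) in groups.items()
    }


# ---------------------------------------------------------------------------
# Report files
# ---------------------------------------------------------------------------


def write_tables(
    classifications: Sequence[cl.TrialClassification],
    changes_by_trial: dict[str, list[ch.StartDateChange]],
    flips: dict[str, ch.StartDateChange],
    summary: dict,
    directory,
) -> dict[str, Path]:
    """Write classification.csv, changes.csv, summary.json and summary.csv.

    Row order is deterministic (trial_id, then version_number); empty inputs
    still produce valid header-only files.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = {
        "classification": directory / "classification.csv",
        "changes": directory / "changes.csv",
        "summary_json": directory / "summary.json",
        "summary_csv": directory / "summary.csv",
    }

    rows = []
    for c in sorted(classifications, key=lambda c: c.trial_id):
        rows.append(
            {
                "trial_id": c.trial_id,
                "category": c.category.value,
                "launch_status": c.launch.status.value,
                "launch_basis_version": c.launch.basis_version_number,
                "launch_start_date": (
                    c.launch.start_date_used.isoformat() if c.launch.start_date_used else ""
                ),
                "followup_status": c.followup.status.value,
                "followup_basis_version": c.followup.basis_version_number,
                "followup_start_date": (
                    c.followup.start_date_used.isoformat()
                    if c.followup.start_date_used
                    else ""
                ),
                "phase_group": c.subgroups.phase_group.value,
                "sponsor_group": c.subgroups.sponsor_group.value,
                "fields": ";".join(sorted(c.subgroups.fields)),
            }
        )
    pd.DataFrame(
        rows,
        columns=[
            "trial_id",
            "category",
            "launch_status",
            "launch_basis_version",
            "launch_start_date",
            "followup_status",
            "followup_basis_version",
            "followup_start_date",
            "phase_group",
            "sponsor_group",
            "fields",
        ],
    ).to_csv(paths["classification"], index=False)

    change_rows = []
    for trial_id in sorted(changes_by_trial):
        flip = flips.get(trial_id)
        for event in changes_by_trial[trial_id]:
            change_rows.append(
                {
                    "trial_id": trial_id,
                    "version_number": event.version_number,
                    "version_date": event.version_date.isoformat(),
                    "from_date": event.from_date.isoformat(),
                    "to_date": event.to_date.isoformat(),
                    "delta_days": event.delta_days,
                    "timing": event.timing.value,
                    "is_decisive_flip": str(
                        flip is not None and flip.version_number == event.version_number
                    ).lower(),
                }
            )
    pd.DataFrame(
        change_rows,
        columns=[
            "trial_id",
            "version_number",
            "version_date",
            "from_date",
            "to_date",
            "delta_days",
            "timing",
            "is_decisive_flip",
        ],
    ).to_csv(paths["changes"], index=False)

    with open(paths["summary_json"], "w", encoding="utf-8") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True)
        fh.write("\n")
    _summary_to_csv(summary, paths["summary_csv"])
    return paths


def _summary_to_csv(summary: dict, path) -> None:
    """Flatten the summary into one row per (metric, subgroup)."""
    rows = []

    def walk(prefix: str, node) -> None:
        if isinstance(node, dict):
            if set(node) >= {"count", "of", "percent"}:
                rows.append(
                    {
                        "metric": prefix,
                        "count": node["count"],
                        "of": node["of"],
                        "percent": node["percent"],
                    }
                )
            else:
                for key in sorted(node):
                    walk(f"{prefix}.{key}" if prefix else str(key), node[key])
        else:
            rows.append({"metric": prefix, "count": "", "of": "", "percent": node})

    walk("", summary)
    pd.DataFrame(rows, columns=["metric", "count", "of", "percent"]).to_csv(
        path, index=False
    )


def run_pipeline(
    histories_path,
    out_dir,
    config: cl.AuditConfig | None = None,
    publications_path=None,
    extractions_path=None,
    fmt: str = "jsonl",
) -> PipelineRun:
    """File-to-file pipeline execution.

    Missing optional publication/extraction inputs skip the concordance
    stage with a logged notice; malformed history input raises before any
    output is written.
    """
    config = config or cl.AuditConfig()
    out_dir = Path(out_dir)
    histories = read_histories(histories_path, format=fmt)
    publications = extractions = None
    notices = []
    if publications_path is not None and extractions_path is not None:
        publications = cc.read_publications_csv(publications_path)
        extractions = cc.read_extractions_csv(extractions_path)
    else:
        notices.append("concordance stage skipped: no publication/extraction inputs")

    classifications, changes_by_trial, flips, summary, excluded = audit_cohort(
        histories, config, publications, extractions
    )
    paths = write_tables(classifications, changes_by_trial, flips, summary, out_dir)

    n_unclassifiable = sum(
        1 for c in classifications if c.category is cl.Category.UNCLASSIFIABLE
    )
    flowchart = {
        "ingested": len(histories),
        "excluded": len(excluded),
        "eligible": len(classifications),
        "classified": len(classifications) - n_unclassifiable,
        "unclassifiable": n_unclassifiable,
    }
    paths["flowchart"] = out_dir / "flowchart_counts.json"
    with open(paths["flowchart"], "w", encoding="utf-8") as fh:
        json.dump(flowchart, fh, indent=2, sort_keys=True)
        fh.write("\n")

    paths["log"] = out_dir / "run.log"
    with open(paths["log"], "w", encoding="utf-8") as fh:
        for notice in notices:
            fh.write(f"NOTICE {notice}\n")
        for trial_id, reason in sorted(excluded):
            fh.write(f"EXCLUDED {trial_id}: {reason}\n")
        for c in classifications:
            if c.category is cl.Category.UNCLASSIFIABLE:
                fh.write(f"UNCLASSIFIABLE {c.trial_id}\n")

    return PipelineRun(
        config=config,
        out_dir=out_dir,
        n_ingested=len(histories),
        n_eligible=len(classifications),
        n_classified=len(classifications) - n_unclassifiable,
        n_unclassifiable=n_unclassifiable,
        summary=summary,
        paths=paths,
    )
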