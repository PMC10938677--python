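"""Synthetic registry histories with known ground truth.

Two generators are provided.  :func:`generate_stochastic` draws a cohort
with the statistical structure the audit assumes — a share of trials
registered retrospectively at launch, a small fraction of those later
edited to look prospective ("flips"), start-date edits timed before or
after completion, and start dates at day or month precision — and emits
per-trial truth labels, so classifier output can be validated exactly and
generator parameters can be recovered statistically.

:func:`build_exact_fixture` instead realizes an exact composition: every
category/subgroup cell count is specified up front and the builder emits
templated histories such that running the full audit pipeline reproduces
each cell exactly.  The packaged ``paper_mirror`` composition encodes the
counts of a published 2015 ClinicalTrials.gov cohort audit.
"""

from __future__ import annotations

import dataclasses
import datetime as dt
import random
from importlib import resources
from typing import Sequence

import pandas as pd
import yaml

from .changes import ChangeTiming
from .classify import Category
from .concordance import ExtractionRecord, PublicationRecord
from .model import (
    CompletionType,
    OverallStatus,
    PartialDate,
    SponsorClass,
    TrialHistory,
    VersionRecord,
)


class SpecError(ValueError):
    """An infeasible or internally inconsistent generator specification."""


def _month_floor(d: dt.date) -> dt.date:
    return d.replace(day=1)


def _add_months(year: int, month: int, k: int) -> tuple[int, int]:
    index = year * 12 + (month - 1) + k
    return index // 12, index % 12 + 1


# ---------------------------------------------------------------------------
# Stochastic cohorts
# ---------------------------------------------------------------------------


@dataclasses.dataclass(frozen=True)
class CohortSpec:
    """Parameters of a stochastic registry cohort.

    Defaults emulate the structure of the 2015 ClinicalTrials.gov cohort:
    roughly half the trials registered retrospectively, about 4% of those
    later flipped to look prospective (two thirds of the flips made after
    completion), about 31% of the non-flipping retrospective trials editing
    their start date at least once, a version count averaging ~6.5 with a
    long tail, and a minority of start dates reported at month precision.
    """

    n_trials: int = 1000
    p_retrospective_initial: float = 0.48
    p_flip_given_retrospective: float = 0.04
    p_post_completion_flip: float = 0.672
    p_change_given_retrospective_nonflip: float = 0.31
    version_count_mean: float = 6.5
    version_count_max: int = 30
    month_precision_probability: float = 0.3
    registration_window: tuple[dt.date, dt.date] = (dt.date(2015, 1, 1), dt.date(2015, 12, 31))
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_trials < 1:
            raise SpecError("n_trials must be >= 1")
        for name in (
            "p_retrospective_initial",
            "p_flip_given_retrospective",
            "p_post_completion_flip",
            "p_change_given_retrospective_nonflip",
            "month_precision_probability",
        ):
            value = getattr(self, name)
            if not 0.0 <= value <= 1.0:
                raise SpecError(f"{name} must lie in [0, 1], got {value}")
        if self.version_count_mean < 2:
            raise SpecError("version_count_mean must be >= 2")
        if self.version_count_max < 3:
            raise SpecError("version_count_max must be >= 3 to allow flip histories")
        if self.registration_window[0] > self.registration_window[1]:
            raise SpecError("registration_window must be ordered")

    @classmethod
    def from_yaml(cls, path) -> "CohortSpec":
        with open(path, "r", encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
        if "registration_window" in raw:
            lo, hi = raw["registration_window"]
            raw["registration_window"] = (
                dt.date.fromisoformat(str(lo)),
                dt.date.fromisoformat(str(hi)),
            )
        return cls(**raw)


@dataclasses.dataclass(frozen=True)
class TruthLabel:
    """Ground truth recorded while generating one trial."""

    trial_id: str
    category: Category
    flip_timing: ChangeTiming | None
    has_start_date_change: bool


_CONDITION_POOL = (
    "Breast Carcinoma",
    "Hypertension",
    "Parkinson Disease",
    "Chronic Low Back Pain",
    "Type 2 Diabetes Mellitus",
    "Asthma",
    "Coronary Artery Disease",
    "Major Depressive Disorder",
    "Rheumatoid Arthritis",
    "Non-Small Cell Lung Cancer",
)

_PHASE_POOL = ("Phase 1", "Phase 2", "Phase 3", "Phase 1 | Phase 2", "N/A", "Phase 4")


def _start_partial(anchor: dt.date, month_precision: bool) -> PartialDate:
    if month_precision:
        return PartialDate(anchor.year, anchor.month)
    return PartialDate.from_date(anchor)


def generate_stochastic(spec: CohortSpec) -> tuple[list[TrialHistory], list[TruthLabel]]:
    """Draw a seeded cohort; identical spec and seed give identical output."""
    rng = random.Random(spec.seed)
    histories: list[TrialHistory] = []
    truths: list[TruthLabel] = []
    window_days = (spec.registration_window[1] - spec.registration_window[0]).days
    for i in range(spec.n_trials):
        trial_id = f"NCT{10_000_000 + i:08d}"
        reg = spec.registration_window[0] + dt.timedelta(days=rng.randint(0, window_days))
        retro = rng.random() < spec.p_retrospective_initial
        month_precision = rng.random() < spec.month_precision_probability
        flip = retro and rng.random() < spec.p_flip_given_retrospective
        post_flip = flip and rng.random() < spec.p_post_completion_flip
        change = (
            retro
            and not flip
            and rng.random() < spec.p_change_given_retrospective_nonflip
        )

        n = 2 + _poisson(rng, max(0.0, spec.version_count_mean - 2))
        n = min(n, spec.version_count_max)
        if flip:
            n = max(n, 3)
        elif change:
            n = max(n, 2)
        offsets = sorted([rng.randint(0, 14)] + rng.sample(range(30, 1800), n - 1))
        dates = [reg + dt.timedelta(days=o) for o in offsets]

        if flip:
            if post_flip:
                completion_idx = rng.randint(1, n - 2)
                flip_idx = rng.randint(completion_idx + 1, n - 1)
            else:
                completion_idx = rng.randint(2, n - 1)
                flip_idx = rng.randint(1, completion_idx - 1)
        else:
            completion_idx = rng.randint(1, n - 1)
            flip_idx = None
        change_idx = rng.randint(1, n - 1) if change else None
        actual_completion = dates[completion_idx] - dt.timedelta(days=rng.randint(1, 45))

        if retro:
            start0 = reg - dt.timedelta(days=rng.randint(32, 365))
        else:
            start0 = reg + dt.timedelta(days=rng.randint(0, 180))
        starts = [_start_partial(start0, month_precision)] * n
        if flip:
            new = _start_partial(reg + dt.timedelta(days=rng.randint(0, 60)), month_precision)
            starts = starts[:flip_idx] + [new] * (n - flip_idx)
        elif change:
            if month_precision:
                reg_ym = (reg.year, reg.month)
                up = _add_months(start0.year, start0.month, 1)
                y, m = up if up < reg_ym else _add_months(start0.year, start0.month, -1)
                new = PartialDate(y, m)
            else:
                cap = (_month_floor(reg) - dt.timedelta(days=1) - start0).days
                new_anchor = start0 + dt.timedelta(days=rng.randint(1, min(25, cap)))
                new = PartialDate.from_date(new_anchor)
            starts = starts[:change_idx] + [new] * (n - change_idx)

        phase = rng.choice(_PHASE_POOL)
        sponsor = SponsorClass.INDUSTRY if rng.random() < 0.3 else SponsorClass.OTHER
        conditions = (rng.choice(_CONDITION_POOL),)
        versions = []
        for j in range(n):
            completed = j >= completion_idx
            versions.append(
                VersionRecord(
                    version_number=j + 1,
                    version_date=dates[j],
                    overall_status=(
                        OverallStatus.COMPLETED if completed else OverallStatus.RECRUITING
                    ),
                    start_date=starts[j],
                    completion_date=(
                        PartialDate.from_date(actual_completion)
                        if completed
                        else PartialDate.from_date(
                            dates[j] + dt.timedelta(days=rng.randint(60, 400))
                        )
                    ),
                    completion_type=(
                        CompletionType.ACTUAL if completed else CompletionType.ANTICIPATED
                    ),
                    phase_label=phase,
                    sponsor_class=sponsor,
                    enrollment=rng.randint(10, 500),
                    conditions=conditions,
                )
            )
        histories.append(TrialHistory(trial_id, reg, tuple(versions)))
        if flip:
            category = Category.RETROACTIVELY_PROSPECTIVE
            timing = ChangeTiming.POST_COMPLETION if post_flip else ChangeTiming.PRE_COMPLETION
        elif retro:
            category, timing = Category.STABLE_RETROSPECTIVE, None
        else:
            category, timing = Category.STABLE_PROSPECTIVE, None
        truths.append(TruthLabel(trial_id, category, timing, flip or change))
    return histories, truths


def _poisson(rng: random.Random, lam: float) -> int:
    """Knuth's method; lam here is small (a few units)."""
    if lam <= 0:
        return 0
    import math

    threshold = math.exp(-lam)
    k, p = 0, 1.0
    while True:
        p *= rng.random()
        if p <= threshold:
            return k
        k += 1


def write_truth_csv(truths: Sequence[TruthLabel], path) -> None:
    pd.DataFrame(
        [
            {
                "trial_id": t.trial_id,
                "category": t.category.value,
                "flip_timing": t.flip_timing.value if t.flip_timing else "",
                "has_start_date_change": str(t.has_start_date_change).lower(),
            }
            for t in truths
        ],
        columns=["trial_id", "category", "flip_timing", "has_start_date_change"],
    ).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Exact-composition fixtures
# ---------------------------------------------------------------------------


@dataclasses.dataclass(frozen=True)
class CompositionSpec:
    """Exact cell counts the deterministic fixture must realize.

    Consistency of every subcount against its parent is validated on
    construction; an inconsistent composition raises :class:`SpecError`
    listing all violated constraints.
    """

    n_total: int
    n_originally_retrospective: int
    n_retroactively_prospective: int
    n_retroactively_prospective_post_completion: int
    n_originally_retrospective_with_change: int
    n_control_latest_change_post_completion: int
    n_phase1_total: int
    n_phase1_retroactively_prospective: int
    n_published_retroactively_prospective: int
    n_published_claims_prospective: int
    n_published_flips_concordant: int = 0
    n_published_controls: int = 0
    n_published_controls_concordant: int = 0
    registration_year: int = 2015

    def __post_init__(self) -> None:
        violations = []

        def require(ok: bool, message: str) -> None:
            if not ok:
                violations.append(message)

        c = self
        controls = c.n_originally_retrospective - c.n_retroactively_prospective
        controls_with_change = (
            c.n_originally_retrospective_with_change - c.n_retroactively_prospective
        )
        require(c.n_total >= 1, "n_total must be >= 1")
        require(
            c.n_originally_retrospective <= c.n_total,
            "originally-retrospective count exceeds total",
        )
        require(
            c.n_retroactively_prospective <= c.n_originally_retrospective,
            "retroactively-prospective count exceeds originally-retrospective count",
        )
        require(
            c.n_retroactively_prospective_post_completion <= c.n_retroactively_prospective,
            "post-completion flip count exceeds flip count",
        )
        require(
            c.n_retroactively_prospective
            <= c.n_originally_retrospective_with_change
            <= c.n_originally_retrospective,
            "with-change count must lie between flip count and retrospective count",
        )
        require(
            c.n_control_latest_change_post_completion <= max(controls_with_change, 0),
            "control post-completion count exceeds controls with a change",
        )
        require(c.n_phase1_total <= c.n_total, "Phase-1 total exceeds total")
        require(
            c.n_phase1_retroactively_prospective
            <= min(c.n_phase1_total, c.n_retroactively_prospective),
            "Phase-1 flip count exceeds Phase-1 total or flip count",
        )
        require(
            c.n_phase1_total - c.n_phase1_retroactively_prospective
            <= c.n_total - c.n_originally_retrospective,
            "non-flip Phase-1 trials do not fit into the stable-prospective pool",
        )
        require(
            c.n_published_retroactively_prospective <= c.n_retroactively_prospective,
            "published flip count exceeds flip count",
        )
        require(
            c.n_published_claims_prospective <= c.n_published_retroactively_prospective,
            "prospective-claim count exceeds published flip count",
        )
        require(
            c.n_published_flips_concordant <= c.n_published_retroactively_prospective,
            "concordant published flip count exceeds published flip count",
        )
        require(
            c.n_published_controls <= max(controls, 0),
            "published control count exceeds control count",
        )
        require(
            c.n_published_controls_concordant <= c.n_published_controls,
            "concordant published control count exceeds published control count",
        )
        if violations:
            raise SpecError("inconsistent composition: " + "; ".join(violations))

    @classmethod
    def from_yaml(cls, path=None) -> "CompositionSpec":
        """Load a composition; without a path, the packaged paper-mirror one."""
        if path is None:
            source = resources.files("retroregistry.data").joinpath("paper_mirror.yaml")
            raw = yaml.safe_load(source.read_text(encoding="utf-8"))
        else:
            with open(path, "r", encoding="utf-8") as fh:
                raw = yaml.safe_load(fh)
        return cls(**{k: int(v) for k, v in raw.items()})


@dataclasses.dataclass(frozen=True)
class Fixture:
    histories: list[TrialHistory]
    truths: list[TruthLabel]
    publications: list[PublicationRecord]
    extractions: list[ExtractionRecord]


def build_exact_fixture(composition: CompositionSpec, seed: int = 0) -> Fixture:
    """Emit templated histories realizing every composition cell exactly.

    Six templates are used: post-completion flips, pre-completion flips,
    controls whose latest edit is post-completion, controls with a
    pre-completion edit, controls without edits, and stable prospective
    trials.  Histories are minimal — status progressions contain only what
    classification reads — and all dates derive deterministically from the
    seed.  Every tenth no-edit trial reports its start date at month
    precision to exercise the month-level comparison path.
    """
    c = composition
    rng = random.Random(seed)
    year = c.registration_year
    window = (dt.date(year, 1, 1), dt.date(year, 12, 31))
    window_days = (window[1] - window[0]).days

    n_flip_post = c.n_retroactively_prospective_post_completion
    n_flip_pre = c.n_retroactively_prospective - n_flip_post
    controls = c.n_originally_retrospective - c.n_retroactively_prospective
    controls_with_change = (
        c.n_originally_retrospective_with_change - c.n_retroactively_prospective
    )
    n_ctrl_post = c.n_control_latest_change_post_completion
    n_ctrl_pre = controls_with_change - n_ctrl_post
    n_ctrl_none = controls - controls_with_change
    n_stable_pro = c.n_total - c.n_originally_retrospective

    templates = (
        ["flip_post"] * n_flip_post
        + ["flip_pre"] * n_flip_pre
        + ["ctrl_post"] * n_ctrl_post
        + ["ctrl_pre"] * n_ctrl_pre
        + ["ctrl_none"] * n_ctrl_none
        + ["stable_pro"] * n_stable_pro
    )

    histories: list[TrialHistory] = []
    truths: list[TruthLabel] = []
    flip_ids: list[str] = []
    flip_first_start: dict[str, PartialDate] = {}
    flip_final_start: dict[str, PartialDate] = {}
    control_ids: list[str] = []
    control_original_start: dict[str, PartialDate] = {}

    n_phase1_nonflip = c.n_phase1_total - c.n_phase1_retroactively_prospective
    flip_seen = 0
    stable_seen = 0

    for i, template in enumerate(templates):
        trial_id = f"NCT{20_000_000 + i:08d}"
        reg = window[0] + dt.timedelta(days=rng.randint(0, window_days))
        jitter = rng.randint(0, 299)
        is_flip = template.startswith("flip")
        if is_flip:
            phase = "Phase 1" if flip_seen < c.n_phase1_retroactively_prospective else "Phase 2"
            flip_seen += 1
        elif template == "stable_pro":
            phase = "Phase 1" if stable_seen < n_phase1_nonflip else "Phase 3"
            stable_seen += 1
        else:
            phase = "Phase 2"
        sponsor = SponsorClass.INDUSTRY if i % 5 == 0 else SponsorClass.OTHER
        conditions = (_CONDITION_POOL[i % len(_CONDITION_POOL)],)
        month_precision = template in ("ctrl_none", "stable_pro") and i % 10 == 0

        if template == "stable_pro":
            start0 = _start_partial(reg + dt.timedelta(days=10 + jitter % 60), month_precision)
        else:
            start0 = _start_partial(reg - dt.timedelta(days=40 + jitter), month_precision)
        start1 = None
        if is_flip:
            start1 = _start_partial(reg + dt.timedelta(days=jitter % 40), month_precision)
        elif template in ("ctrl_post", "ctrl_pre"):
            start1 = PartialDate.from_date(
                start0.anchor() + dt.timedelta(days=1 + jitter % 20)
            )

        common = dict(phase_label=phase, sponsor_class=sponsor, conditions=conditions)

        def v(number, offset, status, start, completion_offset, completion_type):
            return VersionRecord(
                version_number=number,
                version_date=reg + dt.timedelta(days=offset),
                overall_status=status,
                start_date=start,
                completion_date=PartialDate.from_date(reg + dt.timedelta(days=completion_offset)),
                completion_type=completion_type,
                enrollment=30 + jitter,
                **common,
            )

        R, CO = OverallStatus.RECRUITING, OverallStatus.COMPLETED
        ANT, ACT = CompletionType.ANTICIPATED, CompletionType.ACTUAL
        if template == "flip_post":
            versions = [
                v(1, 3, R, start0, 400, ANT),
                v(2, 300, R, start0, 400, ANT),
                v(3, 500, CO, start0, 450, ACT),
                v(4, 700, CO, start1, 450, ACT),
            ]
            timing = ChangeTiming.POST_COMPLETION
        elif template == "flip_pre":
            versions = [
                v(1, 3, R, start0, 600, ANT),
                v(2, 200, R, start1, 600, ANT),
                v(3, 650, CO, start1, 610, ACT),
                v(4, 800, CO, start1, 610, ACT),
            ]
            timing = ChangeTiming.PRE_COMPLETION
        elif template == "ctrl_post":
            versions = [
                v(1, 3, R, start0, 400, ANT),
                v(2, 500, CO, start0, 450, ACT),
                v(3, 700, CO, start1, 450, ACT),
            ]
            timing = None
        elif template == "ctrl_pre":
            versions = [
                v(1, 3, R, start0, 600, ANT),
                v(2, 200, R, start1, 600, ANT),
                v(3, 650, CO, start1, 610, ACT),
            ]
            timing = None
        else:  # ctrl_none, stable_pro
            versions = [
                v(1, 3, R, start0, 400, ANT),
                v(2, 500, CO, start0, 450, ACT),
            ]
            timing = None

        histories.append(TrialHistory(trial_id, reg, tuple(versions)))
        if is_flip:
            category = Category.RETROACTIVELY_PROSPECTIVE
            flip_ids.append(trial_id)
            flip_first_start[trial_id] = start0
            flip_final_start[trial_id] = start1
        elif template == "stable_pro":
            category = Category.STABLE_PROSPECTIVE
        else:
            category = Category.STABLE_RETROSPECTIVE
            control_ids.append(trial_id)
            control_original_start[trial_id] = start0
        truths.append(
            TruthLabel(trial_id, category, timing, is_flip or start1 is not None)
        )

    publications, extractions = _fixture_publications(
        c,
        flip_ids,
        flip_first_start,
        flip_final_start,
        control_ids,
        control_original_start,
    )
    return Fixture(histories, truths, publications, extractions)


def _fixture_publications(
    c: CompositionSpec,
    flip_ids: list[str],
    flip_first_start: dict[str, PartialDate],
    flip_final_start: dict[str, PartialDate],
    control_ids: list[str],
    control_original_start: dict[str, PartialDate],
) -> tuple[list[PublicationRecord], list[ExtractionRecord]]:
    publications: list[PublicationRecord] = []
    extractions: list[ExtractionRecord] = []

    def add(trial_id: str, k: int, published_start: PartialDate | None, claims: bool) -> str:
        pub_id = f"PMID{90_000_000 + k:08d}"
        if k % 2 == 0:
            publications.append(PublicationRecord(pub_id, (trial_id,), "A randomized trial."))
        else:
            publications.append(
                PublicationRecord(
                    pub_id, (), f"Results of a trial registered as {trial_id}."
                )
            )
        extractions.append(
            ExtractionRecord(
                trial_id=trial_id,
                publication_id=pub_id,
                is_results_publication=True,
                published_start_date=published_start,
                claims_prospective=claims,
            )
        )
        return pub_id

    k = 0
    for j, trial_id in enumerate(flip_ids[: c.n_published_retroactively_prospective]):
        concordant = j < c.n_published_flips_concordant
        published = flip_first_start[trial_id] if concordant else flip_final_start[trial_id]
        add(trial_id, k, published, claims=j < c.n_published_claims_prospective)
        k += 1
    for j, trial_id in enumerate(control_ids[: c.n_published_controls]):
        concordant = j < c.n_published_controls_concordant
        original = control_original_start[trial_id]
        published = (
            original
            if concordant
            else PartialDate.from_date(original.anchor() - dt.timedelta(days=90))
        )
        add(trial_id, k, published, claims=False)
        k += 1
    return publications, extractions
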