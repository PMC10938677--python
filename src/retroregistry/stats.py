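"""Statistical kernels used by the audit, implemented from first principles.

The inference in this package rests on a single test: the two-sample test
for equality of proportions with Yates' continuity correction,

    chi2 = N * (max(0, |ad - bc| - N/2))**2 / ((a+b)(c+d)(a+c)(b+d)),

referred to the chi-square distribution with one degree of freedom, whose
survival function is ``erfc(sqrt(x/2))``.  The companion power calculation
uses the uncorrected normal approximation for the difference of two
proportions.
"""

from __future__ import annotations

import dataclasses
import math
from decimal import ROUND_HALF_UP, Decimal


class UndefinedStatisticError(ValueError):
    """A zero row or column margin leaves the chi-square statistic undefined."""


@dataclasses.dataclass(frozen=True)
class TwoByTwoTable:
    """Counts for two groups: group 1 = (a successes, b failures),
    group 2 = (c, d)."""

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValueError("cell counts must be non-negative")
        if self.a + self.b < 1 or self.c + self.d < 1:
            raise ValueError("each group needs at least one observation")

    @classmethod
    def from_proportion_counts(cls, x1: int, n1: int, x2: int, n2: int) -> "TwoByTwoTable":
        """Build from (successes, group size) per group."""
        return cls(x1, n1 - x1, x2, n2 - x2)


@dataclasses.dataclass(frozen=True)
class TwoProportionTestResult:
    chi2: float
    df: int
    p_value: float
    p1: float
    p2: float


def chi_square_sf_df1(x: float) -> float:
    """Survival function P(X >= x) of the chi-square distribution, 1 df."""
    if x < 0:
        raise ValueError(f"chi-square statistic must be non-negative, got {x}")
    return math.erfc(math.sqrt(x / 2.0))


def yates_two_prop_test(table: TwoByTwoTable) -> TwoProportionTestResult:
    """Two-proportion test for equality of proportions with continuity
    correction.

    The corrected statistic clamps at zero when |ad - bc| <= N/2.  A zero
    row or column margin raises :class:`UndefinedStatisticError`.
    """
    a, b, c, d = table.a, table.b, table.c, table.d
    n = a + b + c + d
    margins = [(a + b), (c + d), (a + c), (b + d)]
    if 0 in margins:
        raise UndefinedStatisticError(f"zero margin in 2x2 table {table}")
    cross = abs(a * d - b * c)
    corrected = max(0.0, cross - n / 2.0)
    chi2 = n * corrected**2 / math.prod(margins)
    return TwoProportionTestResult(
        chi2=chi2,
        df=1,
        p_value=chi_square_sf_df1(chi2),
        p1=a / (a + b),
        p2=c / (c + d),
    )


def _norm_cdf(z: float) -> float:
    return 0.5 * math.erfc(-z / math.sqrt(2.0))


def _norm_ppf(q: float, tol: float = 1e-12) -> float:
    """Standard normal quantile by bisection on the CDF (monotone, bounded)."""
    if not 0.0 < q < 1.0:
        raise ValueError("quantile argument must lie in (0, 1)")
    lo, hi = -40.0, 40.0
    while hi - lo > tol:
        mid = (lo + hi) / 2.0
        if _norm_cdf(mid) < q:
            lo = mid
        else:
            hi = mid
    return (lo + hi) / 2.0


@dataclasses.dataclass(frozen=True)
class PowerSpec:
    """Design of a two-sample proportion comparison for a power calculation."""

    p1: float
    p2: float
    n_per_group: int
    alpha: float = 0.05
    sides: int = 2

    def __post_init__(self) -> None:
        for p in (self.p1, self.p2):
            if not 0.0 <= p <= 1.0:
                raise ValueError("proportions must lie in [0, 1]")
        if self.n_per_group < 2:
            raise ValueError("n_per_group must be >= 2")
        if not 0.0 < self.alpha < 1.0:
            raise ValueError("alpha must lie in (0, 1)")
        if self.sides not in (1, 2):
            raise ValueError("sides must be 1 or 2")


def power_two_prop(spec: PowerSpec) -> float:
    """Normal-approximation power for the two-sample proportion comparison
    (no continuity correction).

    With pooled null SD sigma0 at p-bar = (p1+p2)/2 and alternative SD
    sigma1, the power is
    Phi((delta - z*sigma0)/sigma1) + Phi((-delta - z*sigma0)/sigma1).
    """
    n = spec.n_per_group
    delta = abs(spec.p1 - spec.p2)
    p_bar = (spec.p1 + spec.p2) / 2.0
    sigma0 = math.sqrt(2.0 * p_bar * (1.0 - p_bar) / n)
    sigma1 = math.sqrt(
        spec.p1 * (1.0 - spec.p1) / n + spec.p2 * (1.0 - spec.p2) / n
    )
    z = _norm_ppf(1.0 - spec.alpha / spec.sides)
    return _norm_cdf((delta - z * sigma0) / sigma1) + _norm_cdf(
        (-delta - z * sigma0) / sigma1
    )


def percent(count: int, total: int, decimals: int = 1) -> float:
    """Percentage rounded half-up to the given number of decimals (100*c/t).

    Matches table-style rendering: 158/235 -> 67.2.  Returns 0.0 for an
    empty denominator.
    """
    if total == 0:
        return 0.0
    exact = Decimal(100 * count) / Decimal(total)
    quantum = Decimal(1).scaleb(-decimals)
    return float(exact.quantize(quantum, rounding=ROUND_HALF_UP))


def _cell(count: int, total: int) -> dict:
    return {"count": count, "of": total, "percent": percent(count, total)}


def summarize_cohort(
    classifications,
    changes_by_trial,
    flips_by_trial,
    version_counts,
    reporting=None,
    displacement=None,
) -> dict:
    """Assemble the cohort summary tables.

    Parameters
    ----------
    classifications
        Sequence of per-trial classifications (one per eligible trial).
    changes_by_trial
        Mapping trial_id -> list of start-date change events.
    flips_by_trial
        Mapping trial_id -> decisive flip event, for every trial classified
        retroactively prospective.
    version_counts
        Mapping trial_id -> number of in-window versions.
    reporting
        Optional mapping of group name -> publication-reporting tally.
    displacement
        Optional launch-to-follow-up displacement summary for the
        originally-retrospective trials.

    Percentages are rendered to one decimal, half-up, as in the registry
    audit's tables.  The section comparing flip timing against the control
    trials includes the two-proportion test with continuity correction when
    both groups are non-empty.
    """
    # local imports: these modules build on the domain model, the kernel
    # functions above do not
    import statistics as _st

    from .changes import ChangeTiming
    from .classify import Category, RegistrationStatus

    n = len(classifications)
    by_category = {cat: [] for cat in Category}
    for cl in classifications:
        by_category[cl.category].append(cl)

    flips = by_category[Category.RETROACTIVELY_PROSPECTIVE]
    originally_retro = [
        cl for cl in classifications if cl.launch.status is RegistrationStatus.RETROSPECTIVE
    ]
    controls = [cl for cl in originally_retro if cl.category is not
                Category.RETROACTIVELY_PROSPECTIVE]

    n_flip_post = sum(
        1
        for cl in flips
        if flips_by_trial.get(cl.trial_id) is not None
        and flips_by_trial[cl.trial_id].timing is ChangeTiming.POST_COMPLETION
    )
    n_retro_changed = sum(
        1 for cl in originally_retro if changes_by_trial.get(cl.trial_id)
    )
    n_ctrl_latest_post = sum(
        1
        for cl in controls
        if changes_by_trial.get(cl.trial_id)
        and changes_by_trial[cl.trial_id][-1].timing is ChangeTiming.POST_COMPLETION
    )

    flip_versions = [
        flips_by_trial[cl.trial_id].version_number
        for cl in flips
        if flips_by_trial.get(cl.trial_id) is not None
    ]
    counts = list(version_counts.values())

    summary: dict = {
        "cohort": {"n_classified": n},
        "categories": {
            cat.value: _cell(len(group), n) for cat, group in by_category.items()
        },
        "retroactively_prospective": {
            "n": len(flips),
            "post_completion_flip": _cell(n_flip_post, len(flips)),
            "flip_version_median": float(_st.median(flip_versions)) if flip_versions else None,
        },
        "originally_retrospective": {
            "n": len(originally_retro),
            "with_start_date_change": _cell(n_retro_changed, len(originally_retro)),
        },
        "controls": {
            "n": len(controls),
            "latest_change_post_completion": _cell(n_ctrl_latest_post, len(controls)),
        },
        "versions_per_trial": {
            "mean": round(_st.fmean(counts), 1) if counts else None,
            "median": float(_st.median(counts)) if counts else None,
            "max": max(counts) if counts else None,
        },
        "subgroups": _subgroup_tables(classifications, by_category),
    }

    if displacement is not None:
        summary["originally_retrospective"]["displacement"] = {
            "n_trials_with_change": displacement.n_trials_with_change,
            "n_total": displacement.n_total,
            "median_delta_days": displacement.median_delta_days,
            "mean_delta_days": displacement.mean_delta_days,
        }

    if flips and controls:
        try:
            test = yates_two_prop_test(
                TwoByTwoTable.from_proportion_counts(
                    n_flip_post, len(flips), n_ctrl_latest_post, len(controls)
                )
            )
            summary["post_completion_timing_test"] = {
                "chi2": test.chi2,
                "df": test.df,
                "p_value": test.p_value,
                "p1": test.p1,
                "p2": test.p2,
            }
        except (UndefinedStatisticError, ValueError):
            pass

    if reporting:
        summary["publications"] = dict(reporting)
        groups = list(reporting.values())
        assessed = [
            (g["concordance"]["count"], g["concordance"]["n_assessed"])
            for g in groups
            if g.get("concordance", {}).get("n_assessed")
        ]
        if len(assessed) == 2:
            try:
                test = yates_two_prop_test(
                    TwoByTwoTable.from_proportion_counts(
                        assessed[0][0], assessed[0][1], assessed[1][0], assessed[1][1]
                    )
                )
                summary["concordance_test"] = {
                    "chi2": test.chi2,
                    "df": test.df,
                    "p_value": test.p_value,
                    "p1": test.p1,
                    "p2": test.p2,
                }
            except (UndefinedStatisticError, ValueError):
                pass
    return summary


def _subgroup_tables(classifications, by_category) -> dict:
    from .classify import Category
    from .model import PhaseGroup, SponsorClass

    flip_ids = {cl.trial_id for cl in by_category[Category.RETROACTIVELY_PROSPECTIVE]}

    def table(group_of, keys):
        out = {}
        for key in keys:
            members = [cl for cl in classifications if group_of(cl) == key]
            n_flip = sum(1 for cl in members if cl.trial_id in flip_ids)
            out[key] = {
                "n": len(members),
                "retroactively_prospective": _cell(n_flip, len(members)),
            }
        return out

    fields = sorted({f for cl in classifications for f in cl.subgroups.fields})
    out = {
        "phase": table(lambda cl: cl.subgroups.phase_group.value,
                       [g.value for g in PhaseGroup]),
        "sponsor": table(lambda cl: cl.subgroups.sponsor_group.value,
                         [g.value for g in SponsorClass]),
        "field": {},
    }
    for field in fields:
        members = [cl for cl in classifications if field in cl.subgroups.fields]
        n_flip = sum(1 for cl in members if cl.trial_id in flip_ids)
        out["field"][field] = {
            "n": len(members),
            "retroactively_prospective": _cell(n_flip, len(members)),
        }
    return out
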