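# Methods

## The audit model

Each trial is represented as a registration (submission) date plus an
ordered list of archived registry versions; every version carries the
overall status, the start date and the completion date as reported at that
time. The audit never sees anything the registry's public history does not
contain, and it is deliberately *windowed*: versions posted more than
`followup_years` (default 5) calendar years after registration are
invisible, so every trial is judged on an equal follow-up. The window
boundary is inclusive — a version posted exactly on the anniversary counts —
and a Feb 29 registration anchors to Feb 28 in non-leap target years.

Two assessments are made per trial:

* **Launch** — the earliest in-window version whose overall status is in
  the launch set (Recruiting, Enrolling by invitation, Active not
  recruiting, Completed, Terminated). Not-yet-recruiting and Withdrawn
  versions do not count as launched; Withdrawn is excluded because a
  withdrawn trial never enrolled anyone.
* **Follow-up** — the latest in-window version.

At each, the version's start date is compared with the registration date:
prospective iff start ≥ registration − grace, retrospective otherwise.
Equality is prospective. When the start date is known only to the month,
*both* sides are truncated to (year, month) before comparing — this is the
only reading under which a month-rounded start can be compared at all
without inventing a day, and it keeps "equality ⇒ prospective". The grace
period (default 0 days) shifts the registration reference back before
truncation.

The two verdicts yield the category: R→P is *retroactively prospective*,
P→R *retroactively retrospective*, otherwise stable. If the launch version
is missing or either decisive version lacks a start date, the trial is
*unclassifiable*: start dates are never imputed from neighbouring
versions, since imputing would manufacture classifications the record does
not support. Unclassifiable counts are carried through to the flowchart
output.

**Eligibility.** A cohort filter keeps trials registered inside a
configured window (e.g. calendar 2015) whose *follow-up version* status is
Completed or Terminated — i.e. trials that finished within the follow-up
horizon. The registry history itself does not say which version's status
defines "completed by follow-up"; using the follow-up version is the
choice made here, since it is the last information inside the equal-window
view.

## Change events and flip timing

A *change event* is an edit of the start date between consecutive
in-window versions. Versions without a start date are skipped and the
comparison resumes at the next present value, so an edit across a gap is
still one event. Day deltas anchor month-precision dates to the first of
the month — the only convention that makes month-level deltas well-defined
and order-preserving.

For a retroactively prospective trial, the *decisive flip* is the change
at the earliest version whose assessment is prospective **and stays
prospective** through the rest of the window (the lasting flip). When the
assessment oscillates (R, P, R, P, …) the transient early flip is not the
decisive one; oscillating trials are logged.

Each change is timed against the completion date *in force when the edit
was made*: only versions up to and including the change version are
consulted (no look-ahead), an Actual completion date is preferred over an
Anticipated one, and within each kind the latest reported value wins. The
change is post-completion iff its version's posting date is strictly later
than that reference, compared at the coarser of the two precisions; with
no usable completion date the timing is undetermined. For control trials
(originally retrospective, not flipped) the timing statistic uses the
*latest* change event.

The launch-to-follow-up displacement per trial is the follow-up start
minus the launch start in days (month dates anchored to day 1); the cohort
summary reports the median and mean over trials with nonzero displacement.

## Statistics

* **Two-proportion test with continuity correction.**
  χ² = N·(max(0, |ad−bc| − N/2))² / ((a+b)(c+d)(a+c)(b+d)), df = 1. The
  statistic clamps at zero when |ad−bc| ≤ N/2 (standard Yates practice)
  and is undefined on a zero margin. P-values use the χ²₁ survival
  function erfc(√(x/2)), accurate to ≤1e−10 against an independent
  reference over x ≤ 100.
* **Power.** Normal approximation *without* continuity correction: with
  Δ = |p₁−p₂|, σ₀² = 2p̄(1−p̄)/n at p̄ = (p₁+p₂)/2 and
  σ₁² = p₁(1−p₁)/n + p₂(1−p₂)/n,
  power = Φ((Δ − z σ₀)/σ₁) + Φ((−Δ − z σ₀)/σ₁). The uncorrected form is
  used because it is the one that yields the canonical "80% at 200 per
  group for 10% vs 20%, α = 0.05" design value (0.802); the corrected
  variant gives ≈0.77. A Monte-Carlo cross-check at 10⁵ replicates agrees
  to well under 0.02.
* **Rendering.** Percentages print to one decimal, rounded half-up
  (158/235 → 67.2), matching table conventions.

## Publication concordance

A publication matches a trial when the NCT number (``NCT`` + 8 digits)
appears among its secondary identifiers or anywhere in its title/abstract
text. The registry's *original* start date is the first one the record
ever reported for retrospectively registered trials, and the launch
version's value for prospectively registered ones. Registry and published
start dates are judged concordant after truncating both to the coarser of
their precisions (a day-level 2015-01-15 agrees with a published "January
2015"); publications reporting no start date are excluded from the
concordance denominator and the excluded count is reported. One
consensus extraction record per (trial, publication) pair is assumed —
inter-rater reconciliation happens upstream of this package.

## Synthetic cohorts

**Stochastic generator** (`generate_stochastic`). Defaults encode the
study conditions of a 2015 registry cohort: p(retrospective at launch) =
0.48, p(flip | retrospective) = 0.04, p(post-completion | flip) = 0.672,
p(edit | retrospective non-flip) = 0.31, version count 2 + Poisson(4.5)
capped at 30 (mean ≈ 6.5), month-precision start dates with probability
0.3 (the registry mixes month- and day-precision starts; the exact share
is not published, 0.3 is a plausible middle ground), registrations uniform
over calendar 2015. Retrospective starts are drawn ≥32 days before
registration so day- and month-level verdicts agree, and flipped starts
land on/after the registration date, so ground-truth labels match the
classifier *exactly*, not just statistically — the generator by design
never produces undetermined pathways, borderline month collisions, or
trials still running at follow-up. Real histories contain all of those,
plus withdrawn/suspended detours and missing fields; passing tests on
synthetic cohorts therefore validate the audit logic, not the messiness
tolerance of any particular export. A single `random.Random(seed)` stream
makes output byte-identical per seed.

**Exact-composition fixture** (`build_exact_fixture`). Six minimal
templates (2–4 versions each: post-completion flip, pre-completion flip,
control with post-completion edit, control with pre-completion edit,
control without edits, stable prospective) are instantiated in exactly the
counts a `CompositionSpec` demands; internal consistency of all cells is
validated on load. Dates derive deterministically from the seed, with
jitter ranges chosen so no draw can cross a category boundary — which is
why every composition cell is reproduced exactly for *any* seed. The
packaged `paper_mirror.yaml` composition realizes the printed counts of
the published 2015 cohort audit; cells the source reports only as
percentages (the Phase-1 denominator, the control post-completion count,
the published-control concordance split) are backed out from the printed
one-decimal percentages and documented in that file. Fixture histories
are deliberately short; the ~6.5-version mean is a property of the
stochastic generator, not the fixture.

## Numerical and degenerate-input choices

* All dates are timezone-free calendar dates; comparisons are pure date
  comparisons.
* The normal quantile in the power formula is computed by bisection on the
  erfc-based CDF to 1e−12 — monotone, bounded and dependency-free.
* Unknown overall-status strings map to `UNKNOWN` with a logged warning
  rather than failing: real exports contain legacy labels. Malformed
  dates, duplicate version numbers, versions predating registration and
  missing columns are hard errors naming the trial and line.
* Empty cohorts, empty change lists and empty extraction sets produce
  zero-count summaries and header-only CSVs, never exceptions; the
  undefined median/mean of an empty displacement set is `None`.
* The audit pipeline contains no randomness and no timestamps; reruns are
  byte-identical.

## Problem sizes

The packaged paper-mirror run processes 11,908 trials (~33,000 versions)
end-to-end in well under a minute on one core; property suites use 50–5,000
trial cohorts, sized so that binomial standard errors make the parameter-
recovery checks meaningful (±3 SE at n = 5,000 resolves 0.04 ± 0.008).

## Known limitations

* Field tagging is keyword-substring matching over condition strings — an
  editable approximation of registry search, with no ontology expansion.
* The completion-date reference for timing prefers information available
  at edit time; an audit preferring the final Actual completion date would
  time a small number of edits differently. Each event's timing verdict is
  recorded per row in `changes.csv` so re-analysis is possible.
* The registration date is the submission date throughout; registries also
  expose a later *posting* date, which this audit does not use.
* Only start-date edits are analyzed; outcome, enrollment and eligibility
  edits are out of scope.
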