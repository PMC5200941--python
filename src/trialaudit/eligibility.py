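"""Trial- and sponsor-level inclusion filters with a per-filter audit trail.

A trial enters the audit denominator only if it is an interventional study,
completed, finished more than a fixed window (default 24 months) before the
as-of date and no earlier than January 2006, in phase 2/3/4 or N/A, has no
results-disposition filing (a formal request to delay posting registry
results), and belongs to a lead sponsor with at least ``min_sponsor_trials``
such trials. Each record keeps the outcome of every filter so the exported
per-trial table can show exactly where a trial dropped out.
"""
from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass, field

from .dates import PartialDate, months_between
from .registry import TrialRecord

__all__ = [
    "FILTER_ORDER",
    "SPONSOR_FILTER",
    "DEFAULT_PHASE_WHITELIST",
    "EligibilityConfig",
    "EligibilityDecision",
    "FilterReport",
    "effective_completion_date",
    "check_trial",
    "filter_sponsors",
    "evaluate_corpus",
]

log = logging.getLogger(__name__)

#: Trial-level filters, in evaluation order.
FILTER_ORDER = ("study_type", "status", "completion_window", "phase", "no_disposition")
#: The corpus-level filter applied after the trial-level cascade.
SPONSOR_FILTER = "sponsor_volume"

#: Phases retained by default. "Phase 1/Phase 2" is excluded because it
#: contains a phase-1 component; override via ``phase_whitelist``.
DEFAULT_PHASE_WHITELIST = frozenset(
    {"phase 2", "phase 2/phase 3", "phase 3", "phase 4", "n/a"}
)


@dataclass(frozen=True)
class EligibilityConfig:
    """Tunable inclusion thresholds.

    as_of_date: the audit census month.
    window_months: completion must be strictly more than this many months
        before ``as_of_date`` (default 24, so results have had time to appear).
    earliest_completion: completion must be in or after this month
        (default January 2006).
    min_sponsor_trials: minimum trial-level-eligible trials a lead sponsor
        needs for its trials to be retained (default 30; applied as >=).
    prefer_primary_completion: when both completion dates are present, use
        primary_completion_date instead of completion_date.
    """

    as_of_date: PartialDate
    window_months: int = 24
    earliest_completion: PartialDate = PartialDate(2006, 1)
    phase_whitelist: frozenset[str] = DEFAULT_PHASE_WHITELIST
    min_sponsor_trials: int = 30
    prefer_primary_completion: bool = False


@dataclass(frozen=True)
class EligibilityDecision:
    """Outcome of the trial-level filter cascade for one record."""

    nct_id: str
    per_filter: dict[str, str]  # filter name -> "pass" | "fail"
    eligible: bool

    @property
    def first_failing(self) -> str | None:
        for name in FILTER_ORDER:
            if self.per_filter.get(name) == "fail":
                return name
        return None


@dataclass
class FilterReport:
    """How many records fell at each filter (first-fail attribution)."""

    counts: dict[str, int] = field(default_factory=dict)
    n_input: int = 0
    n_eligible: int = 0


def effective_completion_date(
    trial: TrialRecord, *, prefer_primary: bool = False
) -> PartialDate | None:
    """The completion date used for window and publication-date comparisons.

    ``completion_date`` takes precedence when both are recorded (flip with
    ``prefer_primary``); falls back to ``primary_completion_date``; absent
    when neither is recorded.
    """
    first, second = trial.completion_date, trial.primary_completion_date
    if prefer_primary:
        first, second = second, first
    return first if first is not None else second


def check_trial(
    trial: TrialRecord,
    as_of: PartialDate,
    *,
    window_months: int = 24,
    earliest_completion: PartialDate = PartialDate(2006, 1),
    phase_whitelist: frozenset[str] = DEFAULT_PHASE_WHITELIST,
    prefer_primary_completion: bool = False,
) -> EligibilityDecision:
    """Evaluate the five trial-level filters, in fixed order.

    Every filter is evaluated (the decision records all outcomes, not just
    the first failure). Missing data fails the filter that needs it.
    The completion window passes iff the effective completion date ``d``
    satisfies ``months_between(d, as_of) > window_months`` and
    ``d >= earliest_completion``, both at month precision.
    """
    per_filter: dict[str, str] = {}

    per_filter["study_type"] = (
        "pass"
        if trial.study_type is not None and trial.study_type.strip().lower() == "interventional"
        else "fail"
    )
    per_filter["status"] = (
        "pass"
        if trial.overall_status is not None and trial.overall_status.strip().lower() == "completed"
        else "fail"
    )

    completion = effective_completion_date(trial, prefer_primary=prefer_primary_completion)
    if completion is None:
        per_filter["completion_window"] = "fail"
    else:
        in_window = (
            months_between(completion, as_of) > window_months
            and completion >= earliest_completion
        )
        per_filter["completion_window"] = "pass" if in_window else "fail"

    per_filter["phase"] = (
        "pass"
        if trial.phase is not None and trial.phase.strip().lower() in phase_whitelist
        else "fail"
    )
    per_filter["no_disposition"] = "fail" if trial.has_results_disposition else "pass"

    eligible = all(per_filter[name] == "pass" for name in FILTER_ORDER)
    return EligibilityDecision(nct_id=trial.nct_id, per_filter=per_filter, eligible=eligible)


def filter_sponsors(
    decisions: list[EligibilityDecision],
    trials: list[TrialRecord],
    min_trials: int = 30,
) -> tuple[list[TrialRecord], FilterReport]:
    """Drop trials of low-volume sponsors; build the cascade report.

    Retains trials whose lead sponsor has at least ``min_trials`` trials
    passing all trial-level filters. The report attributes each excluded
    record to the first filter it failed, with low-volume-sponsor exclusions
    counted under ``sponsor_volume``; totals satisfy
    ``n_input - n_eligible == sum(counts.values())``.
    """
    if min_trials < 1:
        raise ValueError("min_trials must be >= 1")
    by_id = {t.nct_id: t for t in trials}
    report = FilterReport(counts={name: 0 for name in FILTER_ORDER + (SPONSOR_FILTER,)})
    report.n_input = len(decisions)

    volume: Counter[str] = Counter()
    for decision in decisions:
        if decision.eligible:
            volume[by_id[decision.nct_id].lead_sponsor_name] += 1

    eligible: list[TrialRecord] = []
    for decision in decisions:
        trial = by_id[decision.nct_id]
        first = decision.first_failing
        if first is not None:
            report.counts[first] += 1
        elif volume[trial.lead_sponsor_name] < min_trials:
            report.counts[SPONSOR_FILTER] += 1
        else:
            eligible.append(trial)
    report.n_eligible = len(eligible)
    return eligible, report


def evaluate_corpus(
    trials: list[TrialRecord], config: EligibilityConfig
) -> tuple[list[EligibilityDecision], list[TrialRecord], FilterReport]:
    """Run the full cascade (trial-level filters, then sponsor volume)."""
    decisions = [
        check_trial(
            t,
            config.as_of_date,
            window_months=config.window_months,
            earliest_completion=config.earliest_completion,
            phase_whitelist=config.phase_whitelist,
            prefer_primary_completion=config.prefer_primary_completion,
        )
        for t in trials
    ]
    eligible, report = filter_sponsors(decisions, trials, config.min_sponsor_trials)
    return decisions, eligible, report
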