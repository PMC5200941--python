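"""Per-trial verdicts and sponsor/class/corpus statistics.

A trial counts as *reported* if it has structured summary results posted on
the registry (the results-date tag) or at least one accepted results
publication from the linkage stage; otherwise it is *unreported*. Sponsor
and class summaries carry exact rational percentages; display rounding is
round-half-up, applied only at format time.
"""
from __future__ import annotations

import logging
from collections import defaultdict
from dataclasses import dataclass
from fractions import Fraction
from typing import Iterable, Mapping, Sequence

from .linkage import MatchEvidence
from .registry import TrialRecord

__all__ = [
    "DisseminationStatus",
    "SponsorSummary",
    "ConcordanceTable",
    "ascertain",
    "summarize_sponsors",
    "summarize_classes",
    "round_half_up",
    "format_percent",
    "rank",
    "concordance",
]

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class DisseminationStatus:
    """Per-trial verdict plus the evidence trail behind it."""

    nct_id: str
    reported: bool
    sources: frozenset[str]  # subset of {"registry_results", "publication"}
    evidence: tuple[MatchEvidence, ...] = ()


@dataclass(frozen=True)
class SponsorSummary:
    """Audit statistics for one sponsor (or one sponsor class)."""

    sponsor_name: str
    sponsor_class: str
    n_eligible: int
    n_missing: int
    pct_missing: Fraction  # exact, on the 0-100 scale
    unreported_enrollment: int


@dataclass(frozen=True)
class ConcordanceTable:
    """2x2 agreement between this audit and an external per-trial verdict."""

    both_reported: int
    both_unreported: int
    theirs_reported_ours_not: int
    theirs_unreported_ours_reported: int

    @property
    def overlap(self) -> int:
        return (
            self.both_reported
            + self.both_unreported
            + self.theirs_reported_ours_not
            + self.theirs_unreported_ours_reported
        )

    @property
    def ours_reported_pct(self) -> Fraction:
        return Fraction(
            100 * (self.both_reported + self.theirs_unreported_ours_reported),
            self.overlap,
        )

    @property
    def theirs_reported_pct(self) -> Fraction:
        return Fraction(
            100 * (self.both_reported + self.theirs_reported_ours_not),
            self.overlap,
        )


def ascertain(trial: TrialRecord, evidence: Iterable[MatchEvidence]) -> DisseminationStatus:
    """Combine registry results and publication matches into a verdict."""
    evidence = tuple(evidence)
    for item in evidence:
        if item.nct_id != trial.nct_id:
            raise ValueError(
                f"evidence for {item.nct_id} passed to trial {trial.nct_id}"
            )
    sources = set()
    if trial.has_registry_results:
        sources.add("registry_results")
    if any(item.accepted for item in evidence):
        sources.add("publication")
    return DisseminationStatus(
        nct_id=trial.nct_id,
        reported=bool(sources),
        sources=frozenset(sources),
        evidence=evidence,
    )


def _summarize(
    groups: Mapping[tuple[str, str], list[TrialRecord]],
    statuses: Mapping[str, DisseminationStatus],
) -> list[SponsorSummary]:
    summaries = []
    for (name, sponsor_class), members in sorted(groups.items()):
        n_eligible = len(members)
        n_missing = 0
        enrollment = 0
        for trial in members:
            status = statuses[trial.nct_id]
            if not status.reported:
                n_missing += 1
                if trial.enrollment is None:
                    log.info(
                        "unreported trial %s has no enrollment; counted as 0",
                        trial.nct_id,
                    )
                else:
                    enrollment += trial.enrollment
        summaries.append(
            SponsorSummary(
                sponsor_name=name,
                sponsor_class=sponsor_class,
                n_eligible=n_eligible,
                n_missing=n_missing,
                pct_missing=Fraction(100 * n_missing, n_eligible),
                unreported_enrollment=enrollment,
            )
        )
    return summaries


def summarize_sponsors(
    trials: Sequence[TrialRecord], statuses: Mapping[str, DisseminationStatus]
) -> list[SponsorSummary]:
    """One summary per lead sponsor, over the eligible trials given.

    Every trial must have a verdict. Missing enrollment counts as zero in
    the unreported-enrollment sum (logged). Sponsor identity is the exact
    lead-sponsor string; within a sponsor the class of its first trial (in
    nct_id order) is used in the rare event a sponsor spans classes.
    """
    groups: dict[tuple[str, str], list[TrialRecord]] = defaultdict(list)
    class_of: dict[str, str] = {}
    for trial in sorted(trials, key=lambda t: t.nct_id):
        cls = class_of.setdefault(trial.lead_sponsor_name, trial.sponsor_class)
        groups[(trial.lead_sponsor_name, cls)].append(trial)
    return _summarize(groups, statuses)


def summarize_classes(
    trials: Sequence[TrialRecord], statuses: Mapping[str, DisseminationStatus]
) -> list[SponsorSummary]:
    """One summary per sponsor class (industry / NIH / US Fed / other);
    classes with no eligible trials are omitted."""
    groups: dict[tuple[str, str], list[TrialRecord]] = defaultdict(list)
    for trial in trials:
        groups[(trial.sponsor_class, trial.sponsor_class)].append(trial)
    return _summarize(groups, statuses)


def round_half_up(value: Fraction, decimals: int = 0) -> Fraction:
    """Round an exact rational half-up (not banker's) to ``decimals``."""
    scale = 10**decimals
    scaled = value * scale
    # floor(x + 1/2) on exact rationals
    rounded = (2 * scaled.numerator + scaled.denominator) // (2 * scaled.denominator)
    return Fraction(rounded, scale)


def format_percent(n_missing: int, n_eligible: int, decimals: int = 0) -> str:
    """Display text for ``100 * n_missing / n_eligible``, round-half-up."""
    if n_eligible <= 0:
        raise ValueError("n_eligible must be positive")
    if decimals not in (0, 1):
        raise ValueError("decimals must be 0 or 1")
    value = round_half_up(Fraction(100 * n_missing, n_eligible), decimals)
    if decimals == 0:
        return f"{int(value)}%"
    return f"{float(value):.1f}%"


_RANK_KEYS = frozenset({"n_missing", "n_eligible", "pct_missing"})


def rank(
    summaries: Sequence[SponsorSummary],
    key: str = "n_missing",
    descending: bool = True,
) -> list[SponsorSummary]:
    """Order summaries for display.

    Default: highest number of unreported trials first, to surface the
    larger, better-known organisations rather than small sponsors with
    extreme proportions. Ties always break by sponsor name ascending.
    """
    if key not in _RANK_KEYS:
        raise ValueError(f"unknown rank key: {key!r}")
    by_name = sorted(summaries, key=lambda s: s.sponsor_name)
    return sorted(by_name, key=lambda s: getattr(s, key), reverse=descending)


def concordance(
    ours: Mapping[str, bool], theirs: Mapping[str, bool]
) -> ConcordanceTable:
    """2x2 agreement over the trials present in both verdict maps.

    ``ours`` / ``theirs`` map nct_id -> reported?. Trials present in only
    one map are ignored; an empty intersection is an error.
    """
    shared = ours.keys() & theirs.keys()
    if not shared:
        raise ValueError("no overlapping trials between the two verdict sets")
    cells = {(True, True): 0, (False, False): 0, (True, False): 0, (False, True): 0}
    for nct_id in shared:
        cells[(theirs[nct_id], ours[nct_id])] += 1
    return ConcordanceTable(
        both_reported=cells[(True, True)],
        both_unreported=cells[(False, False)],
        theirs_reported_ours_not=cells[(True, False)],
        theirs_unreported_ours_reported=cells[(False, True)],
    )
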