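"""Registry-ID-to-citation linkage and results screening.

Candidate results publications for a trial are citations carrying its NCT
identifier, either in the secondary-ID (registry accession) field — where
journals are required to replicate registry IDs cited in the article — or,
failing that, in the title/abstract text (a small fraction of records carry
the ID only there). Candidates then pass three screens before counting as
results evidence:

* ``post_completion`` — drop papers published before the trial's completion
  month (protocol-era publications cannot report results);
* ``not_protocol`` — drop papers whose title contains "study protocol";
* ``therapy_filter`` — keep only papers satisfying the selected therapy
  clinical-query (broad by default), dropping commentary and secondary
  analyses.
"""
from __future__ import annotations

import logging
import re
from dataclasses import dataclass
from typing import Iterable, Sequence

from .citations import CitationRecord
from .dates import PartialDate
from .eligibility import effective_completion_date
from .queries import FieldedQuery, THERAPY_FILTERS, evaluate_query
from .registry import TrialRecord

__all__ = [
    "MatchEvidence",
    "SCREEN_ORDER",
    "extract_nct_ids",
    "CitationIndex",
    "candidate_citations",
    "screen_post_completion",
    "screen_not_protocol",
    "link_trial",
]

log = logging.getLogger(__name__)

SCREEN_ORDER = ("post_completion", "not_protocol", "therapy_filter")

# NCT followed by exactly eight digits, case-insensitive; a ninth digit or a
# preceding alphanumeric disqualifies the occurrence.
_NCT_TEXT_RE = re.compile(r"(?<![A-Za-z0-9])NCT(\d{8})(?!\d)", re.IGNORECASE)
_NCT_EXACT_RE = re.compile(r"^NCT\d{8}$", re.IGNORECASE)


@dataclass(frozen=True)
class MatchEvidence:
    """One trial-citation candidate pair with its screening outcome."""

    nct_id: str
    pmid: str
    route: str  # "secondary_id" | "text"
    screens: dict[str, str]  # screen name -> "pass" | "fail" | "not-evaluated"
    accepted: bool


def extract_nct_ids(text: str) -> set[str]:
    """All registry identifiers mentioned in free text, upper-cased.

    Matches NCT followed by exactly eight digits (case-insensitive); longer
    digit runs are not registry IDs and are ignored.
    """
    return {f"NCT{m.group(1)}" for m in _NCT_TEXT_RE.finditer(text)}


class CitationIndex:
    """NCT-id -> citation lookup over a corpus, built once.

    For each citation, IDs found in the secondary-ID field take the
    ``secondary_id`` route; IDs found only in title/abstract text take the
    ``text`` route. A citation matching a trial by both carriers is indexed
    once, under ``secondary_id``.
    """

    def __init__(self, corpus: Iterable[CitationRecord]):
        self.by_pmid: dict[str, CitationRecord] = {}
        self._routes: dict[str, dict[str, str]] = {}  # nct_id -> {pmid: route}
        for citation in corpus:
            if citation.pmid in self.by_pmid:
                raise ValueError(f"duplicate pmid in corpus: {citation.pmid}")
            self.by_pmid[citation.pmid] = citation
            secondary = {
                sid.upper()
                for sid in citation.secondary_ids
                if _NCT_EXACT_RE.match(sid.strip())
            }
            text_ids = extract_nct_ids(citation.title + " " + citation.abstract)
            for nct_id in secondary:
                self._routes.setdefault(nct_id, {})[citation.pmid] = "secondary_id"
            for nct_id in text_ids - secondary:
                self._routes.setdefault(nct_id, {}).setdefault(citation.pmid, "text")

    def candidates(self, nct_id: str) -> set[tuple[str, str]]:
        """All ``(pmid, route)`` pairs whose citation mentions ``nct_id``."""
        return {(pmid, route) for pmid, route in self._routes.get(nct_id, {}).items()}


def candidate_citations(
    trial: TrialRecord, corpus: Sequence[CitationRecord] | CitationIndex
) -> set[tuple[str, str]]:
    """Citations carrying the trial's registry ID, with their match route."""
    index = corpus if isinstance(corpus, CitationIndex) else CitationIndex(corpus)
    return index.candidates(trial.nct_id)


def screen_post_completion(citation: CitationRecord, completion: PartialDate) -> bool:
    """Pass iff the citation is not from before the completion month.

    "Before" is strict at month precision: publication in the completion
    month itself passes.
    """
    return citation.pub_date >= completion


def screen_not_protocol(citation: CitationRecord) -> bool:
    """Fail any citation whose title contains "study protocol" (contiguous,
    case-insensitive); the abstract is not consulted."""
    return "study protocol" not in citation.title.lower()


def link_trial(
    trial: TrialRecord,
    corpus: Sequence[CitationRecord] | CitationIndex,
    variant: str = "broad",
    *,
    query: FieldedQuery | None = None,
) -> list[MatchEvidence]:
    """Screen every candidate citation for one trial.

    Returns one :class:`MatchEvidence` per candidate (ordered by PMID), with
    all three screens evaluated; ``accepted`` requires every screen to pass.
    A trial with no completion date cannot be screened for pre-completion
    publication: that screen is marked not-evaluated and treated as passing,
    with a warning.
    """
    if query is None:
        try:
            query = THERAPY_FILTERS[variant]
        except KeyError:
            raise ValueError(f"unknown therapy-filter variant: {variant!r}") from None
    index = corpus if isinstance(corpus, CitationIndex) else CitationIndex(corpus)
    completion = effective_completion_date(trial)
    if completion is None:
        log.warning(
            "trial %s has no completion date; post-completion screen skipped",
            trial.nct_id,
        )

    evidence: list[MatchEvidence] = []
    for pmid, route in sorted(index.candidates(trial.nct_id)):
        citation = index.by_pmid[pmid]
        screens: dict[str, str] = {}
        if completion is None:
            screens["post_completion"] = "not-evaluated"
        else:
            screens["post_completion"] = (
                "pass" if screen_post_completion(citation, completion) else "fail"
            )
        screens["not_protocol"] = "pass" if screen_not_protocol(citation) else "fail"
        screens["therapy_filter"] = "pass" if evaluate_query(query, citation) else "fail"
        accepted = all(v != "fail" for v in screens.values())
        evidence.append(
            MatchEvidence(
                nct_id=trial.nct_id,
                pmid=pmid,
                route=route,
                screens=screens,
                accepted=accepted,
            )
        )
    return evidence
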