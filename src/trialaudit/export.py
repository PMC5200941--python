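"""End-to-end audit runs and the on-disk output feed.

``run_pipeline`` wires the stages together in memory: eligibility cascade,
citation linkage, ascertainment, aggregation. ``run_audit`` is the on-disk
entry point used by the CLI: it loads a registry directory and a citation
corpus, runs the pipeline, and writes the output feed — sponsor and class
summary JSON, a full per-trial CSV (every record before filtering, with its
per-filter audit trail), a filter report, and the parse log. Outputs are
deterministic: fixed key order, sponsors in default rank order, trials by
nct_id, so re-runs on identical inputs are byte-identical.
"""
from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import pandas as pd

from .ascertainment import (
    DisseminationStatus,
    SponsorSummary,
    ascertain,
    format_percent,
    rank,
    summarize_classes,
    summarize_sponsors,
)
from .citations import CitationRecord, read_citations
from .dates import PartialDate
from .eligibility import (
    DEFAULT_PHASE_WHITELIST,
    FILTER_ORDER,
    SPONSOR_FILTER,
    EligibilityConfig,
    EligibilityDecision,
    FilterReport,
    evaluate_corpus,
)
from .linkage import CitationIndex, link_trial
from .registry import TrialRecord, load_registry, write_parse_log

__all__ = ["RunConfig", "AuditError", "AuditResult", "run_pipeline", "run_audit"]

log = logging.getLogger(__name__)


class AuditError(RuntimeError):
    """A run cannot proceed (missing inputs, empty eligible set, ...)."""


@dataclass(frozen=True)
class RunConfig:
    """Configuration of one audit run."""

    registry_dir: Path
    citations_path: Path
    as_of: PartialDate
    out_dir: Path
    min_sponsor_trials: int = 30
    therapy_variant: str = "broad"
    window_months: int = 24
    earliest_completion: PartialDate = PartialDate(2006, 1)
    phase_whitelist: frozenset[str] = DEFAULT_PHASE_WHITELIST
    log_level: str = "INFO"


@dataclass
class AuditResult:
    """Everything one pipeline run computed."""

    trials: list[TrialRecord]
    decisions: dict[str, EligibilityDecision]
    eligible: list[TrialRecord]
    filter_report: FilterReport
    statuses: dict[str, DisseminationStatus]
    sponsor_summaries: list[SponsorSummary]
    class_summaries: list[SponsorSummary]
    parse_log: list[dict] = field(default_factory=list)

    @property
    def n_unreported(self) -> int:
        return sum(1 for s in self.statuses.values() if not s.reported)


def run_pipeline(
    trials: Sequence[TrialRecord],
    citations: Sequence[CitationRecord],
    *,
    as_of: PartialDate,
    min_sponsor_trials: int = 30,
    therapy_variant: str = "broad",
    window_months: int = 24,
    earliest_completion: PartialDate = PartialDate(2006, 1),
    phase_whitelist: frozenset[str] = DEFAULT_PHASE_WHITELIST,
) -> AuditResult:
    """Run the full audit over in-memory corpora."""
    config = EligibilityConfig(
        as_of_date=as_of,
        window_months=window_months,
        earliest_completion=earliest_completion,
        phase_whitelist=phase_whitelist,
        min_sponsor_trials=min_sponsor_trials,
    )
    decisions, eligible, report = evaluate_corpus(list(trials), config)

    index = CitationIndex(citations)
    statuses: dict[str, DisseminationStatus] = {}
    for trial in eligible:
        evidence = link_trial(trial, index, therapy_variant)
        statuses[trial.nct_id] = ascertain(trial, evidence)

    return AuditResult(
        trials=list(trials),
        decisions={d.nct_id: d for d in decisions},
        eligible=eligible,
        filter_report=report,
        statuses=statuses,
        sponsor_summaries=summarize_sponsors(eligible, statuses),
        class_summaries=summarize_classes(eligible, statuses),
    )


def _summary_json(summary: SponsorSummary) -> dict:
    return {
        "name": summary.sponsor_name,
        "class": summary.sponsor_class,
        "n_eligible": summary.n_eligible,
        "n_missing": summary.n_missing,
        "pct_missing": format_percent(summary.n_missing, summary.n_eligible, 0),
        "pct_missing_1dp": format_percent(summary.n_missing, summary.n_eligible, 1),
        "unreported_enrollment": summary.unreported_enrollment,
    }


def _write_json(obj, path: Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(obj, fh, indent=2)
        fh.write("\n")


def write_summaries(summaries: Sequence[SponsorSummary], path: Path) -> None:
    """Write a ranked summary feed (default order: most missing first)."""
    _write_json([_summary_json(s) for s in rank(summaries)], path)


def trials_table(result: AuditResult) -> pd.DataFrame:
    """The full per-trial table: every record before filtering, one row per
    trial, with per-filter flags, eligibility, verdict and evidence routes."""
    eligible_ids = {t.nct_id for t in result.eligible}
    rows = []
    for trial in sorted(result.trials, key=lambda t: t.nct_id):
        decision = result.decisions[trial.nct_id]
        row = {
            "nct_id": trial.nct_id,
            "sponsor": trial.lead_sponsor_name,
            "sponsor_class": trial.sponsor_class,
        }
        for name in FILTER_ORDER:
            row[f"filter_{name}"] = decision.per_filter[name]
        if decision.eligible:
            row[f"filter_{SPONSOR_FILTER}"] = (
                "pass" if trial.nct_id in eligible_ids else "fail"
            )
        else:
            row[f"filter_{SPONSOR_FILTER}"] = "not-evaluated"
        row["eligible"] = trial.nct_id in eligible_ids
        status = result.statuses.get(trial.nct_id)
        row["reported"] = "" if status is None else str(status.reported).lower()
        row["sources"] = "" if status is None else ";".join(sorted(status.sources))
        row["routes"] = (
            ""
            if status is None
            else ";".join(
                sorted({e.route for e in status.evidence if e.accepted})
            )
        )
        row["enrollment"] = "" if trial.enrollment is None else trial.enrollment
        rows.append(row)
    return pd.DataFrame(rows)


def run_audit(config: RunConfig) -> AuditResult:
    """Load inputs, run the audit, write the output feed under ``out_dir``.

    Raises :class:`AuditError` when inputs are missing or no trial survives
    the filters (an empty denominator means the inputs, not the sponsors,
    are the problem).
    """
    registry_dir = Path(config.registry_dir)
    citations_path = Path(config.citations_path)
    if not registry_dir.is_dir():
        raise AuditError(f"registry directory not found: {registry_dir}")
    if not citations_path.is_file():
        raise AuditError(f"citation corpus not found: {citations_path}")

    try:
        trials, parse_log = load_registry(registry_dir)
    except ValueError as exc:
        raise AuditError(str(exc)) from exc
    citations = read_citations(citations_path)

    result = run_pipeline(
        trials,
        citations,
        as_of=config.as_of,
        min_sponsor_trials=config.min_sponsor_trials,
        therapy_variant=config.therapy_variant,
        window_months=config.window_months,
        earliest_completion=config.earliest_completion,
        phase_whitelist=config.phase_whitelist,
    )
    result.parse_log = parse_log

    if not result.eligible:
        raise AuditError(
            "no eligible trials: every record failed the filter cascade "
            f"({dict(result.filter_report.counts)}); check the as-of date "
            "and the sponsor-volume threshold against the corpus"
        )

    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    write_summaries(result.sponsor_summaries, out_dir / "sponsors.json")
    write_summaries(result.class_summaries, out_dir / "classes.json")
    trials_table(result).to_csv(out_dir / "trials.csv", index=False)
    _write_json(
        {
            "n_input": result.filter_report.n_input,
            "n_eligible": result.filter_report.n_eligible,
            "counts": result.filter_report.counts,
        },
        out_dir / "filter_report.json",
    )
    write_parse_log(parse_log, out_dir / "parse_log.jsonl")

    log.info(
        "audit complete: %d/%d trials eligible, %d unreported",
        len(result.eligible), len(result.trials), result.n_unreported,
    )
    return result
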