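"""Synthetic registry and citation corpora with planted ground truth.

Every stage of the audit is testable without network access: this module
emits a registry directory (one XML record per trial, in the dialect
:mod:`trialaudit.registry` parses), a JSON-lines citation corpus, and a
ground-truth table recording what was planted — each trial's eligibility
outcome (and first failing filter), its reporting status and evidence
route, and every decoy citation with the screen expected to reject it.

Planted structure:

* per-sponsor unreported rates are realized **exactly by count** (a 40-trial
  sponsor with rate 0.5 gets exactly 20 unreported trials), so corpus-level
  statistics are exact, not sampled;
* a reported trial posts registry summary results with probability
  ``p_registry_results``; otherwise it receives exactly one
  accepted-by-construction results paper, carrying the NCT ID in the
  secondary-ID field — or, with probability ``p_text_only``, only in the
  abstract text (emulating the small fraction of records whose registry ID
  is never replicated into the secondary-ID field);
* optional decoy citations per trial: a protocol paper ("study protocol" in
  the title), a pre-completion paper, and a commentary failing the therapy
  query — each constructed to fail exactly one screen;
* an optional block of ineligible trials, one per filter failure mode, plus
  a sub-threshold sponsor;
* optional unrelated citations mentioning no eligible trial (some carry
  nine-digit near-miss identifiers).

Generation is deterministic given the seed: one pseudo-random stream,
consumed in a fixed documented order (sponsors in listed order; per trial:
completion month, phase, enrollment, reporting draws, then decoy draws).
"""
from __future__ import annotations

import csv
import random
from dataclasses import dataclass, field
from fractions import Fraction
from pathlib import Path
from typing import Union

import yaml

from .citations import CitationRecord, write_citations
from .dates import PartialDate, months_between, parse_partial_date
from .registry import TrialRecord, serialize_trial_xml

__all__ = [
    "SponsorProfile",
    "FixtureSpec",
    "DecoyTruth",
    "TrialTruth",
    "GroundTruth",
    "generate_corpus",
    "generate",
    "ineligible_block",
    "demo_spec",
    "load_spec",
    "write_ground_truth",
]

_PHASES = ("Phase 2", "Phase 2/Phase 3", "Phase 3", "Phase 4", "N/A")
_DRUGS = ("Acetylzine", "Boravir", "Cortamab", "Dexorel", "Enzapride", "Folinast")
_CONDITIONS = ("hypertension", "asthma", "migraine", "psoriasis", "sepsis", "gout")


@dataclass(frozen=True)
class SponsorProfile:
    name: str
    sponsor_class: str
    n_trials: int
    true_unreported_rate: float


@dataclass(frozen=True)
class FixtureSpec:
    """Parameters of a planted corpus. See the module docstring."""

    sponsor_profiles: tuple[SponsorProfile, ...]
    seed: int = 0
    as_of: PartialDate = PartialDate(2016, 10)
    p_registry_results: float = 0.4
    p_text_only: float = 0.015
    p_protocol_decoy: float = 0.15
    p_precompletion_decoy: float = 0.05
    p_commentary_decoy: float = 0.15
    n_unrelated: int = 0
    include_ineligible: bool = True
    date_window: tuple[PartialDate, PartialDate] = (
        PartialDate(2006, 6),
        PartialDate(2014, 9),
    )

    @property
    def n_trials(self) -> int:
        return sum(p.n_trials for p in self.sponsor_profiles)

    def validate(self) -> None:
        if not self.sponsor_profiles:
            raise ValueError("fixture spec needs at least one sponsor profile")
        for p in self.sponsor_profiles:
            if p.n_trials < 1:
                raise ValueError(f"sponsor {p.name!r}: n_trials must be >= 1")
            if not 0.0 <= p.true_unreported_rate <= 1.0:
                raise ValueError(f"sponsor {p.name!r}: rate outside [0, 1]")
        for name in (
            "p_registry_results",
            "p_text_only",
            "p_protocol_decoy",
            "p_precompletion_decoy",
            "p_commentary_decoy",
        ):
            value = getattr(self, name)
            if not 0.0 <= value <= 1.0:
                raise ValueError(f"{name} outside [0, 1]: {value}")
        if self.n_unrelated < 0:
            raise ValueError("n_unrelated must be >= 0")
        earliest, latest = self.date_window
        if earliest > latest:
            raise ValueError("date_window earliest after latest")
        if months_between(latest, self.as_of) <= 24:
            raise ValueError(
                "date_window must end more than 24 months before as_of, "
                "or planted-eligible trials would fail the completion window"
            )


@dataclass(frozen=True)
class DecoyTruth:
    pmid: str
    screen: str  # the screen expected to reject this citation


@dataclass(frozen=True)
class TrialTruth:
    """What was planted for one trial. ``reported`` is None for trials the
    audit should exclude before ascertainment."""

    nct_id: str
    sponsor: str
    sponsor_class: str
    eligible: bool
    first_failing: str | None
    reported: bool | None
    source: str | None  # "registry_results" | "publication" | None
    route: str | None  # "secondary_id" | "text" | None
    decoys: tuple[DecoyTruth, ...] = ()


@dataclass
class GroundTruth:
    trials: dict[str, TrialTruth] = field(default_factory=dict)

    @property
    def eligible_ids(self) -> set[str]:
        return {t.nct_id for t in self.trials.values() if t.eligible}

    @property
    def n_eligible(self) -> int:
        return len(self.eligible_ids)

    @property
    def n_unreported(self) -> int:
        return sum(
            1 for t in self.trials.values() if t.eligible and t.reported is False
        )

    @property
    def pct_missing(self) -> Fraction:
        return Fraction(100 * self.n_unreported, self.n_eligible)


def _add_months(date: PartialDate, delta: int) -> PartialDate:
    total = date.year * 12 + (date.month - 1) + delta
    return PartialDate(total // 12, total % 12 + 1)


def _random_month(rng: random.Random, window: tuple[PartialDate, PartialDate]) -> PartialDate:
    span = months_between(window[0], window[1])
    return _add_months(window[0], rng.randint(0, span))


class _Counter:
    def __init__(self, prefix: str, start: int, width: int):
        self.prefix, self.value, self.width = prefix, start, width

    def next(self) -> str:
        self.value += 1
        return f"{self.prefix}{self.value:0{self.width}d}"


def _results_paper(
    rng: random.Random,
    pmid: str,
    nct_id: str,
    completion: PartialDate,
    text_only: bool,
) -> CitationRecord:
    drug = rng.choice(_DRUGS)
    cond = rng.choice(_CONDITIONS)
    pub_date = _add_months(completion, rng.randint(0, 18))
    abstract = (
        f"Outcomes were assessed in adults with {cond}. "
        f"{drug} improved the primary endpoint versus placebo."
    )
    secondary: frozenset[str] = frozenset()
    if text_only:
        abstract += f" Registered at ClinicalTrials.gov ({nct_id})."
    else:
        secondary = frozenset({nct_id})
    return CitationRecord(
        pmid=pmid,
        title=f"{drug} for {cond}: a randomized controlled trial",
        abstract=abstract,
        pub_date=pub_date,
        mesh_terms=frozenset({"Humans", cond.capitalize()}),
        publication_types=frozenset({"Journal Article", "Randomized Controlled Trial"}),
        subheadings=frozenset({"therapeutic use"}),
        secondary_ids=secondary,
    )


def _decoy(
    rng: random.Random,
    kind: str,
    pmid: str,
    nct_id: str,
    completion: PartialDate,
) -> tuple[CitationRecord, DecoyTruth]:
    drug = rng.choice(_DRUGS)
    cond = rng.choice(_CONDITIONS)
    if kind == "protocol":
        citation = CitationRecord(
            pmid=pmid,
            title=f"{drug} for {cond}: study protocol for a randomized controlled trial",
            abstract=f"This paper describes the design of a trial in {cond}.",
            pub_date=_add_months(completion, rng.randint(0, 6)),
            mesh_terms=frozenset({"Humans"}),
            publication_types=frozenset({"Journal Article"}),
            secondary_ids=frozenset({nct_id}),
        )
        return citation, DecoyTruth(pmid, "not_protocol")
    if kind == "precompletion":
        citation = CitationRecord(
            pmid=pmid,
            title=f"{drug} for {cond}: a randomized controlled trial",
            abstract=f"Baseline characteristics of participants with {cond}.",
            pub_date=_add_months(completion, -rng.randint(1, 12)),
            mesh_terms=frozenset({"Humans"}),
            publication_types=frozenset({"Journal Article", "Randomized Controlled Trial"}),
            secondary_ids=frozenset({nct_id}),
        )
        return citation, DecoyTruth(pmid, "post_completion")
    if kind == "commentary":
        citation = CitationRecord(
            pmid=pmid,
            title=f"Comment on {cond} management",
            abstract=f"An editorial discussing recent findings in {cond} ({nct_id}).",
            pub_date=_add_months(completion, rng.randint(1, 12)),
            mesh_terms=frozenset({"Humans"}),
            publication_types=frozenset({"Comment"}),
        )
        return citation, DecoyTruth(pmid, "therapy_filter")
    raise ValueError(f"unknown decoy kind: {kind}")


def ineligible_block(
    spec: FixtureSpec, *, nct_start: int = 90_000_000
) -> tuple[list[TrialRecord], list[TrialTruth]]:
    """Trials planted to fail each filter, one per failure mode.

    The block is attribute-fixed (no random draws): an observational study,
    a terminated study, a too-recent completion, a pre-2006 completion, a
    phase-1 study, a disposition filing, and a two-trial sponsor that fails
    the sponsor-volume threshold. All other attributes are
    eligible-compatible, so each trial's *first* failing filter is the
    planted one.
    """
    sponsor = spec.sponsor_profiles[0]
    good_date = spec.date_window[0]

    def make(offset: int, first_failing: str | None, **overrides) -> tuple[TrialRecord, TrialTruth]:
        base = dict(
            nct_id=f"NCT{nct_start + offset:08d}",
            study_type="Interventional",
            overall_status="Completed",
            phase="Phase 3",
            completion_date=good_date,
            lead_sponsor_name=sponsor.name,
            sponsor_class=sponsor.sponsor_class,
            enrollment=100,
        )
        base.update(overrides)
        trial = TrialRecord(**base)
        truth = TrialTruth(
            nct_id=trial.nct_id,
            sponsor=trial.lead_sponsor_name,
            sponsor_class=trial.sponsor_class,
            eligible=False,
            first_failing=first_failing,
            reported=None,
            source=None,
            route=None,
        )
        return trial, truth

    planted = [
        make(1, "study_type", study_type="Observational"),
        make(2, "status", overall_status="Terminated"),
        make(3, "completion_window", completion_date=_add_months(spec.as_of, -12)),
        make(4, "completion_window", completion_date=PartialDate(2005, 12)),
        make(5, "phase", phase="Phase 1"),
        make(6, "no_disposition", has_results_disposition=True),
        make(
            7, "sponsor_volume",
            lead_sponsor_name="Understudied Clinic", sponsor_class="other",
        ),
        make(
            8, "sponsor_volume",
            lead_sponsor_name="Understudied Clinic", sponsor_class="other",
        ),
    ]
    return [t for t, _ in planted], [truth for _, truth in planted]


def generate_corpus(
    spec: FixtureSpec,
) -> tuple[list[TrialRecord], list[CitationRecord], GroundTruth]:
    """Build the in-memory corpora and ground truth for ``spec``."""
    spec.validate()
    rng = random.Random(spec.seed)
    nct = _Counter("NCT", 0, 8)
    pmid = _Counter("", 9_000_000, 0)

    trials: list[TrialRecord] = []
    citations: list[CitationRecord] = []
    truth = GroundTruth()

    for profile in spec.sponsor_profiles:
        n_unreported = int(profile.true_unreported_rate * profile.n_trials + 0.5)
        reported_flags = [False] * n_unreported + [True] * (
            profile.n_trials - n_unreported
        )
        rng.shuffle(reported_flags)

        for reported in reported_flags:
            nct_id = nct.next()
            completion = _random_month(rng, spec.date_window)
            phase = rng.choice(_PHASES)
            enrollment = rng.randint(10, 800)

            source: str | None = None
            route: str | None = None
            if reported:
                if rng.random() < spec.p_registry_results:
                    source = "registry_results"
                else:
                    source = "publication"
                    route = (
                        "text" if rng.random() < spec.p_text_only else "secondary_id"
                    )
                    citations.append(
                        _results_paper(
                            rng, pmid.next(), nct_id, completion, route == "text"
                        )
                    )

            decoys: list[DecoyTruth] = []
            for kind, p in (
                ("protocol", spec.p_protocol_decoy),
                ("precompletion", spec.p_precompletion_decoy),
                ("commentary", spec.p_commentary_decoy),
            ):
                if rng.random() < p:
                    citation, decoy = _decoy(rng, kind, pmid.next(), nct_id, completion)
                    citations.append(citation)
                    decoys.append(decoy)

            trials.append(
                TrialRecord(
                    nct_id=nct_id,
                    study_type="Interventional",
                    overall_status="Completed",
                    phase=phase,
                    completion_date=completion,
                    lead_sponsor_name=profile.name,
                    sponsor_class=profile.sponsor_class,
                    enrollment=enrollment,
                    has_registry_results=source == "registry_results",
                )
            )
            truth.trials[nct_id] = TrialTruth(
                nct_id=nct_id,
                sponsor=profile.name,
                sponsor_class=profile.sponsor_class,
                eligible=True,
                first_failing=None,
                reported=reported,
                source=source,
                route=route,
                decoys=tuple(decoys),
            )

    if spec.include_ineligible:
        block_trials, block_truths = ineligible_block(spec)
        trials.extend(block_trials)
        for t in block_truths:
            truth.trials[t.nct_id] = t

    for _ in range(spec.n_unrelated):
        cond = rng.choice(_CONDITIONS)
        near_miss = rng.random() < 0.25
        abstract = f"A narrative review of {cond} epidemiology."
        if near_miss:
            # nine digits: must never be read as a registry ID
            abstract += f" (see report NCT{rng.randint(0, 10**9 - 1):09d})"
        citations.append(
            CitationRecord(
                pmid=pmid.next(),
                title=f"Advances in {cond} management",
                abstract=abstract,
                pub_date=_random_month(rng, spec.date_window),
                mesh_terms=frozenset({"Humans"}),
                publication_types=frozenset({"Review"}),
            )
        )

    return trials, citations, truth


def write_ground_truth(truth: GroundTruth, path: Union[str, Path]) -> None:
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(
            ["nct_id", "sponsor", "sponsor_class", "eligible", "first_failing",
             "reported", "source", "route", "decoys"]
        )
        for nct_id in sorted(truth.trials):
            t = truth.trials[nct_id]
            writer.writerow([
                t.nct_id, t.sponsor, t.sponsor_class,
                str(t.eligible).lower(),
                t.first_failing or "",
                "" if t.reported is None else str(t.reported).lower(),
                t.source or "", t.route or "",
                ";".join(f"{d.pmid}:{d.screen}" for d in t.decoys),
            ])


def generate(spec: FixtureSpec, out_dir: Union[str, Path]) -> GroundTruth:
    """Write the corpora for ``spec`` under ``out_dir``.

    Produces ``registry/<nct_id>.xml``, ``citations.jsonl`` and
    ``ground_truth.csv``; byte-identical across runs with the same spec.
    """
    out_dir = Path(out_dir)
    registry_dir = out_dir / "registry"
    registry_dir.mkdir(parents=True, exist_ok=True)

    trials, citations, truth = generate_corpus(spec)
    for trial in trials:
        (registry_dir / f"{trial.nct_id}.xml").write_bytes(serialize_trial_xml(trial))
    write_citations(citations, out_dir / "citations.jsonl")
    write_ground_truth(truth, out_dir / "ground_truth.csv")
    return truth


def demo_spec(seed: int = 20161020) -> FixtureSpec:
    """A small three-sponsor corpus used by the examples and test suite."""
    return FixtureSpec(
        sponsor_profiles=(
            SponsorProfile("Bolingbrook Pharma", "industry", 40, 0.25),
            SponsorProfile("National Institute of Trial Sciences", "NIH", 36, 0.5),
            SponsorProfile("St. Swithin's University Hospital", "other", 44, 0.75),
        ),
        seed=seed,
        n_unrelated=25,
    )


def load_spec(path: Union[str, Path]) -> FixtureSpec:
    """Read a fixture spec from a YAML file.

    Schema::

        seed: 7
        as_of: 2016-10
        p_registry_results: 0.4
        p_text_only: 0.015
        p_protocol_decoy: 0.15
        p_precompletion_decoy: 0.05
        p_commentary_decoy: 0.15
        n_unrelated: 25
        include_ineligible: true
        date_window: ["2006-06", "2014-09"]
        sponsors:
          - {name: Example Pharma, class: industry, n_trials: 40, unreported_rate: 0.5}
    """
    with open(path, encoding="utf-8") as fh:
        raw = yaml.safe_load(fh)
    if not isinstance(raw, dict) or "sponsors" not in raw:
        raise ValueError(f"fixture spec {path} must be a mapping with a 'sponsors' list")
    profiles = tuple(
        SponsorProfile(
            name=s["name"],
            sponsor_class=s.get("class", "other"),
            n_trials=int(s["n_trials"]),
            true_unreported_rate=float(s["unreported_rate"]),
        )
        for s in raw["sponsors"]
    )
    kwargs: dict = {"sponsor_profiles": profiles}
    for key in (
        "seed", "p_registry_results", "p_text_only", "p_protocol_decoy",
        "p_precompletion_decoy", "p_commentary_decoy", "n_unrelated",
        "include_ineligible",
    ):
        if key in raw:
            kwargs[key] = raw[key]
    if "as_of" in raw:
        kwargs["as_of"] = parse_partial_date(str(raw["as_of"]))
    if "date_window" in raw:
        earliest, latest = raw["date_window"]
        kwargs["date_window"] = (
            parse_partial_date(str(earliest)),
            parse_partial_date(str(latest)),
        )
    spec = FixtureSpec(**kwargs)
    spec.validate()
    return spec
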