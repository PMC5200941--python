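import math
from dataclasses import replace
from fractions import Fraction

import pytest

from trialaudit.dates import PartialDate
from trialaudit.eligibility import FILTER_ORDER
from trialaudit.export import run_pipeline
from trialaudit.synthetic import (
    FixtureSpec,
    SponsorProfile,
    demo_spec,
    generate,
    generate_corpus,
    ineligible_block,
    load_spec,
)

AS_OF = PartialDate(2016, 10)


def one_sponsor_spec(n=40, rate=0.5, seed=7, **kwargs):
    return FixtureSpec(
        sponsor_profiles=(SponsorProfile("Example Pharma", "industry", n, rate),),
        seed=seed,
        include_ineligible=False,
        **kwargs,
    )


def test_unreported_rates_realized_exactly_by_count():
    _, _, truth = generate_corpus(one_sponsor_spec(40, 0.5, seed=7))
    assert truth.n_eligible == 40
    assert truth.n_unreported == 20
    assert truth.pct_missing == Fraction(50)


@pytest.mark.parametrize("n,rate,expected", [(35, 0.0, 0), (35, 1.0, 35), (49, 0.9, 44)])
def test_exact_count_rounding(n, rate, expected):
    _, _, truth = generate_corpus(one_sponsor_spec(n, rate))
    assert truth.n_unreported == expected


def test_protocol_decoy_probability_one_plants_one_decoy_per_trial():
    spec = one_sponsor_spec(10, 0.5, p_protocol_decoy=1.0,
                            p_precompletion_decoy=0.0, p_commentary_decoy=0.0)
    _, citations, truth = generate_corpus(spec)
    by_pmid = {c.pmid: c for c in citations}
    for t in truth.trials.values():
        protocol_decoys = [d for d in t.decoys if d.screen == "not_protocol"]
        assert len(protocol_decoys) == 1
        assert "study protocol" in by_pmid[protocol_decoys[0].pmid].title.lower()


def test_same_seed_gives_byte_identical_output(tmp_path):
    spec = demo_spec()
    generate(spec, tmp_path / "a")
    generate(spec, tmp_path / "b")
    files_a = sorted(p.relative_to(tmp_path / "a") for p in (tmp_path / "a").rglob("*") if p.is_file())
    files_b = sorted(p.relative_to(tmp_path / "b") for p in (tmp_path / "b").rglob("*") if p.is_file())
    assert files_a == files_b and len(files_a) > 3
    for rel in files_a:
        assert (tmp_path / "a" / rel).read_bytes() == (tmp_path / "b" / rel).read_bytes()


def test_different_seeds_differ():
    _, _, t1 = generate_corpus(one_sponsor_spec(seed=1))
    _, _, t2 = generate_corpus(one_sponsor_spec(seed=2))
    reported1 = [t.reported for t in t1.trials.values()]
    reported2 = [t.reported for t in t2.trials.values()]
    assert reported1 != reported2  # same counts, different placement


def test_ineligible_block_plants_one_failure_per_mode():
    spec = demo_spec()
    trials, truths = ineligible_block(spec)
    planted = [t.first_failing for t in truths]
    for name in FILTER_ORDER:
        assert name in planted
    assert planted.count("sponsor_volume") == 2
    assert planted.count("completion_window") == 2  # too recent + pre-2006
    assert all(not t.eligible for t in truths)
    assert len({t.nct_id for t in trials}) == len(trials)


@pytest.mark.parametrize(
    "bad",
    [
        dict(p_text_only=1.5),
        dict(n_unrelated=-1),
        dict(date_window=(PartialDate(2014, 1), PartialDate(2010, 1))),
        dict(date_window=(PartialDate(2014, 1), PartialDate(2015, 6))),  # inside window
        dict(sponsor_profiles=()),
        dict(sponsor_profiles=(SponsorProfile("X", "other", 5, 1.2),)),
    ],
)
def test_inconsistent_spec_rejected(bad):
    spec = replace(one_sponsor_spec(), **bad)
    with pytest.raises(ValueError):
        spec.validate()


def test_end_to_end_ground_truth_recovery(demo_corpus):
    """The full pipeline reproduces everything the generator planted."""
    trials, citations, truth = demo_corpus
    result = run_pipeline(trials, citations, as_of=AS_OF)

    assert {t.nct_id for t in result.eligible} == truth.eligible_ids
    eligible_ids = truth.eligible_ids
    for nct_id, planted in truth.trials.items():
        decision = result.decisions[nct_id]
        if planted.first_failing in FILTER_ORDER:
            assert decision.first_failing == planted.first_failing
        elif planted.first_failing == "sponsor_volume":
            assert decision.eligible and nct_id not in eligible_ids
        if not planted.eligible:
            continue
        status = result.statuses[nct_id]
        assert status.reported == planted.reported
        if planted.source == "registry_results":
            assert status.sources == {"registry_results"}
        elif planted.source == "publication":
            assert "publication" in status.sources
            assert {e.route for e in status.evidence if e.accepted} == {planted.route}
        else:
            assert status.sources == frozenset()
        # every planted decoy is rejected at exactly the planted screen
        evidence_by_pmid = {e.pmid: e for e in status.evidence}
        for decoy in planted.decoys:
            screens = evidence_by_pmid[decoy.pmid].screens
            assert not evidence_by_pmid[decoy.pmid].accepted
            assert screens[decoy.screen] == "fail"
            assert all(v == "pass" for k, v in screens.items() if k != decoy.screen)


def test_corpus_pct_missing_equals_planted_rate(demo_corpus):
    trials, citations, truth = demo_corpus
    result = run_pipeline(trials, citations, as_of=AS_OF)
    assert Fraction(100 * result.n_unreported, len(result.eligible)) == truth.pct_missing


def test_text_only_route_fraction_converges_to_planted_probability():
    """Across seeds, the share of results papers carrying the registry ID
    only in the abstract is binomial around p_text_only (checked at 3 sigma)."""
    p = 0.015
    text_only = total = 0
    for seed in range(40):
        spec = one_sponsor_spec(60, 0.0, seed=seed, p_registry_results=0.0,
                                p_protocol_decoy=0.0, p_precompletion_decoy=0.0,
                                p_commentary_decoy=0.0)
        _, _, truth = generate_corpus(spec)
        routes = [t.route for t in truth.trials.values() if t.source == "publication"]
        total += len(routes)
        text_only += sum(1 for r in routes if r == "text")
    assert total == 2400
    tolerance = 3 * math.sqrt(p * (1 - p) / total)
    assert abs(text_only / total - p) <= tolerance


def test_load_spec_round_trip(tmp_path):
    spec_file = tmp_path / "fixture.yaml"
    spec_file.write_text(
        """
seed: 11
as_of: 2016-10
p_registry_results: 0.3
n_unrelated: 5
date_window: ["2007-01", "2013-12"]
sponsors:
  - {name: Alpha, class: industry, n_trials: 12, unreported_rate: 0.25}
  - {name: Beta, class: NIH, n_trials: 8, unreported_rate: 0.5}
"""
    )
    spec = load_spec(spec_file)
    assert spec.seed == 11
    assert spec.n_trials == 20
    assert spec.date_window == (PartialDate(2007, 1), PartialDate(2013, 12))
    assert spec.sponsor_profiles[1].true_unreported_rate == 0.5


def test_load_spec_rejects_malformed_file(tmp_path):
    bad = tmp_path / "bad.yaml"
    bad.write_text("just a string")
    with pytest.raises(ValueError):
        load_spec(bad)


def test_generated_files_reload_cleanly(tmp_path):
    from trialaudit.citations import read_citations
    from trialaudit.registry import load_registry

    spec = one_sponsor_spec(8, 0.5, n_unrelated=3)
    generate(spec, tmp_path)
    records, log = load_registry(tmp_path / "registry")
    assert len(records) == 8 and log == []
    citations = read_citations(tmp_path / "citations.jsonl")
    in_memory = generate_corpus(spec)[1]
    assert citations == in_memory
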