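from fractions import Fraction

import pytest

from trialaudit.ascertainment import (
    ConcordanceTable,
    SponsorSummary,
    ascertain,
    concordance,
    format_percent,
    rank,
    round_half_up,
    summarize_classes,
    summarize_sponsors,
)
from trialaudit.linkage import MatchEvidence
from trialaudit.registry import TrialRecord


def make_trial(nct=1, sponsor="Example Pharma", cls="industry", enrollment=100,
               registry_results=False):
    return TrialRecord(
        nct_id=f"NCT{nct:08d}", lead_sponsor_name=sponsor, sponsor_class=cls,
        enrollment=enrollment, has_registry_results=registry_results,
    )


def make_evidence(nct_id, accepted, pmid="99"):
    screens = {"post_completion": "pass", "not_protocol": "pass",
               "therapy_filter": "pass" if accepted else "fail"}
    return MatchEvidence(nct_id=nct_id, pmid=pmid, route="secondary_id",
                         screens=screens, accepted=accepted)


class TestAscertain:
    def test_registry_results_alone_suffice(self):
        status = ascertain(make_trial(registry_results=True), [])
        assert status.reported and status.sources == {"registry_results"}

    def test_accepted_publication_alone_suffices(self):
        trial = make_trial()
        status = ascertain(trial, [make_evidence(trial.nct_id, True)])
        assert status.reported and status.sources == {"publication"}

    def test_only_rejected_matches_leave_trial_unreported(self):
        trial = make_trial()
        status = ascertain(trial, [make_evidence(trial.nct_id, False)])
        assert not status.reported and status.sources == frozenset()

    def test_foreign_evidence_rejected(self):
        with pytest.raises(ValueError):
            ascertain(make_trial(1), [make_evidence("NCT00000002", True)])


def _statuses(trials, unreported_ids):
    return {
        t.nct_id: ascertain(
            t, [] if t.nct_id in unreported_ids else [make_evidence(t.nct_id, True)]
        )
        for t in trials
    }


def test_summaries_conserve_corpus_totals():
    trials = (
        [make_trial(i, "GSK-ish", "industry") for i in range(10)]
        + [make_trial(100 + i, "Uni Hospital", "other") for i in range(6)]
    )
    unreported = {"NCT00000000", "NCT00000001", "NCT00000100"}
    statuses = _statuses(trials, unreported)
    sponsors = summarize_sponsors(trials, statuses)
    classes = summarize_classes(trials, statuses)
    for summaries in (sponsors, classes):
        assert sum(s.n_eligible for s in summaries) == len(trials)
        assert sum(s.n_missing for s in summaries) == len(unreported)
        for s in summaries:
            assert 0 <= s.n_missing <= s.n_eligible
            assert s.pct_missing == Fraction(100 * s.n_missing, s.n_eligible)
    by_name = {s.sponsor_name: s for s in sponsors}
    assert by_name["GSK-ish"].n_missing == 2
    assert by_name["Uni Hospital"].pct_missing == Fraction(100, 6)


def test_missing_enrollment_counts_zero_in_unreported_sum():
    trials = [make_trial(1, enrollment=500), make_trial(2, enrollment=None)]
    statuses = _statuses(trials, {"NCT00000001", "NCT00000002"})
    (summary,) = summarize_sponsors(trials, statuses)
    assert summary.unreported_enrollment == 500


def test_single_trial_sponsor_fully_unreported_is_100_percent():
    trials = [make_trial(1, "Solo")]
    (summary,) = summarize_sponsors(trials, _statuses(trials, {"NCT00000001"}))
    assert summary.n_missing == summary.n_eligible == 1
    assert summary.pct_missing == Fraction(100)


def test_empty_class_omitted():
    trials = [make_trial(1, cls="industry")]
    classes = summarize_classes(trials, _statuses(trials, set()))
    assert [s.sponsor_name for s in classes] == ["industry"]


# Every printed table row of the audit this package reproduces, plus the
# corpus and class figures: all consistent with round-half-up display.
PRINTED_ROWS = [
    (285, 435, 0, "66%"), (201, 534, 0, "38%"), (194, 558, 0, "35%"),
    (186, 292, 0, "64%"), (183, 809, 0, "23%"), (125, 612, 0, "20%"),
    (62, 471, 0, "13%"), (35, 35, 0, "100%"), (32, 35, 0, "91%"),
    (27, 30, 0, "90%"), (44, 49, 0, "90%"), (39, 44, 0, "89%"),
    (0, 96, 0, "0%"), (1, 32, 0, "3%"), (5, 115, 0, "4%"),
    (15, 292, 0, "5%"), (3, 58, 0, "5%"),
    (11714, 25927, 1, "45.2%"), (2390, 8799, 1, "27.2%"),
    (122, 470, 1, "26.0%"), (361, 996, 1, "36.2%"), (8841, 15662, 1, "56.4%"),
]


@pytest.mark.parametrize("n_missing,n_eligible,decimals,expected", PRINTED_ROWS)
def test_format_percent_reproduces_printed_rows(n_missing, n_eligible, decimals, expected):
    assert format_percent(n_missing, n_eligible, decimals) == expected


def test_rounding_is_half_up_not_bankers():
    assert format_percent(45, 200, 0) == "23%"  # 22.5 -> 23 (banker's: 22)
    assert format_percent(1, 16, 1) == "6.3%"  # 6.25 -> 6.3 (banker's: 6.2)
    assert round_half_up(Fraction(5, 2)) == 3
    assert round_half_up(Fraction(-1, 2)) == 0  # floor(x + 1/2) convention


def test_format_percent_rejects_empty_denominator():
    with pytest.raises(ValueError):
        format_percent(0, 0)


def make_summary(name, n_missing, n_eligible, cls="other"):
    return SponsorSummary(
        sponsor_name=name, sponsor_class=cls, n_eligible=n_eligible,
        n_missing=n_missing, pct_missing=Fraction(100 * n_missing, n_eligible),
        unreported_enrollment=0,
    )


class TestRank:
    summaries = [
        make_summary("GammaCorp", 183, 809),
        make_summary("AlphaPharma", 285, 435),
        make_summary("BetaBio", 183, 400),
        make_summary("DeltaInstitute", 35, 35),
    ]

    def test_default_is_most_missing_first_ties_alphabetical(self):
        names = [s.sponsor_name for s in rank(self.summaries)]
        assert names == ["AlphaPharma", "BetaBio", "GammaCorp", "DeltaInstitute"]

    def test_percent_key_puts_fully_missing_sponsor_first(self):
        names = [s.sponsor_name for s in rank(self.summaries, key="pct_missing")]
        assert names[0] == "DeltaInstitute"

    def test_rank_is_an_idempotent_permutation(self):
        once = rank(self.summaries, key="n_eligible", descending=False)
        assert sorted(s.sponsor_name for s in once) == sorted(
            s.sponsor_name for s in self.summaries
        )
        assert rank(once, key="n_eligible", descending=False) == once

    def test_unknown_key_rejected(self):
        with pytest.raises(ValueError):
            rank(self.summaries, key="enrollment")


def _verdict_maps(both_rep, both_unrep, theirs_only, ours_only):
    ours, theirs = {}, {}
    i = 0
    for count, (their_v, our_v) in [
        (both_rep, (True, True)), (both_unrep, (False, False)),
        (theirs_only, (True, False)), (ours_only, (False, True)),
    ]:
        for _ in range(count):
            ours[f"NCT{i:08d}"] = our_v
            theirs[f"NCT{i:08d}"] = their_v
            i += 1
    return ours, theirs


class TestConcordance:
    def test_printed_cells_give_60_percent_ours_reported(self):
        ours, theirs = _verdict_maps(1149, 534, 497, 382)
        table = concordance(ours, theirs)
        assert table == ConcordanceTable(1149, 534, 497, 382)
        assert table.overlap == 2562
        assert round_half_up(table.ours_reported_pct) == 60

    def test_identical_verdicts_have_empty_off_diagonal(self):
        ours, _ = _verdict_maps(3, 2, 0, 0)
        table = concordance(ours, dict(ours))
        assert table.theirs_reported_ours_not == 0
        assert table.theirs_unreported_ours_reported == 0

    def test_single_disagreement(self):
        table = concordance({"NCT00000001": False}, {"NCT00000001": True})
        assert table.theirs_reported_ours_not == 1
        assert table.overlap == 1

    def test_only_the_intersection_counts(self):
        ours = {"NCT00000001": True, "NCT00000002": False}
        theirs = {"NCT00000001": True, "NCT00000009": True}
        assert concordance(ours, theirs).overlap == 1

    def test_empty_intersection_is_an_error(self):
        with pytest.raises(ValueError):
            concordance({"NCT00000001": True}, {"NCT00000002": True})
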