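# trialaudit

An audit engine for clinical-trial results transparency. Roughly half of
registered clinical trials never make their results public — a systematic
bias that distorts the evidence base doctors and patients rely on. Manual
publication-bias cohort studies are accurate but expensive one-off sweeps;
`trialaudit` implements the automated alternative: given a registry
snapshot (per-trial XML records in the 2016-era clinicaltrials.gov dialect)
and a local citation corpus (PubMed-style records), it determines which
completed trials have **no discoverable results** — neither structured
summary results posted on the registry nor a matched results publication —
and ranks sponsors by their share of missing results. It is written for
meta-researchers, transparency campaigners and sponsors auditing their own
portfolio.

## Method

1. **Eligibility cascade.** A trial enters the denominator iff it is
   interventional, completed, finished strictly more than 24 months before
   the as-of date and no earlier than January 2006, in phase 2, 2/3, 3, 4
   or N/A, has no results-disposition filing (a formal request to delay
   posting), and its lead sponsor has ≥ 30 such trials. Every record keeps
   a per-filter audit trail.
2. **Results ascertainment.** A trial counts as *reported* if (a) the
   registry carries structured summary results (the results-date tag), or
   (b) some citation carries its NCT identifier — in the secondary-ID
   field, or only in the title/abstract text (≈1.5 % of records) — and
   survives three screens: published no earlier than the completion month,
   no "study protocol" in the title, and passing the validated *therapy*
   clinical-query filter (broad by default, narrow selectable), which
   removes commentary and secondary analyses.
3. **Aggregation.** Per-sponsor and per-class summaries
   (`pct_missing = 100·n_missing/n_eligible`, kept as exact rationals,
   displayed round-half-up), rankings by count or proportion, enrollment in
   unreported trials, and a 2×2 concordance table against any external
   per-trial verdict set.

A synthetic-corpus generator (`trialaudit.synthetic`) emits both corpora
with planted ground truth — eligibility outcomes, reporting statuses,
evidence routes, and decoy citations built to fail exactly one screen — so
the entire pipeline is testable offline.

## Worked example

```sh
audit fixtures --out demo
audit run --registry-dir demo/registry --citations demo/citations.jsonl \
          --as-of 2016-10 --out demo_out
```

prints

```
wrote 128 trials (120 eligible, 61 planted unreported) to demo
120 eligible trials, 61 missing results; outputs in demo_out
```

The demo corpus plants three sponsors with unreported rates 0.25/0.50/0.75
plus one ineligible trial per filter failure mode (128 records in, 120
eligible). `demo_out/sponsors.json` is the ranked feed; its first entry is
the worst performer:

```json
{
  "name": "St. Swithin's University Hospital",
  "class": "other",
  "n_eligible": 44,
  "n_missing": 33,
  "pct_missing": "75%",
  "pct_missing_1dp": "75.0%",
  "unreported_enrollment": 14369
}
```

i.e. 33 of its 44 eligible trials (75 %) have no discoverable results,
covering 14 369 enrolled participants — exactly the planted rates, since
the generator realizes rates by count. `demo_out/filter_report.json` shows
where the 8 excluded records fell (one per planted failure mode, two each
for the completion window and the sponsor-volume threshold), and
`demo_out/trials.csv` lists every pre-filter record with its per-filter
flags, verdict and evidence routes.

## Layout

| module | role |
|---|---|
| `trialaudit.dates` | month-precision partial dates |
| `trialaudit.registry` | registry XML parsing/serialization, corpus loading |
| `trialaudit.eligibility` | filter cascade, sponsor-volume threshold, filter report |
| `trialaudit.citations` | citation records, JSON-lines I/O, PubMed XML adapter |
| `trialaudit.queries` | fielded boolean query evaluator, therapy filters |
| `trialaudit.linkage` | NCT-ID matching, screening, match evidence |
| `trialaudit.ascertainment` | verdicts, summaries, ranking, concordance |
| `trialaudit.synthetic` | planted-ground-truth corpus generator |
| `trialaudit.export`, `trialaudit.cli` | pipeline runner, output feed, `audit` CLI |

See `docs/methods.md` for the full description of the model, its
parameters and its limitations.
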