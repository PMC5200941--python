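# Methods

## The audit model

The package operationalizes "failure to share trial results" as a
deterministic predicate over two corpora frozen at an *as-of* month: a
registry snapshot and a citation corpus. A completed trial is **unreported**
iff it passes the eligibility cascade and no results evidence is found by
either ascertainment route. There is no statistical model and no randomness
in the audit itself; every probability in this package lives in the
synthetic-corpus generator. Given identical inputs and configuration, every
output file is byte-identical across runs (fixed key order; sponsors in
default rank order; trials by NCT ID).

### Dates

Registry dates are frequently month-only, so all comparisons are at month
precision: a `PartialDate` carries an optional day that is parsed and
round-tripped but never consulted. "More than 24 months ago" is the strict
exact calendar-month difference `(y2−y1)·12 + (m2−m1) > 24`; "after
Jan 1 2006" is read at month precision as *completion ≥ January 2006*,
since a month-granular date cannot distinguish January 1 from January 2.
"Published before completion" is likewise strict: a paper from the
completion month itself passes the screen, on the view that a same-month
publication can report results.

### Eligibility cascade

Five trial-level filters in fixed order — study type (interventional),
status (completed), completion window, phase (2, 2/3, 3, 4, N/A; the
1/2 combination is excluded because it contains a phase-1 component, and
the whitelist is configurable), no results-disposition filing — followed by
the corpus-level sponsor-volume threshold. All five filters are evaluated
for every record (the audit trail shows each outcome); exclusion counts
attribute each record to the *first* filter it fails. Missing data fails
the filter that needs it.

Decisions that were genuinely open, and how they were fixed here:

* **Completion-date precedence.** When both `completion_date` and
  `primary_completion_date` exist, the overall completion date wins;
  `prefer_primary_completion` flips this. Rationale: the overall date is
  the registry's primary completion field, and precedence only matters for
  the minority of records carrying both.
* **Sponsor-volume threshold as ≥ 30, on trial-level-eligible counts.**
  A published sponsor ranking produced by this method lists a sponsor with
  exactly 30 eligible trials, which is only consistent with an inclusive
  threshold applied after the trial-level filters; the threshold is a
  config knob (`min_sponsor_trials`).
* **Sponsor identity is the exact lead-sponsor string.** Name variants
  ("Pfizer" vs "Pfizer Inc.") are distinct sponsors, matching how registry
  rankings are usually published. No fuzzy clustering is attempted.
* **Duplicate registry records** (same NCT ID in two files) are resolved
  deterministically: first file in lexicographic filename order wins,
  later ones are logged.

### Results ascertainment

Route 1 is the presence of the registry's structured-results date tag.
Route 2 matches the trial's NCT identifier (NCT + exactly eight digits,
case-insensitive; a ninth digit or an adjoining alphanumeric disqualifies
the occurrence) against each citation's secondary-ID field and, because a
small fraction of records carry the ID only in free text, against the
title/abstract. A citation matching by both carriers is counted once, as a
secondary-ID match. One citation may serve as evidence for several trials
(multi-arm reports).

Candidates then pass three screens: post-completion, not-protocol (the
contiguous substring "study protocol" in the *title* only — non-contiguous
occurrences such as "study of protocol deviations" pass), and a therapy
clinical-query filter. Both standard validated variants ship as explicit
ASTs:

* broad/sensitive: `(clinical[tiab] AND trial[tiab]) OR "clinical trials
  as topic"[MeSH] OR "clinical trial"[pt] OR random*[tiab] OR "random
  allocation"[MeSH] OR "therapeutic use"[sh]`
* narrow/specific: `"randomized controlled trial"[pt] OR
  (randomized[tiab] AND controlled[tiab] AND trial[tiab])`

Broad is the default variant. Term semantics over a *local* corpus are
necessarily simpler than a live search index: title/abstract terms match
whitespace-delimited, case-insensitive tokens with leading/trailing
punctuation stripped (truncation = prefix match); MeSH, publication-type
and subheading terms are case-insensitive set membership with **no MeSH
tree explosion**. These semantics are deterministic and checkable against
a brute-force set-theoretic oracle, which the test suite does on
randomized corpora and randomized query trees. The practical consequence
of no explosion: a record typed only `Randomized Controlled Trial` does
not satisfy `"clinical trial"[pt]`, but every such record the broad filter
should keep is caught by its `random*[tiab]` arm in practice.

### Aggregation and display

Percentages are exact `Fraction`s internally; display rounding is
round-half-up on the exact rational (never banker's rounding, never
floating-point), at integer or one-decimal precision. Missing enrollment
counts as zero in unreported-enrollment sums (logged), since excluding
such trials would silently shrink the figure. Rankings are stable sorts
with ties broken by sponsor name; the default ordering is most missing
results first, which surfaces large well-known sponsors rather than small
sponsors with extreme proportions. The concordance table compares this
audit's verdicts with any external per-trial verdict map over the
intersection of their trial IDs only.

## The synthetic-corpus generator

`trialaudit.synthetic` emulates the two input corpora with planted ground
truth. What it emulates: registry records spanning all filter failure
modes; results papers whose registry ID sits in the secondary-ID field or
(with probability `p_text_only`, default 0.015 — the observed fraction of
records carrying a valid ID only in the abstract) in the text; protocol
papers, pre-completion papers and commentary, each constructed from small
template pools so its therapy-query outcome and failing screen are decided
by construction, not chance; and unrelated citations, a quarter of which
carry nine-digit near-miss identifiers to exercise the matcher's boundary.

Key parameters (all in `FixtureSpec`):

| parameter | default | meaning |
|---|---|---|
| `sponsor_profiles` | — | per sponsor: name, class, trial count, true unreported rate |
| `as_of` | 2016-10 | census month |
| `date_window` | 2006-06 … 2014-09 | completion months of planted-eligible trials (must end > 24 months before `as_of`) |
| `p_registry_results` | 0.4 | a reported trial posts registry summary results rather than a paper; chosen below one half because statutory summary-results posting is historically the rarer of the two routes |
| `p_text_only` | 0.015 | results paper carries the ID only in title/abstract |
| `p_protocol_decoy` / `p_precompletion_decoy` / `p_commentary_decoy` | 0.15 / 0.05 / 0.15 | per-trial decoy probabilities |
| `n_unrelated` | 0 | citations mentioning no planted trial |

Unreported **rates are realized exactly by count** (rate 0.5 over 40 trials
plants exactly 20 unreported trials, half-up on fractional products), so
corpus-level statistics are exact targets rather than samples; per-paper
route and decoy draws remain Bernoulli so their frequencies can be tested
statistically. One seeded pseudo-random stream is consumed in a documented
order (sponsors in listed order; per trial: completion month, phase,
enrollment, reporting draws, decoy draws; then unrelated citations), which
makes same-seed output byte-identical.

What the generator does **not** emulate — and therefore what passing tests
do not show about real data: realistic medical prose (linkage here never
faces ambiguous or mistyped identifiers), results papers that omit the
registry ID entirely (the main false-"unreported" mechanism in practice),
indexing latency, sponsor-name variants, or registry records that drift
between snapshot dates. Ground-truth recovery being exact on fixtures
demonstrates that the pipeline implements its stated rules faithfully, not
that those rules have any particular sensitivity or specificity on live
registry and citation data.

## Problem sizes

The test suite's largest fixture is 5,000 trials with ≈20,000 citations
(ten 500-trial sponsors, every decoy probability 1, 3,000 unrelated
citations), which one pipeline run processes in a few seconds thanks to a
single NCT-ID → citation index built once per corpus. The acceptance
script uses eight 250-trial sponsors at a planted 50 % unreported rate.
Both sizes are the package's own choice of a corpus large enough to
exercise every route and screen many hundreds of times while keeping a
full run interactive.

## Known limitations

* Identifier-based linkage only; no probabilistic record linkage. A trial
  whose results paper omits the NCT ID is adjudicated unreported.
* The registry's `results_reference` links are deliberately not used as a
  results route: they are editorially uncontrolled and frequently point at
  unrelated publications.
* The 2016-era XML dialect only; the post-2016 registry JSON API is out of
  scope, as is any live fetching — both corpora are local files.
* Query semantics are local (no MeSH explosion, no stemming); results can
  differ from a live PubMed search over the same records.
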