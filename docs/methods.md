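# Methods

## Scenario spaces

A space is a declarative config (YAML/JSON): per population, an ordered
list of variables with ordered levels, and a treatment list.  Scenarios
are the full Cartesian product of the levels, enumerated odometer-style
(variables in config order, last variable cycling fastest), and carry a
stable, diff-friendly id of the form
`POP|var1=level1|var2=level2|...`.  Indications are scenarios crossed
with that population's treatments, scenarios first.  "No treatment" is an
ordinary treatment option so it can be tabulated like any other.

The packaged `round2-default` space covers iron deficiency in IBD with
two populations.  NAID: previous treatment (7 levels: none, plus
success/failure for oral, low-dose IV and high-dose IV), conditions with
additional iron need (2), IBD activity (2) — 28 scenarios × 5 treatments.
IDA adds haemoglobin bands (<8, 8–<10, 10–<12 g/dL; half-open,
upper-exclusive, the cut-points reported for this study population) and
physical symptoms (2) — 168 scenarios × 6 treatments.  The published
source for this space prints only the variable names and the totals
(196 scenarios, 1148 indications); the level structure above is the
unique factorisation consistent with those totals
(5·28 + 6·168 = 1148, 28 + 168 = 196) and with the treatment-history
options discussed in the study's results.  Any other structure can be
expressed via config; the first-round space (56 + 112 scenarios) is
expressible but not shipped because its levels were never published.

## Rating tables

Long format, one row per (rater, scenario, treatment, round); integer
ratings 1–9.  The panel is the sorted set of rater ids unless declared
explicitly.  Validation is strict: ratings outside 1–9, unknown
indications and duplicate keys are errors naming the offending row.
Completeness (every rater × every indication) is asserted before vectors
are assembled — there is no principled imputation rule for missing panel
ratings, so gaps are a hard error listing the missing pairs.  Rounds are
tagged but never merged: a panel that revises its scenario structure
between rounds makes cross-round comparison of indications undefined.
CSV output is canonically sorted, hence byte-stable.

## Classification

`classify` computes the order-statistic median (midpoint of the central
pair for even P, so half-integer medians occur and — lying in no section —
classify as uncertain), the agreement flag (max section count ≥ A), the
disagreement flag (both extreme-section counts ≥ D) and the category
(median band + disagreement, as in the README).  Disagreement counts use
the section membership of raw ratings, never of the median.  At the
default P = 16, A = 12, D = 5, agreement and disagreement are mutually
exclusive by pigeonhole (12 + 5 > 16).  No variant disagreement
statistics (e.g. IPRAS) are implemented — only the printed rules.

Thresholds for other panel sizes default to A = ⌈0.75 P⌉ and
D = max(2, round(0.3125 P)) capped at P.  This is an extrapolation of the
12/16 and 5/16 fractions, not a published rule; both are overridable.

## Summaries

* **Appropriateness distribution** — per (population, treatment), percent
  of scenarios in each category.  Percentages are exact; the three values
  per row are computed as cumulative differences so the row sums to
  exactly 100.0 in floating point (each entry is the exact percentage to
  1 ulp).  Whole-percent rounding is display-only.
* **Agreement / disagreement rates** — percent of indications flagged.
* **Scenario option counts** — per-scenario number of appropriate
  treatments, plus the shares of scenarios with ≥1 and with exactly 1
  appropriate option.
* **Preferred option** — two rules, because "preferred" admits two
  readings: `highest_median_among_appropriate` (default; a tied maximum
  is surfaced as a tie share, never silently broken) and
  `unique_appropriate` (preferred only when exactly one option is
  appropriate).
* **Discriminativeness** — for each variable, the fraction of
  (scenario-pair, treatment) comparisons, over all scenario pairs
  differing in exactly that variable, whose categories differ.  This
  matched-pair score is our operationalisation of the cross-tabulations
  used to ask which patient characteristics move the recommendation; it
  is symmetric, scale-free and exactly computable.  Single-level
  variables have no pairs and report a null score.

## Synthetic panels

The generator plants, per indication, a category drawn from a
(appropriate, uncertain, inappropriate, split) mix — defaults
(0.4, 0.3, 0.25, 0.05), a round dominated by clear calls with a small
polarised minority, which is what consensus rounds that have already been
through a discussion meeting look like.  Latent scores sit at the section
midpoints θ = 8 / 5 / 2 (so the noise-free round recovers every planted
label exactly); split indications pair θ = 2 with an opposed θ′ = 8, and
exactly round(split_fraction · P) raters (default 5/16) score around θ′,
which triggers the disagreement rule deterministically.  Ratings are
`clamp(round(θ + bias_r + ε), 1, 9)` with ε ~ N(0, σ²) and per-rater bias
defaulting to 0.  One seeded RNG stream drives each table;
`simulate_round` derives independent sub-seeds for the plant and the
noise so changing σ never reshuffles the plant.

What this emulates — and does not: a complete, integer-valued panel round
with tunable consensus structure.  It does not model real rater
behaviour (end-aversion, correlated specialty blocs, scenario-difficulty
effects, ordinal response thresholds), so recovery rates measured on it
certify the *pipeline arithmetic*, not the reliability of any real
panel.  A cumulative-logit rater model could replace it behind the same
interface.

Recovery is reported as a confusion matrix (planted kind × classified
category) plus the percent of indications whose classified category
equals the intended label, overall and excluding split plants.

## Decision-support export

Classified results map to traffic-light grades (appropriate → green,
uncertain → optional/yellow, inappropriate → red), one record per
scenario, exported as versioned JSON (space config + records + optional
per-treatment consideration notes) that re-imports to an identical set.
Provenance is tagged `computed` or `transcribed-fixture`.

The packaged fixture set transcribes a published round-2 summary that
reports grades only at the previous-treatment × activity (NAID) and
previous-treatment × haemoglobin (IDA) margins; cells the summary does
not pin down are graded `optional` rather than guessed, and cells it
states as inappropriate (no treatment; IBD-medication adjustment in
inactive disease; transfusion at Hb ≥ 8 g/dL) are graded so.  The fixture
is a synthetic stand-in at full scenario resolution — the true
per-scenario outcomes were never deposited — and is therefore never used
as a correctness oracle for the classifier.

## Numerical and testing choices

* Problem sizes: the full default space (16 × 1148) runs in well under a
  second per round, so tests and the acceptance script use it directly;
  the exhaustive rule check uses a reduced panel (P = 6, A = 5, D = 2,
  all 9⁶ = 531 441 vectors) to keep enumeration complete yet quick.
* The exhaustive check compares `classify` against an independent literal
  transcription of the three rule sentences (numpy median + section
  counts); the two routes share no code.
* Monotone noise degradation of recovery is asserted on the mean over
  5 seeds, since single-seed recovery curves can tie or cross by chance.
* Ties in the preferred-option rule, degenerate inputs (empty vectors,
  empty tables, single-level variables, incomplete profiles) and invalid
  ratings all raise or are surfaced explicitly; nothing is silently
  dropped or broken.

## Known limitations

* The published headline percentages of the source study (71% agreement,
  the per-treatment distribution table, the 98% / 83% / 77% shares)
  depend on the 16 experts' raw ratings, which were never deposited;
  they are not reproducible from code and are not asserted anywhere.
* The round-2 level structure is inferred (uniquely) from printed totals,
  not transcribed from a published listing.
* Threshold scaling to panel sizes other than 16 is an extrapolation.
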