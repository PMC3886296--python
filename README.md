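# ruamkit

Tools for RAND/UCLA appropriateness-method (RUAM) panels: enumerate
clinical scenario spaces by permutation, classify 9-point expert ratings
into *appropriate* / *uncertain* / *inappropriate* with the standard
agreement and disagreement rules, summarise a rating round, simulate
synthetic panels with planted ground truth, and export a patient-profile
decision-support lookup.

## The problem

The RUAM is a modified Delphi procedure for deciding when a medical
intervention is appropriate for a specific patient profile.  A panel of
experts rates every *indication* — one (clinical scenario, treatment)
pair — on a 9-point scale (1 = inappropriate, 5 = uncertain,
9 = appropriate), where scenarios are built by Cartesian permutation of
clinical variables (e.g. previous treatment × haemoglobin band × disease
activity).  `ruamkit` implements the arithmetic of such a study as tested,
reusable code, for panel methodologists who need to run the rating
pipeline, audit its rules, or embed the outcomes in a decision tool.

The packaged default space describes a second-round panel on iron
deficiency in inflammatory bowel disease: non-anaemic iron deficiency
(NAID, 28 scenarios × 5 treatments) and iron-deficiency anaemia (IDA,
168 scenarios × 6 treatments) — 196 scenarios and 1148 indications.

## The classification rules

For a panel of *P* = 16 raters, with the scale split into sections 1–3,
4–6 and 7–9, an indication with rating vector *r* is classified from:

* **agreement** — at least *A* = 12 of the 16 ratings lie in the same
  section;
* **disagreement** — at least *D* = 5 ratings lie in section 1–3 **and**
  at least 5 in section 7–9;
* **category** — *appropriate* if median(*r*) ∈ [7, 9] without
  disagreement, *inappropriate* if median(*r*) ∈ [1, 3] without
  disagreement, otherwise *uncertain*.

For even panels the median is the midpoint of the two central order
statistics; a half-integer median such as 6.5 lies in no section and
classifies as uncertain.  *A* and *D* scale to other panel sizes as
⌈0.75 P⌉ and max(2, round(0.3125 P)), and can be overridden.

## Worked example

```python
import ruamkit as rk

space = rk.default_space()
print(f"{len(space.all_scenarios())} scenarios, "
      f"{len(space.enumerate_indications())} indications")

# simulate a 16-rater round: 40% appropriate, 30% uncertain, 25%
# inappropriate and 5% polarised ("split") indications, rater noise 0.5
truth, table = rk.simulate_round(space, seed=42, noise_sd=0.5,
                                 category_mix=(0.4, 0.3, 0.25, 0.05))
results = rk.classify_all(table)
print(f"agreement: {rk.agreement_rate(results):.1f}%  "
      f"disagreement: {rk.disagreement_rate(results):.1f}%")

report = rk.recovery_report(truth, results)
print(f"planted-label recovery: {report.recovery_rate:.1f}%")
print(report.confusion)
```

prints

```
196 scenarios, 1148 indications
agreement: 96.5%  disagreement: 3.5%
planted-label recovery: 100.0%
classified     appropriate  inappropriate  uncertain
kind
appropriate            488              0          0
uncertain                0              0        347
inappropriate            0            273          0
split                    0              0         40
```

Every planted label was recovered: at this noise level the classifier
reproduces the intended category of each indication, and the 40 polarised
indications land in *uncertain* via the disagreement rule, as designed.
The agreement rate (96.5% of indications with ≥12/16 ratings in one
section) is a property of this synthetic round, not of any real panel.

A single vector can be classified directly — a polarised panel
(five 2s, six 5s, five 8s) triggers disagreement:

```python
r = rk.classify([2]*5 + [5]*6 + [8]*5, rk.PanelConfig(panel_size=16))
# median 5.0, disagreement=True, category=uncertain
```

The same pipeline is scriptable from a shell:

```
ruamkit simulate --sigma 0.5 --seed 42 --out ratings.csv
ruamkit classify --ratings ratings.csv --out results.csv
ruamkit summarize --ratings ratings.csv --out report.json
ruamkit export-tool --ratings ratings.csv --out tool.json
```

`export-tool` writes the decision-support JSON: one record per patient
profile with a traffic-light grade per treatment (appropriate → green,
optional → yellow, inappropriate → red), re-importable with
`rk.import_tool_json`.  `rk.transcribed_recommendations()` returns the
packaged transcription of a published round-2 summary (provenance
`"transcribed-fixture"`, distinct from computed sets).

## Documentation

See `docs/methods.md` for the model and procedure details, the synthetic
rater model and its limitations, and the numerical choices.
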