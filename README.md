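# neuroagree

Inter-rater agreement for **span-level annotation of neurologic signs and
symptoms** in clinical notes.

Clinical phenotyping turns the free text of electronic health records into
computable concepts in two steps: raters (human or machine) mark the text
span of each sign or symptom, and each span is *normalized* to a concept in
an ontology and its machine-readable code (e.g. `ataxic` → *ataxia* → UMLS
CUI `C0004134`). Measuring how well raters agree on this task is the point
of this package. It is aimed at annotation-study designers and NLP
evaluators who need chance-corrected agreement for span annotations, plus a
fully synthetic test bed for the whole pipeline.

## The agreement model

Notes are split into lines; each line is one annotation context (a
*screen*). For a rater pair A and B, the items entering the agreement
statistic are:

* one item per element of **A ∪ B**, the union of the two raters' spans
  (matched by exact character offsets by default, with an optional
  overlap-matching mode), and
* one agreeing item per **null screen** — a screen in which neither rater
  annotated anything,

so the denominator is |A ∪ B| + null_screens. Two tasks share this
denominator: the **text-span task** (ratings "present"/"null") and the
**category-label task**, where ratings are the seven-way span taxonomy —
*unigram, bigram, trigram, tetragram, extended* (> 4 words), *compound*
(several concepts in one span, e.g. "brisk ankle and knee reflex") and
*tabular* (column-formatted screens, typically right/left body sides).

Agreement is reported as **concordance** (unadjusted percent agreement,
100·p̂ₒ) and **Cohen's κ**:

    κ = (pₒ − pₑ) / (1 − pₑ),   pₑ = Σ_c p_A(c) · p_B(c)

with pₑ the chance agreement implied by each rater's marginal rating
frequencies over the units. Rater-pair groups (human–human vs
human–machine) are compared with a classical one-way ANOVA on the
pair-round κ values.

Because real EHR annotation data cannot be shipped, the package includes a
synthetic corpus generator (planted concepts of varying token length,
negated concepts that must not be annotated, tabular screens, neutral filler
screens) and simulated annotator profiles with per-category sensitivity,
false-positive rate, boundary jitter, label confusion and negation errors.

## Worked example

Twenty agreement units: 8 spans marked by both raters, one marked only by A,
one only by B, and 10 null screens.

```python
from neuroagree.agreement import (AgreementUnit, observed_agreement,
                                  expected_agreement, cohen_kappa, concordance)

units  = [AgreementUnit(("n", i), "span_unit", (0, 5), "present", "present") for i in range(8)]
units += [AgreementUnit(("n", 8), "span_unit", (0, 5), "present", "null"),
          AgreementUnit(("n", 9), "span_unit", (0, 5), "null", "present")]
units += [AgreementUnit(("n", i), "null_screen_unit", None, "null", "null") for i in range(10, 20)]

print("po =", observed_agreement(units))
print("pe =", expected_agreement(units))
print("kappa =", round(cohen_kappa(units), 3))
print("concordance =", concordance(units), "%")
```

prints

```
po = 0.9
pe = 0.505
kappa = 0.798
concordance = 90.0 %
```

18 of 20 units agree, so pₒ = 0.90 and concordance is 90%. Each rater marks
9 of 20 units "present", giving pₑ = 0.45² + 0.55² = 0.505 and
κ = (0.900 − 0.505)/0.495 ≈ 0.798 — chance-corrected agreement is lower
than raw agreement because most screens are null and "both silent" is easy
to achieve by chance.

The same statistics from the command line, on a simulated corpus:

```
neuroagree simulate --seed 1 --out-dir demo
neuroagree score --screens demo/screens.jsonl demo/A1.jsonl demo/A2.jsonl --task span
```

```
[
  {
    "concordance_pct": 92.58675078864354,
    "kappa": 0.7607393489746431,
    "n_units": 634,
    ...
  }
]
```

— two simulated human raters (sensitivity 0.92 each) over 625 screens agree
on 92.6% of 634 units, κ = 0.76. `neuroagree report --config cfg.yaml
--out-dir out` runs the full multi-round pipeline (simulation or real JSONL
files) and writes `report.json`, `pairwise.csv` and a plain-text summary;
`neuroagree normalize` maps annotated spans to ontology concepts.

## Layout

| module | purpose |
| --- | --- |
| `neuroagree.annotation_model` | screens, spans, JSONL I/O, validation |
| `neuroagree.category_labeling` | the seven-way taxonomy and automatic labeling |
| `neuroagree.agreement` | agreement units, concordance, Cohen's κ |
| `neuroagree.ontology` | lookup-table + similarity normalization to concepts |
| `neuroagree.synthetic` | corpus generator and annotator simulator |
| `neuroagree.report` | round summaries, one-way ANOVA, pipeline |
| `neuroagree.cli` | `simulate` / `score` / `normalize` / `report` subcommands |

See `docs/methods.md` for the statistical model, simulator assumptions and
numerical conventions.
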