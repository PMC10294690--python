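# Methods

## Agreement model

The unit of agreement is per span, not per screen. For raters A and B the
unit list over a corpus of screens is built as follows:

* a screen annotated by neither rater contributes **one null-screen unit**
  whose two ratings are both "null" — an agreement;
* otherwise the rater's spans on the screen are paired (exact offset match
  by default; see *Span matching*), and every matched pair and every
  unmatched span contributes **one span unit**.

The denominator is therefore |A ∪ B| + null_screens. On the text-span task
a unit's ratings are "present"/"null"; on the category-label task they are
the raters' category labels, with "null" for the rater who did not mark the
span. The two tasks share one denominator: an unmatched span counts as a
label disagreement against "null" rather than being conditioned away. This
unconditional choice keeps the label-task κ comparable to the span-task κ
on the same corpus.

Observed agreement pₒ is the fraction of agreeing units; concordance is
100·pₒ. Chance agreement is Cohen's formulation, pₑ = Σ_c p_A(c)·p_B(c)
from the per-rater marginal rating frequencies over the units, and
κ = (pₒ − pₑ)/(1 − pₑ). Properties maintained by construction and verified
by the test suite: symmetry under rater swap, κ ≤ 1 with equality iff
pₒ = 1 (given pₑ < 1), and agreement with a brute-force contingency-table
evaluation to 1e-12.

Degenerate cases: an all-null corpus has pₒ = pₑ = 1; κ is returned as 1.0
by convention with a warning. pₑ = 1 with pₒ < 1 cannot arise from real
ratings (pₑ = 1 forces both raters constant on the same category), but the
error path exists for defensive completeness. Negative κ values are
returned as computed; the conventional interpretation of κ as ranging from
0 to 1 is interpretive, not definitional.

## Span matching

The default match criterion is **exact character offsets**: two raters agree
on a span only if both mark the identical [start, end) range. This is the
strictest defensible reading and makes the A ∪ B denominator unambiguous.
An **overlap** mode (greedy pairing by maximal character overlap, ties
broken by leftmost start) is provided for sensitivity analyses but is off by
default, as is edge-whitespace trimming. Offsets are 0-based, half-open,
counted in Unicode code points. Within one rater's output, overlapping
spans on a screen are rejected at validation: the compound category exists
precisely so that multi-concept regions are marked as one span.

## Category taxonomy

Label assignment is a total function with priority **tabular > compound >
length**:

* *tabular* — a property of the screen, not the span: the screen contains
  at least two runs of two or more consecutive spaces (column alignment) or
  both "right" and "left" as words (body-side headers). Both heuristics are
  configurable.
* *compound* — a marker token ("and", "or", or an attached comma) joining
  tokens strictly inside the span, at least one token on each side.
  Compound must outrank length because compound spans can exceed four
  tokens ("brisk ankle and knee reflex" has five).
* otherwise by token count: 1 → unigram … 4 → tetragram, > 4 → extended.
  Hyphenated words count as one token by default (hyphens are a documented
  source of label disagreement; the switch `hyphen_joins_tokens` exposes
  the alternative convention).

## Normalization

Concept catalogs are TSV files (`concept_id`, `preferred_label`, `code`,
pipe-delimited `synonyms`). The lookup table maps every normalized phrase
(lowercased, whitespace-collapsed, edge punctuation stripped) to its
concept; a phrase shared by two concepts is an error at table build time.
Spans missing the table fall back to the best character-trigram cosine
similarity over all table phrases, accepted at threshold 0.7 (default,
configurable). Trigram cosine was chosen as the default scorer because it
is deterministic, dependency-free and adequate for inflectional variants
(ataxic/ataxia ≈ 0.87); the scorer is pluggable for anything stronger. Ties
in best similarity break to the lexicographically smallest concept id.
Normalization is downstream of agreement scoring and does not affect κ.

The packaged catalog `synthetic_neuro_ontology.tsv` is a synthetic stand-in
of ~60 neurologic sign/symptom concepts mimicking the structure of a real
neuro-ontology. The concept *ataxia* carries its real UMLS CUI `C0004134`;
all other codes are synthetic placeholders (`C9xxxxxx`). Real catalogs in
the same TSV format load through the same path.

## Synthetic corpus and annotator model

The generator emulates the structure of screen-per-line EHR annotation
corpora. Defaults (one "round"): 5 notes × 125 screens = 625 screens,
concept-screen fraction 0.25, so roughly 130–160 planted signs/symptoms per
round and a majority of null screens — the regime in which null-screen
handling dominates the statistics. Per concept screen, independently:
negated with probability 0.15 (planted in a denial template, recorded as a
do-not-annotate span), else tabular with probability 0.05, else a sentence
whose span category is drawn from the mix unigram 0.35, bigram 0.25,
trigram 0.15, tetragram 0.08, extended 0.05, compound 0.12 — short spans
dominating, as in clinical text. Compound spans join two unigram concepts
with "and". All text is template-based; templates are chosen so that
non-tabular screens never trigger the tabular detector and filler screens
contain no catalog phrase.

Annotator profiles: **sensitivity** (scalar, or per-category for raters
whose recall degrades with span length), **false-positive rate** (expected
spurious 1–2-token spans per 100 screens, placed on non-gold, non-negated
text), **boundary jitter** (probability of moving one span edge by one
token), **label confusion** (a stochastic matrix; the default confuses a
category with its length-adjacent neighbours, compound/tabular with
extended) and **negation-error rate** (probability of annotating a negated
concept). The default human profile uses sensitivity 0.92, 0.5 false
positives per 100 screens, jitter 0.02, confusion 0.03, negation error
0.02; the default machine profile uses per-category sensitivity decreasing
from 0.94 (unigram) to 0.72 (extended), 0.67 tabular — unweighted mean
0.80 — with 2 false positives per 100 screens, jitter 0.05, confusion 0.08,
negation error 0.05. The human/machine sensitivity levels are calibration
choices that echo the κ gap reported for human-human vs human-machine rater
pairs in EHR annotation studies (≈ 0.85 vs ≈ 0.76); they are not estimates
from data, and per-category machine sensitivities are not separately
identifiable from aggregate κ.

What passing tests on this simulator do **not** show: real notes have
abbreviation ambiguity, anaphora, laterality modifiers, misspellings and
rater-specific systematic biases, none of which the template generator
produces. Simulated agreement is therefore an upper-bound sanity check on
the *statistics*, not a forecast of agreement on real EHR text.

In the restricted regime — zero false positives, jitter and negation
errors, scalar sensitivities, one gold span per concept screen,
`negated_fraction = 0` — concordance has the closed form

    (1 − f) + f · [s_A·s_B + (1 − s_A)(1 − s_B)]

since a concept screen agrees when both raters mark the span or both miss
it (a jointly missed screen becomes a null screen and agrees), and every
screen contributes exactly one unit. The simulator is checked against this
form at 5,000 screens (tolerance ±0.02, well above the binomial sampling
error of ≈ 0.005).

## Rounds, groups and ANOVA

Pairwise results are tagged by round and pair group (human-human /
human-machine). Summaries report per-group mean and sample SD (ddof = 1;
absent for n = 1) of κ and concordance, per round and pooled. Groups are
compared by classical one-way ANOVA on the pair-round values pooled across
rounds (3 human-human and 3 human-machine pairs × 3 rounds → 18
observations, df = (1, 16)); whether rounds should instead be modelled as a
factor is left open, matching the reporting convention the pipeline
follows. The decomposition is written out directly (SSB/SSW) because the
all-groups-identical case must return F = 0, p = 1 rather than NaN; zero
within-group variance with unequal means raises an explicit infinite-F
error. The p-value is the upper tail of the F distribution. Post hoc
pairwise comparisons are not applied by default. ANOVA on κ values
inherits the usual normality/homogeneity caveats; with 18 bounded
observations the p-values are indicative, not exact.

## Determinism and problem sizes

Every stochastic component takes an explicit seed; child seeds for rounds
and raters are derived with `numpy.random.SeedSequence`, so a pipeline
config plus seed reproduces byte-identical JSON reports. Test and
acceptance problem sizes — 625-screen rounds, 5,000-screen Monte-Carlo
checks, 20 replicates for the group-ordering property — were chosen so the
binomial/sampling error is several times smaller than each assertion's
tolerance while the whole suite runs in seconds.

## Pipeline notes

The relabeling stage (recomputing category labels from the taxonomy rules)
is off by default in the pipeline: simulated and human raters carry their
own label choices, and overwriting them would make label-task agreement
trivially perfect. It is available (`relabel: true`) for corpora whose
files carry placeholder labels. The machine annotator is represented as a
simulated profile throughout; training an actual model is out of scope.
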