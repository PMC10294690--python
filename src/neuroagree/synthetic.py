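"""Synthetic clinical-note corpora and simulated annotators.

Real sign/symptom annotation data from electronic health records cannot be
redistributed, so this module generates gold-standard corpora with the same
structure — screen-per-line notes where most screens contain nothing to
annotate, planted concepts of varying token length, negated concepts that
must *not* be annotated, and column-formatted (tabular) screens — and
simulates raters with controllable imperfections: per-category sensitivity,
spurious (false-positive) spans, boundary jitter, label confusion and
negation errors.

Defaults mirror the structure of the study conditions this package models:
five notes of 125 screens (625 annotation screens per round) with roughly a
quarter of screens carrying a concept, human-like raters with scalar
sensitivity 0.92 and 0.5 spurious spans per 100 screens, and a machine-like
rater whose per-category sensitivity decreases with span length (mean 0.80)
with 2 spurious spans per 100 screens.

Everything is bit-reproducible given the config/profile seeds.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Union

import numpy as np

from .annotation_model import (
    AnnotationSet,
    CategoryLabel,
    Screen,
    SpanAnnotation,
    write_annotations,
)
from .category_labeling import LabelingConfig, assign_category, token_count

__all__ = [
    "CorpusConfig",
    "GoldDocument",
    "AnnotatorProfile",
    "generate_corpus",
    "simulate_annotator",
    "expected_concordance",
    "corpus_screens",
    "gold_annotation_set",
    "write_corpus",
    "default_human_profile",
    "default_machine_profile",
    "adjacent_confusion",
]

ScreenKey = tuple[str, int]

# (prefix, suffix) sentence templates; span offsets are len(prefix) arithmetic.
POSITIVE_TEMPLATES: tuple[tuple[str, str], ...] = (
    ("The patient reports ", "."),
    ("Exam notable for ", "."),
    ("He has developed ", " over the past week."),
    ("Neurologic review positive for ", "."),
    ("She continues to have ", "."),
)

NEGATION_TEMPLATES: tuple[tuple[str, str], ...] = (
    ("The patient denies ", "."),
    ("No ", " on exam."),
    ("She denies any ", "."),
    ("There is no evidence of ", "."),
)

NULL_TEMPLATES: tuple[str, ...] = (
    "Medications were reviewed with the patient.",
    "Follow up in three months.",
    "Laboratory studies were unremarkable.",
    "The plan was discussed in detail.",
    "Imaging was reviewed at the visit.",
    "Vital signs were stable today.",
    "The patient will continue current therapy.",
    "Records were requested from the outside hospital.",
)

# column-formatted screen: two runs of double spaces plus right/left headers
TABULAR_SUFFIX = "  right decreased  left normal"

_LENGTH_CATEGORIES = (
    CategoryLabel.UNIGRAM,
    CategoryLabel.BIGRAM,
    CategoryLabel.TRIGRAM,
    CategoryLabel.TETRAGRAM,
    CategoryLabel.EXTENDED,
)

DEFAULT_CATEGORY_MIX: dict[CategoryLabel, float] = {
    CategoryLabel.UNIGRAM: 0.35,
    CategoryLabel.BIGRAM: 0.25,
    CategoryLabel.TRIGRAM: 0.15,
    CategoryLabel.TETRAGRAM: 0.08,
    CategoryLabel.EXTENDED: 0.05,
    CategoryLabel.COMPOUND: 0.12,
}


@dataclass(frozen=True)
class CorpusConfig:
    """Study conditions for one synthetic corpus (one annotation round)."""

    n_notes: int = 5
    screens_per_note: int = 125
    concept_screen_fraction: float = 0.25
    negated_fraction: float = 0.15
    category_mix: dict[CategoryLabel, float] = field(
        default_factory=lambda: dict(DEFAULT_CATEGORY_MIX)
    )
    tabular_screen_fraction: float = 0.05
    spans_per_concept_screen: int = 1
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("concept_screen_fraction", "negated_fraction", "tabular_screen_fraction"):
            value = getattr(self, name)
            if not 0.0 <= value <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {value}")
        total = sum(self.category_mix.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"category_mix must sum to 1, got {total}")
        if self.spans_per_concept_screen < 1:
            raise ValueError("spans_per_concept_screen must be >= 1")


@dataclass
class GoldDocument:
    """One synthetic note with its gold and negated (do-not-annotate) spans."""

    note_id: str
    screens: list[Screen]
    gold: dict[ScreenKey, list[SpanAnnotation]]
    negated: dict[ScreenKey, list[SpanAnnotation]]


@dataclass(frozen=True)
class AnnotatorProfile:
    """Behavioral parameters of a simulated rater.

    ``sensitivity`` is either a scalar probability of annotating any gold
    span, or a per-category mapping (a machine-like rater is typically less
    sensitive to longer spans).  ``false_positive_rate`` is expected spurious
    spans per 100 screens.  ``boundary_jitter`` is the probability that an
    annotated span has one edge moved by one token.  ``label_confusion`` maps
    each true category to a distribution over assigned categories (None
    means labels are always correct).  ``negation_error_rate`` is the
    probability of wrongly annotating a negated concept.
    """

    rater_id: str
    sensitivity: Union[float, dict[CategoryLabel, float]] = 1.0
    false_positive_rate: float = 0.0
    boundary_jitter: float = 0.0
    label_confusion: dict[CategoryLabel, dict[CategoryLabel, float]] | None = None
    negation_error_rate: float = 0.0
    seed: int = 0
    kind: str = "human"

    def __post_init__(self) -> None:
        values = (
            [self.sensitivity]
            if isinstance(self.sensitivity, (int, float))
            else list(self.sensitivity.values())
        )
        for v in values + [self.boundary_jitter, self.negation_error_rate]:
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"profile {self.rater_id!r}: probability {v} outside [0, 1]")
        if self.false_positive_rate < 0:
            raise ValueError("false_positive_rate must be non-negative")
        if self.label_confusion is not None:
            for cat, row in self.label_confusion.items():
                if abs(sum(row.values()) - 1.0) > 1e-9:
                    raise ValueError(f"label_confusion row for {cat} does not sum to 1")

    def sensitivity_for(self, category: CategoryLabel) -> float:
        if isinstance(self.sensitivity, (int, float)):
            return float(self.sensitivity)
        try:
            return self.sensitivity[category]
        except KeyError:
            raise ValueError(
                f"profile {self.rater_id!r}: no sensitivity for category {category.value!r}"
            ) from None


def adjacent_confusion(p: float) -> dict[CategoryLabel, dict[CategoryLabel, float]]:
    """Confusion matrix that mislabels with probability p into neighbor classes.

    Length classes confuse with adjacent lengths; compound and tabular
    confuse with extended (the boundary cases raters actually mix up).
    """
    L = CategoryLabel
    neighbors = {
        L.UNIGRAM: [L.BIGRAM],
        L.BIGRAM: [L.UNIGRAM, L.TRIGRAM],
        L.TRIGRAM: [L.BIGRAM, L.TETRAGRAM],
        L.TETRAGRAM: [L.TRIGRAM, L.EXTENDED],
        L.EXTENDED: [L.TETRAGRAM, L.COMPOUND],
        L.COMPOUND: [L.EXTENDED],
        L.TABULAR: [L.EXTENDED],
    }
    matrix = {}
    for cat, others in neighbors.items():
        row = {cat: 1.0 - p}
        for other in others:
            row[other] = row.get(other, 0.0) + p / len(others)
        matrix[cat] = row
    return matrix


def default_human_profile(rater_id: str, seed: int = 0) -> AnnotatorProfile:
    """A trained human rater: high uniform sensitivity, few spurious spans."""
    return AnnotatorProfile(
        rater_id=rater_id,
        sensitivity=0.92,
        false_positive_rate=0.5,
        boundary_jitter=0.02,
        label_confusion=adjacent_confusion(0.03),
        negation_error_rate=0.02,
        seed=seed,
        kind="human",
    )


def default_machine_profile(rater_id: str = "NN", seed: int = 0) -> AnnotatorProfile:
    """A machine-like rater: sensitivity decreasing with span length, mean 0.80."""
    L = CategoryLabel
    return AnnotatorProfile(
        rater_id=rater_id,
        sensitivity={
            L.UNIGRAM: 0.94,
            L.BIGRAM: 0.89,
            L.TRIGRAM: 0.84,
            L.TETRAGRAM: 0.79,
            L.EXTENDED: 0.72,
            L.COMPOUND: 0.75,
            L.TABULAR: 0.67,
        },
        false_positive_rate=2.0,
        boundary_jitter=0.05,
        label_confusion=adjacent_confusion(0.08),
        negation_error_rate=0.05,
        seed=seed,
        kind="machine",
    )


def _phrase_pools(lexicon, labeling: LabelingConfig) -> dict[object, list[str]]:
    """Bucket lexicon phrases by token count; exclude compound-marker phrases."""
    pools: dict[object, list[str]] = {1: [], 2: [], 3: [], 4: [], "extended": []}
    for concept in lexicon:
        for phrase in concept.phrases():
            toks = phrase.split()
            if any(t.lower() in ("and", "or") or "," in t for t in toks):
                continue
            n = token_count(phrase, labeling)
            pools[n if n <= 4 else "extended"].append(phrase)
    return pools


_POOL_KEY = {
    CategoryLabel.UNIGRAM: 1,
    CategoryLabel.BIGRAM: 2,
    CategoryLabel.TRIGRAM: 3,
    CategoryLabel.TETRAGRAM: 4,
    CategoryLabel.EXTENDED: "extended",
}


def _pick(rng: np.random.Generator, pool: list[str]) -> str:
    return pool[int(rng.integers(len(pool)))]


def _concept_phrase(
    rng: np.random.Generator, category: CategoryLabel, pools: dict[object, list[str]]
) -> str:
    if category is CategoryLabel.COMPOUND:
        first = _pick(rng, pools[1])
        second = _pick(rng, pools[1])
        while second == first and len(pools[1]) > 1:
            second = _pick(rng, pools[1])
        return f"{first} and {second}"
    pool = pools[_POOL_KEY[category]]
    if not pool:
        raise ValueError(f"lexicon has no phrase of category {category.value!r}")
    return _pick(rng, pool)


def generate_corpus(config: CorpusConfig, lexicon) -> list[GoldDocument]:
    """Generate one synthetic corpus (one document per note).

    Per screen, independently: with probability ``concept_screen_fraction``
    the screen carries a concept; a carried concept is negated with
    probability ``negated_fraction`` (planted in a denial template and
    recorded as a do-not-annotate span), else rendered as a tabular screen
    with probability ``tabular_screen_fraction`` or as a sentence whose
    category is drawn from ``category_mix``.  Remaining screens are neutral
    filler.  ``line_index`` is the global record position, so the corpus can
    round-trip through one JSONL file.
    """
    if not lexicon:
        raise ValueError("generate_corpus requires a non-empty lexicon")
    labeling = LabelingConfig()
    pools = _phrase_pools(lexicon, labeling)
    for key, pool in pools.items():
        if not pool:
            raise ValueError(f"lexicon has no phrases for pool {key!r}")
    rng = np.random.default_rng(config.seed)
    mix_cats = list(config.category_mix.keys())
    mix_probs = np.array([config.category_mix[c] for c in mix_cats], dtype=float)
    mix_probs = mix_probs / mix_probs.sum()

    docs: list[GoldDocument] = []
    line_index = 0
    for n in range(config.n_notes):
        note_id = f"note-{n:03d}"
        screens: list[Screen] = []
        gold: dict[ScreenKey, list[SpanAnnotation]] = {}
        negated: dict[ScreenKey, list[SpanAnnotation]] = {}
        for _ in range(config.screens_per_note):
            key = (note_id, line_index)
            if rng.random() >= config.concept_screen_fraction:
                text = NULL_TEMPLATES[int(rng.integers(len(NULL_TEMPLATES)))]
                screens.append(Screen(note_id, line_index, text))
            elif rng.random() < config.negated_fraction:
                phrase = _pick(rng, pools[1] + pools[2])
                prefix, suffix = NEGATION_TEMPLATES[int(rng.integers(len(NEGATION_TEMPLATES)))]
                text = prefix + phrase + suffix
                screen = Screen(note_id, line_index, text)
                screens.append(screen)
                span = SpanAnnotation(
                    start=len(prefix),
                    end=len(prefix) + len(phrase),
                    surface=phrase,
                    label=assign_category(
                        SpanAnnotation(len(prefix), len(prefix) + len(phrase), phrase,
                                       CategoryLabel.UNIGRAM),
                        screen, labeling),
                )
                negated[key] = [span]
            elif rng.random() < config.tabular_screen_fraction:
                phrase = _pick(rng, pools[1] + pools[2])
                text = phrase + TABULAR_SUFFIX
                screens.append(Screen(note_id, line_index, text))
                gold[key] = [
                    SpanAnnotation(0, len(phrase), phrase, CategoryLabel.TABULAR)
                ]
            else:
                spans: list[SpanAnnotation] = []
                category = mix_cats[int(rng.choice(len(mix_cats), p=mix_probs))]
                phrase = _concept_phrase(rng, category, pools)
                prefix, suffix = POSITIVE_TEMPLATES[int(rng.integers(len(POSITIVE_TEMPLATES)))]
                text = prefix + phrase + suffix
                spans.append(
                    SpanAnnotation(len(prefix), len(prefix) + len(phrase), phrase, category)
                )
                for _ in range(config.spans_per_concept_screen - 1):
                    extra_cat = mix_cats[int(rng.choice(len(mix_cats), p=mix_probs))]
                    extra = _concept_phrase(rng, extra_cat, pools)
                    lead = " Also notes "
                    start = len(text) + len(lead)
                    text = text + lead + extra + "."
                    spans.append(SpanAnnotation(start, start + len(extra), extra, extra_cat))
                screens.append(Screen(note_id, line_index, text))
                gold[key] = spans
            line_index += 1
        docs.append(GoldDocument(note_id, screens, gold, negated))
    return docs


def corpus_screens(docs: list[GoldDocument]) -> list[Screen]:
    """Flatten a corpus into its ordered screen list."""
    return [screen for doc in docs for screen in doc.screens]


def gold_annotation_set(docs: list[GoldDocument], rater_id: str = "GOLD") -> AnnotationSet:
    """The gold spans as an AnnotationSet (a perfect rater's output)."""
    annotations = {}
    for doc in docs:
        for key, spans in doc.gold.items():
            annotations[key] = sorted(spans, key=lambda s: s.start)
    return AnnotationSet(rater_id=rater_id, annotations=annotations)


_TOKEN_RE = re.compile(r"\S+")


def _token_offsets(text: str) -> list[tuple[int, int]]:
    return [(m.start(), m.end()) for m in _TOKEN_RE.finditer(text)]


def _jitter_span(
    rng: np.random.Generator, span: SpanAnnotation, screen: Screen
) -> tuple[int, int]:
    """Move one span edge by one token; return possibly-unchanged offsets."""
    offsets = _token_offsets(screen.text)
    starts = [s for s, _ in offsets]
    ends = [e for _, e in offsets]
    inside = [i for i, (s, e) in enumerate(offsets) if s >= span.start and e <= span.end]
    moves: list[tuple[int, int]] = []
    if span.start in starts:
        i = starts.index(span.start)
        if i > 0:  # extend left
            moves.append((starts[i - 1], span.end))
        if len(inside) > 1:  # shrink from the left
            moves.append((starts[inside[1]], span.end))
    if span.end in ends:
        j = ends.index(span.end)
        if j < len(ends) - 1:  # extend right
            moves.append((span.start, ends[j + 1]))
        if len(inside) > 1:  # shrink from the right
            moves.append((span.start, ends[inside[-2]]))
    valid = [(s, e) for s, e in moves if 0 <= s < e <= len(screen.text)]
    if not valid:
        return span.start, span.end
    return valid[int(rng.integers(len(valid)))]


def _confused_label(
    rng: np.random.Generator,
    label: CategoryLabel,
    confusion: dict[CategoryLabel, dict[CategoryLabel, float]] | None,
) -> CategoryLabel:
    if confusion is None or label not in confusion:
        return label
    row = confusion[label]
    r = rng.random()
    cumulative = 0.0
    for cat, p in row.items():
        cumulative += p
        if r < cumulative:
            return cat
    return label


def _overlaps(start: int, end: int, spans: list[tuple[int, int]]) -> bool:
    return any(start < e and s < end for s, e in spans)


def simulate_annotator(docs: list[GoldDocument], profile: AnnotatorProfile) -> AnnotationSet:
    """Simulate one rater over a gold corpus.

    Each gold span is annotated with its category's sensitivity; annotated
    spans get boundary jitter and label confusion per the profile.  Negated
    spans are wrongly annotated at ``negation_error_rate``.  Spurious spans
    of one or two tokens are placed on non-gold, non-negated text at
    ``false_positive_rate`` per 100 screens.  Bit-reproducible given
    ``profile.seed``.
    """
    rng = np.random.default_rng(profile.seed)
    labeling = LabelingConfig()
    annotations: dict[ScreenKey, list[SpanAnnotation]] = {}
    fp_prob = profile.false_positive_rate / 100.0
    for doc in docs:
        for screen in doc.screens:
            key = screen.key
            gold = doc.gold.get(key, [])
            negated = doc.negated.get(key, [])
            taken: list[tuple[int, int]] = []
            spans: list[SpanAnnotation] = []

            for gspan in gold:
                if rng.random() >= profile.sensitivity_for(gspan.label):
                    continue
                start, end = gspan.start, gspan.end
                if profile.boundary_jitter and rng.random() < profile.boundary_jitter:
                    start, end = _jitter_span(rng, gspan, screen)
                if _overlaps(start, end, taken):
                    continue
                label = _confused_label(rng, gspan.label, profile.label_confusion)
                spans.append(SpanAnnotation(start, end, screen.text[start:end], label))
                taken.append((start, end))

            for nspan in negated:
                if rng.random() < profile.negation_error_rate and not _overlaps(
                    nspan.start, nspan.end, taken
                ):
                    label = _confused_label(rng, nspan.label, profile.label_confusion)
                    spans.append(
                        SpanAnnotation(nspan.start, nspan.end, nspan.surface, label)
                    )
                    taken.append((nspan.start, nspan.end))

            if fp_prob and rng.random() < fp_prob:
                offsets = _token_offsets(screen.text)
                forbidden = taken + [(s.start, s.end) for s in gold] + [
                    (s.start, s.end) for s in negated
                ]
                for _ in range(10):  # rejection-sample a free token window
                    if not offsets:
                        break
                    i = int(rng.integers(len(offsets)))
                    width = int(rng.integers(1, 3))
                    j = min(i + width - 1, len(offsets) - 1)
                    start, end = offsets[i][0], offsets[j][1]
                    if not _overlaps(start, end, forbidden):
                        fp = SpanAnnotation(
                            start, end, screen.text[start:end], CategoryLabel.UNIGRAM
                        )
                        label = assign_category(fp, screen, labeling)
                        spans.append(replace(fp, label=label))
                        taken.append((start, end))
                        break

            if spans:
                annotations[key] = sorted(spans, key=lambda s: (s.start, s.end))
    return AnnotationSet(rater_id=profile.rater_id, annotations=annotations)


def expected_concordance(
    profile_a: AnnotatorProfile, profile_b: AnnotatorProfile, f: float
) -> float:
    """Closed-form concordance for two error-free-boundary raters.

    Valid only when both profiles have zero false-positive, jitter and
    negation-error rates, sensitivities are scalar, and the corpus plants
    exactly one gold span per concept screen with no negated screens
    (``negated_fraction=0``), so that ``f`` is the realized gold-screen
    fraction.  Then a concept screen agrees when both raters mark the span
    or both miss it (a missed-by-both screen is a null screen and agrees):

        (1 − f) + f · [sA·sB + (1 − sA)(1 − sB)]
    """
    for profile in (profile_a, profile_b):
        if not isinstance(profile.sensitivity, (int, float)):
            raise ValueError("closed form requires scalar sensitivities")
        if profile.false_positive_rate or profile.boundary_jitter or profile.negation_error_rate:
            raise ValueError(
                "closed form requires zero false-positive, jitter and negation-error rates"
            )
    if not 0.0 <= f <= 1.0:
        raise ValueError("f must be in [0, 1]")
    sa, sb = float(profile_a.sensitivity), float(profile_b.sensitivity)
    return (1.0 - f) + f * (sa * sb + (1.0 - sa) * (1.0 - sb))


def write_corpus(
    docs: list[GoldDocument], out_dir: Union[str, Path]
) -> dict[str, Path]:
    """Write screens.jsonl plus a gold-standard sidecar; return the paths."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    screens = corpus_screens(docs)
    screens_path = out_dir / "screens.jsonl"
    with screens_path.open("w", encoding="utf-8") as handle:
        for screen in screens:
            handle.write(
                json.dumps(
                    {"note_id": screen.note_id, "text": screen.text},
                    ensure_ascii=False, sort_keys=True,
                )
                + "\n"
            )
    gold_path = out_dir / "gold.jsonl"
    write_annotations(gold_annotation_set(docs), screens, gold_path)
    negated_path = out_dir / "negated.jsonl"
    negated_set = AnnotationSet(
        rater_id="NEGATED",
        annotations={k: v for doc in docs for k, v in doc.negated.items()},
    )
    write_annotations(negated_set, screens, negated_path)
    return {"screens": screens_path, "gold": gold_path, "negated": negated_path}
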