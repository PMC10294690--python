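"""Normalization of annotated text spans to concepts in a concept catalog.

Normalization is the second step of clinical concept extraction: a free-text
span ("patient movements were ataxic") is mapped to a canonical concept
(ataxia) and its machine-readable code (the UMLS CUI C0004134).  The primary
mechanism is a phrase lookup table built from every concept's preferred label
and synonyms; spans missing the table fall back to a string-similarity search
with a configurable threshold.

The default similarity scorer is a character-trigram cosine: deterministic,
dependency-free, and adequate for inflectional variants (ataxic/ataxia).  A
different scorer can be passed to :func:`normalize_span`.

The packaged fixture catalog (``data/synthetic_neuro_ontology.tsv``) is a
small synthetic stand-in, ~60 neurologic sign/symptom concepts shaped like a
real neuro-ontology; see :func:`load_fixture_concepts`.
"""

from __future__ import annotations

import csv
import logging
import string
from collections import Counter
from dataclasses import dataclass, field
from importlib import resources
from math import sqrt
from pathlib import Path
from typing import Callable, Literal, Union

from .annotation_model import AnnotationSet

__all__ = [
    "Concept",
    "LookupTable",
    "ConceptMatch",
    "AmbiguousPhraseError",
    "normalize_phrase",
    "load_concepts",
    "load_fixture_concepts",
    "build_lookup",
    "phrase_similarity",
    "normalize_span",
    "normalize_set",
]

logger = logging.getLogger(__name__)

DEFAULT_THRESHOLD = 0.7


class AmbiguousPhraseError(ValueError):
    """The same phrase maps to two different concepts."""


@dataclass(frozen=True)
class Concept:
    """A catalog entry: identifier, preferred label, external code, synonyms."""

    concept_id: str
    preferred_label: str
    code: str
    synonyms: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if not self.preferred_label:
            raise ValueError(f"concept {self.concept_id!r} has an empty preferred label")

    def phrases(self) -> tuple[str, ...]:
        return (self.preferred_label, *self.synonyms)


@dataclass
class LookupTable:
    """Normalized phrase → concept_id mapping (many phrases per concept)."""

    entries: dict[str, str] = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.entries)


@dataclass(frozen=True)
class ConceptMatch:
    """Outcome of normalizing one span."""

    concept_id: str | None
    code: str | None
    score: float
    method: Literal["exact", "similarity", "none"]


def normalize_phrase(phrase: str) -> str:
    """Lowercase, collapse internal whitespace, strip edge punctuation."""
    collapsed = " ".join(phrase.lower().split())
    return collapsed.strip(string.punctuation + " ")


def load_concepts(path: Union[str, Path]) -> list[Concept]:
    """Load a concept catalog from TSV.

    Columns: ``concept_id``, ``preferred_label``, ``code``, ``synonyms``
    (pipe-delimited, may be empty).
    """
    concepts: list[Concept] = []
    with Path(path).open("r", encoding="utf-8", newline="") as handle:
        reader = csv.DictReader(handle, delimiter="\t")
        for row in reader:
            synonyms = tuple(s for s in (row.get("synonyms") or "").split("|") if s)
            concepts.append(
                Concept(
                    concept_id=row["concept_id"],
                    preferred_label=row["preferred_label"],
                    code=row["code"],
                    synonyms=synonyms,
                )
            )
    seen: dict[str, Concept] = {}
    for c in concepts:
        if c.concept_id in seen:
            raise ValueError(f"duplicate concept_id {c.concept_id!r} in {path}")
        seen[c.concept_id] = c
    return concepts


def load_fixture_concepts() -> list[Concept]:
    """Load the packaged synthetic neuro-ontology fixture."""
    ref = resources.files("neuroagree").joinpath("data/synthetic_neuro_ontology.tsv")
    with resources.as_file(ref) as path:
        return load_concepts(path)


def build_lookup(concepts: list[Concept]) -> LookupTable:
    """One entry per preferred label and synonym, phrase-normalized.

    The same phrase may be listed repeatedly under one concept, but a phrase
    shared by two concepts is ambiguous and raises.
    """
    entries: dict[str, str] = {}
    for concept in concepts:
        for phrase in concept.phrases():
            key = normalize_phrase(phrase)
            if not key:
                raise ValueError(
                    f"concept {concept.concept_id!r}: phrase {phrase!r} normalizes to nothing"
                )
            other = entries.get(key)
            if other is not None and other != concept.concept_id:
                raise AmbiguousPhraseError(
                    f"phrase {key!r} maps to both {other!r} and {concept.concept_id!r}"
                )
            entries[key] = concept.concept_id
    return LookupTable(entries=entries)


def _trigrams(s: str) -> Counter:
    if len(s) < 3:
        return Counter([s])
    return Counter(s[i : i + 3] for i in range(len(s) - 2))


def phrase_similarity(a: str, b: str) -> float:
    """Character-trigram cosine similarity on normalized phrases, in [0, 1].

    Symmetric; exactly 1.0 iff the normalized phrases are equal (an unequal
    pair with identical trigram profiles is capped just below 1).
    """
    if not a.strip() or not b.strip():
        raise ValueError("phrase_similarity requires two non-empty strings")
    na, nb = normalize_phrase(a), normalize_phrase(b)
    if na == nb:
        return 1.0
    ta, tb = _trigrams(na), _trigrams(nb)
    dot = sum(ta[g] * tb.get(g, 0) for g in ta)
    if dot == 0:
        return 0.0
    cos = dot / (sqrt(sum(v * v for v in ta.values())) * sqrt(sum(v * v for v in tb.values())))
    return min(cos, 1.0 - 1e-9)


Scorer = Callable[[str, str], float]


def normalize_span(
    surface: str,
    table: LookupTable,
    concepts: list[Concept],
    threshold: float = DEFAULT_THRESHOLD,
    scorer: Scorer = phrase_similarity,
) -> ConceptMatch:
    """Map one span surface to a concept: exact table hit, else best similarity.

    Ties in best similarity are broken by lexicographically smallest
    concept_id.  Below-threshold best matches yield an unmapped result.
    """
    if not surface.strip():
        raise ValueError("cannot normalize an empty surface")
    by_id = {c.concept_id: c for c in concepts}
    key = normalize_phrase(surface)
    cid = table.entries.get(key)
    if cid is not None:
        code = by_id[cid].code if cid in by_id else None
        return ConceptMatch(concept_id=cid, code=code, score=1.0, method="exact")
    if not table.entries:
        logger.info("empty lookup table: %r left unmapped", surface)
        return ConceptMatch(concept_id=None, code=None, score=0.0, method="none")
    best_score, best_cid = 0.0, None
    for phrase, phrase_cid in table.entries.items():
        score = scorer(key, phrase)
        if score > best_score or (score == best_score and best_cid is not None
                                  and phrase_cid < best_cid):
            best_score, best_cid = score, phrase_cid
    if best_cid is not None and best_score >= threshold:
        code = by_id[best_cid].code if best_cid in by_id else None
        return ConceptMatch(concept_id=best_cid, code=code, score=best_score, method="similarity")
    return ConceptMatch(concept_id=None, code=None, score=best_score, method="none")


SpanKey = tuple[str, int, int, int]


def normalize_set(
    aset: AnnotationSet,
    table: LookupTable,
    concepts: list[Concept],
    threshold: float = DEFAULT_THRESHOLD,
    scorer: Scorer = phrase_similarity,
) -> dict[SpanKey, ConceptMatch]:
    """Normalize every span of an annotation set.

    Keys are ``(note_id, line_index, start, end)``; unmapped spans are
    retained with method "none".  Summary counts are logged.
    """
    out: dict[SpanKey, ConceptMatch] = {}
    for (note_id, line_index), spans in aset.annotations.items():
        for span in spans:
            out[(note_id, line_index, span.start, span.end)] = normalize_span(
                span.surface, table, concepts, threshold, scorer
            )
    tally = Counter(m.method for m in out.values())
    logger.info(
        "normalized %d spans for rater %s: %d exact, %d similarity, %d unmapped",
        len(out), aset.rater_id, tally["exact"], tally["similarity"], tally["none"],
    )
    return out
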