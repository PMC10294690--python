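"""Automatic assignment of the seven-way category-label taxonomy.

A span's label is decided by a total priority rule:

1. ``tabular`` if the *screen* is laid out as columns (runs of multiple
   spaces, or right/left side headers);
2. ``compound`` if the span joins two or more concepts with a conjunction
   ("and", "or") or a comma — this outranks length, since compound spans such
   as "brisk ankle and knee reflex" can exceed four tokens;
3. otherwise by whitespace token count: 1 unigram, 2 bigram, 3 trigram,
   4 tetragram, more than 4 extended.

Hyphenated words count as a single token by default ("visuo-spatial neglect"
is a bigram); this is configurable because hyphen handling is a known source
of label disagreement between raters.
"""

from __future__ import annotations

import re
import string
from dataclasses import dataclass, field

from .annotation_model import (
    AnnotationSet,
    CategoryLabel,
    Screen,
    SpanAnnotation,
    ValidationError,
)

__all__ = [
    "LabelingConfig",
    "token_count",
    "assign_category",
    "relabel_set",
    "is_tabular_screen",
    "is_compound_surface",
]

_WORD_MARKERS = frozenset({"and", "or"})

_LENGTH_LABELS = {
    1: CategoryLabel.UNIGRAM,
    2: CategoryLabel.BIGRAM,
    3: CategoryLabel.TRIGRAM,
    4: CategoryLabel.TETRAGRAM,
}


@dataclass(frozen=True)
class LabelingConfig:
    """Tunable conventions for label assignment.

    ``compound_markers`` are tokens that join concept heads inside one span.
    The tabular detector fires when a screen contains at least
    ``tabular_min_space_runs`` runs of two or more consecutive spaces
    (column alignment), or — when ``tabular_side_headers`` is on — both the
    words "right" and "left" (body-side column headers).
    """

    hyphen_joins_tokens: bool = True
    compound_markers: tuple[str, ...] = ("and", "or", ",")
    tabular_min_space_runs: int = 2
    tabular_side_headers: bool = True

    def __post_init__(self) -> None:
        if not self.compound_markers:
            raise ValueError("compound_markers must be non-empty")


def _tokens(surface: str, config: LabelingConfig) -> list[str]:
    toks = surface.split()
    if not config.hyphen_joins_tokens:
        toks = [part for tok in toks for part in tok.split("-") if part]
    return toks


def token_count(surface: str, config: LabelingConfig | None = None) -> int:
    """Number of whitespace tokens in a span surface (hyphen rule applied)."""
    config = config or LabelingConfig()
    toks = _tokens(surface, config)
    if not toks:
        raise ValidationError("cannot count tokens of an empty or whitespace-only surface")
    return len(toks)


def is_tabular_screen(text: str, config: LabelingConfig | None = None) -> bool:
    """True if the screen text looks column-aligned."""
    config = config or LabelingConfig()
    if len(re.findall(r" {2,}", text)) >= config.tabular_min_space_runs:
        return True
    if config.tabular_side_headers:
        lowered = text.lower()
        if re.search(r"\bright\b", lowered) and re.search(r"\bleft\b", lowered):
            return True
    return False


def is_compound_surface(surface: str, config: LabelingConfig | None = None) -> bool:
    """True if a compound marker joins tokens strictly inside the span."""
    config = config or LabelingConfig()
    toks = surface.split()
    word_markers = {m for m in config.compound_markers if m not in string.punctuation}
    punct_markers = [m for m in config.compound_markers if m in string.punctuation]
    for i, tok in enumerate(toks):
        bare = tok.strip(string.punctuation).lower()
        if bare in word_markers and 0 < i < len(toks) - 1:
            return True
        # attached punctuation marker, e.g. "headache, nausea"
        if i < len(toks) - 1 and any(tok.endswith(m) for m in punct_markers):
            return True
    return False


def assign_category(
    span: SpanAnnotation, screen: Screen, config: LabelingConfig | None = None
) -> CategoryLabel:
    """Label a span by the tabular > compound > length priority rule."""
    config = config or LabelingConfig()
    if screen.text[span.start : span.end] != span.surface:
        raise ValidationError(
            f"span surface {span.surface!r} does not match screen {screen.key}"
        )
    if is_tabular_screen(screen.text, config):
        return CategoryLabel.TABULAR
    if is_compound_surface(span.surface, config):
        return CategoryLabel.COMPOUND
    n = token_count(span.surface, config)
    return _LENGTH_LABELS.get(n, CategoryLabel.EXTENDED)


def relabel_set(
    aset: AnnotationSet, screens: list[Screen], config: LabelingConfig | None = None
) -> AnnotationSet:
    """Replace every span's label with the rule-assigned one (idempotent).

    Span offsets are untouched; errors are re-raised with screen context.
    """
    config = config or LabelingConfig()
    by_key = {s.key: s for s in screens}
    out: dict = {}
    for key, spans in aset.annotations.items():
        screen = by_key.get(key)
        if screen is None:
            raise ValidationError(f"annotation set refers to unknown screen {key}")
        relabeled = []
        for span in spans:
            try:
                label = assign_category(span, screen, config)
            except ValidationError as exc:
                raise ValidationError(f"screen {key}: {exc}") from exc
            relabeled.append(
                SpanAnnotation(start=span.start, end=span.end, surface=span.surface, label=label)
            )
        out[key] = relabeled
    return AnnotationSet(rater_id=aset.rater_id, annotations=out)
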