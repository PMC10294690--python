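"""Domain types and JSONL input/output for span-annotated clinical notes.

A clinical note is split into lines; each line is presented to a rater as a
single annotation context, called a *screen*.  A rater marks contiguous
character ranges (*spans*) on a screen, each carrying one of seven category
labels describing the shape of the marked phrase.  One annotation file holds
the output of exactly one rater over a corpus of screens, as newline-delimited
JSON: one object per screen with a ``text`` field and a ``spans`` list of
``{"start": int, "end": int, "label": str}`` objects (the dialect emitted by
span-annotation tools such as Prodigy).

Offsets are 0-based, half-open ``[start, end)``, counted in Unicode code
points.  Within one rater's output the spans of a screen must be
non-overlapping and sorted by start.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Iterable, Union

__all__ = [
    "CategoryLabel",
    "Screen",
    "SpanAnnotation",
    "AnnotationSet",
    "ValidationFinding",
    "AnnotationFormatError",
    "ValidationError",
    "read_screens",
    "read_annotations",
    "write_annotations",
    "validate_annotation_set",
]

ScreenKey = tuple[str, int]

DEFAULT_NOTE_ID = "note"


class AnnotationFormatError(ValueError):
    """A record in an annotation file could not be parsed."""


class ValidationError(ValueError):
    """An annotation violates a structural invariant."""


class CategoryLabel(str, Enum):
    """Seven-way taxonomy describing the shape of an annotated phrase.

    The first five classes are by token length (one to four words, then
    anything longer); ``compound`` marks a single span containing several
    distinct concepts joined by a conjunction or comma; ``tabular`` marks
    spans on screens laid out as columns (typically right/left body sides).
    """

    UNIGRAM = "unigram"
    BIGRAM = "bigram"
    TRIGRAM = "trigram"
    TETRAGRAM = "tetragram"
    EXTENDED = "extended"
    COMPOUND = "compound"
    TABULAR = "tabular"


@dataclass(frozen=True)
class Screen:
    """One line of note text: the atomic annotation context."""

    note_id: str
    line_index: int
    text: str

    @property
    def key(self) -> ScreenKey:
        return (self.note_id, self.line_index)


@dataclass(frozen=True)
class SpanAnnotation:
    """A character-offset span with its category label.

    ``surface`` is the exact substring ``screen.text[start:end]`` and is
    stored redundantly so a span is interpretable without its screen.
    """

    start: int
    end: int
    surface: str
    label: CategoryLabel

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValidationError(
                f"span offsets must satisfy 0 <= start < end, got ({self.start}, {self.end})"
            )
        if len(self.surface) != self.end - self.start:
            raise ValidationError(
                f"surface length {len(self.surface)} != end - start = {self.end - self.start}"
            )

    @property
    def key(self) -> tuple[int, int]:
        return (self.start, self.end)


@dataclass
class AnnotationSet:
    """One rater's spans over a corpus, keyed by (note_id, line_index)."""

    rater_id: str
    annotations: dict[ScreenKey, list[SpanAnnotation]] = field(default_factory=dict)

    def spans_for(self, key: ScreenKey) -> list[SpanAnnotation]:
        return self.annotations.get(key, [])

    def n_spans(self) -> int:
        return sum(len(v) for v in self.annotations.values())


@dataclass(frozen=True)
class ValidationFinding:
    """One invariant violation, naming the screen, span and rule."""

    screen_key: ScreenKey
    span: SpanAnnotation | None
    rule: str
    message: str


def _iter_records(path: Union[str, Path]) -> Iterable[tuple[int, dict]]:
    """Yield (record_index, parsed object) per non-empty line of a JSONL file."""
    path = Path(path)
    index = 0
    with path.open("r", encoding="utf-8") as handle:
        for lineno, line in enumerate(handle, start=1):
            if not line.strip():
                continue
            try:
                record = json.loads(line)
            except json.JSONDecodeError as exc:
                raise AnnotationFormatError(
                    f"{path}: malformed JSON record on line {lineno}: {exc}"
                ) from exc
            if not isinstance(record, dict):
                raise AnnotationFormatError(
                    f"{path}: record on line {lineno} is not a JSON object"
                )
            yield index, record
            index += 1


def _record_text(record: dict, path: Path, index: int) -> str:
    if "text" not in record:
        raise ValidationError(f"{path}: record {index} is missing the 'text' field")
    text = record["text"]
    if not isinstance(text, str):
        raise ValidationError(f"{path}: record {index} has a non-string 'text' field")
    return text


def read_screens(path: Union[str, Path]) -> list[Screen]:
    """Read a JSONL corpus file into an ordered list of screens.

    ``line_index`` is the record's position in the file; ``note_id`` is taken
    from the record when present, else a fixed default (offset uniqueness is
    then carried by ``line_index`` alone).
    """
    path = Path(path)
    screens: list[Screen] = []
    for index, record in _iter_records(path):
        text = _record_text(record, path, index)
        note_id = str(record.get("note_id", DEFAULT_NOTE_ID))
        screens.append(Screen(note_id=note_id, line_index=index, text=text))
    return screens


def _parse_span(raw: dict, text: str, path: Path, index: int) -> SpanAnnotation:
    try:
        start = int(raw["start"])
        end = int(raw["end"])
        label_name = raw["label"]
    except (KeyError, TypeError, ValueError) as exc:
        raise AnnotationFormatError(
            f"{path}: record {index} has a span missing start/end/label: {raw!r}"
        ) from exc
    if not (0 <= start < end <= len(text)):
        raise ValidationError(
            f"{path}: record {index}: span ({start}, {end}) outside text of length {len(text)}"
        )
    try:
        label = CategoryLabel(label_name)
    except ValueError as exc:
        raise ValidationError(
            f"{path}: record {index}: unknown category label {label_name!r}"
        ) from exc
    return SpanAnnotation(start=start, end=end, surface=text[start:end], label=label)


def read_annotations(path: Union[str, Path], rater_id: str) -> AnnotationSet:
    """Read one rater's JSONL annotation file.

    Surfaces are reconstructed from each record's own text.  Spans are sorted
    by start; overlapping spans within one screen are rejected.
    """
    path = Path(path)
    annotations: dict[ScreenKey, list[SpanAnnotation]] = {}
    for index, record in _iter_records(path):
        text = _record_text(record, path, index)
        note_id = str(record.get("note_id", DEFAULT_NOTE_ID))
        spans = [_parse_span(raw, text, path, index) for raw in record.get("spans", [])]
        spans.sort(key=lambda s: (s.start, s.end))
        for prev, cur in zip(spans, spans[1:]):
            if cur.start < prev.end:
                raise ValidationError(
                    f"{path}: record {index}: overlapping spans "
                    f"({prev.start}, {prev.end}) and ({cur.start}, {cur.end})"
                )
        annotations[(note_id, index)] = spans
    return AnnotationSet(rater_id=rater_id, annotations=annotations)


def write_annotations(
    aset: AnnotationSet, screens: list[Screen], path: Union[str, Path]
) -> Path:
    """Write one rater's annotations over ``screens`` as a JSONL file.

    One record per screen, in screen order, with empty span lists for screens
    the rater left unannotated.  ``read_annotations`` of the written file
    reproduces ``aset`` exactly (restricted to the given screens).
    """
    path = Path(path)
    known = {s.key for s in screens}
    stray = set(aset.annotations) - known
    if stray:
        raise ValidationError(
            f"annotation set for rater {aset.rater_id!r} refers to unknown screens: "
            f"{sorted(stray)[:5]}"
        )
    with path.open("w", encoding="utf-8") as handle:
        for screen in screens:
            record = {
                "note_id": screen.note_id,
                "text": screen.text,
                "spans": [
                    {"start": s.start, "end": s.end, "label": s.label.value}
                    for s in aset.spans_for(screen.key)
                ],
            }
            handle.write(json.dumps(record, ensure_ascii=False, sort_keys=True) + "\n")
    return path


def validate_annotation_set(
    aset: AnnotationSet, screens: list[Screen]
) -> list[ValidationFinding]:
    """Check every structural invariant; return findings instead of raising.

    Rules checked per screen: the key refers to an existing screen; each span
    lies within the text; the stored surface equals the substring at its
    offsets; spans are sorted by start and non-overlapping.
    """
    by_key = {s.key: s for s in screens}
    findings: list[ValidationFinding] = []
    for key, spans in aset.annotations.items():
        screen = by_key.get(key)
        if screen is None:
            findings.append(
                ValidationFinding(key, None, "unknown-screen", f"no screen with key {key}")
            )
            continue
        for span in spans:
            if span.end > len(screen.text):
                findings.append(
                    ValidationFinding(
                        key, span, "out-of-bounds",
                        f"span ({span.start}, {span.end}) exceeds text length {len(screen.text)}",
                    )
                )
            elif screen.text[span.start : span.end] != span.surface:
                findings.append(
                    ValidationFinding(
                        key, span, "surface-mismatch",
                        f"surface {span.surface!r} != text[{span.start}:{span.end}] "
                        f"= {screen.text[span.start:span.end]!r}",
                    )
                )
        ordered = sorted(spans, key=lambda s: (s.start, s.end))
        if ordered != spans:
            findings.append(
                ValidationFinding(key, None, "unsorted", "spans are not sorted by start")
            )
        for prev, cur in zip(ordered, ordered[1:]):
            if cur.start < prev.end:
                findings.append(
                    ValidationFinding(
                        key, cur, "overlap",
                        f"span ({cur.start}, {cur.end}) overlaps ({prev.start}, {prev.end})",
                    )
                )
    return findings
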