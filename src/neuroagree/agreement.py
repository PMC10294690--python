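"""Agreement units, concordance and Cohen's Kappa for two raters' spans.

The unit of agreement is per *span*, not per screen: for a pair of raters A
and B, every element of the union of their spans on a screen contributes one
item to the Kappa denominator, and a screen annotated by neither rater (a
*null screen*) contributes exactly one agreeing item.  The total number of
units is therefore |A ∪ B| + (number of null screens).

Two tasks share the same unit list:

* **span task** — a unit's ratings are "present"/"null" depending on whether
  each rater marked the (matched) span;
* **label task** — a unit's ratings are each rater's category label, or
  "null" for the rater who did not mark the span.  Unmatched spans thus count
  as label disagreements against "null", keeping the denominator shared.

Concordance is the unadjusted percent agreement, 100·po.  Cohen's κ corrects
observed agreement po for the chance agreement pe implied by each rater's
marginal rating frequencies over the units: κ = (po − pe) / (1 − pe).
"""

from __future__ import annotations

import logging
import warnings
from collections import Counter
from dataclasses import dataclass
from itertools import combinations
from typing import Literal

from .annotation_model import AnnotationSet, Screen, SpanAnnotation, ValidationError

__all__ = [
    "NULL_RATING",
    "PRESENT_RATING",
    "MatchConfig",
    "AgreementUnit",
    "AgreementResult",
    "UndefinedKappaError",
    "match_spans",
    "build_units",
    "observed_agreement",
    "expected_agreement",
    "cohen_kappa",
    "concordance",
    "agreement_result",
    "pairwise_agreement",
]

logger = logging.getLogger(__name__)

NULL_RATING = "null"
PRESENT_RATING = "present"

Task = Literal["span", "label"]


class UndefinedKappaError(ValueError):
    """κ is undefined: chance agreement is 1 while observed agreement is not."""


@dataclass(frozen=True)
class MatchConfig:
    """How two raters' spans on one screen are paired.

    ``exact`` pairs spans with identical (start, end) offsets; ``overlap``
    pairs greedily by maximal character overlap (ties: leftmost start).
    ``trim_edges`` ignores leading/trailing whitespace inside a span when
    comparing offsets.
    """

    mode: Literal["exact", "overlap"] = "exact"
    trim_edges: bool = False

    def __post_init__(self) -> None:
        if self.mode not in ("exact", "overlap"):
            raise ValueError(f"unknown match mode {self.mode!r}")


@dataclass(frozen=True)
class AgreementUnit:
    """One item in the Kappa denominator for a rater pair."""

    screen_key: tuple[str, int]
    unit_kind: Literal["span_unit", "null_screen_unit"]
    span_key: tuple[int, int] | None
    rating_a: str
    rating_b: str

    def agrees(self) -> bool:
        return self.rating_a == self.rating_b


@dataclass(frozen=True)
class AgreementResult:
    """Summary statistics for one rater pair on one task."""

    task: str
    n_units: int
    po: float
    pe: float
    kappa: float
    concordance_pct: float


def _effective_key(span: SpanAnnotation, config: MatchConfig) -> tuple[int, int]:
    if not config.trim_edges:
        return span.key
    surface = span.surface
    lead = len(surface) - len(surface.lstrip())
    trail = len(surface) - len(surface.rstrip())
    start, end = span.start + lead, span.end - trail
    return (start, end) if start < end else span.key


def match_spans(
    spans_a: list[SpanAnnotation],
    spans_b: list[SpanAnnotation],
    config: MatchConfig | None = None,
) -> tuple[list[tuple[SpanAnnotation, SpanAnnotation]], list[SpanAnnotation], list[SpanAnnotation]]:
    """Partition two raters' spans on one screen into pairs and singletons.

    Returns ``(matched, a_only, b_only)``; the partition is exhaustive and
    disjoint — every input span appears exactly once.
    """
    config = config or MatchConfig()
    if config.mode == "exact":
        by_key_b = {_effective_key(s, config): s for s in spans_b}
        matched, a_only = [], []
        used = set()
        for sa in spans_a:
            key = _effective_key(sa, config)
            sb = by_key_b.get(key)
            if sb is not None and key not in used:
                matched.append((sa, sb))
                used.add(key)
            else:
                a_only.append(sa)
        b_only = [s for s in spans_b if _effective_key(s, config) not in used]
        return matched, a_only, b_only

    # overlap mode: greedy pairing by maximal character overlap
    candidates = []
    for i, sa in enumerate(spans_a):
        ka = _effective_key(sa, config)
        for j, sb in enumerate(spans_b):
            kb = _effective_key(sb, config)
            ov = min(ka[1], kb[1]) - max(ka[0], kb[0])
            if ov > 0:
                candidates.append((-ov, ka[0], kb[0], i, j))
    candidates.sort()
    matched, used_a, used_b = [], set(), set()
    for _, _, _, i, j in candidates:
        if i not in used_a and j not in used_b:
            matched.append((spans_a[i], spans_b[j]))
            used_a.add(i)
            used_b.add(j)
    a_only = [s for i, s in enumerate(spans_a) if i not in used_a]
    b_only = [s for j, s in enumerate(spans_b) if j not in used_b]
    return matched, a_only, b_only


def _rating(span: SpanAnnotation, task: Task) -> str:
    return PRESENT_RATING if task == "span" else span.label.value


def build_units(
    set_a: AnnotationSet,
    set_b: AnnotationSet,
    screens: list[Screen],
    task: Task = "span",
    config: MatchConfig | None = None,
) -> list[AgreementUnit]:
    """Construct the agreement-unit list for a rater pair over a corpus.

    Per screen: no spans from either rater → one agreeing null-screen unit;
    otherwise one unit per matched pair and per singleton span.
    """
    config = config or MatchConfig()
    known = {s.key for s in screens}
    for aset in (set_a, set_b):
        stray = set(aset.annotations) - known
        if stray:
            raise ValidationError(
                f"rater {aset.rater_id!r} annotates screens absent from the corpus: "
                f"{sorted(stray)[:5]}"
            )
    units: list[AgreementUnit] = []
    for screen in screens:
        key = screen.key
        spans_a = set_a.spans_for(key)
        spans_b = set_b.spans_for(key)
        if not spans_a and not spans_b:
            units.append(
                AgreementUnit(key, "null_screen_unit", None, NULL_RATING, NULL_RATING)
            )
            continue
        matched, a_only, b_only = match_spans(spans_a, spans_b, config)
        for sa, sb in matched:
            units.append(
                AgreementUnit(key, "span_unit", sa.key, _rating(sa, task), _rating(sb, task))
            )
        for sa in a_only:
            units.append(AgreementUnit(key, "span_unit", sa.key, _rating(sa, task), NULL_RATING))
        for sb in b_only:
            units.append(AgreementUnit(key, "span_unit", sb.key, NULL_RATING, _rating(sb, task)))
    return units


def _require_units(units: list[AgreementUnit]) -> None:
    if not units:
        raise ValueError("agreement statistics need a non-empty unit list")


def observed_agreement(units: list[AgreementUnit]) -> float:
    """Fraction of units on which both ratings coincide (po)."""
    _require_units(units)
    return sum(u.agrees() for u in units) / len(units)


def expected_agreement(units: list[AgreementUnit]) -> float:
    """Chance agreement pe = Σ_c pA(c)·pB(c) from per-rater marginals."""
    _require_units(units)
    n = len(units)
    marg_a = Counter(u.rating_a for u in units)
    marg_b = Counter(u.rating_b for u in units)
    return sum(marg_a[c] * marg_b.get(c, 0) for c in marg_a) / (n * n)


def cohen_kappa(units: list[AgreementUnit]) -> float:
    """Chance-corrected agreement κ = (po − pe)/(1 − pe).

    If both po and pe are 1 (e.g. an all-null corpus) κ is returned as 1.0 by
    convention, with a warning; pe = 1 with po < 1 raises.  Negative values
    are returned as computed.
    """
    _require_units(units)
    po = observed_agreement(units)
    pe = expected_agreement(units)
    if pe >= 1.0 - 1e-15:
        if po >= 1.0 - 1e-15:
            warnings.warn(
                "degenerate unit list: both raters constant and agreeing; κ = 1.0 by convention",
                stacklevel=2,
            )
            return 1.0
        raise UndefinedKappaError(f"pe = 1 with po = {po:.6f}: kappa undefined")
    return (po - pe) / (1.0 - pe)


def concordance(units: list[AgreementUnit]) -> float:
    """Unadjusted agreement as a percentage: 100 × po."""
    return 100.0 * observed_agreement(units)


def agreement_result(units: list[AgreementUnit], task: Task) -> AgreementResult:
    """Bundle po, pe, κ and concordance for one unit list."""
    po = observed_agreement(units)
    pe = expected_agreement(units)
    return AgreementResult(
        task=task,
        n_units=len(units),
        po=po,
        pe=pe,
        kappa=cohen_kappa(units),
        concordance_pct=100.0 * po,
    )


def pairwise_agreement(
    sets: list[AnnotationSet],
    screens: list[Screen],
    task: Task = "span",
    config: MatchConfig | None = None,
) -> dict[tuple[str, str], AgreementResult]:
    """One AgreementResult per unordered rater pair (keys sorted by rater id)."""
    if len(sets) < 2:
        raise ValueError("pairwise agreement needs at least two annotation sets")
    config = config or MatchConfig()
    results: dict[tuple[str, str], AgreementResult] = {}
    for set_a, set_b in combinations(sets, 2):
        units = build_units(set_a, set_b, screens, task, config)
        pair = tuple(sorted((set_a.rater_id, set_b.rater_id)))
        results[pair] = agreement_result(units, task)
    return results
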