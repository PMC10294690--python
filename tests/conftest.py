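from __future__ import annotations

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from neuroagree.agreement import AgreementUnit
from neuroagree.annotation_model import CategoryLabel, Screen, SpanAnnotation
from neuroagree.ontology import build_lookup, load_fixture_concepts

settings.register_profile(
    "suite",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


SENTENCE = "The patient had weakness and sensory loss"


@pytest.fixture(scope="session")
def fixture_concepts():
    return load_fixture_concepts()


@pytest.fixture(scope="session")
def fixture_lookup(fixture_concepts):
    return build_lookup(fixture_concepts)


@pytest.fixture
def sentence_screen():
    return Screen(note_id="note", line_index=0, text=SENTENCE)


def make_units(n_both=0, n_a_only=0, n_b_only=0, n_null=0):
    """Span-task unit list: matched pairs, singletons, and null screens."""
    units = []
    k = 0
    for _ in range(n_both):
        units.append(AgreementUnit(("note", k), "span_unit", (0, 5), "present", "present"))
        k += 1
    for _ in range(n_a_only):
        units.append(AgreementUnit(("note", k), "span_unit", (0, 5), "present", "null"))
        k += 1
    for _ in range(n_b_only):
        units.append(AgreementUnit(("note", k), "span_unit", (0, 5), "null", "present"))
        k += 1
    for _ in range(n_null):
        units.append(AgreementUnit(("note", k), "null_screen_unit", None, "null", "null"))
        k += 1
    return units


def random_units(rng: np.random.Generator, n: int, categories: list[str]):
    """Unit list with ratings drawn independently at random (possibly degenerate)."""
    units = []
    for i in range(n):
        ra = categories[int(rng.integers(len(categories)))]
        rb = categories[int(rng.integers(len(categories)))]
        kind = "null_screen_unit" if ra == rb == "null" else "span_unit"
        units.append(
            AgreementUnit(("note", i), kind, None if kind == "null_screen_unit" else (0, 5), ra, rb)
        )
    return units


def contingency_kappa(units):
    """Independent brute-force oracle: full contingency table, then po/pe/κ."""
    cats = sorted({u.rating_a for u in units} | {u.rating_b for u in units})
    idx = {c: i for i, c in enumerate(cats)}
    table = np.zeros((len(cats), len(cats)))
    for u in units:
        table[idx[u.rating_a], idx[u.rating_b]] += 1.0
    n = table.sum()
    po = float(np.trace(table) / n)
    pe = float((table.sum(axis=1) / n) @ (table.sum(axis=0) / n))
    kappa = (po - pe) / (1.0 - pe) if pe < 1.0 else (1.0 if po == 1.0 else float("nan"))
    return po, pe, kappa


def span(screen: Screen, start: int, end: int, label=CategoryLabel.UNIGRAM):
    return SpanAnnotation(start=start, end=end, surface=screen.text[start:end], label=label)
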