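"""Aggregation of pairwise agreement across rounds, group comparison by
one-way ANOVA, and the end-to-end pipeline.

Pairwise results are tagged with an annotation round and a rater-pair group
(human-human vs human-machine).  Summaries report per-group mean and sample
SD of κ and concordance, per round and pooled.  Groups are compared with a
classical one-way ANOVA on the pair-round κ (and concordance) values; the
p-value comes from the F distribution at (groups − 1, N − groups) degrees of
freedom.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path
from statistics import mean, stdev
from typing import Sequence, Union

import numpy as np
import pandas as pd
from scipy import stats

from .agreement import AgreementResult, MatchConfig, agreement_result, build_units
from .annotation_model import AnnotationSet, Screen, read_annotations, read_screens
from .category_labeling import LabelingConfig, relabel_set
from .ontology import build_lookup, load_fixture_concepts, normalize_set
from .synthetic import (
    AnnotatorProfile,
    CorpusConfig,
    corpus_screens,
    default_human_profile,
    default_machine_profile,
    generate_corpus,
    simulate_annotator,
    write_corpus,
)

__all__ = [
    "TaggedResult",
    "GroupStats",
    "RoundSummary",
    "AnovaResult",
    "InfiniteFError",
    "ConfigError",
    "ReportBundle",
    "summarize",
    "anova_oneway",
    "run_pipeline",
    "derive_seed",
]

logger = logging.getLogger(__name__)

HUMAN_HUMAN = "human-human"
HUMAN_MACHINE = "human-machine"
MACHINE_MACHINE = "machine-machine"


class InfiniteFError(ValueError):
    """Zero within-group variance with unequal group means: F is infinite."""


class ConfigError(ValueError):
    """The pipeline configuration is missing or inconsistent."""


def derive_seed(*entropy: int) -> int:
    """Deterministically derive a child seed (< 2^31) from integer entropy."""
    return int(np.random.SeedSequence(list(entropy)).generate_state(1)[0] % (2**31))


@dataclass(frozen=True)
class TaggedResult:
    """One pairwise AgreementResult with its round, pair and group tags."""

    round_id: int
    rater_a: str
    rater_b: str
    group: str
    task: str
    result: AgreementResult

    def __post_init__(self) -> None:
        if not self.group:
            raise ValueError("every pairwise result must carry a group tag")


@dataclass(frozen=True)
class GroupStats:
    n: int
    kappa_mean: float
    kappa_sd: float | None
    concordance_mean: float
    concordance_sd: float | None


@dataclass(frozen=True)
class RoundSummary:
    """Per-group statistics for one round (or pooled) and one task."""

    round_id: Union[int, str]
    task: str
    groups: dict[str, GroupStats]


@dataclass(frozen=True)
class AnovaResult:
    F: float
    df_between: int
    df_within: int
    p: float


def _group_stats(results: list[AgreementResult]) -> GroupStats:
    kappas = [r.kappa for r in results]
    concs = [r.concordance_pct for r in results]
    n = len(results)
    return GroupStats(
        n=n,
        kappa_mean=mean(kappas),
        kappa_sd=stdev(kappas) if n > 1 else None,
        concordance_mean=mean(concs),
        concordance_sd=stdev(concs) if n > 1 else None,
    )


def summarize(tagged: list[TaggedResult]) -> list[RoundSummary]:
    """Per-group mean/SD of κ and concordance, per round and pooled.

    Returns one RoundSummary per (round, task) in first-seen order, followed
    by one pooled summary per task (round_id ``"pooled"``).
    """
    if not tagged:
        raise ValueError("summarize needs at least one tagged result")
    by_round: dict[tuple[Union[int, str], str], dict[str, list[AgreementResult]]] = {}
    order: list[tuple[Union[int, str], str]] = []
    tasks: list[str] = []
    for t in tagged:
        rkey = (t.round_id, t.task)
        if rkey not in by_round:
            by_round[rkey] = {}
            order.append(rkey)
        by_round[rkey].setdefault(t.group, []).append(t.result)
        if t.task not in tasks:
            tasks.append(t.task)
    for task in tasks:
        pooled: dict[str, list[AgreementResult]] = {}
        for t in tagged:
            if t.task == task:
                pooled.setdefault(t.group, []).append(t.result)
        by_round[("pooled", task)] = pooled
        order.append(("pooled", task))
    return [
        RoundSummary(
            round_id=round_id,
            task=task,
            groups={g: _group_stats(rs) for g, rs in sorted(by_round[(round_id, task)].items())},
        )
        for round_id, task in order
    ]


def anova_oneway(groups: Sequence[Sequence[float]]) -> AnovaResult:
    """Classical one-way ANOVA over ≥2 groups of ≥2 values each.

    F = (SSB/df_between) / (SSW/df_within); p is the upper tail of the F
    distribution.  All-equal data yield F = 0; zero within-group variance
    with unequal means raises :class:`InfiniteFError`.
    """
    if len(groups) < 2:
        raise ValueError("one-way ANOVA needs at least two groups")
    arrays = [np.asarray(g, dtype=float) for g in groups]
    for i, arr in enumerate(arrays):
        if arr.size < 2:
            raise ValueError(f"group {i} has fewer than two values")
    all_values = np.concatenate(arrays)
    grand = all_values.mean()
    ssb = sum(a.size * (a.mean() - grand) ** 2 for a in arrays)
    ssw = sum(((a - a.mean()) ** 2).sum() for a in arrays)
    df_between = len(arrays) - 1
    df_within = all_values.size - len(arrays)
    if ssw == 0.0:
        if ssb <= 1e-12 * max(1.0, grand * grand):
            return AnovaResult(F=0.0, df_between=df_between, df_within=df_within, p=1.0)
        raise InfiniteFError(
            "zero within-group variance with unequal group means: F is infinite"
        )
    F = (ssb / df_between) / (ssw / df_within)
    p = float(stats.f.sf(F, df_between, df_within))
    return AnovaResult(F=float(F), df_between=df_between, df_within=df_within, p=p)


def _pair_group(kind_a: str, kind_b: str) -> str:
    kinds = sorted((kind_a, kind_b))
    if kinds == ["human", "human"]:
        return HUMAN_HUMAN
    if kinds == ["machine", "machine"]:
        return MACHINE_MACHINE
    return HUMAN_MACHINE


def _build_profile(spec: dict, seed: int) -> AnnotatorProfile:
    kind = spec.get("kind", "human")
    base = (
        default_machine_profile(spec["rater_id"], seed)
        if kind == "machine"
        else default_human_profile(spec["rater_id"], seed)
    )
    overrides = {
        k: v
        for k, v in spec.items()
        if k in ("sensitivity", "false_positive_rate", "boundary_jitter",
                 "negation_error_rate")
    }
    if overrides:
        from dataclasses import replace

        base = replace(base, **overrides)
    return base


@dataclass
class ReportBundle:
    """Everything the pipeline computed, serializable as a JSON report."""

    tagged: list[TaggedResult]
    summaries: list[RoundSummary]
    anovas: dict[str, AnovaResult]
    corpus_stats: list[dict] = field(default_factory=list)
    normalization: dict | None = None

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "round": t.round_id,
                "task": t.task,
                "rater_a": t.rater_a,
                "rater_b": t.rater_b,
                "group": t.group,
                "n_units": t.result.n_units,
                "po": t.result.po,
                "pe": t.result.pe,
                "kappa": t.result.kappa,
                "concordance_pct": t.result.concordance_pct,
            }
            for t in self.tagged
        ]
        return pd.DataFrame(rows)

    def to_dict(self) -> dict:
        return {
            "pairwise": [
                {
                    "round": t.round_id,
                    "task": t.task,
                    "rater_a": t.rater_a,
                    "rater_b": t.rater_b,
                    "group": t.group,
                    **asdict(t.result),
                }
                for t in self.tagged
            ],
            "summaries": [
                {
                    "round": s.round_id,
                    "task": s.task,
                    "groups": {g: asdict(st) for g, st in s.groups.items()},
                }
                for s in self.summaries
            ],
            "anova": {name: asdict(res) for name, res in self.anovas.items()},
            "corpus": self.corpus_stats,
            "normalization": self.normalization,
        }

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), sort_keys=True, indent=2)


def _simulation_rounds(config: dict, seed: int):
    sim = config["simulation"]
    rounds = int(sim.get("rounds", 3))
    corpus_kwargs = dict(sim.get("corpus", {}))
    profile_specs = sim.get("profiles")
    if not profile_specs:
        raise ConfigError("simulation config lists no annotator profiles")
    lexicon = load_fixture_concepts()
    for r in range(1, rounds + 1):
        corpus_cfg = CorpusConfig(**corpus_kwargs, seed=derive_seed(seed, r, 0))
        docs = generate_corpus(corpus_cfg, lexicon)
        screens = corpus_screens(docs)
        profiles = [
            _build_profile(spec, derive_seed(seed, r, i + 1))
            for i, spec in enumerate(profile_specs)
        ]
        sets = [simulate_annotator(docs, p) for p in profiles]
        kinds = {p.rater_id: p.kind for p in profiles}
        n_gold = sum(len(v) for doc in docs for v in doc.gold.values())
        stats_row = {
            "round": r,
            "n_screens": len(screens),
            "n_gold_spans": n_gold,
            "n_negated_spans": sum(len(v) for doc in docs for v in doc.negated.values()),
        }
        yield r, docs, screens, sets, kinds, stats_row


def _file_round(config: dict):
    screens = read_screens(config["screens"])
    sets, kinds = [], {}
    for spec in config["raters"]:
        aset = read_annotations(spec["path"], spec["rater_id"])
        sets.append(aset)
        kinds[spec["rater_id"]] = spec.get("kind", "human")
    stats_row = {"round": 1, "n_screens": len(screens)}
    yield 1, None, screens, sets, kinds, stats_row


def run_pipeline(config: dict, out_dir: Union[str, Path, None] = None) -> ReportBundle:
    """Execute the full pipeline from a structured configuration.

    The config either contains a ``simulation`` block (rounds, corpus
    parameters, annotator profiles) or names real annotation files
    (``screens`` plus a ``raters`` list).  Stages: generate/read →
    (optionally) relabel → agreement units → pairwise κ/concordance per task
    → group summaries → one-way ANOVA (human-human vs human-machine, pooled
    across rounds) → optional concept normalization of the first rater.
    Fully reproducible given ``seed``; with ``out_dir`` set, writes
    ``report.json``, ``pairwise.csv``, ``summary.txt`` and (simulation path)
    the generated corpus files.
    """
    seed = int(config.get("seed", 0))
    tasks = list(config.get("tasks", ["span", "label"]))
    match = MatchConfig(**config.get("match", {}))
    if "simulation" in config:
        rounds_iter = _simulation_rounds(config, seed)
    elif "screens" in config and config.get("raters"):
        rounds_iter = _file_round(config)
    else:
        raise ConfigError(
            "config must contain either a 'simulation' block or 'screens' + 'raters'"
        )

    tagged: list[TaggedResult] = []
    corpus_stats: list[dict] = []
    first_round_artifacts = None
    for r, docs, screens, sets, kinds, stats_row in rounds_iter:
        try:
            if config.get("relabel", False):
                labeling = LabelingConfig(**config.get("labeling", {}))
                sets = [relabel_set(s, screens, labeling) for s in sets]
            from itertools import combinations

            for set_a, set_b in combinations(sets, 2):
                for task in tasks:
                    units = build_units(set_a, set_b, screens, task, match)
                    result = agreement_result(units, task)
                    a, b = sorted((set_a.rater_id, set_b.rater_id))
                    tagged.append(
                        TaggedResult(
                            round_id=r,
                            rater_a=a,
                            rater_b=b,
                            group=_pair_group(kinds[set_a.rater_id], kinds[set_b.rater_id]),
                            task=task,
                            result=result,
                        )
                    )
        except Exception as exc:
            raise type(exc)(f"round {r} (scoring stage): {exc}") from exc
        corpus_stats.append(stats_row)
        if first_round_artifacts is None:
            first_round_artifacts = (docs, screens, sets)

    summaries = summarize(tagged)

    anovas: dict[str, AnovaResult] = {}
    for task in tasks:
        for metric, getter in (("kappa", lambda res: res.kappa),
                               ("concordance", lambda res: res.concordance_pct)):
            groups: dict[str, list[float]] = {}
            for t in tagged:
                if t.task == task:
                    groups.setdefault(t.group, []).append(getter(t.result))
            usable = [v for v in groups.values() if len(v) >= 2]
            if len(usable) >= 2:
                try:
                    anovas[f"{task}_{metric}"] = anova_oneway(usable)
                except InfiniteFError:
                    logger.warning("ANOVA for %s %s: infinite F (degenerate)", task, metric)

    normalization = None
    if config.get("normalize", False) and first_round_artifacts is not None:
        concepts = load_fixture_concepts()
        table = build_lookup(concepts)
        _, _, sets = first_round_artifacts
        matches = normalize_set(
            sets[0], table, concepts, float(config.get("threshold", 0.7))
        )
        from collections import Counter

        tally = Counter(m.method for m in matches.values())
        normalization = {
            "rater_id": sets[0].rater_id,
            "n_spans": len(matches),
            "exact": tally["exact"],
            "similarity": tally["similarity"],
            "unmapped": tally["none"],
        }

    bundle = ReportBundle(
        tagged=tagged,
        summaries=summaries,
        anovas=anovas,
        corpus_stats=corpus_stats,
        normalization=normalization,
    )

    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        (out_dir / "report.json").write_text(bundle.to_json() + "\n", encoding="utf-8")
        bundle.to_frame().to_csv(out_dir / "pairwise.csv", index=False)
        (out_dir / "summary.txt").write_text(_plain_summary(bundle), encoding="utf-8")
        if "simulation" in config and first_round_artifacts is not None:
            docs, screens, sets = first_round_artifacts
            from .annotation_model import write_annotations

            round_dir = out_dir / "round-1"
            write_corpus(docs, round_dir)
            for aset in sets:
                write_annotations(aset, screens, round_dir / f"{aset.rater_id}.jsonl")
    return bundle


def _plain_summary(bundle: ReportBundle) -> str:
    lines = ["Pairwise agreement summary", "=" * 26, ""]
    for s in bundle.summaries:
        lines.append(f"round {s.round_id} / task {s.task}")
        for group, st in s.groups.items():
            sd = f"{st.kappa_sd:.3f}" if st.kappa_sd is not None else "--"
            csd = f"{st.concordance_sd:.1f}" if st.concordance_sd is not None else "--"
            lines.append(
                f"  {group:<16} n={st.n:<3d} kappa {st.kappa_mean:.3f}±{sd}"
                f"  concordance {st.concordance_mean:.1f}%±{csd}"
            )
        lines.append("")
    if bundle.anovas:
        lines.append("One-way ANOVA (groups pooled across rounds)")
        for name, res in sorted(bundle.anovas.items()):
            lines.append(
                f"  {name:<20} F={res.F:.3f} df=({res.df_between},{res.df_within}) p={res.p:.3f}"
            )
        lines.append("")
    return "\n".join(lines)
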