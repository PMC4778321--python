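"""Micro-averaged scoring, threshold sweeps, and confidence triage.

Correctness is judged at two levels: 4-digit (codes equal through the
subcategory digit, the conventional reporting level) and 3-digit (category
truncations equal, e.g. A01.0 vs A01.1 counts).  Precision, recall and F1
are micro-averaged: tp/fp/fn are summed over all codes before division.
With a single-label coder that always assigns, P = R = F; the two diverge
only through abstention, which this package makes explicit.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Literal, Sequence

import pandas as pd

from .codes import Code, Level, parse_code
from .codesystem import CodeSystem
from .encoder import EncodingResult, encode_batch
from .text_similarity import SimilarityConfig

__all__ = [
    "GoldInstance",
    "LevelScores",
    "EvaluationReport",
    "TriageReport",
    "match_at_level",
    "evaluate",
    "sweep_threshold",
    "triage",
    "read_gold",
]

MatchLevel = Literal["3-digit", "4-digit"]
LEVELS: tuple[MatchLevel, MatchLevel] = ("3-digit", "4-digit")


@dataclass(frozen=True)
class GoldInstance:
    """A diagnostic statement and its manually assigned reference code."""

    diagnosis: str
    code: Code

    def __post_init__(self) -> None:
        if self.code.level not in (Level.SUBCATEGORY, Level.CATEGORY):
            raise ValueError(
                f"gold code {self.code.raw!r} must be subcategory or category level"
            )


def match_at_level(pred: Code, gold: Code, level: MatchLevel) -> bool:
    """Code agreement at 3-digit (category) or 4-digit (subcategory) level.

    Category-level codes (undivided categories) can only match at 3-digit.
    """
    for c in (pred, gold):
        if c.level not in (Level.CATEGORY, Level.SUBCATEGORY, Level.INSTANCE):
            raise ValueError(f"match_at_level needs category-or-deeper codes, got {c.raw!r}")
    if level == "3-digit":
        return pred.category.raw == gold.category.raw
    if level == "4-digit":
        if pred.level is Level.CATEGORY or gold.level is Level.CATEGORY:
            return False
        return pred.subcategory.raw == gold.subcategory.raw
    raise ValueError(f"unknown level {level!r}")


@dataclass
class LevelScores:
    tp: int
    fp: int
    fn: int

    @property
    def precision(self) -> float:
        return self.tp / (self.tp + self.fp) if self.tp + self.fp else 0.0

    @property
    def recall(self) -> float:
        return self.tp / (self.tp + self.fn) if self.tp + self.fn else 0.0

    @property
    def f1(self) -> float:
        p, r = self.precision, self.recall
        return 2 * p * r / (p + r) if p + r else 0.0


@dataclass
class EvaluationReport:
    levels: dict[MatchLevel, LevelScores]
    n_instances: int
    n_abstained: int
    # confidence samples, exposed so rank tests can be applied externally
    confidences_correct: list[float] = field(default_factory=list)
    confidences_incorrect: list[float] = field(default_factory=list)

    def to_dict(self) -> dict:
        out: dict = {"n_instances": self.n_instances, "n_abstained": self.n_abstained}
        for lvl, s in self.levels.items():
            out[lvl] = {
                "tp": s.tp, "fp": s.fp, "fn": s.fn,
                "precision": s.precision, "recall": s.recall, "f1": s.f1,
            }
        return out


def evaluate(
    predictions: Sequence[EncodingResult],
    gold: Sequence[GoldInstance],
    level: MatchLevel | None = None,
) -> EvaluationReport:
    """Micro-averaged P/R/F over aligned prediction and gold lists.

    tp = assigned and correct; fp = assigned and incorrect; fn = gold
    instances without a correct assignment (incorrect or abstained), so
    tp + fn = n_instances at each level.
    """
    if len(predictions) != len(gold):
        raise ValueError(
            f"got {len(predictions)} predictions for {len(gold)} gold instances"
        )
    wanted = LEVELS if level is None else (level,)
    scores = {lvl: LevelScores(0, 0, 0) for lvl in wanted}
    n_abstained = 0
    conf_ok: list[float] = []
    conf_bad: list[float] = []
    for pred, inst in zip(predictions, gold):
        if pred.abstained:
            n_abstained += 1
            for lvl in wanted:
                scores[lvl].fn += 1
            continue
        for lvl in wanted:
            if match_at_level(pred.code, inst.code, lvl):
                scores[lvl].tp += 1
            else:
                scores[lvl].fp += 1
                scores[lvl].fn += 1
        key = "4-digit" if "4-digit" in scores else wanted[0]
        (conf_ok if match_at_level(pred.code, inst.code, key) else conf_bad).append(
            pred.confidence
        )
    return EvaluationReport(scores, len(gold), n_abstained, conf_ok, conf_bad)


def sweep_threshold(
    gold: Sequence[GoldInstance],
    system: CodeSystem,
    config: SimilarityConfig,
    thetas: Sequence[float],
    methods: Sequence[str] = ("flat", "hierarchical"),
    abstain_floor: float = 0.0,
) -> pd.DataFrame:
    """Evaluate every (theta, method) pair; one row per (theta, method, level).

    The theta = 0 rows coincide exactly with the unthresholded metric.
    """
    rows = []
    queries = [g.diagnosis for g in gold]
    for theta in thetas:
        if not 0.0 <= theta <= 1.0:
            raise ValueError(f"theta {theta} outside [0, 1]")
        cfg = replace(config, theta=theta)
        for method in methods:
            preds = encode_batch(queries, system, cfg, method, abstain_floor)
            report = evaluate(preds, gold)
            for lvl, s in report.levels.items():
                rows.append(
                    {
                        "theta": theta,
                        "method": method,
                        "level": lvl,
                        "precision": s.precision,
                        "recall": s.recall,
                        "f1": s.f1,
                        "n_abstained": report.n_abstained,
                    }
                )
    return pd.DataFrame(rows)


@dataclass
class TriageReport:
    """Confidence-threshold split into auto-accepted vs manual-review work."""

    threshold: float
    auto_fraction: float
    auto_f1: float
    manual_f1: float
    n_auto: int
    n_manual: int

    @property
    def manual_fraction(self) -> float:
        return 1.0 - self.auto_fraction


def triage(
    results: Sequence[EncodingResult],
    gold: Sequence[GoldInstance],
    threshold: float,
    level: MatchLevel = "4-digit",
) -> TriageReport:
    """Partition by confidence >= threshold; report per-partition micro-F.

    High-confidence assignments can be recorded without review; the rest go
    to medical coders.
    """
    if not 0.0 <= threshold <= 1.0:
        raise ValueError("threshold must lie in [0, 1]")
    auto_idx = [i for i, r in enumerate(results) if r.confidence >= threshold]
    manual_idx = [i for i in range(len(results)) if i not in set(auto_idx)]

    def _f1(idx: list[int]) -> float:
        if not idx:
            return 0.0
        rep = evaluate([results[i] for i in idx], [gold[i] for i in idx], level)
        return rep.levels[level].f1

    n = len(results)
    return TriageReport(
        threshold=threshold,
        auto_fraction=len(auto_idx) / n if n else 0.0,
        auto_f1=_f1(auto_idx),
        manual_f1=_f1(manual_idx),
        n_auto=len(auto_idx),
        n_manual=len(manual_idx),
    )


def read_gold(path: str | Path) -> list[GoldInstance]:
    """Gold TSV: ``diagnosis<TAB>code`` per line; ``#`` comments allowed."""
    out = []
    for line in Path(path).read_text(encoding="utf-8").splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        diagnosis, code = line.split("\t")
        out.append(GoldInstance(diagnosis, parse_code(code)))
    return out
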