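"""Dual-reward mechanism: accuracy reward + structural format reward.

The total reward for a raw model output against a gold annotation is

    R = w_acc * R_acc + w_fmt * R_fmt
    R_acc = alpha * S_entity + beta * S_triplet + gamma * S_rare
    R_fmt = delta * S_tag + epsilon * S_length

S_entity credits exact entity matches fully and same-type boundary overlaps
partially; S_triplet credits exact canonical quintuple matches; S_rare is the
exactly-recovered fraction of rare gold items (entity types / relations whose
reference share falls below the rarity threshold); S_tag and S_length are 0/1
gates on think/step tag integrity and on the reasoning length falling inside
configured character bounds.  All component scores live in [0, 1], so the
total does too.
"""

from __future__ import annotations

import math
import string
from dataclasses import dataclass, field
from typing import Optional

from pydantic import BaseModel, ConfigDict, model_validator

from .parsing import ParsedOutput, ReasoningTrace, TagReport, parse_prediction_json
from .schema import (
    DocumentAnnotation,
    EntityMention,
    Triplet,
    canonicalize_triplet,
    is_rare,
)
from .stats import REFERENCE_STATS, StatsTable


class RewardWeights(BaseModel):
    """The seven tuned reward coefficients plus matching knobs.

    Defaults are the tuned configuration: alpha=.45, beta=.45, gamma=.1
    (accuracy components), delta=.7, epsilon=.3 (format components), and
    equal global accuracy/format weights of .5 each.
    """

    model_config = ConfigDict(frozen=True)

    alpha: float = 0.45
    beta_triplet: float = 0.45
    gamma: float = 0.10
    delta: float = 0.70
    epsilon_length: float = 0.30
    w_acc: float = 0.50
    w_fmt: float = 0.50
    partial_credit: float = 0.50
    length_bounds: tuple[int, int] = (200, 8000)
    case_insensitive: bool = False
    rarity_threshold: float = 0.05

    @model_validator(mode="after")
    def _sums(self) -> "RewardWeights":
        if not math.isclose(self.alpha + self.beta_triplet + self.gamma, 1.0, abs_tol=1e-9):
            raise ValueError("alpha + beta_triplet + gamma must equal 1")
        if not math.isclose(self.delta + self.epsilon_length, 1.0, abs_tol=1e-9):
            raise ValueError("delta + epsilon_length must equal 1")
        if not math.isclose(self.w_acc + self.w_fmt, 1.0, abs_tol=1e-9):
            raise ValueError("w_acc + w_fmt must equal 1")
        if not 0.0 <= self.partial_credit <= 1.0:
            raise ValueError("partial_credit must lie in [0, 1]")
        lo, hi = self.length_bounds
        if not 0 <= lo < hi:
            raise ValueError("length_bounds must satisfy 0 <= min < max")
        return self


@dataclass
class EntityMatchResult:
    exact: list[tuple[EntityMention, EntityMention]] = field(default_factory=list)
    partial: list[tuple[EntityMention, EntityMention]] = field(default_factory=list)
    false_positives: list[EntityMention] = field(default_factory=list)
    false_negatives: list[EntityMention] = field(default_factory=list)

    @property
    def n_gold(self) -> int:
        return len(self.exact) + len(self.partial) + len(self.false_negatives)

    @property
    def n_pred(self) -> int:
        return len(self.exact) + len(self.partial) + len(self.false_positives)


@dataclass
class TripletMatchResult:
    correct: list[tuple[Triplet, Triplet]] = field(default_factory=list)
    dependency_errors: list[Triplet] = field(default_factory=list)
    spurious: list[Triplet] = field(default_factory=list)
    missed: list[Triplet] = field(default_factory=list)

    @property
    def n_gold(self) -> int:
        return len(self.correct) + len(self.missed)

    @property
    def n_pred(self) -> int:
        return len(self.correct) + len(self.dependency_errors) + len(self.spurious)


@dataclass
class RewardBreakdown:
    """Per-component scores; vacuous (renormalized-away) components are None."""

    s_entity: Optional[float] = None
    s_triplet: Optional[float] = None
    s_rare: Optional[float] = None
    s_tag: Optional[float] = None
    s_length: Optional[float] = None
    r_acc: float = 0.0
    r_fmt: float = 0.0
    r_total: float = 0.0

    def to_dict(self) -> dict:
        return {
            "s_entity": self.s_entity,
            "s_triplet": self.s_triplet,
            "s_rare": self.s_rare,
            "s_tag": self.s_tag,
            "s_length": self.s_length,
            "r_acc": self.r_acc,
            "r_fmt": self.r_fmt,
            "r_total": self.r_total,
        }


# --------------------------------------------------------------------------
# Matching
# --------------------------------------------------------------------------


def _norm_surface(surface: str, case_insensitive: bool) -> str:
    return surface.casefold() if case_insensitive else surface


def surface_tokens(surface: str, case_insensitive: bool = False) -> set[str]:
    toks = {
        tok.strip(string.punctuation)
        for tok in _norm_surface(surface, case_insensitive).split()
    }
    return {t for t in toks if t}


def surfaces_overlap(a: str, b: str, case_insensitive: bool = False) -> bool:
    """Token overlap after punctuation strip ('BRCA2' vs 'BRCA2 mutations')."""
    return bool(surface_tokens(a, case_insensitive) & surface_tokens(b, case_insensitive))


def match_entities(
    gold: DocumentAnnotation,
    pred: DocumentAnnotation,
    case_insensitive: bool = False,
) -> EntityMatchResult:
    """Greedy one-to-one assignment: exact matches first, then partial overlaps.

    Exact means (surface, type) equality; partial means same type with
    token-overlapping but unequal surface (a boundary error in evaluation
    terms, still worth partial credit in the reward).  Order is
    deterministic: gold order, then prediction order.
    """
    if gold.doc_id != pred.doc_id:
        raise ValueError(f"doc_id mismatch: {gold.doc_id!r} vs {pred.doc_id!r}")
    res = EntityMatchResult()
    used = [False] * len(pred.entities)
    unmatched_gold: list[EntityMention] = []
    for g in gold.entities:
        hit = None
        for j, p in enumerate(pred.entities):
            if used[j]:
                continue
            if g.etype == p.etype and _norm_surface(g.surface, case_insensitive) == _norm_surface(
                p.surface, case_insensitive
            ):
                hit = j
                break
        if hit is None:
            unmatched_gold.append(g)
        else:
            used[hit] = True
            res.exact.append((g, pred.entities[hit]))
    still_unmatched: list[EntityMention] = []
    for g in unmatched_gold:
        hit = None
        for j, p in enumerate(pred.entities):
            if used[j]:
                continue
            if g.etype == p.etype and surfaces_overlap(g.surface, p.surface, case_insensitive):
                hit = j
                break
        if hit is None:
            still_unmatched.append(g)
        else:
            used[hit] = True
            res.partial.append((g, pred.entities[hit]))
    res.false_negatives = still_unmatched
    res.false_positives = [p for j, p in enumerate(pred.entities) if not used[j]]
    return res


def match_triplets(
    gold: DocumentAnnotation,
    pred: DocumentAnnotation,
    case_insensitive: bool = False,
) -> TripletMatchResult:
    """Match canonical quintuples; classify the rest as dependency/spurious/missed.

    A dependency error is a predicted quintuple whose canonical relation
    matches an unmatched gold quintuple between overlapping entities, but
    with a wrong entity surface or entity type.
    """
    if gold.doc_id != pred.doc_id:
        raise ValueError(f"doc_id mismatch: {gold.doc_id!r} vs {pred.doc_id!r}")

    def ckey(t: Triplet) -> tuple:
        c = canonicalize_triplet(t)
        return (
            _norm_surface(c.head.surface, case_insensitive),
            c.head.etype,
            c.relation,
            _norm_surface(c.tail.surface, case_insensitive),
            c.tail.etype,
        )

    res = TripletMatchResult()
    used = [False] * len(pred.triplets)
    unmatched_gold: list[Triplet] = []
    for g in gold.triplets:
        gk = ckey(g)
        hit = next(
            (j for j, p in enumerate(pred.triplets) if not used[j] and ckey(p) == gk), None
        )
        if hit is None:
            unmatched_gold.append(g)
        else:
            used[hit] = True
            res.correct.append((g, pred.triplets[hit]))
    res.missed = unmatched_gold
    for j, p in enumerate(pred.triplets):
        if used[j]:
            continue
        pc = canonicalize_triplet(p)
        dep = False
        for g in unmatched_gold:
            gc = canonicalize_triplet(g)
            if gc.relation != pc.relation:
                continue
            if surfaces_overlap(
                gc.head.surface, pc.head.surface, case_insensitive
            ) or surfaces_overlap(gc.tail.surface, pc.tail.surface, case_insensitive):
                dep = True
                break
        (res.dependency_errors if dep else res.spurious).append(p)
    return res


# --------------------------------------------------------------------------
# Reward composition
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class RareRecovery:
    """Rare gold items (by reference frequency) and how many were recovered."""

    n_rare: int
    n_recovered: int


def rare_recovery(
    gold: DocumentAnnotation,
    em: EntityMatchResult,
    tm: TripletMatchResult,
    ref_stats: StatsTable = REFERENCE_STATS,
    threshold: float = 0.05,
) -> RareRecovery:
    exact_gold = {id(g) for g, _ in em.exact}
    correct_gold = {id(g) for g, _ in tm.correct}
    n_rare = n_rec = 0
    for g in gold.entities:
        if is_rare(g.etype, ref_stats, threshold):
            n_rare += 1
            n_rec += id(g) in exact_gold
    for t in gold.triplets:
        if is_rare(canonicalize_triplet(t).relation, ref_stats, threshold):
            n_rare += 1
            n_rec += id(t) in correct_gold
    return RareRecovery(n_rare=n_rare, n_recovered=n_rec)


def _clamp(x: float) -> float:
    return min(1.0, max(0.0, x))


def accuracy_reward(
    em: EntityMatchResult,
    tm: TripletMatchResult,
    rare: RareRecovery,
    w: RewardWeights,
) -> RewardBreakdown:
    """Compose S_entity, S_triplet, S_rare into R_acc.

    Denominators are max(n_gold, n_pred) so spurious output is strictly
    costly while scores stay in [0, 1].  Vacuous components — no triplets on
    either side, or no rare gold items — are dropped and the remaining
    weights renormalized, so documents without rare content can still reach
    R_acc = 1.
    """
    denom_e = max(em.n_gold, em.n_pred)
    s_entity = (
        1.0
        if denom_e == 0
        else _clamp((len(em.exact) + w.partial_credit * len(em.partial)) / denom_e)
    )
    terms: list[tuple[float, float]] = [(w.alpha, s_entity)]

    denom_t = max(tm.n_gold, tm.n_pred)
    s_triplet: Optional[float] = None
    if denom_t > 0:
        s_triplet = _clamp(len(tm.correct) / denom_t)
        terms.append((w.beta_triplet, s_triplet))

    s_rare: Optional[float] = None
    if rare.n_rare > 0:
        s_rare = _clamp(rare.n_recovered / rare.n_rare)
        terms.append((w.gamma, s_rare))

    total_w = sum(wt for wt, _ in terms)
    r_acc = _clamp(sum(wt * s for wt, s in terms) / total_w)
    return RewardBreakdown(s_entity=s_entity, s_triplet=s_triplet, s_rare=s_rare, r_acc=r_acc)


def format_reward(
    tag_report: TagReport,
    trace: ReasoningTrace,
    w: RewardWeights,
) -> RewardBreakdown:
    """R_fmt = delta * S_tag + epsilon * S_length (both all-or-nothing gates)."""
    s_tag = 1.0 if tag_report.tag_integrity_ok else 0.0
    lo, hi = w.length_bounds
    s_length = 1.0 if lo <= trace.total_length <= hi else 0.0
    r_fmt = _clamp(w.delta * s_tag + w.epsilon_length * s_length)
    return RewardBreakdown(s_tag=s_tag, s_length=s_length, r_fmt=r_fmt)


def total_reward(
    gold: DocumentAnnotation,
    raw_output: str,
    w: RewardWeights = RewardWeights(),
    ref_stats: StatsTable = REFERENCE_STATS,
) -> RewardBreakdown:
    """Full pipeline: parse (lenient) -> match -> R_acc; tag check -> R_fmt.

    A reward exists for any raw text: an unparseable payload zeroes R_acc
    but the format components are still scored.
    """
    parsed: ParsedOutput = parse_prediction_json(raw_output, "lenient", doc_id=gold.doc_id)
    fmt = format_reward(parsed.tag_report, parsed.trace, w)
    if parsed.annotation is None:
        acc = RewardBreakdown(r_acc=0.0)
    else:
        em = match_entities(gold, parsed.annotation, w.case_insensitive)
        tm = match_triplets(gold, parsed.annotation, w.case_insensitive)
        rare = rare_recovery(gold, em, tm, ref_stats, w.rarity_threshold)
        acc = accuracy_reward(em, tm, rare, w)
    return RewardBreakdown(
        s_entity=acc.s_entity,
        s_triplet=acc.s_triplet,
        s_rare=acc.s_rare,
        s_tag=fmt.s_tag,
        s_length=fmt.s_length,
        r_acc=acc.r_acc,
        r_fmt=fmt.r_fmt,
        r_total=_clamp(w.w_acc * acc.r_acc + w.w_fmt * fmt.r_fmt),
    )
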