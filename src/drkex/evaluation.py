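"""Strict-match evaluation: P/R/F1 tables, confusion matrix, error taxonomy.

Evaluation is deliberately harsher than the reward: a prediction counts as a
true positive only under exact string matching — identical surface and type
(and, for triplets, identical canonical relation and both endpoints).
Boundary overlaps earn partial reward credit during training but are plain
errors here.  Per-document items are deduplicated to unique (surface, type)
pairs or canonical quintuples, since the quintuple output format carries no
offsets.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .rewards import surfaces_overlap
from .schema import (
    DocumentAnnotation,
    EntityType,
    Triplet,
    CANONICAL_RELATIONS,
    canonicalize_triplet,
    default_sentence_bounds,
    _anchor,
    _sentence_index,
)
from .stats import StatsTable


def compute_prf(tp: int, fp: int, fn: int) -> tuple[float, float, float]:
    """Precision, recall and F1 as fractions, with the 0/0 -> 0 convention."""
    if min(tp, fp, fn) < 0:
        raise ValueError("counts must be non-negative")
    precision = tp / (tp + fp) if tp + fp else 0.0
    recall = tp / (tp + fn) if tp + fn else 0.0
    f1 = harmonic_f1(precision, recall)
    return precision, recall, f1


def harmonic_f1(precision: float, recall: float) -> float:
    """F1 = 2PR / (P + R); 0 when both are 0.  Unit-agnostic (fractions or %)."""
    return 2 * precision * recall / (precision + recall) if precision + recall else 0.0


@dataclass(frozen=True)
class PRFRow:
    tp: int
    fp: int
    fn: int
    precision: float
    recall: float
    f1: float


@dataclass
class MetricsTable:
    """Per-type rows plus an overall row ('ALL'); fractions at full precision."""

    level: str  # "entity" | "triplet"
    average: str  # "micro" | "macro"
    rows: dict[str, PRFRow] = field(default_factory=dict)

    @property
    def overall(self) -> PRFRow:
        return self.rows["ALL"]

    def to_frame(self, percent: bool = True) -> pd.DataFrame:
        scale = 100.0 if percent else 1.0
        records = []
        for name, row in self.rows.items():
            records.append(
                {
                    "type": name,
                    "tp": row.tp,
                    "fp": row.fp,
                    "fn": row.fn,
                    "precision": round(scale * row.precision, 2),
                    "recall": round(scale * row.recall, 2),
                    "f1": round(scale * row.f1, 2),
                }
            )
        return pd.DataFrame.from_records(records)


@dataclass
class ErrorCounts:
    """Taxonomy counts for one gold/predicted document pair (or a corpus sum)."""

    entity: dict[str, int] = field(
        default_factory=lambda: {
            "incorrect_extraction": 0,
            "incorrect_type": 0,
            "boundary_error": 0,
            "missing_entity": 0,
        }
    )
    triplet: dict[str, int] = field(
        default_factory=lambda: {"incorrect_entity_type": 0, "cross_sentence_error": 0}
    )
    entity_exact: int = 0
    triplet_correct: int = 0

    def merge(self, other: "ErrorCounts") -> "ErrorCounts":
        out = ErrorCounts()
        for k in out.entity:
            out.entity[k] = self.entity[k] + other.entity[k]
        for k in out.triplet:
            out.triplet[k] = self.triplet[k] + other.triplet[k]
        out.entity_exact = self.entity_exact + other.entity_exact
        out.triplet_correct = self.triplet_correct + other.triplet_correct
        return out


# --------------------------------------------------------------------------
# Corpus alignment helpers
# --------------------------------------------------------------------------


def _index_corpus(corpus: list[DocumentAnnotation], name: str) -> dict[str, DocumentAnnotation]:
    index: dict[str, DocumentAnnotation] = {}
    for doc in corpus:
        if doc.doc_id in index:
            raise ValueError(f"duplicate doc_id {doc.doc_id!r} in {name} corpus")
        index[doc.doc_id] = doc
    return index


def _entity_items(doc: DocumentAnnotation) -> set[tuple[str, EntityType]]:
    return doc.entity_keys()


def _triplet_items(doc: DocumentAnnotation) -> set[tuple]:
    return doc.canonical_triplet_keys()


def evaluate_extraction(
    gold_corpus: list[DocumentAnnotation],
    pred_corpus: list[DocumentAnnotation],
    level: str = "entity",
    average: str = "micro",
) -> MetricsTable:
    """Exact-match P/R/F1 per type plus an overall row.

    Corpora are aligned by doc_id; a missing prediction counts as an empty
    document.  Micro pools tp/fp/fn across types before computing the
    overall row; macro averages the per-type fractions over types with any
    support.
    """
    if level not in ("entity", "triplet"):
        raise ValueError("level must be 'entity' or 'triplet'")
    if average not in ("micro", "macro"):
        raise ValueError("average must be 'micro' or 'macro'")
    gold_ix = _index_corpus(gold_corpus, "gold")
    pred_ix = _index_corpus(pred_corpus, "predicted")
    type_names = (
        [t.value for t in EntityType] if level == "entity" else list(CANONICAL_RELATIONS)
    )
    counts = {name: [0, 0, 0] for name in type_names}  # tp, fp, fn
    items = _entity_items if level == "entity" else _triplet_items
    type_of = (lambda it: it[1].value) if level == "entity" else (lambda it: it[2])
    empty = DocumentAnnotation(doc_id="", text="")
    for doc_id in list(gold_ix) + [d for d in pred_ix if d not in gold_ix]:
        g_items = items(gold_ix.get(doc_id, empty))
        p_items = items(pred_ix.get(doc_id, empty))
        for it in g_items & p_items:
            counts[type_of(it)][0] += 1
        for it in p_items - g_items:
            counts[type_of(it)][1] += 1
        for it in g_items - p_items:
            counts[type_of(it)][2] += 1

    rows: dict[str, PRFRow] = {}
    for name in type_names:
        tp, fp, fn = counts[name]
        p, r, f = compute_prf(tp, fp, fn)
        rows[name] = PRFRow(tp, fp, fn, p, r, f)
    tp_all = sum(c[0] for c in counts.values())
    fp_all = sum(c[1] for c in counts.values())
    fn_all = sum(c[2] for c in counts.values())
    if average == "micro":
        p, r, f = compute_prf(tp_all, fp_all, fn_all)
    else:
        supported = [rows[n] for n in type_names if sum(counts[n]) > 0]
        if supported:
            p = float(np.mean([r_.precision for r_ in supported]))
            r = float(np.mean([r_.recall for r_ in supported]))
            f = float(np.mean([r_.f1 for r_ in supported]))
        else:
            p = r = f = 0.0
    table = MetricsTable(level=level, average=average)
    table.rows = {"ALL": PRFRow(tp_all, fp_all, fn_all, p, r, f), **rows}
    return table


def confusion_matrix(
    gold_corpus: list[DocumentAnnotation],
    pred_corpus: list[DocumentAnnotation],
) -> pd.DataFrame:
    """Entity-type confusion over surface-matched predictions.

    Diagonal cells count exact (surface, type) matches; off-diagonal cell
    (g, p) counts predictions whose surface exactly matches a gold surface
    annotated with type g but which were typed p.  Predictions and gold
    items without a surface match on the other side are excluded.
    """
    names = [t.value for t in EntityType]
    mat = pd.DataFrame(0, index=names, columns=names, dtype=int)
    gold_ix = _index_corpus(gold_corpus, "gold")
    pred_ix = _index_corpus(pred_corpus, "predicted")
    for doc_id, gold in gold_ix.items():
        pred = pred_ix.get(doc_id)
        if pred is None:
            continue
        gold_items = gold.entity_keys()
        gold_types_by_surface: dict[str, list[EntityType]] = {}
        for surface, etype in sorted(gold_items, key=lambda it: (it[0], it[1].value)):
            gold_types_by_surface.setdefault(surface, []).append(etype)
        for surface, etype in pred.entity_keys():
            if (surface, etype) in gold_items:
                mat.loc[etype.value, etype.value] += 1
            elif surface in gold_types_by_surface:
                mat.loc[gold_types_by_surface[surface][0].value, etype.value] += 1
    return mat


# --------------------------------------------------------------------------
# Error taxonomy
# --------------------------------------------------------------------------


def classify_errors(gold: DocumentAnnotation, pred: DocumentAnnotation) -> ErrorCounts:
    """Classify mismatches per the fixed priority order.

    Entities: exact match > incorrect_type (same surface, wrong type) >
    boundary_error (same type, overlapping unequal surface) >
    incorrect_extraction (unmatched prediction) / missing_entity (unmatched
    gold).  Triplets: exact canonical match > incorrect_entity_type (same
    relation and surfaces, an endpoint type wrong) > cross_sentence_error
    (missed gold whose endpoints sit in different sentences).
    """
    if gold.doc_id != pred.doc_id:
        raise ValueError(f"doc_id mismatch: {gold.doc_id!r} vs {pred.doc_id!r}")
    counts = ErrorCounts()

    gold_ents = list(gold.entities)
    pred_ents = list(pred.entities)
    used_p = [False] * len(pred_ents)

    def take(match_fn) -> int:
        n = 0
        remaining = []
        for g in gold_ents:
            hit = next(
                (j for j, p in enumerate(pred_ents) if not used_p[j] and match_fn(g, p)),
                None,
            )
            if hit is None:
                remaining.append(g)
            else:
                used_p[hit] = True
                n += 1
        gold_ents[:] = remaining
        return n

    counts.entity_exact = take(lambda g, p: g.key == p.key)
    counts.entity["incorrect_type"] = take(
        lambda g, p: g.surface == p.surface and g.etype != p.etype
    )
    counts.entity["boundary_error"] = take(
        lambda g, p: g.etype == p.etype
        and g.surface != p.surface
        and surfaces_overlap(g.surface, p.surface)
    )
    counts.entity["missing_entity"] = len(gold_ents)
    counts.entity["incorrect_extraction"] = used_p.count(False)

    # triplets
    gold_trip = [canonicalize_triplet(t) for t in gold.triplets]
    pred_trip = [canonicalize_triplet(t) for t in pred.triplets]
    used_t = [False] * len(pred_trip)
    remaining_gold: list[Triplet] = []
    for g in gold_trip:
        gk = (g.head.key, g.relation, g.tail.key)
        hit = next(
            (
                j
                for j, p in enumerate(pred_trip)
                if not used_t[j] and (p.head.key, p.relation, p.tail.key) == gk
            ),
            None,
        )
        if hit is None:
            remaining_gold.append(g)
        else:
            used_t[hit] = True
            counts.triplet_correct += 1
    still_missed: list[Triplet] = []
    for g in remaining_gold:
        hit = next(
            (
                j
                for j, p in enumerate(pred_trip)
                if not used_t[j]
                and p.relation == g.relation
                and p.head.surface == g.head.surface
                and p.tail.surface == g.tail.surface
                and (p.head.etype != g.head.etype or p.tail.etype != g.tail.etype)
            ),
            None,
        )
        if hit is None:
            still_missed.append(g)
        else:
            used_t[hit] = True
            counts.triplet["incorrect_entity_type"] += 1

    if still_missed:
        bounds = gold.sentence_bounds
        if not bounds:
            raise ValueError(
                "sentence_bounds required on the gold document for cross-sentence "
                "error classification"
            )
        spans = {m.key: _anchor(m, gold.text) for m in gold.entities}
        for g in still_missed:
            hs = spans.get(g.head.key)
            ts = spans.get(g.tail.key)
            if hs is None or ts is None:
                continue
            hi = _sentence_index(hs[0], bounds)
            ti = _sentence_index(ts[0], bounds)
            if hi is not None and ti is not None and hi != ti:
                counts.triplet["cross_sentence_error"] += 1
    return counts


def classify_errors_corpus(
    gold_corpus: list[DocumentAnnotation],
    pred_corpus: list[DocumentAnnotation],
) -> ErrorCounts:
    gold_ix = _index_corpus(gold_corpus, "gold")
    pred_ix = _index_corpus(pred_corpus, "predicted")
    total = ErrorCounts()
    for doc_id, gold in gold_ix.items():
        pred = pred_ix.get(
            doc_id, DocumentAnnotation(doc_id=doc_id, text=gold.text)
        )
        total = total.merge(classify_errors(gold, pred))
    return total


# --------------------------------------------------------------------------
# Splitting and statistics
# --------------------------------------------------------------------------


def split_corpus(
    corpus: list[DocumentAnnotation],
    train_fraction: float = 0.8,
    seed: int = 0,
) -> tuple[list[DocumentAnnotation], list[DocumentAnnotation]]:
    """Deterministic document-level split; |train| = round(fraction * N).

    The partition is disjoint and exhaustive, and document order within each
    partition preserves the input order.
    """
    if not 0.0 <= train_fraction <= 1.0:
        raise ValueError("train_fraction must lie in [0, 1]")
    n = len(corpus)
    n_train = int(np.floor(train_fraction * n + 0.5))
    rng = np.random.default_rng(seed)
    train_idx = set(map(int, rng.permutation(n)[:n_train]))
    train = [doc for i, doc in enumerate(corpus) if i in train_idx]
    test = [doc for i, doc in enumerate(corpus) if i not in train_idx]
    return train, test


def corpus_statistics(corpus: list[DocumentAnnotation]) -> StatsTable:
    """Entity-mention counts per type and canonical-triplet counts per relation."""
    entity_counts = {t.value: 0 for t in EntityType}
    relation_counts = {r: 0 for r in CANONICAL_RELATIONS}
    for doc in corpus:
        for m in doc.entities:
            entity_counts[m.etype.value] += 1
        for t in doc.triplets:
            relation_counts[canonicalize_triplet(t).relation] += 1
    return StatsTable(entity_counts=entity_counts, relation_counts=relation_counts)
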