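"""Drug-repositioning annotation schema: typed mentions, relations, documents.

The schema fixes 11 entity types (drug, disease, target, side_effect, gene,
biomarker, symptom, complication, anatomy, test, treatment) and 9 canonical
relation types, each with a named inverse, so the directed label registry
exposes 18 labels.  Annotation principles (non-overlap of types on one
surface, non-nesting, minimal punctuation, unidirectional relations,
intrasentence priority, schema compatibility of relation endpoints) are
enforced as *lint-style* violations by :func:`validate_annotation` — data,
not exceptions, so imperfect model predictions remain representable.
"""

from __future__ import annotations

import enum
import re
import string
from dataclasses import dataclass
from typing import Optional, Union

from pydantic import BaseModel, ConfigDict, field_validator, model_validator

from .stats import ConfigError, StatsTable

Span = tuple[int, int]


class SchemaError(ValueError):
    """Raised for unregistered types/relations or structurally invalid input."""


# --------------------------------------------------------------------------
# Entity types
# --------------------------------------------------------------------------


class EntityType(str, enum.Enum):
    DRUG = "drug"
    DISEASE = "disease"
    TARGET = "target"
    SIDE_EFFECT = "side_effect"
    GENE = "gene"
    BIOMARKER = "biomarker"
    SYMPTOM = "symptom"
    COMPLICATION = "complication"
    ANATOMY = "anatomy"
    TEST = "test"
    TREATMENT = "treatment"

    @classmethod
    def parse(cls, name: str) -> "EntityType":
        """Normalize a case/spacing-insensitive alias to its canonical member."""
        key = _normalize_label(name)
        key = _ENTITY_ALIASES.get(key, key)
        try:
            return cls(key)
        except ValueError:
            raise SchemaError(f"unknown entity type: {name!r}") from None


def _normalize_label(name: str) -> str:
    return re.sub(r"[\s\-]+", "_", name.strip().lower())


_ENTITY_ALIASES: dict[str, str] = {
    "anatomical_structure": "anatomy",
    "anatomical_site": "anatomy",
    "clinical_examination": "test",
    "examination": "test",
    "adverse_effect": "side_effect",
    "adverse_event": "side_effect",
    "sideeffect": "side_effect",
    "therapy": "treatment",
}

ENTITY_TYPES: tuple[EntityType, ...] = tuple(EntityType)


# --------------------------------------------------------------------------
# Relation types: 9 canonical labels, 18 directed labels with inverses
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class RelationType:
    canonical_name: str
    inverse_name: str


RELATION_TYPES: tuple[RelationType, ...] = (
    RelationType("treat", "is_treated_by"),
    RelationType("is_target_of", "has_target"),
    RelationType("is_side_effect_of", "has_side_effect"),
    RelationType("is_biomarker_of", "has_biomarker"),
    RelationType("is_examination_for", "has_examination"),
    RelationType("complication_of", "has_complication"),
    RelationType("is_located_in", "is_location_of"),
    RelationType("is_symptom_of", "has_symptom"),
    RelationType("increases_expression_of", "expression_increased_by"),
)

CANONICAL_RELATIONS: tuple[str, ...] = tuple(r.canonical_name for r in RELATION_TYPES)

#: directed label -> (canonical_name, is_inverse)
RELATION_REGISTRY: dict[str, tuple[str, bool]] = {}
for _r in RELATION_TYPES:
    RELATION_REGISTRY[_r.canonical_name] = (_r.canonical_name, False)
    RELATION_REGISTRY[_r.inverse_name] = (_r.canonical_name, True)

_RELATION_ALIASES = {"treats": "treat", "is_treatment_for": "treat"}


def parse_relation(label: str) -> str:
    """Normalize a directed relation label to its registered form."""
    key = _normalize_label(label)
    key = _RELATION_ALIASES.get(key, key)
    if key not in RELATION_REGISTRY:
        raise SchemaError(f"unknown relation label: {label!r}")
    return key


def relation_inverse(label: str) -> str:
    canonical, is_inv = RELATION_REGISTRY[parse_relation(label)]
    rt = next(r for r in RELATION_TYPES if r.canonical_name == canonical)
    return rt.canonical_name if is_inv else rt.inverse_name


# --------------------------------------------------------------------------
# Mentions, triplets, documents
# --------------------------------------------------------------------------


class EntityMention(BaseModel):
    """A typed surface-string mention, with original casing preserved.

    ``span`` is an optional 0-based half-open character interval into the
    owning document's text; the quintuple output dialect carries no offsets,
    so parsed predictions usually have ``span=None`` and are anchored by
    first-occurrence substring search when needed.
    """

    model_config = ConfigDict(frozen=True)

    surface: str
    etype: EntityType
    span: Optional[Span] = None

    @field_validator("surface")
    @classmethod
    def _non_empty(cls, v: str) -> str:
        if not v.strip():
            raise ValueError("entity surface must be non-empty after trimming")
        return v

    @property
    def key(self) -> tuple[str, EntityType]:
        return (self.surface, self.etype)


class Triplet(BaseModel):
    """A directed typed relation: {Entity1; Type1; Relationship; Entity2; Type2}."""

    model_config = ConfigDict(frozen=True)

    head: EntityMention
    relation: str
    tail: EntityMention

    @field_validator("relation")
    @classmethod
    def _registered(cls, v: str) -> str:
        return parse_relation(v)

    @model_validator(mode="after")
    def _distinct_endpoints(self) -> "Triplet":
        if self.head.key == self.tail.key:
            raise ValueError("triplet head and tail must be distinct (surface, type) pairs")
        return self

    def canonical_key(self) -> tuple[str, EntityType, str, str, EntityType]:
        c = canonicalize_triplet(self)
        return (c.head.surface, c.head.etype, c.relation, c.tail.surface, c.tail.etype)


class DocumentAnnotation(BaseModel):
    """One document's text plus its (gold or predicted) entities and triplets."""

    doc_id: str
    text: str
    sentence_bounds: list[Span] = []
    entities: list[EntityMention] = []
    triplets: list[Triplet] = []

    @model_validator(mode="after")
    def _structural(self) -> "DocumentAnnotation":
        prev_end = 0
        for s, e in self.sentence_bounds:
            if not (0 <= s <= e <= len(self.text)):
                raise ValueError(f"sentence bound ({s}, {e}) outside text")
            if s < prev_end:
                raise ValueError("sentence bounds must be ordered and non-overlapping")
            prev_end = e
        keys = {m.key for m in self.entities}
        for t in self.triplets:
            for end in (t.head, t.tail):
                if end.key not in keys:
                    raise ValueError(
                        f"triplet endpoint {end.surface!r}/{end.etype.value} "
                        "missing from entity list"
                    )
        return self

    def entity_keys(self) -> set[tuple[str, EntityType]]:
        return {m.key for m in self.entities}

    def canonical_triplet_keys(self) -> set[tuple]:
        return {t.canonical_key() for t in self.triplets}


def canonicalize_triplet(t: Triplet) -> Triplet:
    """Express a triplet in canonical direction (idempotent).

    Inverse-direction labels are swapped to the canonical label with head and
    tail exchanged; canonical-direction triplets are returned unchanged.
    """
    canonical, is_inverse = RELATION_REGISTRY[parse_relation(t.relation)]
    if not is_inverse:
        if t.relation == canonical:
            return t
        return Triplet(head=t.head, relation=canonical, tail=t.tail)
    return Triplet(head=t.tail, relation=canonical, tail=t.head)


# --------------------------------------------------------------------------
# Compatibility table
# --------------------------------------------------------------------------

TypePair = tuple[EntityType, EntityType]

_DEFAULT_COMPAT: dict[str, set[TypePair]] = {
    "treat": {(EntityType.DRUG, EntityType.DISEASE), (EntityType.TREATMENT, EntityType.DISEASE)},
    "is_target_of": {(EntityType.TARGET, EntityType.DRUG)},
    "is_side_effect_of": {(EntityType.SIDE_EFFECT, EntityType.DRUG)},
    "is_biomarker_of": {(EntityType.BIOMARKER, EntityType.DISEASE)},
    "is_examination_for": {(EntityType.TEST, EntityType.DISEASE)},
    "complication_of": {(EntityType.COMPLICATION, EntityType.DISEASE)},
    "is_located_in": {
        (EntityType.DISEASE, EntityType.ANATOMY),
        (EntityType.COMPLICATION, EntityType.ANATOMY),
        (EntityType.BIOMARKER, EntityType.ANATOMY),
        (EntityType.SYMPTOM, EntityType.ANATOMY),
    },
    "is_symptom_of": {(EntityType.SYMPTOM, EntityType.DISEASE)},
    "increases_expression_of": {
        (EntityType.DRUG, EntityType.GENE),
        (EntityType.GENE, EntityType.GENE),
    },
}


class CompatibilityTable:
    """Admissible (head type, tail type) pairs per canonical relation.

    The full authoritative table is not published; the shipped default is a
    reconstruction and is fully user-overridable (YAML config).
    """

    def __init__(self, mapping: dict[str, set[TypePair]]):
        for rel, pairs in mapping.items():
            if parse_relation(rel) != rel or RELATION_REGISTRY[rel][1]:
                raise SchemaError(f"compatibility table keys must be canonical: {rel!r}")
            if not pairs:
                raise SchemaError(f"relation {rel!r} must admit at least one type pair")
        self.mapping = {rel: set(pairs) for rel, pairs in mapping.items()}

    @classmethod
    def default(cls) -> "CompatibilityTable":
        return cls({rel: set(pairs) for rel, pairs in _DEFAULT_COMPAT.items()})

    @classmethod
    def from_dict(cls, raw: dict[str, list]) -> "CompatibilityTable":
        mapping: dict[str, set[TypePair]] = {}
        for rel, pairs in raw.items():
            mapping[parse_relation(rel)] = {
                (EntityType.parse(h), EntityType.parse(t)) for h, t in pairs
            }
        return cls(mapping)

    def to_dict(self) -> dict[str, list[list[str]]]:
        return {
            rel: sorted([h.value, t.value] for h, t in pairs)
            for rel, pairs in self.mapping.items()
        }

    def allows(self, relation: str, head: EntityType, tail: EntityType) -> bool:
        canonical, is_inverse = RELATION_REGISTRY[parse_relation(relation)]
        if canonical not in self.mapping:
            return False
        pair = (tail, head) if is_inverse else (head, tail)
        return pair in self.mapping[canonical]

    def admissible_pairs(self, canonical_relation: str) -> set[TypePair]:
        return set(self.mapping.get(parse_relation(canonical_relation), set()))


# --------------------------------------------------------------------------
# Validation (annotation principles as lint)
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class Violation:
    code: str
    message: str
    item: str = ""


VIOLATION_CODES = (
    "OVERLAP_TYPE_CONFLICT",
    "NESTED_ENTITY",
    "PUNCTUATION_EDGE",
    "BIDIRECTIONAL_PAIR",
    "CROSS_SENTENCE_WITH_INTRA_ALTERNATIVE",
    "INCOMPATIBLE_RELATION",
    "UNANCHORED_SURFACE",
)

_FRAMING_WORDS = {"and", "or"}

_SENTENCE_RE = re.compile(r"[^.?!]+[.?!]?")


def default_sentence_bounds(text: str) -> list[Span]:
    """Fallback period/question/exclamation sentence splitter."""
    bounds: list[Span] = []
    for m in _SENTENCE_RE.finditer(text):
        seg = m.group()
        if not seg.strip():
            continue
        lead = len(seg) - len(seg.lstrip())
        trail = len(seg) - len(seg.rstrip())
        bounds.append((m.start() + lead, m.end() - trail))
    return bounds


def _anchor(mention: EntityMention, text: str) -> Optional[Span]:
    """Anchored span: declared span if it matches, else first occurrence."""
    if mention.span is not None:
        s, e = mention.span
        if 0 <= s <= e <= len(text) and text[s:e] == mention.surface:
            return (s, e)
        return None
    idx = text.find(mention.surface)
    if idx < 0:
        return None
    return (idx, idx + len(mention.surface))


def _sentence_index(pos: int, bounds: list[Span]) -> Optional[int]:
    for i, (s, e) in enumerate(bounds):
        if s <= pos < e:
            return i
    return None


def validate_annotation(
    doc: DocumentAnnotation,
    compat: Optional[CompatibilityTable] = None,
) -> list[Violation]:
    """Check a document annotation against the annotation principles.

    Returns a list of violations (empty means valid).  Violations are data:
    a structurally well-formed but principle-breaking annotation — exactly
    what an imperfect model emits — must remain scoreable.
    """
    compat = compat or CompatibilityTable.default()
    violations: list[Violation] = []
    bounds = doc.sentence_bounds or default_sentence_bounds(doc.text)

    # one surface string, one entity type
    by_surface: dict[str, set[EntityType]] = {}
    for m in doc.entities:
        by_surface.setdefault(m.surface, set()).add(m.etype)
    for surface, types in by_surface.items():
        if len(types) > 1:
            violations.append(
                Violation(
                    "OVERLAP_TYPE_CONFLICT",
                    f"surface {surface!r} assigned to multiple types: "
                    + ", ".join(sorted(t.value for t in types)),
                    surface,
                )
            )

    # anchoring + nesting
    anchored: list[tuple[EntityMention, Span]] = []
    for m in doc.entities:
        span = _anchor(m, doc.text)
        if span is None:
            violations.append(
                Violation(
                    "UNANCHORED_SURFACE",
                    f"surface {m.surface!r} not found at its span or anywhere in text",
                    m.surface,
                )
            )
        else:
            anchored.append((m, span))
    for i, (mi, (si, ei)) in enumerate(anchored):
        for mj, (sj, ej) in anchored[i + 1 :]:
            inner_in_outer = si <= sj and ej <= ei and (si, ei) != (sj, ej)
            outer_in_inner = sj <= si and ei <= ej and (si, ei) != (sj, ej)
            if inner_in_outer or outer_in_inner:
                violations.append(
                    Violation(
                        "NESTED_ENTITY",
                        f"span of {mj.surface!r} nests with span of {mi.surface!r}",
                        f"{mi.surface}|{mj.surface}",
                    )
                )

    # minimal punctuation / framing conjunctions (lint, never auto-rewritten)
    for m in doc.entities:
        s = m.surface
        tokens = s.split()
        edge_punct = s[0] in string.punctuation or s[-1] in string.punctuation
        framing = tokens and (tokens[0].lower() in _FRAMING_WORDS or tokens[-1].lower() in _FRAMING_WORDS)
        if edge_punct or framing:
            violations.append(
                Violation(
                    "PUNCTUATION_EDGE",
                    f"surface {m.surface!r} has punctuation edge or framing conjunction",
                    m.surface,
                )
            )

    # unidirectional relations: both directions of one canonical pair
    directions: dict[tuple, set[bool]] = {}
    for t in doc.triplets:
        _, is_inverse = RELATION_REGISTRY[t.relation]
        directions.setdefault(t.canonical_key(), set()).add(is_inverse)
    for key, dirs in directions.items():
        if len(dirs) > 1:
            violations.append(
                Violation(
                    "BIDIRECTIONAL_PAIR",
                    f"both directions retained for {key[0]!r} -- {key[2]} -- {key[3]!r}",
                    f"{key[0]}|{key[2]}|{key[3]}",
                )
            )

    # compatibility + intrasentence priority
    spans_by_key = {m.key: span for m, span in anchored}
    intra_by_relation: dict[str, set[int]] = {}
    triplet_sentences: list[tuple[Triplet, Optional[int], Optional[int]]] = []
    for t in doc.triplets:
        c = canonicalize_triplet(t)
        if not compat.allows(c.relation, c.head.etype, c.tail.etype):
            violations.append(
                Violation(
                    "INCOMPATIBLE_RELATION",
                    f"{c.head.etype.value} -- {c.relation} -- {c.tail.etype.value} "
                    "not admitted by compatibility table",
                    f"{c.head.surface}|{c.relation}|{c.tail.surface}",
                )
            )
        hs = spans_by_key.get(c.head.key)
        ts = spans_by_key.get(c.tail.key)
        hi = _sentence_index(hs[0], bounds) if hs else None
        ti = _sentence_index(ts[0], bounds) if ts else None
        triplet_sentences.append((c, hi, ti))
        if hi is not None and hi == ti:
            intra_by_relation.setdefault(c.relation, set()).add(hi)
    for c, hi, ti in triplet_sentences:
        if hi is None or ti is None or hi == ti:
            continue
        alternatives = intra_by_relation.get(c.relation, set())
        if alternatives & {hi, ti}:
            violations.append(
                Violation(
                    "CROSS_SENTENCE_WITH_INTRA_ALTERNATIVE",
                    f"cross-sentence {c.relation} between {c.head.surface!r} and "
                    f"{c.tail.surface!r} despite an intrasentence {c.relation} alternative",
                    f"{c.head.surface}|{c.relation}|{c.tail.surface}",
                )
            )

    return violations


# --------------------------------------------------------------------------
# Rarity
# --------------------------------------------------------------------------

DEFAULT_RARITY_THRESHOLD = 0.05


def is_rare(
    item_type: Union[EntityType, str],
    ref_stats: StatsTable,
    threshold: float = DEFAULT_RARITY_THRESHOLD,
) -> bool:
    """True iff the item's reference relative frequency is below ``threshold``.

    ``item_type`` is an :class:`EntityType` or a canonical relation name.
    Rarity is judged against a fixed reference table (not the current batch)
    so reward values are deterministic across batches.
    """
    if not 0 < threshold < 1:
        raise ConfigError(f"rarity threshold must be in (0, 1), got {threshold}")
    if isinstance(item_type, EntityType):
        name = item_type.value
    else:
        name = str(item_type)
        if name not in ref_stats.entity_counts and name not in ref_stats.relation_counts:
            # allow aliases ("side effect") and canonical relation labels
            try:
                name = EntityType.parse(name).value
            except SchemaError:
                name = parse_relation(name)
                canonical, _ = RELATION_REGISTRY[name]
                name = canonical
    return ref_stats.frequency(name) < threshold
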