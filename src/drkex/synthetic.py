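"""Synthetic gold corpora, controlled prediction perturbation, CoT rendering.

The generator emits template-realized abstracts whose annotations are valid
by construction (every surface occurs verbatim in the text, triplets respect
the compatibility table, sentence bounds are recorded), with entity and
relation type mixtures that track a configurable target composition — by
default the composition of the DrugReC reference corpus.  The perturbation
engine then injects the field's canonical error taxonomy (spurious and
missing entities, type confusions, boundary shifts, cross-sentence misses,
tag corruption) at controlled rates, logging every injection so downstream
error classification and reward scoring can be tested against an exact
ground truth.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Optional

import numpy as np
from pydantic import BaseModel, ConfigDict, model_validator

from .parsing import _TAG_RE, check_tag_integrity, serialize_annotation
from .schema import (
    CompatibilityTable,
    DocumentAnnotation,
    EntityMention,
    EntityType,
    Triplet,
    CANONICAL_RELATIONS,
    _anchor,
    _sentence_index,
)
from .stats import REFERENCE_STATS


class GenerationError(ValueError):
    """Raised when a generator configuration is infeasible."""


# --------------------------------------------------------------------------
# Gazetteer: invented but realistic names, plus a few canonical exemplars
# (Metformin, cetuximab, Docetaxel, BRCA2, p53) kept for fixture continuity.
# --------------------------------------------------------------------------

GAZETTEER: dict[EntityType, tuple[str, ...]] = {
    EntityType.DRUG: (
        "Metformin", "cetuximab", "Docetaxel", "Imatinib", "Gemcitabine",
        "Pembrolizumab", "Rituximab", "Atorvastatin", "Dexamethasone",
        "Erlotinib", "Sirolimus", "Lisinopril",
    ),
    EntityType.DISEASE: (
        "colorectal cancer", "celiac disease", "type 2 diabetes",
        "rheumatoid arthritis", "pulmonary fibrosis", "chronic myeloid leukemia",
        "atrial fibrillation", "ulcerative colitis", "melanoma",
        "Parkinson disease", "multiple myeloma", "psoriasis",
    ),
    EntityType.TARGET: (
        "EGFR", "MDM2", "VEGFR-2", "HER2 receptor", "PD-1 receptor",
        "BCR-ABL fusion protein", "TNF-alpha", "mTOR complex",
    ),
    EntityType.SIDE_EFFECT: (
        "infusion reactions", "neutropenia", "hepatotoxicity",
        "peripheral neuropathy", "QT prolongation", "mucositis", "alopecia",
    ),
    EntityType.GENE: (
        "BRCA2", "p53", "KRAS", "APOE", "MTHFR", "CFTR", "BRAF", "PTEN",
    ),
    EntityType.BIOMARKER: (
        "serum ferritin", "C-reactive protein", "troponin I",
        "anti-tTG antibodies", "HbA1c", "prostate-specific antigen",
        "D-dimer", "interleukin-6",
    ),
    EntityType.SYMPTOM: (
        "nausea", "fatigue", "chest pain", "shortness of breath",
        "joint stiffness", "headache", "dizziness", "night sweats",
    ),
    EntityType.COMPLICATION: (
        "extensive hemorrhage", "renal failure", "secondary infection",
        "deep vein thrombosis", "septic shock", "bowel perforation",
    ),
    EntityType.ANATOMY: (
        "liver", "sigmoid colon", "left ventricle", "bone marrow", "pancreas",
        "hippocampus", "lung parenchyma", "synovial membrane",
    ),
    EntityType.TEST: (
        "colonoscopy", "serological testing", "echocardiography",
        "fasting glucose measurement", "cardiac MRI", "liver biopsy",
        "spirometry", "bone density scanning",
    ),
    EntityType.TREATMENT: (
        "adjuvant chemotherapy", "radiotherapy", "cognitive behavioral therapy",
        "hemodialysis", "physical rehabilitation", "splenectomy", "immunotherapy",
    ),
}

# Intrasentence templates; {h} always precedes {t} so offsets are exact.
_TEMPLATES: dict[str, tuple[str, ...]] = {
    "treat": (
        "{h} treats {t} in adult patients.",
        "{h} showed clinical benefit against {t} in the trial.",
    ),
    "is_target_of": (
        "{h} is the molecular target of {t}.",
        "{h} was identified as the primary target engaged by {t}.",
    ),
    "is_side_effect_of": (
        "{h} was reported after administration of {t}.",
        "{h} emerged as a frequent adverse reaction to {t}.",
    ),
    "is_biomarker_of": (
        "{h} served as a diagnostic biomarker of {t}.",
        "{h} levels reliably indicated {t} in this cohort.",
    ),
    "is_examination_for": (
        "{h} remains the recommended examination for {t}.",
        "{h} confirmed the diagnosis of {t}.",
    ),
    "complication_of": (
        "{h} developed as a complication of {t}.",
        "{h} frequently complicated the course of {t}.",
    ),
    "is_located_in": (
        "{h} was localized in the {t}.",
        "{h} predominantly involved the {t}.",
    ),
    "is_symptom_of": (
        "{h} was a presenting symptom of {t}.",
        "{h} commonly accompanied {t} at diagnosis.",
    ),
    "increases_expression_of": (
        "{h} increases the expression of {t}.",
        "{h} markedly upregulated {t} expression.",
    ),
}

_CROSS_HEAD_TEMPLATES = (
    "The investigators first documented {h} during the study.",
    "Early assessments repeatedly noted {h}.",
)
_CROSS_TAIL_TEMPLATES = (
    "Subsequent workup linked this finding to {t}.",
    "Later review attributed the observation to {t}.",
)
_STANDALONE_TEMPLATES = (
    "The assessment also documented {h} at follow-up.",
    "Investigators additionally recorded {h} in several participants.",
    "A secondary analysis considered {h} as well.",
)
_FILLER_SENTENCES = (
    "Enrollment and monitoring followed standard practice.",
    "No further findings were recorded during observation.",
    "Data were reviewed independently by two readers.",
)
_CLOSING_SENTENCE = "Overall, the cohort tolerated the protocol well at baseline."

# words guaranteed present (closing sentence) and disjoint from gazetteer tokens
_SPURIOUS_PHRASES = ("cohort", "protocol", "baseline", "Overall")

#: confusable-type swap table reflecting observed confusions among
#: semantically adjacent categories; fully configurable.
CONFUSABLE_TYPES: dict[EntityType, tuple[EntityType, ...]] = {
    EntityType.BIOMARKER: (EntityType.GENE, EntityType.TARGET),
    EntityType.GENE: (EntityType.TARGET, EntityType.BIOMARKER),
    EntityType.TARGET: (EntityType.GENE, EntityType.BIOMARKER),
    EntityType.SIDE_EFFECT: (EntityType.COMPLICATION,),
    EntityType.COMPLICATION: (EntityType.SIDE_EFFECT,),
}


# --------------------------------------------------------------------------
# Configuration
# --------------------------------------------------------------------------


def _default_entity_mixture() -> dict[str, float]:
    return REFERENCE_STATS.entity_shares()


def _default_relation_mixture() -> dict[str, float]:
    return REFERENCE_STATS.relation_shares()


class GeneratorConfig(BaseModel):
    model_config = ConfigDict(frozen=True)

    n_docs: int = 100
    entity_mixture: dict[str, float] = None  # type: ignore[assignment]
    relation_mixture: dict[str, float] = None  # type: ignore[assignment]
    entities_per_doc: tuple[int, int] = (10, 16)
    triplets_per_doc: tuple[int, int] = (2, 4)
    sentences_per_doc: tuple[int, int] = (1, 2)  # extra entity-free filler
    cross_sentence_fraction: float = 0.10
    seed: int = 0

    @model_validator(mode="before")
    @classmethod
    def _fill_defaults(cls, values):
        if isinstance(values, dict):
            if values.get("entity_mixture") is None:
                values["entity_mixture"] = _default_entity_mixture()
            if values.get("relation_mixture") is None:
                values["relation_mixture"] = _default_relation_mixture()
        return values

    @model_validator(mode="after")
    def _check(self) -> "GeneratorConfig":
        ent = {EntityType.parse(k).value: float(v) for k, v in self.entity_mixture.items()}
        rel = {}
        for k, v in self.relation_mixture.items():
            if k not in CANONICAL_RELATIONS:
                raise GenerationError(f"relation mixture key must be canonical: {k!r}")
            rel[k] = float(v)
        for t in EntityType:
            ent.setdefault(t.value, 0.0)
        for r in CANONICAL_RELATIONS:
            rel.setdefault(r, 0.0)
        if any(v < 0 for v in ent.values()) or any(v < 0 for v in rel.values()):
            raise GenerationError("mixture frequencies must be non-negative")
        if abs(sum(ent.values()) - 1.0) > 1e-9 or abs(sum(rel.values()) - 1.0) > 1e-9:
            raise GenerationError("mixtures must sum to 1")
        object.__setattr__(self, "entity_mixture", ent)
        object.__setattr__(self, "relation_mixture", rel)
        for name, (lo, hi) in (
            ("entities_per_doc", self.entities_per_doc),
            ("triplets_per_doc", self.triplets_per_doc),
            ("sentences_per_doc", self.sentences_per_doc),
        ):
            if lo < 0 or hi < lo:
                raise GenerationError(f"{name} range ({lo}, {hi}) is empty or negative")
        if not 0.0 <= self.cross_sentence_fraction <= 1.0:
            raise GenerationError("cross_sentence_fraction must lie in [0, 1]")
        if self.n_docs < 0:
            raise GenerationError("n_docs must be non-negative")
        return self


class ErrorProfile(BaseModel):
    """Per-error-type injection rates, all in [0, 1]."""

    model_config = ConfigDict(frozen=True)

    entity_omission: float = 0.0
    entity_spurious: float = 0.0
    entity_type_swap: float = 0.0
    entity_boundary_shift: float = 0.0
    triplet_entity_type_error: float = 0.0
    cross_sentence_drop: float = 0.0
    tag_corruption_rate: float = 0.0
    length_violation_rate: float = 0.0

    @model_validator(mode="after")
    def _rates(self) -> "ErrorProfile":
        for name, value in self.model_dump().items():
            if not 0.0 <= value <= 1.0:
                raise ValueError(f"rate {name} must lie in [0, 1], got {value}")
        return self


@dataclass(frozen=True)
class Injection:
    kind: str
    doc_id: str
    target: str
    replacement: str = ""


InjectionLog = list[Injection]


# --------------------------------------------------------------------------
# Gold corpus generation
# --------------------------------------------------------------------------


def _admissible_pairs(relation, compat, ent_mix):
    pairs = sorted(
        compat.admissible_pairs(relation), key=lambda p: (p[0].value, p[1].value)
    )
    weights = [ent_mix[h.value] * ent_mix[t.value] for h, t in pairs]
    total = sum(weights)
    if total <= 0:
        return [], []
    return pairs, [w / total for w in weights]


def check_feasibility(cfg: GeneratorConfig, compat: CompatibilityTable) -> None:
    for rel, share in cfg.relation_mixture.items():
        if share <= 0:
            continue
        pairs, _ = _admissible_pairs(rel, compat, cfg.entity_mixture)
        if not pairs:
            raise GenerationError(
                f"relation {rel!r} has positive mixture weight but no admissible "
                "(head, tail) type pair with positive entity-mixture weight"
            )


def _template_sentence(template: str, h: Optional[str], t: Optional[str]):
    """Realize a template; return (sentence, {placeholder: offset})."""
    offsets = {}
    out = template
    for name, value in (("h", h), ("t", t)):
        marker = "{" + name + "}"
        if marker in out and value is not None:
            idx = out.index(marker)
            out = out[:idx] + value + out[idx + len(marker) :]
            offsets[name] = (idx, idx + len(value))
    return out, offsets


class _DocBuilder:
    def __init__(self, doc_id: str):
        self.doc_id = doc_id
        self.sentences: list[str] = []
        # (surface, etype, sentence_idx, start_in_sentence)
        self.placements: list[tuple[str, EntityType, int, int]] = []
        self.used_surfaces: set[str] = set()

    def add_sentence(self, sentence: str, placed: list[tuple[str, EntityType, int]]) -> int:
        idx = len(self.sentences)
        self.sentences.append(sentence)
        for surface, etype, start in placed:
            self.placements.append((surface, etype, idx, start))
            self.used_surfaces.add(surface)
        return idx

    def build(self, triplet_specs: list[tuple[str, str, str]]) -> DocumentAnnotation:
        text = " ".join(self.sentences)
        starts = []
        pos = 0
        bounds = []
        for s in self.sentences:
            starts.append(pos)
            bounds.append((pos, pos + len(s)))
            pos += len(s) + 1
        mentions: dict[str, EntityMention] = {}
        order: list[EntityMention] = []
        for surface, etype, sent_idx, off in self.placements:
            if surface in mentions:
                continue
            span = (starts[sent_idx] + off, starts[sent_idx] + off + len(surface))
            m = EntityMention(surface=surface, etype=etype, span=span)
            mentions[surface] = m
            order.append(m)
        triplets = [
            Triplet(head=mentions[h], relation=rel, tail=mentions[t])
            for h, rel, t in triplet_specs
        ]
        return DocumentAnnotation(
            doc_id=self.doc_id,
            text=text,
            sentence_bounds=bounds,
            entities=order,
            triplets=triplets,
        )


def generate_gold_corpus(
    cfg: GeneratorConfig,
    compat: Optional[CompatibilityTable] = None,
) -> list[DocumentAnnotation]:
    """Generate a deterministic gold-annotated corpus.

    Every document passes :func:`drkex.schema.validate_annotation` with zero
    violations by construction.  Standalone (non-triplet) mentions are
    sampled with deficit correction against the target entity mixture, so
    empirical type shares converge on the configured mixture as the corpus
    grows.
    """
    compat = compat or CompatibilityTable.default()
    check_feasibility(cfg, compat)
    rng = np.random.default_rng(cfg.seed)
    relations = list(CANONICAL_RELATIONS)
    rel_p = np.array([cfg.relation_mixture[r] for r in relations], dtype=float)
    global_counts = {t.value: 0 for t in EntityType}

    def note(etype: EntityType) -> None:
        global_counts[etype.value] += 1

    corpus: list[DocumentAnnotation] = []
    for i in range(cfg.n_docs):
        builder = _DocBuilder(f"doc-{i:05d}")
        triplet_specs: list[tuple[str, str, str]] = []
        seen_keys: set[tuple] = set()

        n_trip = int(rng.integers(cfg.triplets_per_doc[0], cfg.triplets_per_doc[1] + 1))
        for _ in range(n_trip):
            rel = relations[int(rng.choice(len(relations), p=rel_p))]
            pairs, weights = _admissible_pairs(rel, compat, cfg.entity_mixture)
            h_type, t_type = pairs[int(rng.choice(len(pairs), p=weights))]
            h_cands = [s for s in GAZETTEER[h_type] if s not in builder.used_surfaces]
            if not h_cands:
                continue
            h_surface = str(h_cands[int(rng.integers(len(h_cands)))])
            t_cands = [
                s
                for s in GAZETTEER[t_type]
                if s not in builder.used_surfaces and s != h_surface
            ]
            if not t_cands:
                continue
            t_surface = str(t_cands[int(rng.integers(len(t_cands)))])
            key = (h_surface, rel, t_surface)
            if key in seen_keys:
                continue
            seen_keys.add(key)
            cross = bool(rng.random() < cfg.cross_sentence_fraction)
            if cross:
                tmpl_h = _CROSS_HEAD_TEMPLATES[int(rng.integers(len(_CROSS_HEAD_TEMPLATES)))]
                tmpl_t = _CROSS_TAIL_TEMPLATES[int(rng.integers(len(_CROSS_TAIL_TEMPLATES)))]
                s1, off1 = _template_sentence(tmpl_h, h_surface, None)
                s2, off2 = _template_sentence(tmpl_t.replace("{t}", "{h}"), t_surface, None)
                builder.add_sentence(s1, [(h_surface, h_type, off1["h"][0])])
                builder.add_sentence(s2, [(t_surface, t_type, off2["h"][0])])
            else:
                options = _TEMPLATES[rel]
                tmpl = options[int(rng.integers(len(options)))]
                sent, offs = _template_sentence(tmpl, h_surface, t_surface)
                builder.add_sentence(
                    sent,
                    [
                        (h_surface, h_type, offs["h"][0]),
                        (t_surface, t_type, offs["t"][0]),
                    ],
                )
            note(h_type)
            note(t_type)
            triplet_specs.append(key)

        # standalone mentions with deficit-corrected type sampling
        n_ent_target = int(rng.integers(cfg.entities_per_doc[0], cfg.entities_per_doc[1] + 1))
        excluded: set[str] = set()
        while len(builder.used_surfaces) < n_ent_target:
            total = sum(global_counts.values()) + 1
            deficits = {
                t.value: cfg.entity_mixture[t.value] * total - global_counts[t.value]
                for t in EntityType
                if cfg.entity_mixture[t.value] > 0 and t.value not in excluded
            }
            if not deficits:
                break
            pick = max(sorted(deficits), key=lambda k: deficits[k])
            etype = EntityType(pick)
            cands = [s for s in GAZETTEER[etype] if s not in builder.used_surfaces]
            if not cands:
                excluded.add(pick)
                continue
            surface = str(cands[int(rng.integers(len(cands)))])
            tmpl = _STANDALONE_TEMPLATES[int(rng.integers(len(_STANDALONE_TEMPLATES)))]
            sent, offs = _template_sentence(tmpl, surface, None)
            builder.add_sentence(sent, [(surface, etype, offs["h"][0])])
            note(etype)

        n_fill = int(rng.integers(cfg.sentences_per_doc[0], cfg.sentences_per_doc[1] + 1))
        for _ in range(n_fill):
            builder.add_sentence(
                _FILLER_SENTENCES[int(rng.integers(len(_FILLER_SENTENCES)))], []
            )
        builder.add_sentence(_CLOSING_SENTENCE, [])
        corpus.append(builder.build(triplet_specs))
    return corpus


# --------------------------------------------------------------------------
# Perturbation
# --------------------------------------------------------------------------


def _confusable(etype: EntityType, rng: np.random.Generator) -> EntityType:
    options = CONFUSABLE_TYPES.get(etype)
    if options is None:
        options = tuple(t for t in EntityType if t != etype)
    return options[int(rng.integers(len(options)))]


_NEXT_WORD_RE = re.compile(r"^\s+([A-Za-z][\w\-]*)")
_PREV_WORD_RE = re.compile(r"([A-Za-z][\w\-]*)\s+$")


def _shift_boundary(m: EntityMention, text: str) -> Optional[EntityMention]:
    """Extend the surface by the adjacent token, or truncate the last token."""
    span = _anchor(m, text)
    if span is None:
        return None
    s, e = span
    nxt = _NEXT_WORD_RE.match(text[e:])
    if nxt:
        new_e = e + nxt.end(1)
        return EntityMention(surface=text[s:new_e], etype=m.etype, span=(s, new_e))
    if " " in m.surface:
        new_surface = m.surface.rsplit(" ", 1)[0]
        return EntityMention(surface=new_surface, etype=m.etype, span=(s, s + len(new_surface)))
    prev = _PREV_WORD_RE.search(text[:s])
    if prev:
        new_s = prev.start(1)
        return EntityMention(surface=text[new_s:e], etype=m.etype, span=(new_s, e))
    return None


def _is_cross_sentence(t: Triplet, doc: DocumentAnnotation) -> bool:
    spans = {m.key: _anchor(m, doc.text) for m in doc.entities}
    hs, ts = spans.get(t.head.key), spans.get(t.tail.key)
    if hs is None or ts is None or not doc.sentence_bounds:
        return False
    hi = _sentence_index(hs[0], doc.sentence_bounds)
    ti = _sentence_index(ts[0], doc.sentence_bounds)
    return hi is not None and ti is not None and hi != ti


def perturb_prediction(
    gold: DocumentAnnotation,
    profile: ErrorProfile,
    seed: int,
) -> tuple[DocumentAnnotation, InjectionLog]:
    """Apply each perturbation independently per item at its configured rate.

    The returned injection log is an exact record of what changed; it is the
    ground truth for error-recovery tests.  Endpoint retyping for
    ``triplet_entity_type_error`` only touches entities participating in a
    single triplet, so one injection maps to exactly one recoverable error.
    """
    rng = np.random.default_rng(seed)
    log: InjectionLog = []
    ents: list[EntityMention] = list(gold.entities)
    trips: list[Triplet] = list(gold.triplets)
    touched: set[str] = set()

    def replace_entity(old: EntityMention, new: EntityMention) -> None:
        nonlocal ents, trips
        ents = [new if m is old else m for m in ents]
        trips = [
            Triplet(
                head=new if t.head.key == old.key else t.head,
                relation=t.relation,
                tail=new if t.tail.key == old.key else t.tail,
            )
            for t in trips
        ]

    # omission
    for m in list(ents):
        if rng.random() < profile.entity_omission:
            ents = [x for x in ents if x is not m]
            trips = [t for t in trips if m.key not in (t.head.key, t.tail.key)]
            touched.add(m.surface)
            log.append(Injection("entity_omission", gold.doc_id, m.surface))

    # type swap
    for m in list(ents):
        if m.surface in touched:
            continue
        if rng.random() < profile.entity_type_swap:
            new_type = _confusable(m.etype, rng)
            new = EntityMention(surface=m.surface, etype=new_type, span=m.span)
            replace_entity(m, new)
            touched.add(m.surface)
            log.append(
                Injection(
                    "entity_type_swap",
                    gold.doc_id,
                    f"{m.surface}:{m.etype.value}",
                    new_type.value,
                )
            )

    # boundary shift
    for m in list(ents):
        if m.surface in touched:
            continue
        if rng.random() < profile.entity_boundary_shift:
            new = _shift_boundary(m, gold.text)
            if new is None or new.surface in {x.surface for x in ents}:
                continue
            replace_entity(m, new)
            touched.add(m.surface)
            touched.add(new.surface)
            log.append(
                Injection("entity_boundary_shift", gold.doc_id, m.surface, new.surface)
            )

    # spurious additions (non-gold phrases taken verbatim from the document)
    candidates = [
        w
        for w in _SPURIOUS_PHRASES
        if w in gold.text and w not in {m.surface for m in ents}
    ]
    for _ in range(len(gold.entities)):
        if not candidates:
            break
        if rng.random() < profile.entity_spurious:
            surface = candidates.pop(0)
            etype = EntityType(
                sorted(t.value for t in EntityType)[int(rng.integers(len(EntityType)))]
            )
            idx = gold.text.find(surface)
            ents.append(
                EntityMention(surface=surface, etype=etype, span=(idx, idx + len(surface)))
            )
            log.append(Injection("entity_spurious", gold.doc_id, surface, etype.value))

    # triplet endpoint retyping
    for t in list(trips):
        if rng.random() < profile.triplet_entity_type_error:
            side = int(rng.integers(2))
            endpoint = (t.head, t.tail)[side]
            participation = sum(
                endpoint.key in (x.head.key, x.tail.key) for x in trips
            )
            if participation != 1 or endpoint.surface in touched:
                continue
            new_type = _confusable(endpoint.etype, rng)
            current = next(m for m in ents if m.key == endpoint.key)
            new = EntityMention(surface=endpoint.surface, etype=new_type, span=current.span)
            replace_entity(current, new)
            touched.add(endpoint.surface)
            log.append(
                Injection(
                    "triplet_entity_type_error",
                    gold.doc_id,
                    f"{endpoint.surface}:{endpoint.etype.value}",
                    new_type.value,
                )
            )

    # cross-sentence triplet drops
    for t in list(trips):
        if _is_cross_sentence(t, gold) and rng.random() < profile.cross_sentence_drop:
            trips = [x for x in trips if x is not t]
            log.append(
                Injection(
                    "cross_sentence_drop",
                    gold.doc_id,
                    f"{t.head.surface}|{t.relation}|{t.tail.surface}",
                )
            )

    pred = DocumentAnnotation(
        doc_id=gold.doc_id,
        text=gold.text,
        sentence_bounds=list(gold.sentence_bounds),
        entities=ents,
        triplets=trips,
    )
    return pred, log


# --------------------------------------------------------------------------
# Chain-of-thought rendering
# --------------------------------------------------------------------------

_PAD_TEXT = " The reasoning continues with schema checks and constraint validation."


def render_model_output(
    pred: DocumentAnnotation,
    tag_ok: bool = True,
    think_length: int = 600,
    seed: int = 0,
) -> str:
    """Render a prediction as raw model output: think/step block + JSON payload.

    The think-block content is padded or truncated so its character count
    (excluding tag tokens) equals ``think_length`` exactly.  With
    ``tag_ok=False`` one random tag corruption (drop, duplicate, or
    transpose) is applied, which is guaranteed to break tag integrity.
    """
    rng = np.random.default_rng(seed)
    ent_desc = "; ".join(f"'{m.surface}' -> {m.etype.value}" for m in pred.entities)
    rel_desc = "; ".join(
        f"'{t.head.surface}' {t.relation} '{t.tail.surface}'" for t in pred.triplets
    )
    steps = [
        "Task framing: approach the passage as a biomedical annotation specialist "
        "and extract schema-conformant drug repositioning knowledge.",
        "Entity identification: " + (ent_desc or "no candidate entities found."),
        "Relation reasoning: " + (rel_desc or "no relations asserted."),
        "Formatting awareness: emit JSON with two root keys, Entities and "
        "Relationships, original casing preserved.",
    ]
    content = sum(len(s) for s in steps)
    if content > think_length:
        budget = think_length
        trimmed = []
        for s in steps:
            trimmed.append(s[:budget])
            budget -= len(trimmed[-1])
        steps = trimmed
    elif content < think_length:
        deficit = think_length - content
        pad = (_PAD_TEXT * (deficit // len(_PAD_TEXT) + 1))[:deficit]
        steps[-1] += pad
    interior = "".join(f"<step>{s}</step>" for s in steps)
    raw = f"<think>{interior}</think>\n" + serialize_annotation(pred)
    if tag_ok:
        return raw
    return _corrupt_tags(raw, rng)


def _corrupt_tags(raw: str, rng: np.random.Generator) -> str:
    tokens = list(_TAG_RE.finditer(raw))
    ops = ["drop", "duplicate", "transpose"]
    order = [ops[int(j)] for j in rng.permutation(len(ops))]
    for op in order:
        if op == "drop" or len(tokens) < 2:
            k = int(rng.integers(len(tokens)))
            m = tokens[k]
            out = raw[: m.start()] + raw[m.end() :]
        elif op == "duplicate":
            k = int(rng.integers(len(tokens)))
            m = tokens[k]
            out = raw[: m.end()] + m.group() + raw[m.end() :]
        else:  # transpose adjacent distinct tokens
            k = int(rng.integers(len(tokens) - 1))
            a, b = tokens[k], tokens[k + 1]
            out = (
                raw[: a.start()]
                + b.group()
                + raw[a.end() : b.start()]
                + a.group()
                + raw[b.end() :]
            )
        if not check_tag_integrity(out).tag_integrity_ok:
            return out
    # dropping the opening think tag always breaks integrity
    m = tokens[0]
    return raw[: m.start()] + raw[m.end() :]
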