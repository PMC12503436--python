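"""JSONL corpus readers/writers and the k-shot annotation prompt renderer."""

from __future__ import annotations

import json
from pathlib import Path
from typing import Iterable, Union

from pydantic import BaseModel, ConfigDict, field_validator

from .parsing import serialize_annotation
from .schema import (
    DocumentAnnotation,
    EntityMention,
    EntityType,
    RELATION_TYPES,
    Triplet,
)

SCHEMA_VERSION = 1

PathLike = Union[str, Path]


class CorpusFormatError(ValueError):
    """Malformed corpus file; message names the offending line."""


def doc_to_record(doc: DocumentAnnotation) -> dict:
    return {
        "schema_version": SCHEMA_VERSION,
        "doc_id": doc.doc_id,
        "text": doc.text,
        "sentence_bounds": [list(b) for b in doc.sentence_bounds],
        "entities": [
            {
                "surface": m.surface,
                "type": m.etype.value,
                "span": list(m.span) if m.span else None,
            }
            for m in doc.entities
        ],
        "triplets": [
            {
                "head": {"surface": t.head.surface, "type": t.head.etype.value},
                "relation": t.relation,
                "tail": {"surface": t.tail.surface, "type": t.tail.etype.value},
            }
            for t in doc.triplets
        ],
    }


def record_to_doc(record: dict) -> DocumentAnnotation:
    def mention(raw: dict) -> EntityMention:
        span = raw.get("span")
        return EntityMention(
            surface=raw["surface"],
            etype=EntityType.parse(raw["type"]),
            span=tuple(span) if span else None,
        )

    # triplet endpoints carry no span; resolve against the entity list
    entities = [mention(e) for e in record.get("entities", [])]
    by_key = {(m.surface, m.etype): m for m in entities}
    triplets = []
    for t in record.get("triplets", []):
        head = mention(t["head"])
        tail = mention(t["tail"])
        triplets.append(
            Triplet(
                head=by_key.get(head.key, head),
                relation=t["relation"],
                tail=by_key.get(tail.key, tail),
            )
        )
    return DocumentAnnotation(
        doc_id=record["doc_id"],
        text=record["text"],
        sentence_bounds=[tuple(b) for b in record.get("sentence_bounds", [])],
        entities=entities,
        triplets=triplets,
    )


def read_corpus(path: PathLike) -> list[DocumentAnnotation]:
    """Read a JSONL corpus, validating structure and doc_id uniqueness."""
    corpus: list[DocumentAnnotation] = []
    seen: set[str] = set()
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            try:
                record = json.loads(line)
            except json.JSONDecodeError as exc:
                raise CorpusFormatError(f"line {lineno}: invalid JSON ({exc})") from None
            for key in ("doc_id", "text"):
                if key not in record:
                    raise CorpusFormatError(f"line {lineno}: missing required field {key!r}")
            try:
                doc = record_to_doc(record)
            except (ValueError, KeyError, TypeError) as exc:
                raise CorpusFormatError(f"line {lineno}: {exc}") from None
            if doc.doc_id in seen:
                raise CorpusFormatError(f"line {lineno}: duplicate doc_id {doc.doc_id!r}")
            seen.add(doc.doc_id)
            corpus.append(doc)
    return corpus


def write_corpus(corpus: Iterable[DocumentAnnotation], path: PathLike) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for doc in corpus:
            fh.write(json.dumps(doc_to_record(doc), ensure_ascii=False) + "\n")


def read_raw_outputs(path: PathLike) -> list[tuple[str, str]]:
    """Read raw model outputs as (doc_id, output_text) pairs from JSONL."""
    out: list[tuple[str, str]] = []
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            try:
                record = json.loads(line)
                out.append((record["doc_id"], record["output_text"]))
            except (json.JSONDecodeError, KeyError, TypeError) as exc:
                raise CorpusFormatError(f"line {lineno}: {exc}") from None
    return out


def write_raw_outputs(pairs: Iterable[tuple[str, str]], path: PathLike) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for doc_id, text in pairs:
            fh.write(json.dumps({"doc_id": doc_id, "output_text": text}) + "\n")


# --------------------------------------------------------------------------
# Annotation prompt
# --------------------------------------------------------------------------

_DEFAULT_ROLE = (
    "You are a biomedical annotation specialist for drug repositioning "
    "knowledge extraction."
)
_DEFAULT_OUTPUT_INSTRUCTIONS = (
    "Return the final answer as a JSON object with exactly two root keys, "
    '"Entities" and "Relationships". Each relationship entry is a quintuple '
    "{Entity1; Type1; Relationship; Entity2; Type2}. Preserve original casing "
    "and embed no explanatory text."
)


def default_schema_digest() -> str:
    lines = ["Entity types (11):"]
    lines += [f"  - {t.value}" for t in EntityType]
    lines.append("Relationship types (9 canonical, each with a directed inverse):")
    lines += [f"  - {r.canonical_name} (inverse: {r.inverse_name})" for r in RELATION_TYPES]
    return "\n".join(lines)


class PromptSpec(BaseModel):
    model_config = ConfigDict(frozen=True, arbitrary_types_allowed=True)

    role_text: str = _DEFAULT_ROLE
    schema_digest: str = ""
    k_examples: tuple[tuple[str, DocumentAnnotation], ...] = ()
    output_instructions: str = _DEFAULT_OUTPUT_INSTRUCTIONS

    @field_validator("k_examples")
    @classmethod
    def _k_bounded(cls, v):
        if len(v) > 10:
            raise ValueError("at most 10 k-shot demonstrations are supported")
        return v


def render_annotation_prompt(spec: PromptSpec) -> str:
    """Deterministic five-section annotation prompt with k-shot demonstrations.

    Sections: role/task, entity and relationship type identification,
    annotation principles, triplet construction, output format.
    """
    digest = spec.schema_digest or default_schema_digest()
    sections = [
        "## Step 1: Role and task\n" + spec.role_text,
        "## Step 2: Identify entity and relationship types\n"
        "Identify candidate entity types and contextual relationship types "
        "according to the predefined schema.\n" + digest,
        "## Step 3: Annotation principles\n"
        "Entities: (1) non-overlapping — one string, one entity type; "
        "(2) non-nesting — no entity inside another entity's span; "
        "(3) minimal punctuation and conjunction. "
        "Relationships: (1) intrasentence priority — prefer triplets within a "
        "single sentence; (2) unidirectional — retain only one directed "
        "relation between any two related entities.",
        "## Step 4: Triplet construction\n"
        "Assemble the extracted entities and their contextual associations "
        "into semantically coherent triplets.",
        "## Step 5: Output format\n" + spec.output_instructions,
    ]
    demos = []
    for i, (text, doc) in enumerate(spec.k_examples, start=1):
        demos.append(
            f"### Demonstration {i}\nInput:\n{text}\nOutput:\n{serialize_annotation(doc)}"
        )
    return "\n\n".join(sections + demos) + "\n"
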