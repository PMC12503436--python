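"""Parsing of raw model output: tag integrity, reasoning trace, JSON payload.

Model outputs are expected to wrap their chain-of-thought in one
``<think>...</think>`` block containing nested ``<step>`` blocks, followed by
a JSON object with two root keys, ``Entities`` and ``Relationships``, whose
relationship entries are quintuples {Entity1; Type1; Relationship; Entity2;
Type2}.  Everything here is total: arbitrary text yields a report, never an
exception.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, field
from typing import Any, Optional

from .schema import (
    DocumentAnnotation,
    EntityMention,
    EntityType,
    SchemaError,
    Triplet,
    parse_relation,
)

_TAG_RE = re.compile(r"</?(?:think|step)>")

THINK_OPEN, THINK_CLOSE, STEP_OPEN, STEP_CLOSE = "<think>", "</think>", "<step>", "</step>"


@dataclass(frozen=True)
class TagReport:
    think_open_count: int
    think_close_count: int
    step_open_count: int
    step_close_count: int
    well_nested: bool
    closure_ordered: bool
    tag_integrity_ok: bool


@dataclass(frozen=True)
class ReasoningTrace:
    steps: tuple[str, ...] = ()
    total_length: int = 0


@dataclass(frozen=True)
class Diagnostic:
    severity: str  # "fatal" | "warning"
    message: str


@dataclass
class ParsedOutput:
    tag_report: TagReport
    trace: ReasoningTrace
    annotation: Optional[DocumentAnnotation]
    diagnostics: list[Diagnostic] = field(default_factory=list)

    @property
    def fatal(self) -> bool:
        return any(d.severity == "fatal" for d in self.diagnostics)


def _tokens(raw: str) -> list[tuple[str, bool, int, int]]:
    """(kind, is_closing, start, end) for every tag token in document order."""
    out = []
    for m in _TAG_RE.finditer(raw):
        tok = m.group()
        closing = tok.startswith("</")
        kind = "think" if "think" in tok else "step"
        out.append((kind, closing, m.start(), m.end()))
    return out


def check_tag_integrity(raw: str) -> TagReport:
    """Stack-based tag matching over think/step tokens; other text is ignored.

    Integrity requires balanced counts, proper nesting, no closing tag before
    its opening tag, exactly one think block, and at least one step block
    completed inside it.
    """
    counts = {("think", False): 0, ("think", True): 0, ("step", False): 0, ("step", True): 0}
    stack: list[str] = []
    well_nested = True
    closure_ordered = True
    think_blocks = 0
    steps_in_think = 0
    for kind, closing, _s, _e in _tokens(raw):
        counts[(kind, closing)] += 1
        if not closing:
            stack.append(kind)
        elif stack and stack[-1] == kind:
            stack.pop()
            if kind == "think":
                think_blocks += 1
            elif kind == "step" and "think" in stack:
                steps_in_think += 1
        elif kind in stack:
            # closes a non-top open tag: interleaved nesting
            well_nested = False
            stack.reverse()
            stack.remove(kind)
            stack.reverse()
        else:
            closure_ordered = False
    balanced = (
        counts[("think", False)] == counts[("think", True)]
        and counts[("step", False)] == counts[("step", True)]
        and not stack
    )
    ok = (
        balanced
        and well_nested
        and closure_ordered
        and think_blocks == 1
        and steps_in_think >= 1
    )
    return TagReport(
        think_open_count=counts[("think", False)],
        think_close_count=counts[("think", True)],
        step_open_count=counts[("step", False)],
        step_close_count=counts[("step", True)],
        well_nested=well_nested,
        closure_ordered=closure_ordered,
        tag_integrity_ok=ok,
    )


def _think_blocks(raw: str) -> list[tuple[int, int, int, int]]:
    """Well-formed top-level think blocks as (open_s, open_e, close_s, close_e)."""
    blocks = []
    stack: list[tuple[str, int, int]] = []
    for kind, closing, s, e in _tokens(raw):
        if not closing:
            stack.append((kind, s, e))
        elif stack and stack[-1][0] == kind:
            _, os_, oe = stack.pop()
            if kind == "think" and not any(k == "think" for k, _, _ in stack):
                blocks.append((os_, oe, s, e))
        elif kind in [k for k, _, _ in stack]:
            for i in range(len(stack) - 1, -1, -1):
                if stack[i][0] == kind:
                    del stack[i]
                    break
    return blocks


def extract_reasoning(raw: str) -> ReasoningTrace:
    """Step contents (document order) and think-content character length.

    Length counts the characters of the first well-formed think block's
    interior, excluding the tag tokens themselves (a tokenizer-independent
    unit).  No well-formed think block yields an empty trace.
    """
    blocks = _think_blocks(raw)
    if not blocks:
        return ReasoningTrace()
    _os, oe, cs, _ce = blocks[0]
    interior = raw[oe:cs]
    tag_chars = sum(m.end() - m.start() for m in _TAG_RE.finditer(interior))
    steps: list[str] = []
    stack: list[tuple[str, int, int]] = []
    for kind, closing, s, e in _tokens(interior):
        if not closing:
            stack.append((kind, s, e))
        elif stack and stack[-1][0] == kind:
            _, _ss, se = stack.pop()
            if kind == "step":
                steps.append(interior[se:s])
    return ReasoningTrace(steps=tuple(steps), total_length=len(interior) - tag_chars)


# --------------------------------------------------------------------------
# JSON payload
# --------------------------------------------------------------------------


def _strip_think(raw: str) -> str:
    out = raw
    for os_, _oe, _cs, ce in reversed(_think_blocks(raw)):
        out = out[:os_] + out[ce:]
    return out


def _top_level_json_objects(text: str) -> list[dict]:
    decoder = json.JSONDecoder()
    objs: list[dict] = []
    i = 0
    while True:
        j = text.find("{", i)
        if j < 0:
            break
        try:
            obj, end = decoder.raw_decode(text, j)
        except ValueError:
            i = j + 1
            continue
        if isinstance(obj, dict):
            objs.append(obj)
        i = end if end > j else j + 1
    return objs


_MISSING = object()


def _root_keys(obj: dict) -> Optional[tuple[Any, Any]]:
    ents = rels = _MISSING
    for k, v in obj.items():
        lk = str(k).strip().lower()
        if lk == "entities":
            ents = v
        elif lk == "relationships":
            rels = v
    if ents is _MISSING or rels is _MISSING:
        return None
    return ents, rels


_ENT_SURFACE_KEYS = ("text", "surface", "entity", "name")
_ENT_TYPE_KEYS = ("type", "etype", "entity_type")


def _parse_entity_entry(entry: Any) -> EntityMention:
    if isinstance(entry, dict):
        lowered = {str(k).strip().lower(): v for k, v in entry.items()}
        surface = next((lowered[k] for k in _ENT_SURFACE_KEYS if k in lowered), None)
        etype = next((lowered[k] for k in _ENT_TYPE_KEYS if k in lowered), None)
    elif isinstance(entry, (list, tuple)) and len(entry) == 2:
        surface, etype = entry
    else:
        raise SchemaError(f"malformed entity entry: {entry!r}")
    if not isinstance(surface, str) or not isinstance(etype, str):
        raise SchemaError(f"malformed entity entry: {entry!r}")
    return EntityMention(surface=surface, etype=EntityType.parse(etype))


_QUINTUPLE_KEYS = ("entity1", "type1", "relationship", "entity2", "type2")


def _parse_relation_entry(entry: Any) -> Triplet:
    if isinstance(entry, dict):
        lowered = {str(k).strip().lower(): v for k, v in entry.items()}
        if "relation" in lowered and "relationship" not in lowered:
            lowered["relationship"] = lowered["relation"]
        try:
            e1, t1, rel, e2, t2 = (lowered[k] for k in _QUINTUPLE_KEYS)
        except KeyError:
            raise SchemaError(f"malformed relationship entry: {entry!r}") from None
    elif isinstance(entry, (list, tuple)) and len(entry) == 5:
        e1, t1, rel, e2, t2 = entry
    else:
        raise SchemaError(f"malformed relationship entry: {entry!r}")
    if not all(isinstance(x, str) for x in (e1, t1, rel, e2, t2)):
        raise SchemaError(f"malformed relationship entry: {entry!r}")
    head = EntityMention(surface=e1, etype=EntityType.parse(t1))
    tail = EntityMention(surface=e2, etype=EntityType.parse(t2))
    try:
        return Triplet(head=head, relation=parse_relation(rel), tail=tail)
    except ValueError as exc:
        raise SchemaError(str(exc)) from None


def parse_prediction_json(
    raw: str,
    compat_mode: str = "lenient",
    doc_id: str = "",
) -> ParsedOutput:
    """Parse raw model text into a :class:`ParsedOutput`.

    The payload is located as the *last* balanced top-level JSON object
    outside think blocks that carries both root keys (models often echo
    demonstration payloads first; recency is the deterministic tie-break).
    ``strict`` mode treats any malformed or schema-unknown entry as fatal;
    ``lenient`` mode (the reward-side default) drops bad entries with
    diagnostics and keeps the rest.
    """
    if compat_mode not in ("strict", "lenient"):
        raise ValueError(f"compat_mode must be 'strict' or 'lenient', got {compat_mode!r}")
    tag_report = check_tag_integrity(raw)
    trace = extract_reasoning(raw)
    diagnostics: list[Diagnostic] = []

    payload = None
    for obj in _top_level_json_objects(_strip_think(raw)):
        if _root_keys(obj) is not None:
            payload = obj
    if payload is None:
        diagnostics.append(
            Diagnostic("fatal", "no JSON object with Entities and Relationships root keys")
        )
        return ParsedOutput(tag_report, trace, None, diagnostics)

    ents_raw, rels_raw = _root_keys(payload)
    if not isinstance(ents_raw, list) or not isinstance(rels_raw, list):
        diagnostics.append(Diagnostic("fatal", "Entities/Relationships must be JSON arrays"))
        return ParsedOutput(tag_report, trace, None, diagnostics)

    entities: list[EntityMention] = []
    seen: set = set()
    for entry in ents_raw:
        try:
            m = _parse_entity_entry(entry)
        except (SchemaError, ValueError) as exc:
            if compat_mode == "strict":
                diagnostics.append(Diagnostic("fatal", f"entity entry rejected: {exc}"))
                return ParsedOutput(tag_report, trace, None, diagnostics)
            diagnostics.append(Diagnostic("warning", f"entity entry dropped: {exc}"))
            continue
        if m.key not in seen:
            seen.add(m.key)
            entities.append(m)

    triplets: list[Triplet] = []
    seen_t: set = set()
    for entry in rels_raw:
        try:
            t = _parse_relation_entry(entry)
        except SchemaError as exc:
            if compat_mode == "strict":
                diagnostics.append(Diagnostic("fatal", f"relationship entry rejected: {exc}"))
                return ParsedOutput(tag_report, trace, None, diagnostics)
            diagnostics.append(Diagnostic("warning", f"relationship entry dropped: {exc}"))
            continue
        ident = (t.head.key, t.relation, t.tail.key)
        if ident in seen_t:
            continue
        seen_t.add(ident)
        triplets.append(t)
        for end in (t.head, t.tail):
            if end.key not in seen:
                seen.add(end.key)
                entities.append(end)
                diagnostics.append(
                    Diagnostic(
                        "warning",
                        f"endpoint {end.surface!r}/{end.etype.value} present only in "
                        "Relationships; added to entity list",
                    )
                )

    annotation = DocumentAnnotation(
        doc_id=doc_id, text="", sentence_bounds=[], entities=entities, triplets=triplets
    )
    return ParsedOutput(tag_report, trace, annotation, diagnostics)


def serialize_annotation(doc: DocumentAnnotation) -> str:
    """Emit the two-root-key JSON dialect (round-trips through the parser)."""
    payload = {
        "Entities": [{"text": m.surface, "type": m.etype.value} for m in doc.entities],
        "Relationships": [
            {
                "Entity1": t.head.surface,
                "Type1": t.head.etype.value,
                "Relationship": t.relation,
                "Entity2": t.tail.surface,
                "Type2": t.tail.etype.value,
            }
            for t in doc.triplets
        ],
    }
    return json.dumps(payload, indent=2, ensure_ascii=False)
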