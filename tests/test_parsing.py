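"""Tag integrity, reasoning extraction, payload parsing, serialization."""

import json
import random

import pytest

from drkex import (
    check_tag_integrity,
    extract_reasoning,
    parse_prediction_json,
    serialize_annotation,
)
from drkex.parsing import _TAG_RE

from conftest import make_doc

TAGS = ["<think>", "</think>", "<step>", "</step>"]


# ---------------------------------------------------------------------------
# independent oracle: recursive-descent parse into a tag tree
# ---------------------------------------------------------------------------


def _oracle_ok(raw: str) -> bool:
    tokens = [
        ("think" if "think" in m.group() else "step", m.group().startswith("</"))
        for m in _TAG_RE.finditer(raw)
    ]

    class Bad(Exception):
        pass

    def parse_children(i):
        children = []
        while i < len(tokens):
            kind, closing = tokens[i]
            if closing:
                return children, i
            sub, j = parse_children(i + 1)
            if j >= len(tokens) or tokens[j] != (kind, True):
                raise Bad
            children.append((kind, sub))
            i = j + 1
        return children, i

    try:
        forest, i = parse_children(0)
        if i != len(tokens):
            raise Bad
    except Bad:
        return False

    def count_kind(nodes, kind):
        return sum(
            (n[0] == kind) + count_kind(n[1], kind) for n in nodes
        )

    def step_inside_think(nodes, inside=False):
        found = False
        for kind, sub in nodes:
            if kind == "step" and inside:
                found = True
            found = found or step_inside_think(sub, inside or kind == "think")
        return found

    return count_kind(forest, "think") == 1 and step_inside_think(forest)


class TestTagIntegrity:
    def test_canonical_well_formed(self):
        rep = check_tag_integrity("<think><step>a</step><step>b</step></think>{}")
        assert rep.tag_integrity_ok
        assert rep.well_nested and rep.closure_ordered

    def test_closure_disorder(self):
        rep = check_tag_integrity("</think><step>a</step><think>")
        assert not rep.closure_ordered
        assert not rep.tag_integrity_ok

    def test_redundant_think_block(self):
        rep = check_tag_integrity("<think><step>a</step></think><think></think>")
        assert not rep.tag_integrity_ok
        assert rep.think_open_count == 2

    def test_think_without_step_fails(self):
        assert not check_tag_integrity("<think>reasoning</think>").tag_integrity_ok

    def test_interleaved_nesting_fails(self):
        rep = check_tag_integrity("<think><step>a</think></step>")
        assert not rep.well_nested
        assert not rep.tag_integrity_ok

    def test_agreement_with_bruteforce_oracle(self):
        rng = random.Random(20240917)
        disagreements = []
        for _ in range(1000):
            n = rng.randint(0, 10)
            raw = "".join(
                rng.choice(TAGS) + rng.choice(["", "x", " text "]) for _ in range(n)
            )
            if check_tag_integrity(raw).tag_integrity_ok != _oracle_ok(raw):
                disagreements.append(raw)
        assert disagreements == []

    def test_single_edit_fragility(self):
        raw = "<think><step>alpha</step><step>beta</step></think>"
        tokens = list(_TAG_RE.finditer(raw))
        assert check_tag_integrity(raw).tag_integrity_ok
        edited = []
        for m in tokens:  # deletion
            edited.append(raw[: m.start()] + raw[m.end() :])
        for m in tokens:  # duplication
            edited.append(raw[: m.end()] + m.group() + raw[m.end() :])
        # transposition of adjacent distinct-kind tokens; swapping a </step>
        # with a following <step> merely nests the steps and stays well-formed
        for a, b in zip(tokens, tokens[1:]):
            if ("think" in a.group()) != ("think" in b.group()):
                edited.append(
                    raw[: a.start()] + b.group() + raw[a.end() : b.start()]
                    + a.group() + raw[b.end() :]
                )
        assert all(not check_tag_integrity(e).tag_integrity_ok for e in edited)


class TestExtractReasoning:
    def test_single_step_length_excludes_tags(self):
        trace = extract_reasoning("<think><step>xy</step></think>")
        assert trace.steps == ("xy",)
        assert trace.total_length == 2

    def test_no_tags(self):
        trace = extract_reasoning("just text with a { } brace")
        assert trace.steps == () and trace.total_length == 0

    def test_steps_in_document_order(self):
        raw = (
            "<think><step>Task framing</step><step>Entity identification</step>"
            "<step>Relation reasoning</step></think>"
        )
        assert extract_reasoning(raw).steps == (
            "Task framing",
            "Entity identification",
            "Relation reasoning",
        )

    def test_interstep_text_counts_toward_length(self):
        trace = extract_reasoning("<think>ab<step>xy</step>cd</think>")
        assert trace.total_length == 6


class TestParsePayload:
    def _payload(self):
        return json.dumps(
            {
                "Entities": [
                    {"text": "cetuximab", "type": "drug"},
                    {"text": "colorectal cancer", "type": "disease"},
                ],
                "Relationships": [
                    {
                        "Entity1": "cetuximab",
                        "Type1": "drug",
                        "Relationship": "treat",
                        "Entity2": "colorectal cancer",
                        "Type2": "disease",
                    }
                ],
            }
        )

    def test_reference_example(self):
        parsed = parse_prediction_json(self._payload())
        assert parsed.annotation is not None
        assert len(parsed.annotation.entities) == 2
        assert len(parsed.annotation.triplets) == 1
        assert parsed.annotation.triplets[0].relation == "treat"

    def test_empty_but_well_formed(self):
        parsed = parse_prediction_json('{"Entities": [], "Relationships": []}')
        assert parsed.annotation is not None
        assert not parsed.fatal
        assert parsed.annotation.entities == []

    def test_missing_root_keys_is_fatal(self):
        parsed = parse_prediction_json('{"Entities": []}')
        assert parsed.annotation is None
        assert parsed.fatal

    def test_lenient_drops_unknown_relation(self):
        payload = json.dumps(
            {
                "Entities": [],
                "Relationships": [
                    ["cetuximab", "drug", "treat", "colorectal cancer", "disease"],
                    ["Docetaxel", "drug", "discontinued_due_to", "nausea", "symptom"],
                    ["nausea", "symptom", "is_symptom_of", "celiac disease", "disease"],
                ],
            }
        )
        parsed = parse_prediction_json(payload, "lenient")
        assert len(parsed.annotation.triplets) == 2
        assert any(d.severity == "warning" for d in parsed.diagnostics)

    def test_strict_mode_rejects_unknown_relation(self):
        payload = json.dumps(
            {
                "Entities": [],
                "Relationships": [
                    ["Docetaxel", "drug", "discontinued_due_to", "nausea", "symptom"]
                ],
            }
        )
        parsed = parse_prediction_json(payload, "strict")
        assert parsed.annotation is None and parsed.fatal

    def test_last_payload_outside_think_wins(self):
        echo = '{"Entities": [{"text": "Metformin", "type": "drug"}], "Relationships": []}'
        raw = (
            f"<think><step>echoing the demo {echo}</step></think>\n"
            f"Example: {echo}\nFinal answer:\n" + self._payload()
        )
        parsed = parse_prediction_json(raw)
        assert {m.surface for m in parsed.annotation.entities} == {
            "cetuximab",
            "colorectal cancer",
        }

    def test_entity_type_aliases_accepted(self):
        payload = json.dumps(
            {"Entities": [{"text": "colonoscopy", "type": "Clinical Examination"}],
             "Relationships": []}
        )
        parsed = parse_prediction_json(payload)
        assert parsed.annotation.entities[0].etype.value == "test"


class TestSerialization:
    def test_empty_annotation(self):
        doc = make_doc("d", "Nothing here.")
        obj = json.loads(serialize_annotation(doc))
        assert obj == {"Entities": [], "Relationships": []}

    def test_round_trip_small(self):
        doc = make_doc(
            "d", "Metformin treats type 2 diabetes.",
            triplets=[("Metformin", "drug", "treat", "type 2 diabetes", "disease")],
        )
        parsed = parse_prediction_json(serialize_annotation(doc), doc_id="d")
        assert parsed.annotation.entity_keys() == doc.entity_keys()
        assert parsed.annotation.canonical_triplet_keys() == doc.canonical_triplet_keys()

    def test_round_trip_generator_corpus(self, gold_corpus):
        for doc in gold_corpus:
            parsed = parse_prediction_json(serialize_annotation(doc), doc_id=doc.doc_id)
            assert parsed.annotation.entity_keys() == doc.entity_keys()
            assert (
                parsed.annotation.canonical_triplet_keys()
                == doc.canonical_triplet_keys()
            )
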