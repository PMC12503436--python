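import pytest

from drkex import (
    DocumentAnnotation,
    EntityMention,
    EntityType,
    GeneratorConfig,
    Triplet,
    generate_gold_corpus,
)


def mention(surface: str, etype: str, span=None) -> EntityMention:
    return EntityMention(surface=surface, etype=EntityType.parse(etype), span=span)


def make_doc(doc_id, text, entities=(), triplets=(), sentence_bounds=()):
    ents = [mention(s, t) for s, t in entities]
    by_key = {(m.surface, m.etype) for m in ents}
    trips = []
    for h, ht, rel, t, tt in triplets:
        head, tail = mention(h, ht), mention(t, tt)
        for m in (head, tail):
            if (m.surface, m.etype) not in by_key:
                ents.append(m)
                by_key.add((m.surface, m.etype))
        trips.append(Triplet(head=head, relation=rel, tail=tail))
    return DocumentAnnotation(
        doc_id=doc_id,
        text=text,
        sentence_bounds=list(sentence_bounds),
        entities=ents,
        triplets=trips,
    )


@pytest.fixture(scope="session")
def gold_corpus():
    """Forty template abstracts with a healthy cross-sentence fraction."""
    return generate_gold_corpus(
        GeneratorConfig(n_docs=40, seed=11, cross_sentence_fraction=0.2)
    )


@pytest.fixture(scope="session")
def small_corpus():
    return generate_gold_corpus(GeneratorConfig(n_docs=8, seed=5))
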