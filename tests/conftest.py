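from __future__ import annotations

import pytest

from crowdkb.extraction import CandidateTriple, Mention, Sentence, \
    SentenceAnnotation
from crowdkb.synthetic import FixtureConfig, generate_end_to_end_scenario
from crowdkb.termhood import Document


def make_annotation(n_entities: int, n_predicates: int,
                    doc_id: str = "D0", index: int = 0) -> SentenceAnnotation:
    """A synthetic sentence annotation with the requested number of
    distinct-surface entity and predicate mentions, laid out left to
    right."""
    width, gap = 8, 2
    ents, preds, parts = [], [], []
    pos = 0
    for i in range(n_entities):
        surf = f"entity{i:02d}"
        ents.append(Mention((pos, pos + width), surf, "entity",
                            float(n_entities - i)))
        parts.append(surf)
        pos += width + gap
    for i in range(n_predicates):
        surf = f"predic{i:02d}"
        preds.append(Mention((pos, pos + width), surf, "predicate",
                             float(n_predicates - i)))
        parts.append(surf)
        pos += width + gap
    text = "  ".join(parts)
    sent = Sentence(doc_id, index, text, (0, len(text)))
    return SentenceAnnotation(sent, tuple(ents), tuple(preds))


@pytest.fixture(scope="session")
def small_scenario():
    """A 12-document noisy scenario shared by read-only tests."""
    return generate_end_to_end_scenario(
        FixtureConfig(n_docs=12, rng_seed=7),
        sensitivity=0.85, specificity=0.85, n_workers_per_hit=5, min_votes=3)


@pytest.fixture
def tiny_corpus():
    return [
        Document("d1", "Obesity and cancer",
                 "Obesity is rising worldwide. Abdominal obesity increases "
                 "breast cancer risk in postmenopausal women."),
        Document("d2", "Adipokines",
                 "Serum leptin is associated with breast cancer risk. "
                 "Adiponectin reduces tumor growth."),
    ]
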