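"""Online extraction: sentence segmentation, dictionary mention tagging,
top-k mention selection, and candidate-triple enumeration.

Triples are extracted from each sentence independently.  Entity pairs are
unordered during enumeration — a sentence with *e* entities and *p*
predicates yields C(e,2)·p candidates — and subject/object orientation is
assigned by textual order (the earlier mention is the subject).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from itertools import combinations
from typing import Callable, Sequence

from ._text import normalize_term, split_sentences
from .termhood import Document, TermEntry

__all__ = [
    "Sentence",
    "Mention",
    "SentenceAnnotation",
    "CandidateTriple",
    "segment_sentences",
    "tag_mentions",
    "select_top_mentions",
    "enumerate_candidate_triples",
    "annotate_corpus",
]


@dataclass(frozen=True)
class Sentence:
    doc_id: str
    index: int
    text: str
    span: tuple[int, int]      # offsets into the abstract, half-open

    @property
    def key(self) -> str:
        return f"{self.doc_id}:{self.index}"


@dataclass(frozen=True)
class Mention:
    span: tuple[int, int]      # offsets into the sentence text, half-open
    surface: str               # normalized dictionary surface matched
    kind: str                  # entity | predicate
    score: float               # termhood score of the dictionary entry


@dataclass(frozen=True)
class SentenceAnnotation:
    sentence: Sentence
    entities: tuple[Mention, ...]
    predicates: tuple[Mention, ...]


@dataclass(frozen=True)
class CandidateTriple:
    """(subject, predicate, object) anchored to one sentence.

    The subject mention starts before the object mention; identity for
    vote counting and KB comparison is the surface triple plus the
    sentence key.
    """

    sentence_key: str
    subject: Mention
    predicate: Mention
    object: Mention

    @property
    def surfaces(self) -> tuple[str, str, str]:
        return (self.subject.surface, self.predicate.surface,
                self.object.surface)

    @property
    def key(self) -> tuple[str, str, str, str]:
        return (self.sentence_key, *self.surfaces)


Segmenter = Callable[[str], list[tuple[int, int]]]


def segment_sentences(doc: Document,
                      segmenter: Segmenter = split_sentences) -> list[Sentence]:
    """Split an abstract into :class:`Sentence` objects.

    The segmenter is pluggable; the default is abbreviation-aware
    (``e.g.``, ``i.e.``, ``et al.`` do not end sentences).  An empty
    abstract yields an empty list.
    """
    out = []
    for i, (a, b) in enumerate(segmenter(doc.abstract)):
        out.append(Sentence(doc.doc_id, i, doc.abstract[a:b], (a, b)))
    return out


# -- dictionary tagging -------------------------------------------------------

def _find_mentions(text: str, entries: Sequence[TermEntry]) -> list[Mention]:
    """Longest-match-wins, leftmost-first dictionary matching of one kind."""
    low = text.lower()
    by_surface = {e.surface: e for e in entries}
    # candidate matches at every position, longest surface first
    hits: list[tuple[int, int, TermEntry]] = []
    for surf, entry in by_surface.items():
        if not surf:
            continue
        start = 0
        while True:
            i = low.find(surf, start)
            if i < 0:
                break
            j = i + len(surf)
            if _word_bounded(low, i, j):
                hits.append((i, j, entry))
            start = i + 1
    # resolve overlaps: longer first, then leftmost, then surface
    hits.sort(key=lambda h: (-(h[1] - h[0]), h[0], h[2].surface))
    taken: list[tuple[int, int]] = []
    chosen: list[tuple[int, int, TermEntry]] = []
    for i, j, entry in hits:
        if all(j <= a or i >= b for a, b in taken):
            taken.append((i, j))
            chosen.append((i, j, entry))
    chosen.sort(key=lambda h: h[0])
    return [Mention((i, j), e.surface, e.kind, e.score) for i, j, e in chosen]


def _word_bounded(low: str, i: int, j: int) -> bool:
    if i > 0 and (low[i - 1].isalnum() or low[i - 1] == "-"):
        return False
    if j < len(low) and (low[j].isalnum() or low[j] == "-"):
        return False
    return True


def tag_mentions(sentence: Sentence,
                 entity_dict: Sequence[TermEntry],
                 predicate_dict: Sequence[TermEntry]) -> SentenceAnnotation:
    """Tag all dictionary mentions in a sentence (un-truncated).

    Mentions of the same kind never overlap (longest match wins, then
    leftmost); entity and predicate spans may intersect each other.
    """
    ents = _find_mentions(sentence.text, entity_dict)
    preds = _find_mentions(sentence.text, predicate_dict)
    return SentenceAnnotation(sentence, tuple(ents), tuple(preds))


def select_top_mentions(ann: SentenceAnnotation,
                        k_e: int = 4, k_p: int = 3) -> SentenceAnnotation:
    """Keep the ``k_e`` highest-scoring entities and ``k_p`` predicates.

    Ties are broken lexicographically on the surface, then by span start.
    Idempotent.  Surviving mentions are re-ordered by span start.
    """
    def top(mentions: tuple[Mention, ...], k: int) -> tuple[Mention, ...]:
        ranked = sorted(mentions, key=lambda m: (-m.score, m.surface, m.span[0]))
        kept = ranked[:k]
        return tuple(sorted(kept, key=lambda m: m.span[0]))

    return SentenceAnnotation(ann.sentence, top(ann.entities, k_e),
                              top(ann.predicates, k_p))


def enumerate_candidate_triples(ann: SentenceAnnotation) -> list[CandidateTriple]:
    """All (unordered entity pair) x predicate combinations of a sentence.

    Yields exactly C(e,2)·p triples before surface-level deduplication;
    repeated mentions of the same surface collapse to one option.  Listing
    order is deterministic: (subject span, object span, predicate span).
    """
    ents = sorted(ann.entities, key=lambda m: m.span)
    preds = sorted(ann.predicates, key=lambda m: m.span)
    out: list[CandidateTriple] = []
    seen: set[tuple[str, str, str]] = set()
    for e1, e2 in combinations(ents, 2):
        s, o = (e1, e2) if e1.span <= e2.span else (e2, e1)
        for p in preds:
            t = CandidateTriple(ann.sentence.key, s, p, o)
            if t.surfaces not in seen:
                seen.add(t.surfaces)
                out.append(t)
    return out


def annotate_corpus(docs: Sequence[Document],
                    entity_dict: Sequence[TermEntry],
                    predicate_dict: Sequence[TermEntry],
                    k_e: int = 4, k_p: int = 3,
                    segmenter: Segmenter = split_sentences,
                    ) -> list[SentenceAnnotation]:
    """Segment, tag and truncate every sentence of a corpus, in order."""
    anns = []
    for doc in docs:
        for sent in segment_sentences(doc, segmenter):
            ann = tag_mentions(sent, entity_dict, predicate_dict)
            anns.append(select_top_mentions(ann, k_e, k_p))
    return anns
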