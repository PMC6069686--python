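"""Offline dictionary construction: candidate-term extraction and
termhood scoring.

Candidate entity and predicate terms are harvested from a corpus of titles
and abstracts with part-of-speech patterns, then ranked by a termhood score
combining three factors:

* ``pattern_prob`` — the empirical probability of the term's POS-tag
  sequence among all candidates of its kind (linguistic evidence);
* ``idf`` — ``log10(n_docs / doc_freq)`` (corpus dispersion);
* ``cvalue`` — a multi-word termhood statistic rewarding frequent long
  terms while discounting occurrences nested inside longer candidates.

``score = pattern_prob * idf * cvalue``.  Each factor is kept on
:class:`TermStats` so alternative conventions can be swapped in.
"""

from __future__ import annotations

import math
from collections import Counter, defaultdict
from dataclasses import dataclass, field
from typing import Iterable, Literal, Sequence

from ._text import normalize_term, pos_tag, tokenize

__all__ = [
    "Document",
    "TermStats",
    "TermEntry",
    "PatternConfig",
    "ENTITY_PATTERNS",
    "PREDICATE_PATTERNS",
    "extract_candidate_terms",
    "lidf_score",
    "score_terms",
    "build_dictionaries",
]

Kind = Literal["entity", "predicate"]


@dataclass(frozen=True)
class Document:
    """A title + abstract record; ``doc_id`` is opaque (e.g. a PMID)."""

    doc_id: str
    title: str
    abstract: str

    @property
    def text(self) -> str:
        return (self.title + ". " + self.abstract) if self.title else self.abstract


@dataclass
class TermStats:
    surface: str                 # normalized
    kind: Kind
    term_freq: int
    doc_freq: int
    pattern_prob: float = 0.0
    cvalue: float = 0.0
    idf: float = 0.0
    n_tokens: int = 1
    tag_seq: tuple[str, ...] = ()


@dataclass(frozen=True, order=True)
class TermEntry:
    surface: str
    score: float
    kind: str


# -- POS patterns -------------------------------------------------------------

@dataclass(frozen=True)
class PatternConfig:
    """A family of tag-sequence patterns for one term kind.

    ``matcher`` decides whether a tag sequence constitutes a candidate term;
    ``max_len`` bounds the n-gram scan.
    """

    name: str
    max_len: int

    def matches(self, tags: Sequence[str]) -> bool:  # pragma: no cover - abstract
        raise NotImplementedError


class _NounPhrasePatterns(PatternConfig):
    """(ADJ|NOUN)* NOUN — the common multi-word-term shape."""

    def matches(self, tags: Sequence[str]) -> bool:
        return (len(tags) >= 1 and tags[-1] == "NOUN"
                and all(t in ("ADJ", "NOUN") for t in tags))


class _VerbPatterns(PatternConfig):
    """AUX? VERB (ADP|PART)? — verb-centred relational phrases."""

    def matches(self, tags: Sequence[str]) -> bool:
        seq = list(tags)
        if not seq:
            return False
        if seq[0] == "AUX":
            seq = seq[1:]
        if not seq or seq[0] != "VERB":
            return False
        seq = seq[1:]
        if seq and seq[0] in ("ADP", "PART"):
            seq = seq[1:]
        return not seq


ENTITY_PATTERNS = _NounPhrasePatterns(name="noun-phrase", max_len=5)
PREDICATE_PATTERNS = _VerbPatterns(name="verb-phrase", max_len=3)


def _iter_candidate_ngrams(tokens: list[str], tags: list[str],
                           patterns: PatternConfig):
    n = len(tokens)
    for i in range(n):
        for j in range(i + 1, min(i + patterns.max_len, n) + 1):
            sub = tags[i:j]
            if patterns.matches(sub):
                yield tokens[i:j], tuple(sub)


def extract_candidate_terms(corpus: Iterable[Document],
                            patterns: PatternConfig,
                            kind: Kind,
                            min_doc_freq: int = 1) -> list[TermStats]:
    """Scan a corpus for candidate terms of one kind.

    Returns one :class:`TermStats` per distinct normalized surface with
    exact term/document frequencies, the pattern probability estimated over
    the corpus, and C-value/IDF filled in (so :func:`lidf_score` can be
    applied directly).

    Raises ``ValueError`` on an empty/None pattern set.  An empty corpus
    yields an empty list.
    """
    if patterns is None:
        raise ValueError("pattern set must be non-empty")
    docs = list(corpus)

    term_freq: Counter[str] = Counter()
    doc_ids: dict[str, set[str]] = defaultdict(set)
    tag_seqs: dict[str, Counter[tuple[str, ...]]] = defaultdict(Counter)
    n_tokens_of: dict[str, int] = {}

    for doc in docs:
        toks = tokenize(doc.text)
        tags = pos_tag(toks)
        for words, seq in _iter_candidate_ngrams(toks, tags, patterns):
            surface = normalize_term(" ".join(words))
            if not surface:
                continue
            term_freq[surface] += 1
            doc_ids[surface].add(doc.doc_id)
            tag_seqs[surface][seq] += 1
            n_tokens_of[surface] = len(words)

    # linguistic-pattern probability: share of candidate occurrences whose
    # tag sequence equals this term's modal tag sequence
    seq_totals: Counter[tuple[str, ...]] = Counter()
    for surface, seqs in tag_seqs.items():
        for seq, c in seqs.items():
            seq_totals[seq] += c
    total_occurrences = sum(seq_totals.values())

    stats: list[TermStats] = []
    for surface, tf in sorted(term_freq.items()):
        df = len(doc_ids[surface])
        if df < min_doc_freq:
            continue
        modal_seq = tag_seqs[surface].most_common(1)[0][0]
        pprob = (seq_totals[modal_seq] / total_occurrences
                 if total_occurrences else 0.0)
        stats.append(TermStats(
            surface=surface, kind=kind, term_freq=tf, doc_freq=df,
            pattern_prob=pprob, n_tokens=n_tokens_of[surface],
            tag_seq=modal_seq,
        ))

    _fill_cvalue(stats)
    n_docs = len(docs)
    for s in stats:
        s.idf = math.log10(n_docs / s.doc_freq) if s.doc_freq else 0.0
    return stats


def _fill_cvalue(stats: list[TermStats]) -> None:
    """Nested-term C-value over the extracted candidate set.

    C-value(a) = log2(|a|+1) * f(a)                       if a is not nested
               = log2(|a|+1) * (f(a) - mean_{b⊃a} f(b))   otherwise

    where b ranges over longer extracted candidates containing ``a`` as a
    token subsequence.  The ``|a|+1`` length factor keeps unigram predicates
    scoreable (plain log2|a| zeroes every single-word term).
    """
    freq = {s.surface: s.term_freq for s in stats}
    tokens_of = {s.surface: tuple(s.surface.split()) for s in stats}
    by_len = sorted(stats, key=lambda s: -s.n_tokens)

    nesting: dict[str, list[str]] = defaultdict(list)
    for longer in by_len:
        lt = tokens_of[longer.surface]
        for shorter in stats:
            if shorter.n_tokens >= longer.n_tokens:
                continue
            if _is_subsequence(tokens_of[shorter.surface], lt):
                nesting[shorter.surface].append(longer.surface)

    for s in stats:
        length_factor = math.log2(s.n_tokens + 1)
        nesters = nesting.get(s.surface, [])
        if nesters:
            discount = sum(freq[b] for b in nesters) / len(nesters)
            s.cvalue = max(length_factor * (s.term_freq - discount), 0.0)
        else:
            s.cvalue = length_factor * s.term_freq


def _is_subsequence(short: tuple[str, ...], long: tuple[str, ...]) -> bool:
    k = len(short)
    return any(long[i:i + k] == short for i in range(len(long) - k + 1))


def lidf_score(stats: TermStats, n_docs: int) -> float:
    """Termhood score: ``pattern_prob * log10(n_docs/doc_freq) * cvalue``.

    Raises ``ValueError`` if ``doc_freq`` is 0 or exceeds ``n_docs``.
    """
    if stats.doc_freq < 1:
        raise ValueError("doc_freq must be >= 1")
    if stats.doc_freq > n_docs:
        raise ValueError("doc_freq cannot exceed n_docs")
    idf = math.log10(n_docs / stats.doc_freq)
    return stats.pattern_prob * idf * stats.cvalue


def score_terms(stats: Iterable[TermStats], n_docs: int) -> list[TermEntry]:
    """Score every term and return entries sorted by descending score,
    breaking ties lexicographically on the surface form."""
    entries = [TermEntry(s.surface, lidf_score(s, n_docs), s.kind)
               for s in stats]
    entries.sort(key=lambda e: (-e.score, e.surface))
    return entries


def build_dictionaries(scored: Iterable[TermStats], n_docs: int,
                       k_entities: int, k_predicates: int,
                       ) -> tuple[list[TermEntry], list[TermEntry]]:
    """Top-k entity and predicate dictionaries from scored term statistics.

    If fewer than ``k`` terms of a kind exist, all are returned, still in
    score order.
    """
    stats = list(scored)
    ents = score_terms((s for s in stats if s.kind == "entity"), n_docs)
    preds = score_terms((s for s in stats if s.kind == "predicate"), n_docs)
    return ents[:k_entities], preds[:k_predicates]
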