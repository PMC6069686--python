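"""Low-level text utilities: normalization, tokenization, a rule-based
part-of-speech tagger, and sentence segmentation.

The tagger is a compact closed-class-lexicon + suffix-heuristic tagger.  It
covers the coarse tag set needed by the candidate-term patterns (NOUN, ADJ,
VERB, AUX, ADP, PART, DET, CCONJ, PRON, NUM, PUNCT, OTHER); it is not a
general-purpose tagger and is tuned for the declarative register of
biomedical abstracts.
"""

from __future__ import annotations

import re
from typing import Iterable

__all__ = [
    "normalize_term",
    "tokenize",
    "tokenize_spans",
    "pos_tag",
    "split_sentences",
]

_WS_RE = re.compile(r"\s+")
_BOUNDARY_PUNCT = ".,;:!?\"'()[]{}"

_TOKEN_RE = re.compile(r"[A-Za-z0-9](?:[A-Za-z0-9'\-]*[A-Za-z0-9])?|[^\sA-Za-z0-9]")


def normalize_term(surface: str) -> str:
    """Canonical form used for dictionary keys and URI minting.

    Lowercase, collapse internal whitespace, strip punctuation at the term
    boundaries (internal hyphens/apostrophes are kept).
    """
    s = _WS_RE.sub(" ", surface.strip().lower())
    return s.strip(_BOUNDARY_PUNCT + " ")


def tokenize(text: str) -> list[str]:
    return _TOKEN_RE.findall(text)


def tokenize_spans(text: str) -> list[tuple[int, int]]:
    """Token character spans (0-based, half-open) in ``text``."""
    return [(m.start(), m.end()) for m in _TOKEN_RE.finditer(text)]


# -- rule-based POS tagging ---------------------------------------------------

_DET = {"a", "an", "the", "this", "that", "these", "those", "each", "every",
        "some", "any", "no", "both", "all", "most", "several", "many", "few",
        "such", "its", "their", "our", "his", "her"}
_ADP = {"of", "in", "on", "at", "by", "for", "with", "from", "to", "into",
        "among", "between", "within", "through", "during", "after", "before",
        "against", "via", "per", "across", "under", "over", "without",
        "towards", "toward", "upon", "as"}
_CCONJ = {"and", "or", "but", "nor", "yet", "so", "than", "while", "whereas",
          "although", "because", "if", "when", "however", "thus", "therefore"}
_PRON = {"it", "they", "we", "he", "she", "i", "you", "who", "which", "whom",
         "them", "us", "him", "there", "itself", "themselves", "one"}
_AUX = {"is", "are", "was", "were", "be", "been", "being", "am", "has",
        "have", "had", "having", "do", "does", "did", "can", "could", "may",
        "might", "must", "shall", "should", "will", "would"}
_PART = {"not", "n't", "to"}

# frequent verbs in abstract prose whose forms do not end in -s/-ed/-ing
_VERB_BASE = {
    "increase", "decrease", "reduce", "raise", "lower", "cause", "induce",
    "promote", "inhibit", "suppress", "affect", "alter", "modulate",
    "regulate", "mediate", "contribute", "lead", "result", "associate",
    "correlate", "link", "relate", "predict", "suggest", "show", "indicate",
    "demonstrate", "reveal", "find", "observe", "report", "include",
    "involve", "require", "remain", "occur", "develop", "play", "influence",
    "elevate", "impair", "enhance", "stimulate", "trigger", "drive",
    "underlie", "precede", "follow", "confer", "exhibit",
}

_ADJ_SUFFIXES = ("al", "ous", "ive", "ic", "ary", "able", "ible", "ant",
                 "ent", "less", "ful", "ish", "like", "ural", "atic")
# nouns frequently ending in -al/-ic etc. would be mistagged; small override
_NOUN_OVERRIDES = {
    "risk", "cancer", "obesity", "factor", "factors", "level", "levels",
    "cell", "cells", "tissue", "rate", "rates", "women", "men", "patients",
    "study", "studies", "trial", "trials", "evidence", "disease", "diseases",
    "insulin", "leptin", "estrogen", "glucose", "index", "mass", "body",
    "breast", "colon", "prostate", "tumor", "tumors", "growth", "diet",
    "intake", "adults", "individuals", "hormone", "hormones", "signaling",
    "inflammation", "adiposity", "survival", "mortality", "incidence",
}


def _tag_word(word: str, prev_tag: str | None) -> str:
    low = word.lower()
    if not any(c.isalnum() for c in word):
        return "PUNCT"
    if low.replace(".", "").replace(",", "").replace("-", "").isdigit():
        return "NUM"
    if low in _NOUN_OVERRIDES:
        return "NOUN"
    if low in _DET:
        return "DET"
    if low in _ADP:
        return "ADP"
    if low in _CCONJ:
        return "CCONJ"
    if low in _PRON:
        return "PRON"
    if low in _AUX:
        return "AUX"
    if low in _PART:
        return "PART"
    if low in _VERB_BASE:
        return "VERB"
    # inflected verb forms: base + s / ed / ing (with e-drop / doubling)
    for stem in _verb_stems(low):
        if stem in _VERB_BASE:
            return "VERB"
    if low.endswith(("ed", "ing")) and prev_tag == "AUX":
        return "VERB"
    if low.endswith(_ADJ_SUFFIXES):
        return "ADJ"
    return "NOUN"


def _verb_stems(low: str) -> Iterable[str]:
    if low.endswith("ies"):
        yield low[:-3] + "y"
    if low.endswith("es"):
        yield low[:-2]
    if low.endswith("s"):
        yield low[:-1]
    if low.endswith("ed"):
        yield low[:-2]
        yield low[:-1]          # e.g. "associated" -> "associate"
        if len(low) > 4 and low[-3] == low[-4]:
            yield low[:-3]      # doubled consonant
    if low.endswith("ing"):
        yield low[:-3]
        yield low[:-3] + "e"
        if len(low) > 5 and low[-4] == low[-5]:
            yield low[:-4]


def pos_tag(tokens: list[str]) -> list[str]:
    tags: list[str] = []
    prev: str | None = None
    for tok in tokens:
        t = _tag_word(tok, prev)
        tags.append(t)
        prev = t
    return tags


# -- sentence segmentation ----------------------------------------------------

_ABBREVIATIONS = {
    "e.g", "i.e", "etc", "vs", "cf", "fig", "figs", "al", "dr", "mr", "mrs",
    "ms", "prof", "no", "vol", "approx", "ca", "resp", "inc", "ltd", "st",
}

_SENT_BOUNDARY_RE = re.compile(r"[.!?]+[\"')\]]*")


def split_sentences(text: str) -> list[tuple[int, int]]:
    """Sentence character spans (0-based, half-open) in ``text``.

    A terminator ends a sentence unless it closes a known abbreviation
    (``e.g.``, ``i.e.``, ``et al.`` ...), is part of a decimal number, or is
    followed by a lowercase continuation.  Spans are trimmed of surrounding
    whitespace and cover all non-whitespace text.
    """
    spans: list[tuple[int, int]] = []
    start = 0
    for m in _SENT_BOUNDARY_RE.finditer(text):
        end = m.end()
        # decimal number like 3.14
        if (m.group().startswith(".") and m.start() > 0
                and text[m.start() - 1].isdigit()
                and end < len(text) and text[end].isdigit()):
            continue
        word = _preceding_word(text, m.start())
        if word.lower() in _ABBREVIATIONS:
            continue
        nxt = _next_nonspace(text, end)
        if nxt is not None and text[nxt].islower():
            continue
        span = _trim(text, start, end)
        if span is not None:
            spans.append(span)
        start = end
    span = _trim(text, start, len(text))
    if span is not None:
        spans.append(span)
    return spans


def _preceding_word(text: str, i: int) -> str:
    j = i
    while j > 0 and (text[j - 1].isalnum() or text[j - 1] == "."):
        j -= 1
    return text[j:i].rstrip(".")


def _next_nonspace(text: str, i: int) -> int | None:
    while i < len(text):
        if not text[i].isspace():
            return i
        i += 1
    return None


def _trim(text: str, start: int, end: int) -> tuple[int, int] | None:
    while start < end and text[start].isspace():
        start += 1
    while end > start and text[end - 1].isspace():
        end -= 1
    return (start, end) if start < end else None
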