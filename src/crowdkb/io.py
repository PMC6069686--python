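"""Readers and writers for the pipeline's on-disk formats.

Corpora: MEDLINE/PubMed XML (``PubmedArticle`` records) or a UTF-8 TSV
dialect ``pmid<TAB>title<TAB>abstract``.  Dictionaries: TSV
``surface<TAB>score<TAB>kind`` sorted descending by score.  Sentence
annotations and candidate triples: JSON Lines, one record per sentence.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Iterable, Sequence, TextIO

from lxml import etree

from .extraction import SentenceAnnotation
from .termhood import Document, TermEntry

__all__ = [
    "read_corpus_tsv",
    "write_corpus_tsv",
    "read_pubmed_xml",
    "read_dictionary",
    "write_dictionary",
    "write_annotations_jsonl",
]


def read_corpus_tsv(fh: TextIO) -> list[Document]:
    docs = []
    for lineno, line in enumerate(fh, start=1):
        line = line.rstrip("\n")
        if not line:
            continue
        parts = line.split("\t")
        if len(parts) != 3:
            raise ValueError(f"line {lineno}: expected 3 tab-separated "
                             f"fields, got {len(parts)}")
        docs.append(Document(*parts))
    return docs


def write_corpus_tsv(docs: Iterable[Document], fh: TextIO) -> None:
    for d in docs:
        fh.write(f"{d.doc_id}\t{d.title}\t{d.abstract}\n")


def read_pubmed_xml(source: str | Path | TextIO) -> list[Document]:
    """PubmedArticle records: PMID, ArticleTitle, AbstractText (multiple
    AbstractText sections are joined with a space)."""
    tree = etree.parse(source)
    docs = []
    for art in tree.iter("PubmedArticle"):
        pmid = art.findtext(".//PMID", default="")
        title = art.findtext(".//ArticleTitle", default="") or ""
        parts = ["".join(el.itertext())
                 for el in art.iter("AbstractText")]
        docs.append(Document(pmid, title, " ".join(p for p in parts if p)))
    return docs


def read_dictionary(fh: TextIO) -> list[TermEntry]:
    entries = []
    for lineno, line in enumerate(fh, start=1):
        line = line.rstrip("\n")
        if not line:
            continue
        parts = line.split("\t")
        if len(parts) != 3:
            raise ValueError(f"line {lineno}: expected surface/score/kind")
        entries.append(TermEntry(parts[0], float(parts[1]), parts[2]))
    return entries


def write_dictionary(entries: Sequence[TermEntry], fh: TextIO) -> None:
    for e in sorted(entries, key=lambda e: (-e.score, e.surface)):
        fh.write(f"{e.surface}\t{e.score:.6g}\t{e.kind}\n")


def write_annotations_jsonl(annotations: Iterable[SentenceAnnotation],
                            fh: TextIO) -> None:
    from .extraction import enumerate_candidate_triples
    for ann in annotations:
        rec = {
            "sentence_id": ann.sentence.key,
            "doc_id": ann.sentence.doc_id,
            "text": ann.sentence.text,
            "span": list(ann.sentence.span),
            "entities": [{"span": list(m.span), "surface": m.surface,
                          "score": m.score} for m in ann.entities],
            "predicates": [{"span": list(m.span), "surface": m.surface,
                            "score": m.score} for m in ann.predicates],
            "triples": [list(t.surfaces)
                        for t in enumerate_candidate_triples(ann)],
        }
        fh.write(json.dumps(rec, ensure_ascii=False) + "\n")
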