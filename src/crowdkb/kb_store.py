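"""RDF knowledge-base construction, SPARQL competency queries, and
triple-set comparison.

Assertions become plain ⟨subject, predicate, object⟩ triples in the
default graph, each resource minted deterministically from its normalized
surface form under the ``oc`` namespace with an ``rdfs:label`` carrying
the human-readable surface.  Per-assertion provenance (source sentence,
detector confidence, origin tag) lives in a named graph per origin so the
default graph stays clean for competency queries.

:func:`compare_kbs` reports the overlap between a baseline-extracted
triple set *B* and a crowd-validated set *C*: |B∩C|, |C−B| and the missed
rate 100·|C−B|/|C|.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence
from urllib.parse import quote, unquote

from rdflib import Dataset, Graph, Literal, Namespace, URIRef
from rdflib.namespace import RDFS, XSD

from ._text import normalize_term
from .relation_model import Assertion

__all__ = [
    "DEFAULT_NAMESPACE",
    "KBGraph",
    "KBComparison",
    "mint_uri",
    "uri_surface",
    "build_graph",
    "run_query",
    "compare_kbs",
]

DEFAULT_NAMESPACE = "http://purl.org/ockb/"
PROV_NS = Namespace(DEFAULT_NAMESPACE + "prov#")

UriTriple = tuple[str, str, str]


def mint_uri(surface: str, namespace: str = DEFAULT_NAMESPACE) -> URIRef:
    """Deterministic, idempotent URI for a surface form.

    The local name is the normalized surface (lowercase, collapsed
    whitespace, boundary punctuation stripped) with reserved characters
    percent-encoded; two surfaces mint the same URI iff they normalize
    identically.  Raises ``ValueError`` on an empty surface."""
    norm = normalize_term(surface)
    if not norm:
        raise ValueError("cannot mint a URI for an empty surface")
    return URIRef(namespace + quote(norm, safe=""))


def uri_surface(uri: URIRef | str, namespace: str = DEFAULT_NAMESPACE) -> str:
    """Recover the normalized surface from a minted URI."""
    s = str(uri)
    if not s.startswith(namespace):
        raise ValueError(f"URI {s!r} not under namespace {namespace!r}")
    return unquote(s[len(namespace):])


@dataclass
class KBComparison:
    n_baseline: int
    n_crowd: int
    intersection: set[UriTriple]
    crowd_only: set[UriTriple]
    missed_rate: float          # percentage, 1 decimal


class KBGraph:
    """An RDF triple collection with per-assertion provenance.

    Duplicate (subject, predicate, object) assertions collapse keeping
    the maximum confidence.  Serializes to Turtle (default graph only) or
    TriG/N-Quads (with provenance graphs)."""

    def __init__(self, namespace: str = DEFAULT_NAMESPACE,
                 prefix: str = "oc"):
        self.namespace = namespace
        self.prefix = prefix
        self.dataset = Dataset()
        self.graph: Graph = self.dataset.default_graph
        self.dataset.bind(prefix, Namespace(namespace))
        self.dataset.bind("prov", PROV_NS)
        # (s,p,o) URI strings -> (confidence, sentence_key, origin)
        self.provenance: dict[UriTriple, tuple[float, str, str]] = {}

    def add_assertion(self, assertion: Assertion,
                      origin: str = "baseline") -> None:
        s_surf, p_surf, o_surf = assertion.triple.surfaces
        s, p, o = (mint_uri(x, self.namespace) for x in (s_surf, p_surf, o_surf))
        key: UriTriple = (str(s), str(p), str(o))
        prev = self.provenance.get(key)
        if prev is not None and prev[0] >= assertion.confidence:
            return
        self.graph.add((s, p, o))
        for node, surf in ((s, s_surf), (p, p_surf), (o, o_surf)):
            self.graph.add((node, RDFS.label, Literal(normalize_term(surf))))
        self.provenance[key] = (assertion.confidence,
                                assertion.triple.sentence_key, origin)
        prov_graph = self.dataset.graph(PROV_NS[origin])
        stmt = URIRef(f"{self.namespace}assertion/"
                      f"{quote(normalize_term(s_surf), safe='')}--"
                      f"{quote(normalize_term(p_surf), safe='')}--"
                      f"{quote(normalize_term(o_surf), safe='')}")
        prov_graph.add((stmt, PROV_NS.confidence,
                        Literal(assertion.confidence, datatype=XSD.double)))
        prov_graph.add((stmt, PROV_NS.sentence,
                        Literal(assertion.triple.sentence_key)))

    @property
    def triples(self) -> set[UriTriple]:
        return {(str(s), str(p), str(o))
                for s, p, o in self.graph
                if p != RDFS.label}

    def serialize(self, format: str = "turtle") -> str:
        if format in ("turtle", "ttl", "nt", "ntriples"):
            return self.graph.serialize(format="nt" if "nt" in format
                                        else "turtle")
        return self.dataset.serialize(format=format)

    @classmethod
    def parse(cls, data: str, format: str = "turtle",
              namespace: str = DEFAULT_NAMESPACE) -> "KBGraph":
        kb = cls(namespace)
        kb.graph.parse(data=data, format=format)
        return kb


def build_graph(assertions: Iterable[Assertion],
                namespace: str = DEFAULT_NAMESPACE,
                origin: str = "baseline") -> KBGraph:
    kb = KBGraph(namespace)
    for a in assertions:
        kb.add_assertion(a, origin)
    return kb


def run_query(kb: KBGraph, query: str):
    """SPARQL 1.1 over the default graph; returns the rdflib result
    (iterable of binding rows)."""
    return kb.graph.query(query)


def compare_kbs(baseline: set[UriTriple] | KBGraph,
                crowd: set[UriTriple] | KBGraph) -> KBComparison:
    """Overlap report between baseline (B) and crowd-validated (C)
    triple sets: |B∩C| + |C−B| = |C|; missed rate = 100·|C−B|/|C|,
    rounded to one decimal (0 when C is empty)."""
    B = baseline.triples if isinstance(baseline, KBGraph) else set(baseline)
    C = crowd.triples if isinstance(crowd, KBGraph) else set(crowd)
    inter = B & C
    crowd_only = C - B
    rate = round(100.0 * len(crowd_only) / len(C), 1) if C else 0.0
    return KBComparison(len(B), len(C), inter, crowd_only, rate)
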