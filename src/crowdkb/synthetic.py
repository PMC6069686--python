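"""Seeded synthetic corpora with planted dictionaries and gold triples.

The generator emulates the shape of an obesity-and-cancer abstract
corpus: multi-sentence abstracts built from templates of the form
"X is associated with Y in Z", a vocabulary of multi-word entity terms
and verb-centred predicate phrases drawn with Zipf-like frequencies, a
configurable rate of sentences carrying a gold relation, and distractor
mentions.  Every sample is deterministic under ``rng_seed``, and the
planted vocabulary doubles as the gold entity/predicate dictionaries, so
the whole pipeline — extraction, HIT construction, simulated workers,
vote aggregation, retraining, KB build — is testable without any
external data.

Entity terms are built from disjoint modifier and head-noun pools with a
unique head per term, so no planted term is nested inside another; this
keeps the noise-free gold-recovery guarantee exact under longest-match
tagging.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np

from .crowdsourcing import HIT, WorkerResponse, TripleKey, \
    partition_into_hits, simulate_workers
from .extraction import SentenceAnnotation, annotate_corpus
from .termhood import Document, TermEntry

__all__ = [
    "FixtureConfig",
    "GoldAnnotation",
    "ScenarioBundle",
    "generate_corpus",
    "generate_end_to_end_scenario",
]

_MODIFIERS = [
    "abdominal", "visceral", "serum", "plasma", "chronic", "systemic",
    "postmenopausal", "dietary", "metabolic", "hormonal", "subcutaneous",
    "circulating", "adipose", "hepatic", "colorectal", "endometrial",
    "mammary", "epithelial", "inflammatory", "oxidative",
]
_HEADS = [
    "obesity", "adiposity", "leptin", "insulin", "adiponectin", "estrogen",
    "inflammation", "hyperinsulinemia", "dyslipidemia", "carcinogenesis",
    "tumorigenesis", "angiogenesis", "apoptosis", "proliferation",
    "glucose", "triglycerides", "cytokines", "aromatase", "igf-1",
    "resistin", "ghrelin", "cortisol", "testosterone", "progesterone",
    "mortality", "incidence", "recurrence", "survival", "metastasis",
    "hypertension", "steatosis", "resistance", "syndrome", "burden",
    "microbiome", "methylation", "autophagy", "senescence", "hypoxia",
    "fibrosis",
]
_PREDICATES = [
    "is associated with", "increases", "reduces", "causes", "promotes",
    "is linked to", "contributes to", "regulates", "inhibits", "mediates",
    "elevates", "suppresses",
]
_CONTEXTS = [
    "postmenopausal women", "obese patients", "murine models",
    "epidemiologic cohorts", "this population", "breast cancer survivors",
]


@dataclass(frozen=True)
class FixtureConfig:
    n_docs: int = 20
    sentences_per_doc: tuple[int, int] = (3, 8)
    entity_vocab_size: int = 25
    predicate_vocab_size: int = 8
    gold_triple_rate: float = 0.7
    distractor_rate: float = 0.3
    zipf_exponent: float = 1.0
    rng_seed: int = 0

    def __post_init__(self) -> None:
        for p in (self.gold_triple_rate, self.distractor_rate):
            if not 0.0 <= p <= 1.0:
                raise ValueError("rates must be probabilities in [0, 1]")
        if self.n_docs < 0 or self.entity_vocab_size < 0:
            raise ValueError("counts must be >= 0")
        if self.gold_triple_rate > 0 and (
                self.entity_vocab_size < 2 or self.predicate_vocab_size < 1):
            raise ValueError(
                "gold_triple_rate > 0 needs >= 2 entities and >= 1 predicate")


@dataclass
class GoldAnnotation:
    """Per-sentence gold triples and per-sentence gold mention spans."""

    triples: dict[str, set[TripleKey]] = field(default_factory=dict)
    mentions: dict[str, list[tuple[int, int, str, str]]] = field(
        default_factory=dict)

    @property
    def all_triples(self) -> set[TripleKey]:
        return set().union(*self.triples.values()) if self.triples else set()


def _build_vocab(cfg: FixtureConfig, rng: np.random.Generator
                 ) -> tuple[list[str], list[str]]:
    if cfg.entity_vocab_size > len(_HEADS):
        raise ValueError(f"entity_vocab_size must be <= {len(_HEADS)}")
    if cfg.predicate_vocab_size > len(_PREDICATES):
        raise ValueError(f"predicate_vocab_size must be <= {len(_PREDICATES)}")
    heads = rng.permutation(_HEADS)[:cfg.entity_vocab_size]
    entities = []
    for h in heads:
        n_mod = int(rng.integers(1, 3))
        mods = rng.choice(_MODIFIERS, size=n_mod, replace=False)
        entities.append(" ".join([*mods, h]))
    preds = [str(p) for p in
             rng.permutation(_PREDICATES)[:cfg.predicate_vocab_size]]
    return entities, preds


def _zipf_probs(n: int, s: float) -> np.ndarray:
    w = 1.0 / np.arange(1, n + 1) ** s
    return w / w.sum()


def _capitalize(s: str) -> str:
    return s[0].upper() + s[1:] if s else s


def generate_corpus(cfg: FixtureConfig) -> tuple[
        list[Document], list[TermEntry], list[TermEntry], GoldAnnotation]:
    """Sample a corpus plus its planted dictionaries and gold annotation.

    Returns ``(documents, entity_dict, predicate_dict, gold)`` where the
    dictionaries carry scores decreasing with Zipf rank (most frequent
    term scores highest), mirroring a termhood-ranked dictionary."""
    rng = np.random.default_rng(cfg.rng_seed)
    entities, predicates = _build_vocab(cfg, rng)
    e_probs = _zipf_probs(len(entities), cfg.zipf_exponent) if entities else None
    p_probs = (_zipf_probs(len(predicates), cfg.zipf_exponent)
               if predicates else None)

    docs: list[Document] = []
    gold = GoldAnnotation()
    for d in range(cfg.n_docs):
        doc_id = f"SYN{d:04d}"
        n_sent = int(rng.integers(cfg.sentences_per_doc[0],
                                  cfg.sentences_per_doc[1] + 1))
        sent_texts: list[str] = []
        sent_records = []   # (mentions, gold_triple | None) per sentence
        for _ in range(n_sent):
            if entities and rng.random() < cfg.gold_triple_rate:
                i, j = rng.choice(len(entities), size=2, replace=False,
                                  p=e_probs)
                e1, e2 = entities[i], entities[j]
                p = predicates[int(rng.choice(len(predicates), p=p_probs))]
                ctx = _CONTEXTS[int(rng.integers(len(_CONTEXTS)))]
                text = f"{_capitalize(e1)} {p} {e2} in {ctx}."
                mentions = [
                    (0, len(e1), e1, "entity"),
                    (len(e1) + 1, len(e1) + 1 + len(p), p, "predicate"),
                    (len(e1) + len(p) + 2,
                     len(e1) + len(p) + 2 + len(e2), e2, "entity"),
                ]
                if rng.random() < cfg.distractor_rate:
                    k = int(rng.choice(len(entities), p=e_probs))
                    if k not in (i, j):
                        e3 = entities[k]
                        base = text[:-1] + ", independent of "
                        mentions.append((len(base), len(base) + len(e3),
                                         e3, "entity"))
                        text = base + e3 + "."
                sent_records.append((mentions, (e1, p, e2)))
            else:
                if entities:
                    i = int(rng.choice(len(entities), p=e_probs))
                    e1 = entities[i]
                    text = (f"The role of {e1} in disease progression "
                            "remains unclear.")
                    off = len("The role of ")
                    mentions = [(off, off + len(e1), e1, "entity")]
                else:
                    text = "No terms occur in this sentence."
                    mentions = []
                sent_records.append((mentions, None))
            sent_texts.append(text)

        abstract = " ".join(sent_texts)
        docs.append(Document(doc_id, f"Synthetic abstract {doc_id}", abstract))
        for idx, (mentions, triple) in enumerate(sent_records):
            skey = f"{doc_id}:{idx}"
            gold.mentions[skey] = mentions
            if triple is not None:
                e1, p, e2 = triple
                gold.triples.setdefault(skey, set()).add(
                    (skey, e1, p, e2))

    # dictionary scores decrease with Zipf rank; ties impossible
    ent_dict = [TermEntry(surf, float(len(entities) - r), "entity")
                for r, surf in enumerate(entities)]
    pred_dict = [TermEntry(surf, float(len(predicates) - r), "predicate")
                 for r, surf in enumerate(predicates)]
    return docs, ent_dict, pred_dict, gold


@dataclass
class ScenarioBundle:
    documents: list[Document]
    entity_dict: list[TermEntry]
    predicate_dict: list[TermEntry]
    gold: GoldAnnotation
    annotations: list[SentenceAnnotation]
    hits: list[HIT]
    responses: list[WorkerResponse]
    expected_validated: set[TripleKey]


def generate_end_to_end_scenario(cfg: FixtureConfig,
                                 sensitivity: float = 0.85,
                                 specificity: float = 0.85,
                                 n_workers_per_hit: int = 5,
                                 min_votes: int = 3,
                                 per_hit: int = 25,
                                 k_e: int = 4, k_p: int = 3,
                                 ) -> ScenarioBundle:
    """Full pipeline bundle: corpus → tagged sentences → HITs → simulated
    responses → expected validated set.

    The expected validated set is recomputed here by an independent
    brute-force pass over the simulated selections (not via
    :func:`crowdkb.crowdsourcing.aggregate_votes`), so it can serve as an
    oracle for the aggregation path."""
    docs, ent_dict, pred_dict, gold = generate_corpus(cfg)
    anns = annotate_corpus(docs, ent_dict, pred_dict, k_e=k_e, k_p=k_p)
    hits = partition_into_hits(anns, per_hit=per_hit,
                               assignments_per_hit=n_workers_per_hit)
    responses = simulate_workers(
        hits, gold.triples, sensitivity=sensitivity, specificity=specificity,
        n_workers_per_hit=n_workers_per_hit, rng_seed=cfg.rng_seed + 1)

    # brute-force recount, independent of aggregate_votes
    votes: dict[TripleKey, set[str]] = {}
    hit_by_id = {h.hit_id: h for h in hits}
    for resp in responses:
        hit = hit_by_id[resp.hit_id]
        for qi, chosen in resp.selections.items():
            for oi in chosen:
                key = hit.questions[qi].options[oi].key
                votes.setdefault(key, set()).add(resp.worker_id)
    expected = {k for k, voters in votes.items() if len(voters) >= min_votes}

    return ScenarioBundle(docs, ent_dict, pred_dict, gold, anns, hits,
                          responses, expected)
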