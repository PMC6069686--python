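"""Build termhood-ranked entity and predicate dictionaries.

Generates a small synthetic abstract corpus, harvests candidate terms
with part-of-speech patterns, scores them (pattern probability x IDF x
C-value) and prints the top of each dictionary.  Higher scores mark terms
that are frequent, multi-word, and concentrated in few documents — the
terms worth tagging downstream.
"""

from crowdkb.synthetic import FixtureConfig, generate_corpus
from crowdkb.termhood import (ENTITY_PATTERNS, PREDICATE_PATTERNS,
                              build_dictionaries, extract_candidate_terms)

docs, _, _, _ = generate_corpus(FixtureConfig(n_docs=30, rng_seed=0))
print(f"corpus: {len(docs)} documents")

stats = (extract_candidate_terms(docs, ENTITY_PATTERNS, "entity")
         + extract_candidate_terms(docs, PREDICATE_PATTERNS, "predicate"))
entities, predicates = build_dictionaries(stats, len(docs),
                                          k_entities=15, k_predicates=8)

print(f"\ntop entities ({len(entities)} kept):")
for e in entities[:8]:
    print(f"  {e.score:8.3f}  {e.surface}")
print(f"\ntop predicates ({len(predicates)} kept):")
for p in predicates[:5]:
    print(f"  {p.score:8.3f}  {p.surface}")
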