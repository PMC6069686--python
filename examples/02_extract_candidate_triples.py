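"""Extract candidate triples from tagged sentences.

Each sentence is tagged against the dictionaries (longest match wins),
truncated to the top 4 entities and top 3 predicates by termhood score,
and every (entity pair) x predicate combination becomes a candidate
triple — at most C(4,2) x 3 = 18 per sentence.  The subject is the
entity that appears first in the text.
"""

from crowdkb.extraction import annotate_corpus, enumerate_candidate_triples
from crowdkb.synthetic import FixtureConfig, generate_corpus

docs, ent_dict, pred_dict, gold = generate_corpus(
    FixtureConfig(n_docs=10, rng_seed=1))
anns = annotate_corpus(docs, ent_dict, pred_dict, k_e=4, k_p=3)

n_triples = 0
example = None
for ann in anns:
    triples = enumerate_candidate_triples(ann)
    n_triples += len(triples)
    if example is None and len(triples) >= 3:
        example = (ann, triples)

print(f"{len(anns)} sentences -> {n_triples} candidate triples")
ann, triples = example
print(f"\nsentence: {ann.sentence.text}")
print(f"entities: {[m.surface for m in ann.entities]}")
print(f"predicates: {[m.surface for m in ann.predicates]}")
print("first candidates (subject — predicate — object):")
for t in triples[:4]:
    s, p, o = t.surfaces
    print(f"  {s} — {p} — {o}")
print(f"\ngold triples planted in this sentence: "
      f"{len(gold.triples.get(ann.sentence.key, set()))}")
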