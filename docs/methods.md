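# Methods

This note documents the models, conventions and design choices behind
`crowdkb`, module by module, including what the synthetic-data generator
does and does not emulate.

## Termhood scoring (offline dictionaries)

Candidate terms are n-grams whose part-of-speech sequence matches a
pattern family: `(ADJ|NOUN)* NOUN` for entities (max 5 tokens) and
`AUX? VERB (ADP|PART)?` for predicates (max 3 tokens). Tagging uses a
compact rule-based tagger (closed-class lexicons for determiners,
adpositions, auxiliaries, pronouns and conjunctions; a base-verb
lexicon with inflection stemming; adjective suffix heuristics; noun as
default, with a small override list for domain nouns ending in
adjective-like suffixes). It targets the declarative register of
biomedical abstracts and is deliberately small; it is pluggable in the
sense that `extract_candidate_terms` accepts any `PatternConfig`.

The termhood score is the product of three exposed factors:

* **pattern probability** — the share of all candidate occurrences (of
  that kind) carrying the term's modal tag sequence. Common shapes
  (NOUN NOUN, ADJ NOUN) score high; rare shapes are discounted.
* **IDF** — `log10(N/df)`, base 10. A term appearing in every document
  scores zero; this is intentional (such terms are corpus stopwords for
  dictionary purposes).
* **C-value** — `log2(|a|+1) · (f(a) − mean_{b⊃a} f(b))`, clipped at 0,
  where `b` ranges over longer extracted candidates containing `a` as a
  token subsequence and `f` counts all occurrences (nested included).
  The `|a|+1` length factor departs from the plain `log2|a|` convention
  so that single-token terms — most predicates — remain scoreable;
  with `log2|a|` every unigram would score exactly zero.

Normalization is lowercase + whitespace collapse + boundary-punctuation
strip, applied identically at dictionary build time, at tagging time and
at URI minting time, so the three layers agree by construction. There is
no document-frequency floor by default (`min_doc_freq=1`, configurable).

Ties in dictionary order are broken lexicographically on the surface
form, making dictionaries byte-reproducible.

## Extraction

Sentence segmentation is regex-based with an abbreviation list (`e.g.`,
`i.e.`, `et al.`, `Fig.` …), decimal-number protection and a
lowercase-continuation heuristic; the segmenter is a plain
`text -> spans` callable and can be swapped. Mention tagging is
dictionary matching with longest-match-wins per kind, leftmost on ties;
entity and predicate spans may cross kinds but never overlap within a
kind. Matches must be word-bounded (no match inside a hyphenated token).

Top-k truncation keeps the `k_e = 4` / `k_p = 3` highest-scoring
mentions (ties: lexicographic surface, then span start) and is
idempotent. Enumeration emits one candidate per unordered entity pair ×
predicate — the `C(e,2)·p` count is forced by the worked sentence
configurations (16 entities × 7 predicates → 840; 4 × 3 → 18) — with
subject/object fixed by text order. Duplicate surface triples within a
sentence collapse to one option, matching how the crowd sees them as
multiple-choice options.

## Relation model

The feature schema is fixed and versioned (26 dimensions): termhood
scores and token/character lengths of the three mentions (statistical);
subject–object token distance, between-token count, predicate position
flags, subject position fraction, sentence length and an 8-bucket
hashed bag-of-words of the tokens between the entities, hashed with
CRC-32 for cross-process stability (lexical); a multiword-predicate
flag and the predicate's best relation-class lexicon match — class
index and Jaccard token overlap (semantic).

The detector is a random forest (default 500 trees, `sqrt` features per
split, balanced class weights, seeded; tests and examples use smaller
forests purely for speed). Training reports seeded stratified 5-fold
cross-validation metrics; support-weighted precision/recall/F is the
headline number because the crowd-feedback datasets are heavily
imbalanced. The confidence threshold λ (default 0.94) gates which
candidates become assertions; acceptance is monotone in λ by
construction.

The relation-class inventory holds 12 named classes plus a mandatory
`other`. Only a few class labels are externally evidenced
("associated with", "is a", "inversely associated with"); the remaining
defaults are drawn from common relation-ontology vocabulary and are
fully configurable. Classification is either 1-nearest-lexicon (token
overlap, exact match short-circuits, zero overlap → `other`) or a
trained multi-class forest over the same schema.

Retraining uses crowd-validated triples as positives and
never-selected triples as negatives, either all of them (imbalanced;
the forest's balanced class weights compensate) or a seeded
without-replacement sample of `n_balance` negatives. The two historical
positive-count conventions (343 vs 347 for the original annotated
corpus) are both representable since counts are plain inputs here; the
package takes whatever sets it is given and never reconciles them.

## Crowdsourcing

HIT batching is an order-preserving partition, `ceil(n/25)` HITs with
only the last under-full; zero-option questions stay in the HIT (so
question indices are stable) but are omitted from the rendered batch
CSV. Option text is the `entity1 — relation — entity2` template and
round-trips through the results-CSV ingester, which rejects malformed
rows with row-level diagnostics while keeping valid ones.

Vote aggregation counts **distinct** workers (repeated submissions by
one worker count once) among assignments meeting the `min_time` filter;
`validated` means ≥ `min_votes`, with an exact-equality mode for
reproducing "= 5 times" table rows. Both the assignment-level threshold
and a derived per-sentence threshold (time/25) are expressible by
scaling `min_time`. Worker scoring treats each sentence as set
retrieval: F1 of selected vs gold options, averaged over qualifying
responses per sentence, then over sentences.

The cost model prices an assignment at `reward × (1 + 0.20)`, with a
further 20% surcharge when a HIT has ≥ 10 assignments. This single
schedule reproduces the three published study totals ($84.00 estimated
and $40.53 actual for a 400-assignment pilot at $0.15; $81.00 for 27
HITs × 5 at $0.50).

Simulated workers select each gold option with probability
`sensitivity` and each non-gold option with probability
`1 − specificity`, independently; assignment time is lognormal (median
600 s, σ = 0.5 on the log scale, a plausible spread for a 25-sentence
task). All randomness flows through one `numpy` generator per call,
seeded explicitly.

## KB store

URIs are `namespace + percent-encoded normalized surface`; minting is
idempotent and collision-free across distinct normalized surfaces, and
decoding recovers the surface. Assertions deduplicate on the URI triple
keeping the maximum confidence. Human-readable `rdfs:label`s accompany
every resource. Provenance (confidence, source sentence, origin tag)
lives in a named graph per origin inside an `rdflib.Dataset`, keeping
the default graph clean for competency queries; Turtle serialization
covers the default graph, TriG/N-Quads include provenance.
`compare_kbs` is exact set arithmetic with the missed rate rounded to
one decimal for reporting.

## Synthetic fixtures

The generator emulates: multi-sentence abstracts whose sentences embed
planted multi-word entity terms and verb-centred predicates in
templated frames ("X is associated with Y in Z", plus filler and
distractor variants), Zipf-distributed term usage, a configurable rate
of gold-relation sentences, and per-sentence gold triples consistent
with the text-order subject convention. Entity terms use disjoint
modifier/head pools with a unique head per term, so no planted term
nests inside another and longest-match tagging recovers gold mentions
exactly on noise-free configs.

It does **not** emulate: real syntactic variety (passives, relative
clauses, coordination), coreference, cross-sentence relations,
ambiguous or overlapping terminology, or annotator disagreement beyond
the independent-Bernoulli worker model. Passing tests therefore
demonstrate the correctness of the pipeline's mechanics and the
statistical behaviour of aggregation/retraining under controlled noise
— not extraction quality on real PubMed text.

## Problem sizes and numerical choices

Tests and the acceptance script run at deliberately small scale chosen
to keep the full suite fast while leaving the measured properties
clearly resolved: 10–25-document corpora, 100–200-tree forests,
1000-candidate parameter-recovery runs, 100-seed Monte-Carlo for the
wisdom-of-crowd comparison, and a 10-seed sign test for the retraining
gain. Reported currency values are rounded to cents; missed rates to
one decimal; metric ties in dictionaries and mention ranking are broken
deterministically as described above. Degenerate inputs (empty corpus,
empty abstract, zero-option questions, empty graphs) return empty
results rather than erroring, except where a contract is violated
(single-class training data, empty validated set, empty surface for URI
minting), which raises `ValueError`.

## Known limitations

* The rule-based tagger is adequate for abstracts and the synthetic
  register but will mistag open-domain text; swap in a trained tagger
  via `PatternConfig` if needed.
* Pattern probability is estimated from the corpus itself, so very
  small corpora give coarse probabilities.
* The feature schema omits syntactic-path features (no parser in the
  stack); the semantic family is lexicon-driven.
* SPARQL support is whatever `rdflib` provides (full 1.1 SELECT);
  provenance is not exposed to queries over the default graph by
  design.
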