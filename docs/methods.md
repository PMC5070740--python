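# Methods

## Model

The engine treats entity retrieval as aggregation over an inverted index of
*paired postings*: each indexed document contributes the pair
`<doc_id, [entity concept ids]>`, and every token of the document keys that
posting. A query retrieves candidate documents through ordinary Boolean
evaluation over the term index; each candidate with a non-empty entity list
is scored

    S_d(q) = T_d(q)^a · N_d^b · Q_d^c · R_d^p

and each entity accumulates S_e(q) = Σ_{d∈D_e(q)} S_d(q), the plain sum
over the documents containing both the query and the entity (no
normalization by |D_e| and no per-entity cap). Entities are returned in
descending S_e; ties break by more contributing documents, then by
concept id, so rankings are fully deterministic.

### Score components

- **Term match** T_d(q) = coord(q,d) × tfidf(q,d). `coord` is the number
  of distinct positive query elements the document matches divided by the
  total number of positive elements |q|; a quoted phrase counts as one
  element and boosts do not affect coord. `tfidf` sums, over matched
  elements t, `boost(t) · sqrt(tf(t,d)) · idf(t)²` with
  `idf(t) = 1 + ln(N/(df(t)+1))` — the classic Lucene practical scoring
  dialect. Query-norm and length-norm are deliberately omitted: they scale
  all candidates of a given query by a common factor (so rankings are
  unchanged) and their omission keeps scores exactly reproducible and easy
  to verify by hand.
- **Entity-count penalty** N_d = 1/min(|E_d|, 10) ∈ [0.1, 1]. A document
  mentioning one entity is strong evidence about that entity; a document
  mentioning dozens dilutes its contribution. Documents with no entities
  are never scored.
- **Journal reputation** Q_d = 1 + IF_d/max(IF)·9 ∈ [1, 10], linear in the
  impact factor relative to the corpus maximum; 1 when the journal has no
  impact factor (or IF = 0).
- **Recency** R_d = (1/2)^(min(M−m_d, 96)/24) ∈ [0.0625, 1]: halves every
  24 months and floors at ages past 96 months. M is the reference month in
  absolute months (year·12 + month). Future-dated documents clamp to age
  0. Documents with no date are kept but placed at the floor and flagged
  in the log — dropping them silently would bias D_e.

### Tunable parameters

| parameter | default | meaning |
|---|---|---|
| `power_term`, `power_entity_count`, `power_reputation`, `power_recency` | 1.0 | exponent of each component; 0 removes it (x^0 = 1), larger values weight it more |
| `reference_month` | corpus's newest publication month | "now" for the recency decay; settable via `--as-of YYYY-MM` for reproducible historical queries |
| `k` | 10 | number of entities returned |

Defaulting the reference month to the newest indexed document (rather than
the wall clock) makes offline scoring reproducible: the same index and
query always yield the same scores.

## Dictionary construction

Source records `(source, surface, type, xrefs)` are merged by union-find:
records sharing any cross-reference ID are synonyms (transitive closure),
and records with identical case-folded surfaces in the same entity group
also merge. Types live in priority-ordered groups — gene_group (gene/
protein, target, transcription factor, miRNA) > chem_group (chemical
compound, drug, toxin) > disease_group > pathway_group — and a concept may
hold several types within one group only; cross-group conflicts are
resolved by keeping the highest-priority group's types. Concept ids are
assigned by sorting merged concepts by group priority and name set, so
builds are deterministic regardless of record order.

Open design points resolved here (the source behaviour is unspecified):

- **Ambiguous surfaces** mapping to more than one concept resolve at build
  time to the highest-priority group, then the smallest concept id.
- **Curation** is replaced by a stop-surface exclusion list (a plain text
  file, one surface per line) applied after merging.

## Mention extraction

Gazetteer matching runs over the word-token stream: a token is a maximal
alphanumeric run with internal hyphens allowed (`BCR-ABL` is one token),
so matches always start and end at word boundaries and `HER` can never
fire inside `OTHER`. At each position the longest dictionary match wins
and matching resumes after it (leftmost-longest, non-overlapping).
Matching is case-insensitive, except dictionary names that are entirely
uppercase and at most 4 characters (gene-symbol style: `TP53`, `CML`)
match case-sensitively, because such symbols collide with ordinary words.

Mutation mentions are a deliberately simple pattern layer, not a
reimplementation of a CRF tagger: protein point mutations
`[A-Z][0-9]+[A-Z]` and coding changes `c.[0-9]+[ACGT]>[ACGT]`, both
requiring word-boundary context. Each normalized (uppercased) surface
becomes its own mutation_group concept. Dictionary and mutation mentions
are merged with the same leftmost-longest rule.

## Query semantics

Stop words (the classic 33-word English list) are removed from bare term
leaves at parse time; the index keeps them, so phrases containing stop
words still match. Bare adjacent terms are OR-combined for retrieval —
this is what makes coord meaningful, since it ranges down to 1/|q| for
documents matching a single element — while explicit `AND` intersects.
`NOT` subtracts from retrieval and never contributes to scoring; a
document retrieved only through negation (possible under explicit `OR`)
matches no positive element, has no defined term score, and is skipped.
An unquoted multi-word name is treated as a bag of terms, not a phrase;
quoting opts into exact-sequence matching.

## Synthetic fixtures

The generator emulates the statistical shape the engine cares about —
short token streams, planted entity mentions at a Poisson rate, impact
factors uniform on [0, 50] with a 10% IF-less fraction, publication dates
uniform over 2008–2015 — while making ground truth exact: filler tokens
and entity-surface tokens are disjoint pools and each entity token belongs
to exactly one surface, so no planted surface is a substring of another
and strict-span precision = recall = 1 is the *correct* outcome for the
matcher, not an optimistic one. What the fixtures do **not** emulate:
natural-language context, ambiguous or nested names, abbreviations,
species variation, and realistic token frequency distributions — so
passing tests certify the mechanics (matching, indexing, scoring,
aggregation), not extraction quality on real abstracts.

A separate cohort generator isolates the recency component: two
equal-sized cohorts with byte-identical term statistics, one older than
the 96-month cap carrying concept A, one a few months old carrying concept
B. With recency power 0 the two concepts tie to within 1e-9; with power p
their score ratio equals (R_new/R_old)^p in closed form; power 4 strictly
promotes the recent cohort's concept.

All randomness flows from a single `numpy` generator seeded by the spec;
identical specs produce byte-identical fixtures.

## Numerical and scale choices

- Scores are plain double-precision products and sums; no log-space is
  needed at these magnitudes (components are bounded within [0.0625, 10]
  apart from tfidf, which is modest for desk-scale corpora).
- Phrase document frequency is not stored; it is recomputed by scanning
  candidate token streams at query time. Fine for the corpus sizes this
  implementation targets (10²–10⁵ abstracts); a production index would
  store positional postings.
- Oracle-equivalence tests compare engine scores to an independently coded
  brute-force re-derivation at 1e-9 absolute tolerance on corpora up to
  200 documents; test corpora use 15–200 documents to keep the whole suite
  around a minute.
- Index rebuild is the only update path besides batch addition; deletion
  is out of scope.

## Known limitations

- Dictionary matching cannot resolve genuinely ambiguous surfaces by
  context; the build-time priority rule is deterministic but blunt.
- The mutation patterns accept plausible false positives (e.g. other
  letter–digit–letter identifiers) and miss most HGVS syntax.
- No proximity search, stemming, abbreviation resolution, or species
  disambiguation.
- Impact factors are taken as given per document; no year-matched IF
  tables.
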