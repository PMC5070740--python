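"""Entity scoring and ranking.

Each candidate document d earns a score for query q as the product of four
components,

    S_d(q) = T_d(q)^a · N_d^b · Q_d^c · R_d^p

and each entity e is scored by summing over the documents that contain both
the query and the entity:  S_e(q) = Σ_{d ∈ D_e(q)} S_d(q).

Components (defaults a = b = c = p = 1 reproduce the plain product):

T_d(q) = coord(q,d) × tfidf(q,d)
    coord is the fraction of query elements the document matches, in
    (0, 1]; tfidf sums, over matched elements t,
    boost(t) · sqrt(tf(t,d)) · idf(t)^2 with idf(t) = 1 + ln(N/(df(t)+1))
    — the classic Lucene practical scoring dialect, without query/length
    normalization so scores are exactly reproducible.
N_d = 1 / min(|E_d|, 10)
    penalty for entity-crowded documents, in [1/10, 1].
Q_d = 1 + IF_d/max(IF) × 9
    journal reputation from the impact factor, in [1, 10]; 1 when the
    journal has no impact factor.
R_d = (1/2)^(min(M − m_d, 96)/24)
    recency: halves every 24 months, floored at 0.0625 past 96 months.
    M is the reference ("as of") month; documents without a date sit at
    the floor.

Raising a component's power weights it more; a power of zero removes the
component entirely.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

from .dictionary import EntityConcept
from .index import CorpusStats, DocumentRecord, InvertedIndex, Posting
from .query import Node, Phrase, QueryAST, Term, match_documents

#: recency floor: ages are capped at this many months
RECENCY_CAP_MONTHS = 96
#: months for the recency score to halve
RECENCY_HALF_LIFE_MONTHS = 24
#: entity-count penalty saturates at this many entities
ENTITY_COUNT_CAP = 10


class RankingError(ValueError):
    pass


@dataclass(frozen=True)
class ScoreWeights:
    """Exponents of the four score components plus the reference month.

    ``reference_month`` is absolute months (year*12 + month); None means
    "use the corpus's latest publication month".
    """

    power_term: float = 1.0
    power_entity_count: float = 1.0
    power_reputation: float = 1.0
    power_recency: float = 1.0
    reference_month: int | None = None

    def __post_init__(self) -> None:
        for name in ("power_term", "power_entity_count",
                     "power_reputation", "power_recency"):
            if getattr(self, name) < 0:
                raise RankingError(f"{name} must be >= 0")


@dataclass(frozen=True)
class DocScore:
    """Per-document component breakdown (the --explain payload)."""

    doc_id: str
    term_match: float
    entity_count: float
    reputation: float
    recency: float
    total: float


@dataclass(frozen=True)
class ScoredEntity:
    concept_id: str
    concept: EntityConcept
    score: float
    contributing: tuple[DocScore, ...]

    @property
    def n_docs(self) -> int:
        return len(self.contributing)


# -- components -------------------------------------------------------------


def idf(term_df: int, n_docs: int) -> float:
    return 1.0 + math.log(n_docs / (term_df + 1))


def term_match_score(
    ast: QueryAST, doc_id: str, index: InvertedIndex
) -> float:
    """T_d(q) = coord × tfidf over the document's matched query elements."""
    matched: list[tuple[Node, int, int]] = []  # (leaf, tf, df)
    for leaf in ast.positive_leaves:
        if isinstance(leaf, Term):
            tf = index.tf(leaf.text, doc_id)
            if tf > 0:
                matched.append((leaf, tf, index.df(leaf.text)))
        else:
            tf = index.phrase_tf(leaf.tokens, doc_id)
            if tf > 0:
                matched.append((leaf, tf, len(index.phrase_docs(leaf.tokens))))
    if not matched:
        raise RankingError(
            f"document {doc_id} matches no positive query element"
        )
    coord = len(matched) / ast.n_elements
    n = index.n_docs
    tfidf = sum(
        leaf.boost * math.sqrt(tf) * idf(df, n) ** 2
        for leaf, tf, df in matched
    )
    return coord * tfidf


def entity_number_score(posting: Posting) -> float:
    """N_d = 1/min(|E_d|, 10); undefined for entity-free documents."""
    n = len(posting.entity_ids)
    if n < 1:
        raise RankingError(
            f"document {posting.doc_id} has no entities; it cannot "
            "contribute to entity scores"
        )
    return 1.0 / min(n, ENTITY_COUNT_CAP)


def reputation_score(doc: DocumentRecord, stats: CorpusStats) -> float:
    """Q_d = 1 + IF_d/max(IF) × 9; 1 for journals without an impact factor."""
    if doc.impact_factor is None or doc.impact_factor == 0:
        return 1.0
    if stats.max_if <= 0:
        raise RankingError(
            "corpus max impact factor is 0 but document "
            f"{doc.doc_id} has impact factor {doc.impact_factor}"
        )
    return 1.0 + (doc.impact_factor / stats.max_if) * 9.0


def recency_score(doc: DocumentRecord, reference_month: int) -> float:
    """R_d = (1/2)^(min(age, 96)/24), age in months; dateless documents
    sit at the 0.0625 floor."""
    if doc.month_index is None:
        age = RECENCY_CAP_MONTHS
    else:
        age = max(reference_month - doc.month_index, 0)
    age = min(age, RECENCY_CAP_MONTHS)
    return 0.5 ** (age / RECENCY_HALF_LIFE_MONTHS)


def document_score(
    ast: QueryAST,
    doc_id: str,
    index: InvertedIndex,
    stats: CorpusStats,
    weights: ScoreWeights,
    reference_month: int,
) -> DocScore:
    """S_d(q) as the weighted product of the four components."""
    doc = index.documents[doc_id]
    t = term_match_score(ast, doc_id, index)
    n = entity_number_score(index.postings[doc_id])
    q = reputation_score(doc, stats)
    r = recency_score(doc, reference_month)
    total = (
        t ** weights.power_term
        * n ** weights.power_entity_count
        * q ** weights.power_reputation
        * r ** weights.power_recency
    )
    return DocScore(doc_id, t, n, q, r, total)


def _matches_any_positive(
    ast: QueryAST, doc_id: str, index: InvertedIndex
) -> bool:
    for leaf in ast.positive_leaves:
        if isinstance(leaf, Term):
            if index.tf(leaf.text, doc_id) > 0:
                return True
        elif index.phrase_tf(leaf.tokens, doc_id) > 0:
            return True
    return False


# -- aggregation ------------------------------------------------------------


def search_entities(
    index: InvertedIndex,
    ast: QueryAST,
    weights: ScoreWeights = ScoreWeights(),
    k: int = 10,
) -> list[ScoredEntity]:
    """Ranked entities for a parsed query.

    Retrieval: Boolean/year evaluation over the index; documents with empty
    entity lists are dropped.  Each surviving document's S_d(q) is added to
    every entity in its posting; entities are filtered by the query's type
    filter (an entity passes if any of its types matches), ranked by
    descending S_e, ties broken by more contributing documents then by
    concept_id.
    """
    if k <= 0:
        raise RankingError("k must be positive")
    reference_month = weights.reference_month
    if reference_month is None:
        reference_month = index.max_month_index() or 0
    stats = index.corpus_stats()

    candidates = match_documents(ast, index)
    per_entity: dict[str, list[DocScore]] = {}
    for doc_id in sorted(candidates):
        posting = index.postings[doc_id]
        if not posting.entity_ids:
            continue
        if not _matches_any_positive(ast, doc_id, index):
            continue  # T_d undefined: retrieved via negation only
        ds = document_score(ast, doc_id, index, stats, weights, reference_month)
        for eid in posting.entity_ids:
            per_entity.setdefault(eid, []).append(ds)

    results = []
    for eid, docs in per_entity.items():
        concept = index.entity_meta[eid]
        if ast.type_filter is not None and ast.type_filter not in concept.types:
            continue
        results.append(ScoredEntity(
            concept_id=eid,
            concept=concept,
            score=sum(d.total for d in docs),
            contributing=tuple(sorted(docs, key=lambda d: (-d.total, d.doc_id))),
        ))
    results.sort(key=lambda e: (-e.score, -e.n_docs, e.concept_id))
    return results[:k]
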