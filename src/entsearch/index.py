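"""Paired-posting inverted index.

Every indexed document contributes one *posting*: the pair
``<doc_id, [entity concept ids found in the document]>``.  Every token of
the document becomes (or extends) a term key pointing at that posting, so a
term lookup returns documents together with their entity lists — the data
the entity ranker aggregates.  Corpus statistics (N, document frequencies,
in-document term counts, maximum journal impact factor) are maintained
incrementally and are identical to a from-scratch rebuild.

Documents are added in batches; deletion is unsupported (rebuild instead).
"""

from __future__ import annotations

import json
import logging
from collections import Counter
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

from ._text import tokenize
from .dictionary import Dictionary, EntityConcept, extract_all, mutation_concept

logger = logging.getLogger(__name__)


class IndexError_(ValueError):
    """Raised on invalid documents or index misuse."""


@dataclass(frozen=True)
class DocumentRecord:
    """An abstract-like document, the unit of indexing.

    ``impact_factor`` is the journal impact factor (None when the journal
    has none); ``pub_year``/``pub_month`` give the publication date (None
    when unknown; such documents are flagged and treated as maximally old
    by the recency score).
    """

    doc_id: str
    text: str
    journal: str = ""
    impact_factor: float | None = None
    pub_year: int | None = None
    pub_month: int | None = None

    def __post_init__(self) -> None:
        if not self.doc_id:
            raise IndexError_("doc_id must be non-empty")
        if self.impact_factor is not None and self.impact_factor < 0:
            raise IndexError_(f"{self.doc_id}: negative impact factor")
        if self.pub_month is not None and not 1 <= self.pub_month <= 12:
            raise IndexError_(f"{self.doc_id}: pub_month out of range")

    @property
    def month_index(self) -> int | None:
        """Publication time in absolute months (year*12 + month).

        A year without a month is taken as January of that year.
        """
        if self.pub_year is None:
            return None
        return self.pub_year * 12 + (self.pub_month or 1)


@dataclass(frozen=True)
class Posting:
    """The index value unit: a document and its entity list."""

    doc_id: str
    entity_ids: tuple[str, ...]

    def __post_init__(self) -> None:
        if len(set(self.entity_ids)) != len(self.entity_ids):
            raise IndexError_(f"{self.doc_id}: duplicate entity ids in posting")


@dataclass
class CorpusStats:
    """Aggregates needed by the scorer: N, df, tf, max impact factor."""

    n_docs: int
    df: dict[str, int]
    term_freq: dict[tuple[str, str], int]
    max_if: float


class InvertedIndex:
    """In-memory paired-posting index with incremental batch addition."""

    def __init__(self, dictionary: Dictionary):
        self.dictionary = dictionary
        self.documents: dict[str, DocumentRecord] = {}
        self.postings: dict[str, Posting] = {}
        self.term_docs: dict[str, set[str]] = {}
        self.doc_tokens: dict[str, list[str]] = {}
        self.doc_tf: dict[str, Counter] = {}
        # concepts referenced by postings, incl. pattern-derived mutations
        self.entity_meta: dict[str, EntityConcept] = {}
        self.max_if: float = 0.0

    # -- construction ------------------------------------------------------

    def add_documents(self, docs: Sequence[DocumentRecord]) -> "InvertedIndex":
        """Index a batch of documents; rejects the whole batch on any
        duplicate doc_id, leaving the index unchanged."""
        docs = list(docs)
        seen = set()
        for d in docs:
            if d.doc_id in self.documents or d.doc_id in seen:
                raise IndexError_(f"duplicate doc_id {d.doc_id!r}; batch rejected")
            seen.add(d.doc_id)
        for d in docs:
            self._add_one(d)
        return self

    def _add_one(self, doc: DocumentRecord) -> None:
        if doc.month_index is None:
            logger.warning(
                "document %s has no publication date; treated as oldest",
                doc.doc_id,
            )
        mentions = extract_all(doc.text, self.dictionary)
        entity_ids: list[str] = []
        for m in mentions:
            if m.concept_id not in entity_ids:
                entity_ids.append(m.concept_id)
            if m.concept_id not in self.entity_meta:
                if m.concept_id in self.dictionary:
                    self.entity_meta[m.concept_id] = self.dictionary[m.concept_id]
                else:
                    self.entity_meta[m.concept_id] = mutation_concept(
                        m.concept_id.split(":", 1)[1]
                    )
        tokens = tokenize(doc.text)
        self.documents[doc.doc_id] = doc
        self.postings[doc.doc_id] = Posting(doc.doc_id, tuple(entity_ids))
        self.doc_tokens[doc.doc_id] = tokens
        self.doc_tf[doc.doc_id] = Counter(tokens)
        for term in set(tokens):
            self.term_docs.setdefault(term, set()).add(doc.doc_id)
        if doc.impact_factor is not None:
            self.max_if = max(self.max_if, doc.impact_factor)

    # -- lookup ------------------------------------------------------------

    def retrieve_postings(self, term: str) -> list[Posting]:
        """Postings of exactly the documents containing *term* (sorted by
        doc_id); empty for unknown terms."""
        return [
            self.postings[d] for d in sorted(self.term_docs.get(term, ()))
        ]

    def corpus_stats(self) -> CorpusStats:
        return CorpusStats(
            n_docs=len(self.documents),
            df={t: len(ds) for t, ds in self.term_docs.items()},
            term_freq={
                (t, d): c
                for d, tf in self.doc_tf.items()
                for t, c in tf.items()
            },
            max_if=self.max_if,
        )

    def tf(self, term: str, doc_id: str) -> int:
        return self.doc_tf[doc_id].get(term, 0)

    def df(self, term: str) -> int:
        return len(self.term_docs.get(term, ()))

    @property
    def n_docs(self) -> int:
        return len(self.documents)

    def max_month_index(self) -> int | None:
        """Latest publication month over the corpus (default 'as of' time)."""
        months = [
            d.month_index for d in self.documents.values()
            if d.month_index is not None
        ]
        return max(months) if months else None

    def phrase_docs(self, phrase_tokens: Sequence[str]) -> set[str]:
        """Doc ids whose token stream contains the tokens consecutively."""
        want = list(phrase_tokens)
        if not want:
            return set()
        candidates = self.term_docs.get(want[0], set())
        for t in want[1:]:
            candidates = candidates & self.term_docs.get(t, set())
        return {d for d in candidates if _contains_run(self.doc_tokens[d], want)}

    def phrase_tf(self, phrase_tokens: Sequence[str], doc_id: str) -> int:
        return _count_runs(self.doc_tokens[doc_id], list(phrase_tokens))

    def state(self) -> dict:
        """Canonical comparable snapshot (order-independent)."""
        return {
            "documents": {d: vars(rec).copy() for d, rec in self.documents.items()},
            "postings": {d: p.entity_ids for d, p in self.postings.items()},
            "terms": {t: sorted(ds) for t, ds in self.term_docs.items()},
            "tf": {d: dict(c) for d, c in self.doc_tf.items()},
            "max_if": self.max_if,
        }

    # -- persistence ---------------------------------------------------------

    def save(self, outdir: str | Path) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        self.dictionary.save(outdir / "dictionary.jsonl")
        with open(outdir / "documents.jsonl", "w", encoding="utf-8") as fh:
            for did in sorted(self.documents):
                d = self.documents[did]
                fh.write(json.dumps({
                    "doc_id": d.doc_id, "text": d.text, "journal": d.journal,
                    "impact_factor": d.impact_factor,
                    "pub_year": d.pub_year, "pub_month": d.pub_month,
                }, ensure_ascii=False) + "\n")
        with open(outdir / "postings.jsonl", "w", encoding="utf-8") as fh:
            for did in sorted(self.postings):
                p = self.postings[did]
                fh.write(json.dumps(
                    {"doc_id": p.doc_id, "entity_ids": list(p.entity_ids)}
                ) + "\n")
        stats = self.corpus_stats()
        with open(outdir / "stats.json", "w", encoding="utf-8") as fh:
            json.dump({
                "n_docs": stats.n_docs,
                "max_if": stats.max_if,
                "n_terms": len(stats.df),
                "n_entities": len(self.entity_meta),
            }, fh, indent=1, sort_keys=True)

    @classmethod
    def load(cls, outdir: str | Path) -> "InvertedIndex":
        outdir = Path(outdir)
        dictionary = Dictionary.load(outdir / "dictionary.jsonl")
        index = cls(dictionary)
        docs = []
        with open(outdir / "documents.jsonl", encoding="utf-8") as fh:
            for line in fh:
                if line.strip():
                    docs.append(DocumentRecord(**json.loads(line)))
        index.add_documents(docs)
        return index


def build_index(
    docs: Iterable[DocumentRecord], dictionary: Dictionary
) -> InvertedIndex:
    """Build a fresh index over *docs*."""
    return InvertedIndex(dictionary).add_documents(list(docs))


def _contains_run(tokens: list[str], want: list[str]) -> bool:
    return _count_runs(tokens, want, stop_at_first=True) > 0


def _count_runs(tokens: list[str], want: list[str], stop_at_first: bool = False) -> int:
    n, w = len(tokens), len(want)
    count = 0
    for i in range(n - w + 1):
        if tokens[i:i + w] == want:
            count += 1
            if stop_at_first:
                return count
    return count
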