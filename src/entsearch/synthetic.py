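"""Deterministic synthetic corpora, dictionaries, and gold annotations.

The generator emulates the statistical shape of an abstract corpus — short
token streams with planted entity mentions, journal impact factors drawn
uniformly, publication months spread over a range — while keeping ground
truth exact: filler vocabulary and entity surfaces are disjoint by
construction and every entity token is used by exactly one surface, so no
planted surface is a substring of another and dictionary matching must
recover precisely the planted mentions.

A "query topic" token can be planted so that designated concepts co-occur
with it at a high rate and all others at a low background rate; ranking
should then recover the designated concepts.  A separate cohort generator
builds an old-vs-new literature split with otherwise identical term
statistics, isolating the recency component of the score.

All randomness flows from the single ``seed`` field of the spec; two runs
with the same spec are byte-identical.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .dictionary import Dictionary, Mention, SourceRecord, merge_records
from .index import DocumentRecord

_GROUP_TYPES = {
    "gene_group": "gene/protein",
    "chem_group": "drug",
    "disease_group": "disease",
    "pathway_group": "pathway",
}


class FixtureError(ValueError):
    pass


@dataclass(frozen=True)
class FixtureSpec:
    """Parameters of a synthetic corpus.

    Defaults give a small but non-trivial corpus: 100 abstracts of ~40
    tokens, 5 concepts per entity group with 1-3 synonyms each, on average
    2 planted mentions per document, impact factors uniform on [0, 50]
    (a tenth of documents in IF-less journals), publication dates spread
    over 2008-2015.
    """

    n_docs: int = 100
    n_concepts_per_group: int = 5
    vocab_size: int = 200
    tokens_per_doc: int = 40
    mean_mentions_per_doc: float = 2.0
    max_impact_factor: float = 50.0
    frac_no_impact_factor: float = 0.1
    year_range: tuple[int, int] = (2008, 2015)
    seed: int = 0
    # optional planted query topic
    topic_token: str | None = None
    n_relevant_concepts: int = 0
    topic_rate_relevant: float = 1.0
    topic_rate_background: float = 0.05

    def __post_init__(self) -> None:
        if min(self.n_docs, self.n_concepts_per_group, self.vocab_size,
               self.tokens_per_doc) <= 0:
            raise FixtureError("all counts must be positive")
        if self.mean_mentions_per_doc < 0:
            raise FixtureError("mean_mentions_per_doc must be >= 0")


@dataclass
class Fixture:
    dictionary: Dictionary
    corpus: list[DocumentRecord]
    gold: dict[str, list[Mention]]
    relevance: dict[str, set[str]]
    surfaces: dict[str, list[str]]  # concept_id -> its surfaces
    source_records: list[SourceRecord] = field(default_factory=list)


def generate_fixture(spec: FixtureSpec) -> Fixture:
    rng = np.random.default_rng(spec.seed)

    filler = [f"w{i:04d}" for i in range(spec.vocab_size)]

    # concepts: 1-3 surfaces each; every entity token used by one surface only
    records: list[SourceRecord] = []
    token_counter = 0
    n_concepts = spec.n_concepts_per_group * len(_GROUP_TYPES)
    concept_surfaces: list[list[str]] = []
    for ci in range(n_concepts):
        etype = list(_GROUP_TYPES.values())[ci % len(_GROUP_TYPES)]
        n_syn = int(rng.integers(1, 4))
        surfaces = []
        for _ in range(n_syn):
            n_tok = int(rng.integers(1, 3))  # 1- or 2-token surfaces
            toks = [f"ent{token_counter + j:04d}" for j in range(n_tok)]
            token_counter += n_tok
            surfaces.append(" ".join(toks))
        concept_surfaces.append(surfaces)
        for s in surfaces:
            records.append(SourceRecord(
                source="synthetic", surface=s, entity_type=etype,
                xrefs=frozenset({f"X{ci:04d}"}),
            ))
    dictionary = merge_records(records)

    # map back: which concept_id did each planted surface land in
    surface_to_cid = {
        s.casefold(): dictionary.name_index[s.casefold()]
        for surfaces in concept_surfaces for s in surfaces
    }
    relevant_ids: list[str] = []
    if spec.topic_token is not None and spec.n_relevant_concepts > 0:
        chosen = rng.choice(n_concepts, size=min(spec.n_relevant_concepts,
                                                 n_concepts), replace=False)
        relevant_ids = sorted(
            surface_to_cid[concept_surfaces[int(c)][0].casefold()]
            for c in chosen
        )

    corpus: list[DocumentRecord] = []
    gold: dict[str, list[Mention]] = {}
    y0, y1 = spec.year_range
    for di in range(spec.n_docs):
        doc_id = f"D{di:05d}"
        units: list[tuple[str, str | None]] = [  # (text, concept_id | None)
            (filler[int(i)], None)
            for i in rng.integers(0, spec.vocab_size, spec.tokens_per_doc)
        ]
        n_mentions = int(rng.poisson(spec.mean_mentions_per_doc))
        planted_cids = []
        for _ in range(n_mentions):
            ci = int(rng.integers(0, n_concepts))
            surfaces = concept_surfaces[ci]
            surf = surfaces[int(rng.integers(0, len(surfaces)))]
            pos = int(rng.integers(0, len(units) + 1))
            units.insert(pos, (surf, surface_to_cid[surf.casefold()]))
            planted_cids.append(surface_to_cid[surf.casefold()])
        if spec.topic_token is not None:
            rate = (
                spec.topic_rate_relevant
                if any(c in relevant_ids for c in planted_cids)
                else spec.topic_rate_background
            )
            if rng.random() < rate:
                pos = int(rng.integers(0, len(units) + 1))
                units.insert(pos, (spec.topic_token, None))

        text, mentions = _assemble(units)
        gold[doc_id] = mentions
        has_if = rng.random() >= spec.frac_no_impact_factor
        impact = float(np.round(rng.uniform(0, spec.max_impact_factor), 3)) \
            if has_if else None
        corpus.append(DocumentRecord(
            doc_id=doc_id,
            text=text,
            journal=f"J{di % 7}" if has_if else "",
            impact_factor=impact,
            pub_year=int(rng.integers(y0, y1 + 1)),
            pub_month=int(rng.integers(1, 13)),
        ))

    relevance: dict[str, set[str]] = {}
    if spec.topic_token is not None and relevant_ids:
        relevance[spec.topic_token] = {
            dictionary[cid].preferred_name() for cid in relevant_ids
        }
    surfaces_by_cid: dict[str, list[str]] = {}
    for surfaces in concept_surfaces:
        cid = surface_to_cid[surfaces[0].casefold()]
        surfaces_by_cid.setdefault(cid, []).extend(surfaces)
    return Fixture(dictionary, corpus, gold, relevance, surfaces_by_cid,
                   source_records=records)


def _assemble(
    units: Sequence[tuple[str, str | None]]
) -> tuple[str, list[Mention]]:
    parts: list[str] = []
    mentions: list[Mention] = []
    offset = 0
    for text, cid in units:
        if parts:
            offset += 1  # the joining space
        if cid is not None:
            mentions.append(Mention(cid, offset, offset + len(text), text))
        parts.append(text)
        offset += len(text)
    return " ".join(parts), mentions


# -- old/new cohort corpus for recency experiments --------------------------


@dataclass
class CohortFixture:
    dictionary: Dictionary
    corpus: list[DocumentRecord]
    query_token: str
    old_concept_id: str   # carried only by the old cohort (age > 96 months)
    new_concept_id: str   # carried only by the new cohort (age < 12 months)
    reference_month: int


@dataclass(frozen=True)
class CohortSpec:
    """Two equal document cohorts differing only in age and carried entity."""

    docs_per_cohort: int = 20
    old_age_months: int = 120   # beyond the 96-month recency cap
    new_age_months: int = 6
    seed: int = 0

    def __post_init__(self) -> None:
        if self.docs_per_cohort <= 0:
            raise FixtureError("docs_per_cohort must be positive")
        if not self.old_age_months > 96 > self.new_age_months:
            raise FixtureError(
                "old cohort must exceed the 96-month cap and the new cohort "
                "must be younger than it"
            )


def cohort_fixture(spec: CohortSpec) -> CohortFixture:
    """Corpus where recency is the only asymmetry between two concepts.

    Every document is the same token stream ("cohorttopic" plus one entity
    surface plus fixed filler), has no impact factor, and each cohort has
    the same size — so with the recency power at 0 the two concepts tie
    exactly, and any separation is attributable to the recency component.
    """
    records = [
        SourceRecord("synthetic", "oldentity", "drug", frozenset({"XOLD"})),
        SourceRecord("synthetic", "newentity", "drug", frozenset({"XNEW"})),
    ]
    dictionary = merge_records(records)
    old_cid = dictionary.name_index["oldentity"]
    new_cid = dictionary.name_index["newentity"]

    reference_month = 2015 * 12 + 6
    corpus = []
    for cohort, age, surface in (
        ("old", spec.old_age_months, "oldentity"),
        ("new", spec.new_age_months, "newentity"),
    ):
        month_index = reference_month - age
        year, month = divmod(month_index, 12)
        if month == 0:
            year, month = year - 1, 12
        for i in range(spec.docs_per_cohort):
            corpus.append(DocumentRecord(
                doc_id=f"{cohort}{i:04d}",
                text=f"cohorttopic {surface} filler tokens alpha beta",
                journal="",
                impact_factor=None,
                pub_year=year,
                pub_month=month,
            ))
    return CohortFixture(
        dictionary=dictionary,
        corpus=corpus,
        query_token="cohorttopic",
        old_concept_id=old_cid,
        new_concept_id=new_cid,
        reference_month=reference_month,
    )
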