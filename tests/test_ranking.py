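"""Score components, document score, and entity ranking."""

import math

import pytest
from hypothesis import given, settings, strategies as st

from entsearch import (
    DocumentRecord,
    ScoreWeights,
    SourceRecord,
    build_index,
    document_score,
    entity_number_score,
    merge_records,
    parse_query,
    recency_score,
    reputation_score,
    search_entities,
    term_match_score,
)
from entsearch.index import CorpusStats, Posting
from entsearch.ranking import RankingError
from entsearch.synthetic import (
    CohortSpec,
    FixtureSpec,
    cohort_fixture,
    generate_fixture,
)

from _oracle import oracle_rank


def doc_aged(months_before, ref=2015 * 12 + 6, doc_id="d"):
    y, m = divmod(ref - months_before, 12)
    if m == 0:
        y, m = y - 1, 12
    return DocumentRecord(doc_id, "t", pub_year=y, pub_month=m)


REF = 2015 * 12 + 6


class TestRecencyScore:
    @pytest.mark.parametrize("age,expected", [
        (0, 1.0),        # published in the query month
        (24, 0.5),       # halves every two years
        (48, 0.25),
        (96, 0.0625),
        (120, 0.0625),   # floored beyond eight years
    ])
    def test_decay_anchors(self, age, expected):
        assert recency_score(doc_aged(age), REF) == pytest.approx(expected)

    def test_future_dates_clamped_to_age_zero(self):
        assert recency_score(doc_aged(-6), REF) == 1.0

    def test_missing_date_sits_at_floor(self):
        assert recency_score(DocumentRecord("d", "t"), REF) == 0.0625

    def test_monotone_nonincreasing_in_age(self):
        scores = [recency_score(doc_aged(a), REF) for a in range(0, 130, 5)]
        assert all(a >= b for a, b in zip(scores, scores[1:]))
        assert all(0.0625 <= s <= 1.0 for s in scores)


class TestReputationScore:
    def stats(self, max_if):
        return CorpusStats(n_docs=1, df={}, term_freq={}, max_if=max_if)

    def test_no_impact_factor_scores_one(self):
        doc = DocumentRecord("d", "t", impact_factor=None)
        assert reputation_score(doc, self.stats(30.0)) == 1.0

    def test_corpus_maximum_scores_ten(self):
        doc = DocumentRecord("d", "t", impact_factor=30.0)
        assert reputation_score(doc, self.stats(30.0)) == 10.0

    def test_half_maximum_scores_five_and_a_half(self):
        doc = DocumentRecord("d", "t", impact_factor=15.0)
        assert reputation_score(doc, self.stats(30.0)) == 5.5

    def test_inconsistent_stats_raise(self):
        doc = DocumentRecord("d", "t", impact_factor=2.0)
        with pytest.raises(RankingError):
            reputation_score(doc, self.stats(0.0))

    @given(st.floats(0.0, 100.0), st.floats(0.001, 100.0))
    @settings(deadline=None, max_examples=80)
    def test_bounds_and_monotonicity(self, if_d, max_extra):
        max_if = if_d + max_extra
        doc = DocumentRecord("d", "t", impact_factor=if_d)
        q = reputation_score(doc, self.stats(max_if))
        assert 1.0 <= q <= 10.0
        higher = DocumentRecord("d", "t", impact_factor=min(if_d + 1, max_if))
        assert reputation_score(higher, self.stats(max_if)) >= q


class TestEntityNumberScore:
    @pytest.mark.parametrize("n,expected", [
        (1, 1.0), (2, 0.5), (4, 0.25), (10, 0.1), (25, 0.1),
    ])
    def test_penalty(self, n, expected):
        posting = Posting("d", tuple(f"e{i}" for i in range(n)))
        assert entity_number_score(posting) == pytest.approx(expected)

    def test_entity_free_document_is_undefined(self):
        with pytest.raises(RankingError):
            entity_number_score(Posting("d", ()))


class TestTermMatchScore:
    def test_single_term_unit_value(self, cml_dictionary):
        # N=2 docs, df=1, tf=1: idf = 1+ln(2/2) = 1, tfidf = 1, coord = 1
        docs = [
            DocumentRecord("a", "imatinib works", pub_year=2014),
            DocumentRecord("b", "nothing here", pub_year=2014),
        ]
        index = build_index(docs, cml_dictionary)
        ast = parse_query("imatinib")
        assert term_match_score(ast, "a", index) == pytest.approx(1.0)

    def test_coord_full_and_partial(self, cml_dictionary):
        docs = [
            DocumentRecord("full", "alpha beta gamma", pub_year=2014),
            DocumentRecord("part", "alpha delta epsilon", pub_year=2014),
        ]
        index = build_index(docs, cml_dictionary)
        ast = parse_query("alpha beta gamma")
        n = index.n_docs

        def idf2(df):
            return (1 + math.log(n / (df + 1))) ** 2

        t_full = term_match_score(ast, "full", index)
        expected_full = 1.0 * (idf2(2) + idf2(1) + idf2(1))
        assert t_full == pytest.approx(expected_full)
        t_part = term_match_score(ast, "part", index)
        assert t_part == pytest.approx((1 / 3) * idf2(2))

    def test_boost_scales_tfidf_not_coord(self, cml_dictionary):
        docs = [DocumentRecord("a", "alpha beta", pub_year=2014)]
        index = build_index(docs, cml_dictionary)
        plain = term_match_score(parse_query("alpha beta"), "a", index)
        boosted = term_match_score(parse_query("alpha^3 beta"), "a", index)
        assert boosted > plain

    def test_unmatched_document_is_callers_error(self, cml_index):
        with pytest.raises(RankingError):
            term_match_score(parse_query("zyzzyva"), "24524212", cml_index)


class TestDocumentScore:
    def test_identity_when_all_components_one(self, cml_dictionary):
        docs = [
            DocumentRecord("a", "imatinib works", impact_factor=None,
                           pub_year=2014, pub_month=6),
            DocumentRecord("b", "nothing here", impact_factor=None,
                           pub_year=2014, pub_month=6),
        ]
        index = build_index(docs, cml_dictionary)
        ast = parse_query("imatinib")
        ds = document_score(ast, "a", index, index.corpus_stats(),
                            ScoreWeights(), reference_month=2014 * 12 + 6)
        assert ds.total == pytest.approx(1.0)
        assert (ds.term_match, ds.entity_count, ds.reputation, ds.recency) \
            == (1.0, 1.0, 1.0, 1.0)

    def test_score_is_product_of_components(self, cml_index):
        ast = parse_query("imatinib")
        stats = cml_index.corpus_stats()
        ref = cml_index.max_month_index()
        ds = document_score(ast, "24524212", cml_index, stats,
                            ScoreWeights(), ref)
        assert ds.total == pytest.approx(
            ds.term_match * ds.entity_count * ds.reputation * ds.recency)

    def test_zero_recency_power_ignores_dates(self, cml_index):
        ast = parse_query("imatinib")
        stats = cml_index.corpus_stats()
        w = ScoreWeights(power_recency=0.0)
        early = document_score(ast, "24524212", cml_index, stats, w, 2014 * 12)
        late = document_score(ast, "24524212", cml_index, stats, w, 2030 * 12)
        assert early.total == late.total

    def test_negative_power_rejected(self):
        with pytest.raises(RankingError):
            ScoreWeights(power_recency=-1.0)


class TestSearchEntities:
    def test_single_document_single_entity(self, cml_dictionary):
        docs = [DocumentRecord("only", "imatinib data", impact_factor=None,
                               pub_year=2014, pub_month=6)]
        index = build_index(docs, cml_dictionary)
        ast = parse_query("data")
        (result,) = search_entities(index, ast, k=5)
        stats = index.corpus_stats()
        ds = document_score(ast, "only", index, stats, ScoreWeights(),
                            index.max_month_index())
        assert result.score == pytest.approx(ds.total)
        assert "imatinib" in result.concept.names

    def test_type_filter_drops_other_groups(self, cml_index):
        ast = parse_query("imatinib", type_filter="drug")
        for e in search_entities(cml_index, ast, k=10):
            assert "drug" in e.concept.types
        ast2 = parse_query("imatinib", type_filter="gene/protein")
        groups = {e.concept.group
                  for e in search_entities(cml_index, ast2, k=10)}
        assert groups <= {"gene_group"}

    def test_k_must_be_positive(self, cml_index):
        with pytest.raises(RankingError):
            search_entities(cml_index, parse_query("imatinib"), k=0)

    def test_entity_free_documents_never_contribute(self, cml_index):
        # d4 matches "abstract" but has no entities
        ast = parse_query("abstract")
        assert search_entities(cml_index, ast, k=10) == []

    def test_adding_matching_document_strictly_raises_score(
            self, cml_dictionary):
        base = [DocumentRecord("a", "imatinib trial", impact_factor=2.0,
                               pub_year=2014, pub_month=1)]
        extra = DocumentRecord("b", "imatinib trial follow-up",
                               impact_factor=1.0, pub_year=2014, pub_month=1)
        ast = parse_query("trial")
        s1 = search_entities(build_index(base, cml_dictionary), ast)[0].score
        s2 = search_entities(build_index(base + [extra], cml_dictionary),
                             ast)[0].score
        assert s2 > s1

    @pytest.mark.parametrize("query,type_filter", [
        ("q0", None),
        ("q0", "drug"),
        ("q0 w0001", None),
        ("q0 AND w0001", None),
        ("q0 NOT w0002", None),
        ("q0 AND (year:[2010 TO 2013])", None),
    ])
    def test_matches_bruteforce_oracle_on_synthetic_corpus(
            self, query, type_filter):
        fx = generate_fixture(FixtureSpec(
            n_docs=100, seed=11, topic_token="q0", n_relevant_concepts=3))
        index = build_index(fx.corpus, fx.dictionary)
        ast = parse_query(query, type_filter=type_filter)
        got = search_entities(index, ast, k=30)
        expected = oracle_rank(fx.corpus, fx.dictionary, ast, k=30)
        assert [e.concept_id for e in got] == [cid for cid, _ in expected]
        for e, (_, score) in zip(got, expected):
            assert e.score == pytest.approx(score, abs=1e-9)

    def test_oracle_equivalence_at_200_docs_nondefault_powers(self):
        fx = generate_fixture(FixtureSpec(n_docs=200, seed=12,
                                          topic_token="q0",
                                          n_relevant_concepts=2))
        index = build_index(fx.corpus, fx.dictionary)
        ast = parse_query("q0")
        powers = (1.0, 2.0, 0.5, 3.0)
        w = ScoreWeights(*powers)
        got = search_entities(index, ast, w, k=40)
        expected = oracle_rank(fx.corpus, fx.dictionary, ast,
                               powers=powers, k=40)
        assert [e.concept_id for e in got] == [cid for cid, _ in expected]
        for e, (_, score) in zip(got, expected):
            assert e.score == pytest.approx(score, abs=1e-9)

    def test_component_bounds_on_randomized_fixture(self):
        fx = generate_fixture(FixtureSpec(n_docs=60, seed=13,
                                          topic_token="q0",
                                          n_relevant_concepts=2))
        index = build_index(fx.corpus, fx.dictionary)
        ast = parse_query("q0")
        for e in search_entities(index, ast, k=50):
            for d in e.contributing:
                assert 0.1 <= d.entity_count <= 1.0
                assert 1.0 <= d.reputation <= 10.0
                assert 0.0625 <= d.recency <= 1.0
                assert d.term_match > 0


class TestRecencyPower:
    def test_power_zero_cohorts_tie(self):
        fx = cohort_fixture(CohortSpec(seed=0))
        index = build_index(fx.corpus, fx.dictionary)
        ast = parse_query(fx.query_token)
        w = ScoreWeights(power_recency=0.0, reference_month=fx.reference_month)
        results = {e.concept_id: e.score
                   for e in search_entities(index, ast, w, k=2)}
        assert abs(results[fx.old_concept_id]
                   - results[fx.new_concept_id]) < 1e-9

    @pytest.mark.parametrize("power", [1.0, 4.0])
    def test_score_ratio_follows_closed_form(self, power):
        spec = CohortSpec(seed=0)
        fx = cohort_fixture(spec)
        index = build_index(fx.corpus, fx.dictionary)
        ast = parse_query(fx.query_token)
        w = ScoreWeights(power_recency=power,
                         reference_month=fx.reference_month)
        results = {e.concept_id: e.score
                   for e in search_entities(index, ast, w, k=2)}
        r_new = 0.5 ** (spec.new_age_months / 24)
        r_old = 0.5 ** (min(spec.old_age_months, 96) / 24)
        assert results[fx.new_concept_id] / results[fx.old_concept_id] \
            == pytest.approx((r_new / r_old) ** power)

    def test_raising_power_promotes_recent_cohort(self):
        fx = cohort_fixture(CohortSpec(seed=0))
        index = build_index(fx.corpus, fx.dictionary)
        ast = parse_query(fx.query_token)
        w4 = ScoreWeights(power_recency=4.0,
                          reference_month=fx.reference_month)
        top = search_entities(index, ast, w4, k=2)
        assert top[0].concept_id == fx.new_concept_id

    def test_power_zero_ranking_invariant_to_date_shuffle(self):
        fx = generate_fixture(FixtureSpec(n_docs=50, seed=14,
                                          topic_token="q0",
                                          n_relevant_concepts=2))
        index = build_index(fx.corpus, fx.dictionary)
        import numpy as np
        rng = np.random.default_rng(0)
        perm = rng.permutation(len(fx.corpus))
        shuffled = [
            DocumentRecord(d.doc_id, d.text, d.journal, d.impact_factor,
                           fx.corpus[perm[i]].pub_year,
                           fx.corpus[perm[i]].pub_month)
            for i, d in enumerate(fx.corpus)
        ]
        index2 = build_index(shuffled, fx.dictionary)
        ast = parse_query("q0")
        w = ScoreWeights(power_recency=0.0)
        a = [(e.concept_id, e.score) for e in search_entities(index, ast, w, k=30)]
        b = [(e.concept_id, e.score) for e in search_entities(index2, ast, w, k=30)]
        for (ca, sa), (cb, sb) in zip(a, b):
            assert ca == cb and sa == pytest.approx(sb, abs=1e-12)
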