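"""Rocchio relevance feedback and lexicon-based expansion."""

import numpy as np
import pytest

from bioquery.corpus import DatasetRecord
from bioquery.errors import BioqueryError
from bioquery.evaluation import Qrels, overlap_similarity
from bioquery.expansion import (
    ExpandedQuery,
    FeedbackSets,
    RocchioParams,
    apply_expansion,
    lexicon_expand,
    oracle_feedback,
    prf_feedback,
    query_vector,
    rocchio_expand,
    rocchio_vector,
    select_expansion_terms,
)
from bioquery.index import build_index
from bioquery.query_formulation import Lexicon, LexiconEntry, tag_entities
from bioquery.search import MultiFieldQuery, QueryClause

from reference import dense_rocchio


class TestRocchioVector:
    def test_worked_example(self):
        feedback = FeedbackSets(
            relevant={"r1": {"b": 2.0}},
            irrelevant={"n1": {"a": 1.0, "b": 1.0}},
        )
        out = rocchio_vector({"a": 1.0}, feedback, RocchioParams())
        assert out == pytest.approx({"a": 0.9, "b": 0.9})

    def test_zero_beta_gamma_returns_alpha_q(self):
        params = RocchioParams(alpha=2.0, beta=0.0, gamma=0.0)
        feedback = FeedbackSets(
            relevant={"r": {"x": 5.0}}, irrelevant={"n": {"y": 3.0}}
        )
        out = rocchio_vector({"a": 1.0, "b": 2.0}, feedback, params)
        positive = {t: w for t, w in out.items() if w > 0}
        assert positive == {"a": 2.0, "b": 4.0}

    def test_empty_dnr_drops_subtraction(self):
        feedback = FeedbackSets(relevant={"r": {"b": 4.0}}, irrelevant={})
        out = rocchio_vector({"a": 1.0}, feedback, RocchioParams())
        assert out == pytest.approx({"a": 1.0, "b": 2.0})

    def test_negative_coordinates_clamped(self):
        feedback = FeedbackSets(relevant={}, irrelevant={"n": {"a": 100.0}})
        out = rocchio_vector({"a": 1.0}, feedback, RocchioParams())
        assert out["a"] == 0.0

    def test_overlapping_feedback_sets_rejected(self):
        with pytest.raises(BioqueryError):
            FeedbackSets(relevant={"d": {}}, irrelevant={"d": {}})

    def test_matches_dense_brute_force_on_random_instances(self):
        rng = np.random.default_rng(7)
        terms = [f"t{i}" for i in range(30)]
        for _ in range(100):
            def rand_vec():
                n = int(rng.integers(1, 10))
                chosen = rng.choice(len(terms), size=n, replace=False)
                return {terms[int(i)]: float(rng.uniform(0, 5)) for i in chosen}
            q = rand_vec()
            dr = {f"r{i}": rand_vec() for i in range(int(rng.integers(0, 5)))}
            dnr = {f"n{i}": rand_vec() for i in range(int(rng.integers(0, 5)))}
            params = RocchioParams(
                alpha=float(rng.uniform(0, 2)),
                beta=float(rng.uniform(0, 2)),
                gamma=float(rng.uniform(0, 2)),
            )
            got = rocchio_vector(q, FeedbackSets(dr, dnr), params)
            expected = dense_rocchio(
                q, list(dr.values()), list(dnr.values()),
                params.alpha, params.beta, params.gamma,
            )
            for t in set(got) | set(expected):
                assert got.get(t, 0.0) == pytest.approx(
                    expected.get(t, 0.0), abs=1e-12
                )


class TestSelectExpansionTerms:
    def test_rank_and_exclude(self):
        out = select_expansion_terms(
            {"a": 0.9, "b": 0.9, "c": 0.4}, ["a"], 1
        )
        assert out.expansion_terms == [("b", 0.9)]

    def test_zero_terms(self):
        out = select_expansion_terms({"a": 1.0, "b": 0.5}, ["a"], 0)
        assert out.expansion_terms == []

    def test_tie_broken_lexicographically(self):
        out = select_expansion_terms(
            {"zz": 0.7, "aa": 0.7, "q": 1.0}, ["q"], 1
        )
        assert out.expansion_terms == [("aa", 0.7)]

    def test_descending_weights(self):
        out = select_expansion_terms(
            {"a": 0.1, "b": 0.9, "c": 0.5}, [], 3
        )
        weights = [w for _, w in out.expansion_terms]
        assert weights == sorted(weights, reverse=True)


class TestFeedbackSets:
    def _index(self):
        records = [
            DatasetRecord(f"d{i}", "r", "c",
                          {"title": f"term{i}", "description": f"word{i} shared"})
            for i in range(12)
        ]
        return build_index(records)

    def test_prf_truncates_to_available(self):
        index = self._index()
        # query matches only 7 documents
        query = MultiFieldQuery(
            [QueryClause("description", tuple(f"word{i}" for i in range(7)))]
        )
        feedback = prf_feedback(index, query, RocchioParams(prf_k=10))
        assert len(feedback.relevant) == 7
        assert feedback.irrelevant == {}

    def test_prf_deterministic(self, small_index, small_collection):
        query = MultiFieldQuery(
            [QueryClause("description", ("sig00n0", "sig00n1"))]
        )
        a = prf_feedback(small_index, query, RocchioParams())
        b = prf_feedback(small_index, query, RocchioParams())
        assert a.relevant == b.relevant

    def test_prf_source_field_switch(self):
        index = self._index()
        query = MultiFieldQuery([QueryClause("description", ("word1",))])
        by_title = prf_feedback(
            index, query, RocchioParams(source_field="title")
        )
        assert by_title.relevant["d1"] == index.doc_vector("d1", "title")

    def test_oracle_grade_partition(self):
        index = self._index()
        qrels = Qrels({"q1": {"d1": 2, "d2": 1, "d3": 0, "d4": -1}})
        feedback = oracle_feedback(qrels, "q1", index)
        assert set(feedback.relevant) == {"d1", "d2"}
        assert set(feedback.irrelevant) == {"d3"}

    def test_oracle_unknown_query_raises(self):
        with pytest.raises(BioqueryError):
            oracle_feedback(Qrels({}), "nope", self._index())

    def test_oracle_all_unjudged_gives_empty_sets(self):
        index = self._index()
        qrels = Qrels({"q1": {"d1": -1, "d2": -1}})
        feedback = oracle_feedback(qrels, "q1", index)
        assert feedback.relevant == {} and feedback.irrelevant == {}


class TestLexiconExpand:
    def _setup(self):
        lexicon = Lexicon(
            [LexiconEntry("G:1", "gene", "TP53", ("p53", "trp53"))]
        )
        records = [
            DatasetRecord("d1", "r", "c", {"description": "p53 pathway study"}),
            DatasetRecord("d2", "r", "c", {"description": "p53 and apoptosis"}),
            DatasetRecord("d3", "r", "c", {"description": "trp53 knockout"}),
            DatasetRecord("d4", "r", "c", {"description": "unrelated work"}),
        ]
        return lexicon, build_index(records)

    def test_idf_ranking(self):
        lexicon, index = self._setup()
        tagged = tag_entities("TP53 expression", lexicon)
        out = lexicon_expand(tagged, lexicon, index, n_terms=1)
        # trp53 (df=1) is rarer than p53 (df=2) -> higher idf -> selected
        assert [t for t, _ in out.expansion_terms] == ["trp53"]
        assert out.expansion_terms[0][1] == pytest.approx(
            index.idf("trp53", "description")
        )

    def test_no_mentions_no_expansion(self):
        lexicon, index = self._setup()
        tagged = tag_entities("something else entirely", lexicon)
        out = lexicon_expand(tagged, lexicon, index)
        assert out.expansion_terms == []

    def test_original_terms_excluded(self):
        lexicon, index = self._setup()
        tagged = tag_entities("p53 data", lexicon)
        out = lexicon_expand(tagged, lexicon, index, n_terms=5)
        assert "p53" not in [t for t, _ in out.expansion_terms]


class TestApplyExpansion:
    def _query(self):
        return MultiFieldQuery(
            [
                QueryClause("title", ("a", "b")),
                QueryClause("description", ("a", "b")),
                QueryClause("article_title", ("a", "b")),
                QueryClause("genes", ("g",), 2.0),
            ]
        )

    def test_empty_expansion_is_identity(self):
        query = self._query()
        out = apply_expansion(
            query, ExpandedQuery(["a", "b"], [], "rocchio_prf")
        )
        assert out.clauses == query.clauses

    def test_terms_added_to_always_on_clauses_only(self):
        expanded = ExpandedQuery(["a", "b"], [("x", 1.0), ("y", 0.5)], "rocchio_prf")
        out = apply_expansion(self._query(), expanded)
        for clause in out.clauses:
            if clause.field == "genes":
                assert clause.terms == ("g",)
            else:
                assert clause.terms == ("a", "b", "x", "y")

    def test_idempotent(self):
        expanded = ExpandedQuery(["a", "b"], [("x", 1.0)], "rocchio_prf")
        once = apply_expansion(self._query(), expanded)
        twice = apply_expansion(once, expanded)
        assert twice.clauses == once.clauses


def test_oracle_terms_occur_in_relevant_source_fields(small_collection, small_index):
    """With complete qrels, every oracle expansion term must appear in at
    least one relevant document's source field."""
    from bioquery.analysis import analyze
    for qid, text in small_collection.queries:
        feedback = oracle_feedback(small_collection.qrels, qid, small_index)
        expanded = rocchio_expand(
            small_index, MultiFieldQuery([QueryClause("description", ("x",))]),
            analyze(text), feedback=feedback, method="rocchio_oracle",
        )
        relevant_terms = set()
        for doc_id in feedback.relevant:
            relevant_terms.update(small_index.doc_terms(doc_id, "description"))
        for term, _ in expanded.expansion_terms:
            assert term in relevant_terms


def test_prf_expansion_increases_query_relevant_overlap(small_collection, small_index):
    """Rocchio-PRF terms must pull the query toward the vocabulary its
    relevant documents share (higher mean description overlap)."""
    from bioquery.analysis import analyze
    from bioquery.experiment import ExperimentConfig, Variant, formulate

    config = ExperimentConfig()
    improved = 0
    total = 0
    for qid, text in small_collection.queries:
        original = analyze(text)
        query = formulate(
            Variant("b", "builder"), qid, text, small_collection.lexicon, config
        )
        expanded = rocchio_expand(small_index, query, original, RocchioParams())
        new_terms = set(original) | {t for t, _ in expanded.expansion_terms}
        rel = small_collection.qrels.relevant_docs(qid)
        before, after = [], []
        for doc_id in rel:
            terms = set(small_index.doc_terms(doc_id, "description"))
            if not terms:
                continue
            before.append(overlap_similarity(set(original), terms))
            after.append(overlap_similarity(new_terms, terms))
        total += 1
        if np.mean(after) > np.mean(before):
            improved += 1
    assert improved == total
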