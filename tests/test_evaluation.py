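"""TREC I/O, conventional and inferred metrics, overlap similarity."""

import math

import pytest

from bioquery.errors import BioqueryError, ParseError
from bioquery.evaluation import (
    Qrels,
    average_precision,
    evaluate_runs,
    inferred_ap,
    inferred_ndcg,
    ndcg_at_k,
    overlap_similarity,
    precision_at_k,
    read_qrels,
    read_run,
    read_sampling_sidecar,
    recall,
    write_qrels,
    write_sampling_sidecar,
)
from bioquery.search import RunRanking, write_run


class TestQrelsIO:
    def test_read_grades(self, tmp_path):
        path = tmp_path / "qrels.txt"
        path.write_text("q1 0 d1 2\nq1 0 d2 0\nq2 0 d1 -1\n")
        qrels = read_qrels(path)
        assert qrels.grade("q1", "d1") == 2
        assert qrels.grade("q2", "d1") == -1
        assert qrels.grade("q9", "dx") == -1  # absent pairs are unjudged

    def test_out_of_scale_grade_rejected(self, tmp_path):
        path = tmp_path / "qrels.txt"
        path.write_text("q1 0 d1 3\n")
        with pytest.raises(ParseError) as err:
            read_qrels(path)
        assert err.value.line_number == 1

    def test_malformed_line_reports_number(self, tmp_path):
        path = tmp_path / "qrels.txt"
        path.write_text("q1 0 d1 2\nq1 d2 1\n")
        with pytest.raises(ParseError) as err:
            read_qrels(path)
        assert err.value.line_number == 2

    def test_round_trip(self, tmp_path):
        qrels = Qrels({"q1": {"d1": 2, "d2": 0}, "q2": {"d3": 1}})
        path = tmp_path / "qrels.txt"
        write_qrels(qrels, path)
        assert read_qrels(path).grades == qrels.grades


class TestRunIO:
    def test_round_trip_and_resort(self, tmp_path):
        path = tmp_path / "a.run"
        # deliberately out of order: reader must re-sort by score desc
        path.write_text(
            "q1 Q0 d2 1 0.5 tag\nq1 Q0 d1 2 0.9 tag\nq1 Q0 d3 3 0.5 tag\n"
        )
        runs = read_run(path)
        assert runs["q1"].doc_ids() == ["d1", "d2", "d3"]

    def test_write_then_read(self, tmp_path):
        ranking = RunRanking("q1", [("d1", 2.0), ("d2", 1.0)], "tag")
        path = tmp_path / "b.run"
        write_run([ranking], path)
        back = read_run(path)
        assert back["q1"].doc_ids() == ["d1", "d2"]
        assert back["q1"].run_tag == "tag"

    def test_malformed_run_line(self, tmp_path):
        path = tmp_path / "c.run"
        path.write_text("q1 Q0 d1 1 notanumber tag\n")
        with pytest.raises(ParseError):
            read_run(path)


QRELS = Qrels({"q": {"d1": 2, "d2": 0, "d3": 1, "d4": 1, "d5": -1}})


class TestPrecisionRecall:
    def test_precision_examples(self):
        ranking = ["d1", "d2", "d3"]  # relevant at ranks 1 and 3
        assert precision_at_k(ranking, QRELS, "q", 10) == pytest.approx(0.2)
        assert precision_at_k(["d1", "d3"], QRELS, "q", 2) == 1.0

    def test_short_ranking_padded(self):
        assert precision_at_k(["d1", "x", "d3", "y"], QRELS, "q", 10) == \
            pytest.approx(0.2)

    def test_unjudged_and_minus_one_non_relevant(self):
        assert precision_at_k(["d5", "d2", "zz"], QRELS, "q", 3) == 0.0

    def test_recall_ratio(self):
        # 2 of 3 relevant retrieved
        assert recall(["d1", "d3", "d2"], QRELS, "q") == pytest.approx(2 / 3)
        assert recall(["d1"], QRELS, "q", cutoff=0) == 0.0
        assert recall(["d1", "d3", "d4"], QRELS, "q") == 1.0

    def test_recall_no_relevant_raises(self):
        qrels = Qrels({"q": {"d1": 0}})
        with pytest.raises(BioqueryError):
            recall(["d1"], qrels, "q")


class TestAveragePrecision:
    def test_worked_example(self):
        qrels = Qrels({"q": {"r1": 2, "r2": 1}})
        assert average_precision(["r1", "n", "r2"], qrels, "q") == \
            pytest.approx((1 + 2 / 3) / 2)

    def test_perfect_ranking(self):
        qrels = Qrels({"q": {"r1": 2, "r2": 1}})
        assert average_precision(["r1", "r2"], qrels, "q") == 1.0

    def test_nothing_retrieved(self):
        qrels = Qrels({"q": {"r1": 2}})
        assert average_precision(["n1", "n2"], qrels, "q") == 0.0


class TestNDCG:
    def test_worked_example(self):
        qrels = Qrels({"q": {"a": 2, "b": 0, "c": 1}})
        dcg = 3.0 + 0.0 + 1.0 / 2.0
        idcg = 3.0 + 1.0 / math.log2(3)
        assert ndcg_at_k(["a", "b", "c"], qrels, "q") == \
            pytest.approx(dcg / idcg)

    def test_ideal_ordering_is_one(self):
        qrels = Qrels({"q": {"a": 2, "b": 1, "c": 0}})
        assert ndcg_at_k(["a", "b", "c"], qrels, "q") == pytest.approx(1.0)

    def test_swap_toward_front_never_decreases(self):
        qrels = Qrels({"q": {"a": 2, "b": 1, "c": 0, "d": 0}})
        worse = ndcg_at_k(["c", "b", "d", "a"], qrels, "q")
        better = ndcg_at_k(["a", "b", "d", "c"], qrels, "q")
        assert better >= worse

    def test_zero_ideal_raises(self):
        qrels = Qrels({"q": {"a": 0}})
        with pytest.raises(BioqueryError):
            ndcg_at_k(["a"], qrels, "q")


class TestInferredMetrics:
    def test_full_sampling_equals_exact(self):
        qrels = Qrels({"q": {"d1": 2, "d2": 0, "d3": 1, "d4": 0}})
        ranking = ["d1", "x", "d3", "d2", "d4"]
        assert inferred_ap(ranking, qrels, "q", 1.0) == pytest.approx(
            average_precision(ranking, qrels, "q"), abs=1e-12
        )
        assert inferred_ndcg(ranking, qrels, "q", 1.0) == pytest.approx(
            ndcg_at_k(ranking, qrels, "q"), abs=1e-12
        )

    def test_single_sampled_relevant_at_rank_one(self):
        qrels = Qrels({"q": {"d1": 1}})
        assert inferred_ap(["d1"], qrels, "q", 0.5) == pytest.approx(1.0)

    def test_no_sampled_judgments_raises(self):
        qrels = Qrels({"q": {"d1": -1}})
        with pytest.raises(BioqueryError):
            inferred_ap(["d1"], qrels, "q", 0.5)
        with pytest.raises(BioqueryError):
            inferred_ndcg(["d1"], qrels, "q", 0.5)

    def test_rate_out_of_range(self):
        qrels = Qrels({"q": {"d1": 1}})
        with pytest.raises(BioqueryError):
            inferred_ap(["d1"], qrels, "q", 0.0)
        with pytest.raises(BioqueryError):
            inferred_ndcg(["d1"], qrels, "q", 1.5)


class TestOverlap:
    def test_identical_and_disjoint(self):
        assert overlap_similarity({"a", "b"}, {"a", "b"}) == 1.0
        assert overlap_similarity({"a"}, {"b"}) == 0.0

    def test_formula(self):
        assert overlap_similarity({"a", "b", "c"}, {"b", "c", "d", "e"}) == \
            pytest.approx(2 / 3)

    def test_empty_set_undefined(self):
        with pytest.raises(BioqueryError):
            overlap_similarity(set(), {"a"})


def test_evaluate_runs_report(tmp_path):
    qrels = Qrels({"q1": {"d1": 2, "d2": 0}, "q2": {"d3": 1}})
    runs = {
        "q1": RunRanking("q1", [("d1", 2.0), ("d2", 1.0)]),
        "q2": RunRanking("q2", [("x", 1.0), ("d3", 0.5)]),
    }
    report = evaluate_runs(runs, qrels, precision_ks=(1,))
    assert report.per_query["q1"]["AP"] == 1.0
    assert report.per_query["q2"]["AP"] == 0.5
    assert report.means["MAP"] == pytest.approx(0.75)
    tsv = report.to_tsv()
    assert tsv.startswith("query_id\t") and "mean\t" in tsv


def test_evaluate_runs_skips_unjudged_query():
    qrels = Qrels({"q1": {"d1": 1}})
    runs = {
        "q1": RunRanking("q1", [("d1", 1.0)]),
        "q9": RunRanking("q9", [("d1", 1.0)]),
    }
    with pytest.warns(UserWarning):
        report = evaluate_runs(runs, qrels, precision_ks=(1,))
    assert "q9" not in report.per_query


def test_sampling_sidecar_round_trip(tmp_path):
    rates = {"q1": 0.5, "q2": 1.0}
    path = tmp_path / "sampling.tsv"
    write_sampling_sidecar(rates, path)
    assert read_sampling_sidecar(path) == rates
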