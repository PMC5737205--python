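"""TREC-style evaluation: qrels/run I/O, conventional and inferred metrics,
and the overlap-similarity analysis.

Relevance is graded on a 4-value scale: 2 (relevant), 1 (partially
relevant), 0 (judged irrelevant), -1 (unjudged).  Conventional binary
metrics (P@k, Recall, AP) treat grade >= 1 as relevant and everything else
- including unjudged - as non-relevant.  NDCG uses gain 2^g - 1 over grades
2/1/0 (-1 contributes 0) and a 1/log2(rank+1) discount.

When only a uniformly sampled subset of the judgment pool is graded (the
unsampled remainder is marked -1), the inferred estimators infAP and
infNDCG estimate the fully-judged values:

* infAP replaces the exact precision at each sampled relevant rank by its
  expectation: documents above the rank that are in the pool but unsampled
  are relevant with probability estimated from the sampled pool documents
  above that rank; docs outside the pool are non-relevant.  The per-query
  estimate averages these expected precisions over the sampled relevant
  documents.
* infNDCG estimates DCG by inverse-probability weighting: each sampled
  pool document contributes its discounted gain divided by the sampling
  rate, which is unbiased for the fully-judged DCG because every pool
  document is sampled with the same probability.  The ideal DCG is
  computed from the pool's grade counts scaled up by 1/rate (fractional
  counts are interpolated across ideal rank positions).

Both estimators reduce exactly to AP / NDCG when the sampling rate is 100%.

Term-set similarity uses the overlap coefficient
``Overlap(X1, X2) = |X1 ∩ X2| / min(|X1|, |X2|)``.
"""

from __future__ import annotations

import math
import warnings
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from .errors import BioqueryError, ParseError
from .search import RunRanking

VALID_GRADES = (2, 1, 0, -1)


class Qrels:
    """Graded judgments: query_id -> {doc_id -> grade}."""

    def __init__(self, grades: Mapping[str, Mapping[str, int]] | None = None):
        self.grades: dict[str, dict[str, int]] = {
            qid: dict(docs) for qid, docs in (grades or {}).items()
        }
        for qid, docs in self.grades.items():
            for doc_id, grade in docs.items():
                if grade not in VALID_GRADES:
                    raise BioqueryError(
                        f"grade {grade} for ({qid}, {doc_id}) outside {VALID_GRADES}"
                    )

    def query_ids(self) -> list[str]:
        return sorted(self.grades)

    def grade(self, query_id: str, doc_id: str, default: int = -1) -> int:
        return self.grades.get(query_id, {}).get(doc_id, default)

    def relevant_docs(self, query_id: str) -> set[str]:
        return {
            d for d, g in self.grades.get(query_id, {}).items() if g >= 1
        }

    def num_relevant(self, query_id: str) -> int:
        return len(self.relevant_docs(query_id))


def read_qrels(path: str | Path) -> Qrels:
    """Read 4-column TREC qrels (qid, iteration, docid, grade)."""
    grades: dict[str, dict[str, int]] = {}
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line:
                continue
            parts = line.split()
            if len(parts) != 4:
                raise ParseError("expected 4 whitespace-separated columns", lineno)
            qid, _, doc_id, grade_str = parts
            try:
                grade = int(grade_str)
            except ValueError:
                raise ParseError(f"non-integer grade {grade_str!r}", lineno) from None
            if grade not in VALID_GRADES:
                raise ParseError(f"grade {grade} outside {VALID_GRADES}", lineno)
            grades.setdefault(qid, {})[doc_id] = grade
    return Qrels(grades)


def write_qrels(qrels: Qrels, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for qid in qrels.query_ids():
            for doc_id in sorted(qrels.grades[qid]):
                fh.write(f"{qid} 0 {doc_id} {qrels.grades[qid][doc_id]}\n")


def read_run(path: str | Path) -> dict[str, RunRanking]:
    """Read a 6-column TREC run file; rankings are re-sorted by score
    descending then doc_id ascending, regardless of the stored ranks."""
    items: dict[str, list[tuple[str, float]]] = {}
    tags: dict[str, str] = {}
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line:
                continue
            parts = line.split()
            if len(parts) != 6:
                raise ParseError("expected 6 whitespace-separated columns", lineno)
            qid, _, doc_id, _, score_str, tag = parts
            try:
                score = float(score_str)
            except ValueError:
                raise ParseError(f"non-numeric score {score_str!r}", lineno) from None
            items.setdefault(qid, []).append((doc_id, score))
            tags[qid] = tag
    runs = {}
    for qid, pairs in items.items():
        pairs.sort(key=lambda p: (-p[1], p[0]))
        runs[qid] = RunRanking(qid, pairs, tags[qid])
    return runs


def read_sampling_sidecar(path: str | Path) -> dict[str, float]:
    """TSV sidecar (query_id, sampling rate) for inferred metrics."""
    rates: dict[str, float] = {}
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 2:
                raise ParseError("expected 2 tab-separated columns", lineno)
            rates[parts[0]] = float(parts[1])
    return rates


def write_sampling_sidecar(rates: Mapping[str, float], path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for qid in sorted(rates):
            fh.write(f"{qid}\t{rates[qid]:g}\n")


def _doc_ids(ranking: RunRanking | Sequence[str]) -> list[str]:
    if isinstance(ranking, RunRanking):
        return ranking.doc_ids()
    return list(ranking)


def _grades_for(qrels: Qrels, query_id: str) -> dict[str, int]:
    return qrels.grades.get(query_id, {})


def precision_at_k(
    ranking: RunRanking | Sequence[str], qrels: Qrels, query_id: str, k: int
) -> float:
    """Fraction of the first k ranks holding a grade >= 1 document;
    rankings shorter than k count missing ranks as non-relevant."""
    if k < 1:
        raise BioqueryError("k must be >= 1")
    grades = _grades_for(qrels, query_id)
    docs = _doc_ids(ranking)[:k]
    hits = sum(1 for d in docs if grades.get(d, -1) >= 1)
    return hits / k


def recall(
    ranking: RunRanking | Sequence[str],
    qrels: Qrels,
    query_id: str,
    cutoff: int | None = None,
) -> float:
    """Fraction of the query's relevant documents retrieved within cutoff."""
    total = qrels.num_relevant(query_id)
    if total == 0:
        raise BioqueryError(f"query {query_id!r} has no relevant documents")
    docs = _doc_ids(ranking)
    if cutoff is not None:
        if cutoff == 0:
            return 0.0
        docs = docs[:cutoff]
    grades = _grades_for(qrels, query_id)
    hits = sum(1 for d in docs if grades.get(d, -1) >= 1)
    return hits / total


def average_precision(
    ranking: RunRanking | Sequence[str], qrels: Qrels, query_id: str
) -> float:
    """AP = (1/R) * sum of P@k over the ranks k of relevant documents."""
    total = qrels.num_relevant(query_id)
    if total == 0:
        raise BioqueryError(f"query {query_id!r} has no relevant documents")
    grades = _grades_for(qrels, query_id)
    hits = 0
    acc = 0.0
    for rank, doc_id in enumerate(_doc_ids(ranking), 1):
        if grades.get(doc_id, -1) >= 1:
            hits += 1
            acc += hits / rank
    return acc / total


def _gain(grade: int) -> float:
    return float(2 ** grade - 1) if grade > 0 else 0.0


def ndcg_at_k(
    ranking: RunRanking | Sequence[str],
    qrels: Qrels,
    query_id: str,
    k: int | None = None,
) -> float:
    """NDCG with gain 2^grade - 1 and discount 1/log2(rank + 1); the ideal
    ranking sorts the judged pool's grades descending."""
    grades = _grades_for(qrels, query_id)
    docs = _doc_ids(ranking)
    if k is not None:
        docs = docs[:k]
    dcg = sum(
        _gain(grades.get(doc_id, -1)) / math.log2(rank + 1)
        for rank, doc_id in enumerate(docs, 1)
    )
    ideal = sorted((g for g in grades.values() if g > 0), reverse=True)
    if k is not None:
        ideal = ideal[:k]
    idcg = sum(
        _gain(g) / math.log2(rank + 1) for rank, g in enumerate(ideal, 1)
    )
    if idcg == 0:
        raise BioqueryError(f"query {query_id!r} has an ideal DCG of zero")
    return dcg / idcg


def inferred_ap(
    ranking: RunRanking | Sequence[str],
    qrels: Qrels,
    query_id: str,
    rate: float,
) -> float:
    """Expected-AP estimator under uniform sampling of the judgment pool.

    Pool membership is every (query, doc) pair present in the qrels;
    sampled pairs carry grades {0, 1, 2}, unsampled ones grade -1.  With
    rate = 1 the value equals :func:`average_precision` exactly.
    """
    if not 0 < rate <= 1:
        raise BioqueryError("sampling rate must be in (0, 1]")
    grades = _grades_for(qrels, query_id)
    sampled_relevant = sum(1 for g in grades.values() if g >= 1)
    if sampled_relevant == 0:
        raise BioqueryError(
            f"query {query_id!r} has no sampled relevant documents"
        )
    rel_above = 0       # sampled relevant above current rank
    nonrel_above = 0    # sampled judged-irrelevant above current rank
    unsampled_above = 0  # pool members above current rank without a grade
    acc = 0.0
    for rank, doc_id in enumerate(_doc_ids(ranking), 1):
        grade = grades.get(doc_id)
        if grade is not None and grade >= 1:
            sampled_pool_above = rel_above + nonrel_above
            frac = rel_above / sampled_pool_above if sampled_pool_above else 0.0
            expected_rel_above = rel_above + unsampled_above * frac
            acc += (1.0 + expected_rel_above) / rank
        if grade is None:
            pass
        elif grade == -1:
            unsampled_above += 1
        elif grade >= 1:
            rel_above += 1
        else:
            nonrel_above += 1
    return acc / sampled_relevant


def _ideal_dcg_fractional(grade_masses: list[tuple[int, float]], k: int | None) -> float:
    """Ideal DCG when each grade carries a (possibly fractional) document
    count; mass is consumed one rank position at a time, highest grade
    first, mixing gains inside a position at a fractional boundary."""
    idcg = 0.0
    rank = 1
    carry = 1.0  # remaining capacity of the current rank position
    gain_here = 0.0
    for grade, mass in sorted(grade_masses, reverse=True):
        if grade <= 0:
            continue
        while mass > 1e-12:
            take = min(mass, carry)
            gain_here += take * _gain(grade)
            mass -= take
            carry -= take
            if carry <= 1e-12:
                if k is None or rank <= k:
                    idcg += gain_here / math.log2(rank + 1)
                rank += 1
                carry = 1.0
                gain_here = 0.0
                if k is not None and rank > k:
                    return idcg
    if gain_here > 0 and (k is None or rank <= k):
        idcg += gain_here / math.log2(rank + 1)
    return idcg


def inferred_ndcg(
    ranking: RunRanking | Sequence[str],
    qrels: Qrels,
    query_id: str,
    rate: float,
    k: int | None = None,
) -> float:
    """Expected-NDCG estimator under uniform sampling (see module docs).

    Reduces exactly to :func:`ndcg_at_k` at rate = 1.
    """
    if not 0 < rate <= 1:
        raise BioqueryError("sampling rate must be in (0, 1]")
    grades = _grades_for(qrels, query_id)
    sampled = [g for g in grades.values() if g >= 0]
    if not sampled:
        raise BioqueryError(f"query {query_id!r} has no sampled judgments")
    docs = _doc_ids(ranking)
    if k is not None:
        docs = docs[:k]
    dcg = 0.0
    for rank, doc_id in enumerate(docs, 1):
        grade = grades.get(doc_id)
        if grade is None or grade == -1:
            continue
        dcg += _gain(grade) / (rate * math.log2(rank + 1))
    counts = Counter(g for g in sampled if g > 0)
    masses = [(g, c / rate) for g, c in counts.items()]
    idcg = _ideal_dcg_fractional(masses, k)
    if idcg == 0:
        raise BioqueryError(f"query {query_id!r} has an estimated ideal DCG of zero")
    return dcg / idcg


def overlap_similarity(x1: Iterable[str], x2: Iterable[str]) -> float:
    """Overlap coefficient |X1 ∩ X2| / min(|X1|, |X2|)."""
    s1, s2 = set(x1), set(x2)
    if not s1 or not s2:
        raise BioqueryError("overlap similarity is undefined for empty sets")
    return len(s1 & s2) / min(len(s1), len(s2))


@dataclass
class MetricReport:
    """Per-query metric values and their arithmetic means."""

    per_query: dict[str, dict[str, float]] = field(default_factory=dict)
    means: dict[str, float] = field(default_factory=dict)

    def to_tsv(self) -> str:
        metrics = sorted(self.means)
        lines = ["query_id\t" + "\t".join(metrics)]
        for qid in sorted(self.per_query):
            row = self.per_query[qid]
            lines.append(
                qid + "\t" + "\t".join(
                    f"{row[m]:.4f}" if m in row else "-" for m in metrics
                )
            )
        lines.append(
            "mean\t" + "\t".join(f"{self.means[m]:.4f}" for m in metrics)
        )
        return "\n".join(lines) + "\n"


def evaluate_runs(
    runs: Mapping[str, RunRanking],
    qrels: Qrels,
    precision_ks: Sequence[int] = (10, 100),
    ndcg_k: int | None = None,
    sampling_rates: Mapping[str, float] | None = None,
) -> MetricReport:
    """Evaluate a run per query and average; queries without judgments are
    skipped with a warning, per standard practice."""
    report = MetricReport()
    sums: dict[str, float] = {}
    counts: dict[str, int] = {}
    for qid in sorted(runs):
        if qid not in qrels.grades:
            warnings.warn(f"query {qid!r} absent from qrels; skipped")
            continue
        ranking = runs[qid]
        row: dict[str, float] = {}
        for k in precision_ks:
            row[f"P@{k}"] = precision_at_k(ranking, qrels, qid, k)
        if qrels.num_relevant(qid) > 0:
            row["recall"] = recall(ranking, qrels, qid)
            row["AP"] = average_precision(ranking, qrels, qid)
        else:
            warnings.warn(f"query {qid!r} has no relevant docs; AP/recall skipped")
        try:
            row["NDCG"] = ndcg_at_k(ranking, qrels, qid, ndcg_k)
        except BioqueryError:
            warnings.warn(f"query {qid!r} has zero ideal DCG; NDCG skipped")
        if sampling_rates is not None and qid in sampling_rates:
            rate = sampling_rates[qid]
            try:
                row["infAP"] = inferred_ap(ranking, qrels, qid, rate)
                row["infNDCG"] = inferred_ndcg(ranking, qrels, qid, rate, ndcg_k)
            except BioqueryError:
                warnings.warn(f"query {qid!r}: inferred metrics undefined; skipped")
        report.per_query[qid] = row
        for name, value in row.items():
            sums[name] = sums.get(name, 0.0) + value
            counts[name] = counts.get(name, 0) + 1
    report.means = {
        ("MAP" if name == "AP" else name): sums[name] / counts[name]
        for name in sums
    }
    return report


def overlap_field_statistics(
    query_terms: Mapping[str, set[str]],
    field_terms: Mapping[str, Mapping[str, set[str]]],
    relevant: Mapping[str, set[str]],
) -> list[tuple[str, int, float, float, float]]:
    """Distribution of query <-> relevant-document field overlap per field.

    ``field_terms`` maps field -> doc_id -> term set.  Returns rows of
    (field, n, 25th percentile, median, 75th percentile) suitable for a
    box-plot-style TSV summary.
    """
    import numpy as np

    rows = []
    for name in sorted(field_terms):
        values = []
        docs = field_terms[name]
        for qid, qterms in query_terms.items():
            if not qterms:
                continue
            for doc_id in relevant.get(qid, ()):  # noqa: B905
                dterms = docs.get(doc_id)
                if dterms:
                    values.append(overlap_similarity(qterms, dterms))
        if values:
            q1, med, q3 = np.percentile(values, [25, 50, 75])
            rows.append((name, len(values), float(q1), float(med), float(q3)))
    return rows
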