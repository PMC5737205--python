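"""Query expansion: Rocchio relevance feedback and lexicon-based enrichment.

Rocchio combines the query vector with the centroids of relevant and
irrelevant document vectors::

    Q' = alpha * Q + (beta / |DR|) * sum(dr) - (gamma / |DNR|) * sum(dnr)

with the standard parameterization alpha = 1, beta = 0.5, gamma = 0.1.
Feedback sets come either from pseudo-relevance feedback (the top-k
documents of an initial run, k = 10, treated as relevant; no negative set)
or from a qrels oracle (grade >= 1 relevant, grade 0 irrelevant) that gives
an upper bound on what expansion can achieve.  Document vectors are the
tf-idf vectors of a single source field, the description field by default
since it is the richest source of expansion terms.

The lexicon method skips retrieval entirely: names associated with entities
mentioned in the query (synonyms, acronyms, common denominations) are
ranked by idf, following the intuition that frequent collection terms are
of low utility and rare ones of high utility.

Selected expansion terms (top five by default) are appended unweighted to
the three always-on clauses of the multi-field query; the Q' weights serve
only to rank candidates.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

from .analysis import AnalyzerConfig, DEFAULT_ANALYZER, analyze
from .errors import BioqueryError
from .index import FieldedIndex
from .query_formulation import Lexicon, TaggedQuery
from .search import MultiFieldQuery, QueryClause, search


@dataclass(frozen=True)
class RocchioParams:
    alpha: float = 1.0
    beta: float = 0.5
    gamma: float = 0.1
    prf_k: int = 10
    n_terms: int = 5
    source_field: str = "description"

    def __post_init__(self) -> None:
        if min(self.alpha, self.beta, self.gamma) < 0:
            raise BioqueryError("alpha, beta, gamma must be non-negative")
        if self.prf_k < 1:
            raise BioqueryError("prf_k must be >= 1")
        if self.n_terms < 0:
            raise BioqueryError("n_terms must be >= 0")


@dataclass
class FeedbackSets:
    """Relevant (DR) and irrelevant (DNR) document vectors, keyed by doc_id."""

    relevant: dict[str, dict[str, float]] = field(default_factory=dict)
    irrelevant: dict[str, dict[str, float]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        shared = set(self.relevant) & set(self.irrelevant)
        if shared:
            raise BioqueryError(f"docs in both feedback sets: {sorted(shared)}")


@dataclass
class ExpandedQuery:
    original_terms: list[str]
    expansion_terms: list[tuple[str, float]]
    method: str  # rocchio_prf | rocchio_oracle | lexicon

    def terms(self) -> list[str]:
        return [t for t, _ in self.expansion_terms]


def query_vector(terms: Sequence[str]) -> dict[str, float]:
    """Raw term-count vector of the analyzed query (the Q of Rocchio)."""
    vec: dict[str, float] = {}
    for term in terms:
        vec[term] = vec.get(term, 0.0) + 1.0
    return vec


def rocchio_vector(
    qvec: Mapping[str, float],
    feedback: FeedbackSets,
    params: RocchioParams = RocchioParams(),
) -> dict[str, float]:
    """Combine query and feedback centroids; negative coordinates are
    clamped to zero.  An empty feedback set contributes nothing."""
    out: dict[str, float] = {t: params.alpha * w for t, w in qvec.items()}
    if feedback.relevant:
        coef = params.beta / len(feedback.relevant)
        for vec in feedback.relevant.values():
            for term, w in vec.items():
                out[term] = out.get(term, 0.0) + coef * w
    if feedback.irrelevant:
        coef = params.gamma / len(feedback.irrelevant)
        for vec in feedback.irrelevant.values():
            for term, w in vec.items():
                out[term] = out.get(term, 0.0) - coef * w
    return {t: w for t, w in ((t, max(w, 0.0)) for t, w in out.items())}


def prf_feedback(
    index: FieldedIndex,
    query: MultiFieldQuery,
    params: RocchioParams = RocchioParams(),
) -> FeedbackSets:
    """Pseudo-relevance feedback: source-field vectors of the top prf_k
    documents of an initial run; the negative set stays empty."""
    initial = search(query, index, top_n=params.prf_k)
    relevant = {
        doc_id: index.doc_vector(doc_id, params.source_field)
        for doc_id in initial.doc_ids()
    }
    return FeedbackSets(relevant=relevant, irrelevant={})


def oracle_feedback(
    qrels: "Qrels",  # noqa: F821 - evaluation.Qrels, avoided as a hard import
    query_id: str,
    index: FieldedIndex,
    source_field: str = "description",
) -> FeedbackSets:
    """Judgment-derived feedback: grade >= 1 docs are relevant, grade 0
    irrelevant, grade -1 (unjudged) excluded.  Docs absent from the index
    are skipped."""
    grades = qrels.grades.get(query_id)
    if grades is None:
        raise BioqueryError(f"query {query_id!r} not present in qrels")
    relevant: dict[str, dict[str, float]] = {}
    irrelevant: dict[str, dict[str, float]] = {}
    for doc_id, grade in grades.items():
        if doc_id not in index.labels:
            continue
        if grade >= 1:
            relevant[doc_id] = index.doc_vector(doc_id, source_field)
        elif grade == 0:
            irrelevant[doc_id] = index.doc_vector(doc_id, source_field)
    return FeedbackSets(relevant=relevant, irrelevant=irrelevant)


def select_expansion_terms(
    qprime: Mapping[str, float],
    original_terms: Sequence[str],
    n_terms: int,
    method: str = "rocchio_prf",
) -> ExpandedQuery:
    """Top n_terms new terms by Q' weight (ties: lexicographic order);
    original query terms and non-positive weights are excluded."""
    original = set(original_terms)
    candidates = [
        (term, w) for term, w in qprime.items() if w > 0 and term not in original
    ]
    candidates.sort(key=lambda item: (-item[1], item[0]))
    return ExpandedQuery(
        original_terms=list(original_terms),
        expansion_terms=candidates[: n_terms],
        method=method,
    )


def rocchio_expand(
    index: FieldedIndex,
    query: MultiFieldQuery,
    original_terms: Sequence[str],
    params: RocchioParams = RocchioParams(),
    feedback: FeedbackSets | None = None,
    method: str = "rocchio_prf",
) -> ExpandedQuery:
    """Convenience wrapper: feedback (PRF unless given) -> Q' -> selection."""
    if feedback is None:
        feedback = prf_feedback(index, query, params)
    qprime = rocchio_vector(query_vector(original_terms), feedback, params)
    return select_expansion_terms(qprime, original_terms, params.n_terms, method)


def lexicon_expand(
    tagged: TaggedQuery,
    lexicon: Lexicon,
    index: FieldedIndex,
    source_field: str = "description",
    n_terms: int = 5,
    config: AnalyzerConfig = DEFAULT_ANALYZER,
) -> ExpandedQuery:
    """Expand with associated names of the entities mentioned in the query,
    ranked by idf in the source field (rare terms are of high utility)."""
    candidates: set[str] = set()
    for mention in tagged.mentions:
        entry = lexicon.entries[mention.entry_id]
        for name in entry.all_names():
            candidates.update(analyze(name, config))
    original = set(tagged.analyzed_terms)
    scored = [
        (term, index.idf(term, source_field))
        for term in candidates
        if term not in original
    ]
    scored.sort(key=lambda item: (-item[1], item[0]))
    return ExpandedQuery(
        original_terms=list(tagged.analyzed_terms),
        expansion_terms=scored[:n_terms],
        method="lexicon",
    )


def apply_expansion(
    query: MultiFieldQuery,
    expanded: ExpandedQuery,
    always_on_fields: tuple[str, ...] = ("title", "description", "article_title"),
) -> MultiFieldQuery:
    """Append the expansion terms (boost 1) to the always-on clauses.

    Entity-field clauses are untouched; terms already present in a clause
    are not duplicated, so applying the same expansion twice is a no-op.
    """
    new_terms = expanded.terms()
    if not new_terms:
        return query
    clauses = []
    for clause in query.clauses:
        if clause.field in always_on_fields:
            present = set(clause.terms)
            extra = tuple(t for t in new_terms if t not in present)
            clauses.append(replace(clause, terms=clause.terms + extra))
        else:
            clauses.append(clause)
    return MultiFieldQuery(clauses=clauses, category_filter=query.category_filter)
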