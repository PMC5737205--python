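"""End-to-end experiment harness wiring all modules together.

A *variant* is one retrieval configuration: which query construction to use
(flat field clauses or the entity-aware multi-field builder) and which
expansion method, if any, to apply on top.  ``run_experiment`` executes
every requested variant over a collection and returns one ranking set plus
a metric report per variant; the CLI writes them as TREC run files and
metric TSVs.

Stock variants:

``baseline1``          description field only
``baseline2``          title + description
``multifield``         entity-aware builder (boosts, entity fields, filter)
``multifield-prf``     builder + Rocchio pseudo-relevance feedback
``multifield-oracle``  builder + Rocchio with qrels-derived feedback
``multifield-lexicon`` builder + lexicon idf-ranked expansion

The field-ablation grid (every single field and unordered field pair)
mirrors a one-/two-field query sweep and is available via
:func:`field_ablation_variants`.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field
from itertools import combinations
from typing import Mapping, Sequence

from .analysis import AnalyzerConfig, DEFAULT_ANALYZER, analyze
from .corpus import TEXT_FIELDS, DatasetRecord
from .errors import BioqueryError
from .evaluation import MetricReport, Qrels, evaluate_runs
from .expansion import (
    RocchioParams,
    lexicon_expand,
    apply_expansion,
    oracle_feedback,
    rocchio_expand,
)
from .index import FieldedIndex, build_index
from .query_formulation import (
    BuilderOptions,
    CategoryRuleSet,
    DEFAULT_CATEGORY_RULES,
    Lexicon,
    build_query,
    tag_entities,
)
from .search import MultiFieldQuery, QueryClause, RunRanking, search


@dataclass(frozen=True)
class Variant:
    """One retrieval configuration.

    ``construction`` is ``"fields"`` (flat clauses over ``fields``) or
    ``"builder"``; ``expansion`` is None, ``"rocchio-prf"``,
    ``"rocchio-oracle"`` or ``"lexicon"``.
    """

    name: str
    construction: str = "builder"
    fields: tuple[str, ...] = ()
    expansion: str | None = None


STOCK_VARIANTS = (
    Variant("baseline1", "fields", ("description",)),
    Variant("baseline2", "fields", ("title", "description")),
    Variant("multifield", "builder"),
    Variant("multifield-prf", "builder", expansion="rocchio-prf"),
    Variant("multifield-oracle", "builder", expansion="rocchio-oracle"),
    Variant("multifield-lexicon", "builder", expansion="lexicon"),
)


def field_ablation_variants(
    fields: Sequence[str] = TEXT_FIELDS,
) -> list[Variant]:
    """Single-field and field-pair variants (diagonal + upper triangle)."""
    variants = [Variant(f"field:{f}", "fields", (f,)) for f in fields]
    variants += [
        Variant(f"field:{a}+{b}", "fields", (a, b))
        for a, b in combinations(fields, 2)
    ]
    return variants


@dataclass
class ExperimentConfig:
    analyzer: AnalyzerConfig = DEFAULT_ANALYZER
    builder: BuilderOptions = BuilderOptions()
    category_rules: CategoryRuleSet = dc_field(
        default_factory=lambda: DEFAULT_CATEGORY_RULES
    )
    rocchio: RocchioParams = RocchioParams()
    top_n: int = 100
    precision_ks: tuple[int, ...] = (10, 100)


@dataclass
class VariantResult:
    variant: Variant
    runs: dict[str, RunRanking]
    report: MetricReport
    expansion_terms: dict[str, list[tuple[str, float]]] = dc_field(
        default_factory=dict
    )


def formulate(
    variant: Variant,
    query_id: str,
    text: str,
    lexicon: Lexicon,
    config: ExperimentConfig,
) -> MultiFieldQuery:
    """Build the (unexpanded) multi-field query a variant starts from."""
    if variant.construction == "fields":
        terms = tuple(analyze(text, config.analyzer))
        if not terms:
            raise BioqueryError(f"query {query_id!r} analyzes to no terms")
        return MultiFieldQuery(
            [QueryClause(f, terms) for f in variant.fields]
        )
    if variant.construction == "builder":
        tagged = tag_entities(text, lexicon, config.analyzer, config.category_rules)
        return build_query(tagged, config.analyzer, config.builder)
    raise BioqueryError(f"unknown construction {variant.construction!r}")


def run_variant(
    variant: Variant,
    index: FieldedIndex,
    queries: Sequence[tuple[str, str]],
    lexicon: Lexicon,
    qrels: Qrels | None,
    config: ExperimentConfig = ExperimentConfig(),
) -> VariantResult:
    runs: dict[str, RunRanking] = {}
    chosen_terms: dict[str, list[tuple[str, float]]] = {}
    for qid, text in queries:
        query = formulate(variant, qid, text, lexicon, config)
        if variant.expansion is not None:
            original = list(analyze(text, config.analyzer))
            if variant.expansion == "rocchio-prf":
                expanded = rocchio_expand(
                    index, query, original, config.rocchio, method="rocchio_prf"
                )
            elif variant.expansion == "rocchio-oracle":
                if qrels is None:
                    raise BioqueryError("oracle expansion requires qrels")
                feedback = oracle_feedback(
                    qrels, qid, index, config.rocchio.source_field
                )
                expanded = rocchio_expand(
                    index, query, original, config.rocchio,
                    feedback=feedback, method="rocchio_oracle",
                )
            elif variant.expansion == "lexicon":
                tagged = tag_entities(
                    text, lexicon, config.analyzer, config.category_rules
                )
                expanded = lexicon_expand(
                    tagged, lexicon, index, config.rocchio.source_field,
                    config.rocchio.n_terms, config.analyzer,
                )
            else:
                raise BioqueryError(f"unknown expansion {variant.expansion!r}")
            chosen_terms[qid] = expanded.expansion_terms
            query = apply_expansion(query, expanded)
        runs[qid] = search(
            query, index, top_n=config.top_n, query_id=qid, run_tag=variant.name
        )
    report = (
        evaluate_runs(runs, qrels, config.precision_ks)
        if qrels is not None
        else MetricReport()
    )
    return VariantResult(variant, runs, report, chosen_terms)


def run_experiment(
    records: Sequence[DatasetRecord],
    queries: Sequence[tuple[str, str]],
    lexicon: Lexicon,
    qrels: Qrels | None,
    variants: Sequence[Variant] = STOCK_VARIANTS,
    config: ExperimentConfig = ExperimentConfig(),
    index: FieldedIndex | None = None,
) -> dict[str, VariantResult]:
    """Index once, then execute every variant; returns results by name."""
    if index is None:
        index = build_index(records, config.analyzer)
    return {
        v.name: run_variant(v, index, queries, lexicon, qrels, config)
        for v in variants
    }
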