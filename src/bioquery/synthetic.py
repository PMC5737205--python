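"""Seeded synthetic collections with planted relevance structure.

The generator emulates the shape of a multi-repository biomedical dataset
collection: five repositories with different field masks and categories, a
Zipf-distributed background vocabulary, an entity lexicon (genes, organisms,
diseases) drawn from a disjoint alphabet so that planted signal is
controllable, keyword queries that mention entities and category
key-phrases, and graded qrels in which relevance is planted by controlled
term injection:

* grade-2 (relevant) documents receive ``injection_strength`` query topic
  terms in their title and description, the query's entity names in the
  matching entity fields (where the repository provides them), and the
  query's full *signal vocabulary* - extra terms shared across the query's
  relevant documents that stand in for the topical vocabulary relevant
  datasets share but queries lack;
* grade-1 (partially relevant) documents receive a strict subset: one topic
  term and half of the signal vocabulary, in the description only;
* grade-0 documents are judged but receive no planted terms.

This construction reproduces, by design, the qualitative contrasts the
retrieval pipeline is meant to exploit: query/relevant-description overlap
exceeds query/non-relevant overlap, entity fields discriminate relevant
documents, and relevance feedback can discover the shared signal
vocabulary that the original query misses.

Identical seeds and configs produce byte-identical output files.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from .corpus import DatasetRecord, UNSPECIFIED_CATEGORY
from .errors import BioqueryError
from .evaluation import Qrels
from .query_formulation import Lexicon, LexiconEntry

_SYLLABLES = [
    "ba", "ce", "di", "fo", "gu", "ha", "ke", "li", "mo", "nu",
    "pa", "re", "si", "to", "vu", "wa", "xe", "yi", "zo", "qu",
]


def _background_word(i: int) -> str:
    # Deterministic pseudo-word: 3 syllables from the base-20 digits of i.
    a, rem = divmod(i, 400)
    b, c = divmod(rem, 20)
    return _SYLLABLES[a % 20] + _SYLLABLES[b] + _SYLLABLES[c]


@dataclass(frozen=True)
class RepositorySpec:
    name: str
    category: str
    fields: tuple[str, ...]
    n_docs: int


#: Default repository layout: five repositories, heterogeneous field masks.
DEFAULT_REPOSITORIES = (
    RepositorySpec(
        "clintrials_syn", "Clinical trials",
        ("title", "description", "keywords", "diseases", "treatment"), 400,
    ),
    RepositorySpec(
        "geo_syn", "Gene expression",
        ("title", "description", "keywords", "organisms"), 400,
    ),
    RepositorySpec(
        "pdb_syn", "Protein structure",
        ("title", "description", "keywords", "organisms", "genes",
         "article_title", "article_abstract"), 400,
    ),
    RepositorySpec(
        "pepatlas_syn", "Proteomic data",
        ("title", "description", "organisms", "article_title",
         "article_abstract"), 400,
    ),
    RepositorySpec(
        "bioproj_syn", UNSPECIFIED_CATEGORY,
        ("title", "description", "keywords"), 400,
    ),
)

_CATEGORY_PHRASES = {
    "Gene expression": "gene expression",
    "Clinical trials": "clinical trial",
    "Protein structure": "protein structure",
    "Proteomic data": "proteomic data",
}


@dataclass(frozen=True)
class GeneratorConfig:
    """Study conditions for the synthetic collection.

    Defaults: 5 repositories x 400 documents (2,000 total), a 600-word
    Zipfian background vocabulary, 20 queries, 8 relevant / 6 partially
    relevant / 25 judged-irrelevant documents per query, full judgment
    sampling, 3 injected topic terms and 6 signal-vocabulary terms.
    """

    seed: int = 0
    repositories: tuple[RepositorySpec, ...] = DEFAULT_REPOSITORIES
    n_background_terms: int = 600
    zipf_exponent: float = 1.1
    n_genes: int = 40
    n_organisms: int = 25
    n_diseases: int = 20
    n_queries: int = 20
    n_topic_terms: int = 4
    n_relevant: int = 8
    n_partial: int = 6
    n_judged_nonrelevant: int = 25
    sampling_rate: float = 1.0
    injection_strength: int = 3
    n_signal_terms: int = 6

    def __post_init__(self) -> None:
        if self.injection_strength > self.n_topic_terms:
            raise BioqueryError("injection_strength cannot exceed n_topic_terms")
        if min(self.n_relevant, self.n_partial, self.n_judged_nonrelevant) < 0:
            raise BioqueryError("per-query judgment counts must be >= 0")


@dataclass
class SyntheticCollection:
    records: list[DatasetRecord]
    lexicon: Lexicon
    queries: list[tuple[str, str]]  # (query_id, text)
    qrels: Qrels
    sampling_rates: dict[str, float] = field(default_factory=dict)


def _make_lexicon(config: GeneratorConfig) -> Lexicon:
    entries = []
    for i in range(config.n_genes):
        name = f"zg{_background_word(i)[:4]}{i}"
        entries.append(
            LexiconEntry(
                f"GENE:{i}", "gene", name,
                (f"{name}syn", f"{name}alt"),
            )
        )
    for i in range(config.n_organisms):
        genus = f"zor{_background_word(i)[:4]}{i}"
        entries.append(
            LexiconEntry(
                f"ORG:{i}", "organism", f"{genus} zsp{i}",
                (f"{genus}",),
            )
        )
    for i in range(config.n_diseases):
        name = f"zd{_background_word(i)[:4]}{i}"
        entries.append(
            LexiconEntry(f"DIS:{i}", "disease", name, (f"{name}osis",))
        )
    return Lexicon(entries)


def _zipf_probs(config: GeneratorConfig) -> np.ndarray:
    ranks = np.arange(1, config.n_background_terms + 1, dtype=float)
    p = ranks ** -config.zipf_exponent
    return p / p.sum()


def _sample_words(rng, probs, n: int) -> list[str]:
    idx = rng.choice(len(probs), size=n, p=probs)
    return [_background_word(int(i)) for i in idx]


def _base_record(
    rng, probs, repo: RepositorySpec, doc_id: str, lexicon: Lexicon
) -> DatasetRecord:
    organisms = [
        e.canonical_name
        for e in (
            lexicon.entries[f"ORG:{int(i)}"]
            for i in rng.choice(
                sum(1 for k in lexicon.entries if k.startswith("ORG:")),
                size=int(rng.integers(1, 3)),
                replace=False,
            )
        )
    ]
    n_genes_avail = sum(1 for k in lexicon.entries if k.startswith("GENE:"))
    genes = [
        lexicon.entries[f"GENE:{int(i)}"].canonical_name
        for i in rng.choice(n_genes_avail, size=int(rng.integers(0, 3)), replace=False)
    ]
    diseases = [
        lexicon.entries[f"DIS:{int(i)}"].canonical_name
        for i in rng.choice(
            sum(1 for k in lexicon.entries if k.startswith("DIS:")),
            size=int(rng.integers(1, 3)),
            replace=False,
        )
    ]
    fields: dict[str, str | list[str]] = {}
    for name in repo.fields:
        if name == "title":
            fields[name] = " ".join(_sample_words(rng, probs, int(rng.integers(5, 9))))
        elif name == "description":
            fields[name] = " ".join(_sample_words(rng, probs, int(rng.integers(25, 41))))
        elif name == "keywords":
            fields[name] = _sample_words(rng, probs, int(rng.integers(3, 6)))
        elif name == "organisms":
            fields[name] = organisms
        elif name == "genes":
            if genes:  # individual docs may leave a provided field empty
                fields[name] = genes
        elif name == "article_title":
            fields[name] = " ".join(_sample_words(rng, probs, int(rng.integers(6, 11))))
        elif name == "article_abstract":
            fields[name] = " ".join(_sample_words(rng, probs, int(rng.integers(30, 51))))
        elif name == "diseases":
            fields[name] = " ".join(diseases)
        elif name == "treatment":
            fields[name] = " ".join(_sample_words(rng, probs, int(rng.integers(4, 9))))
    return DatasetRecord(
        doc_id=doc_id, repository=repo.name, category=repo.category, fields=fields
    )


def _append(record: DatasetRecord, name: str, extra: str) -> None:
    if name not in record.fields:
        return
    value = record.fields[name]
    if isinstance(value, list):
        value.append(extra)
    else:
        record.fields[name] = f"{value} {extra}"


def generate_collection(config: GeneratorConfig) -> SyntheticCollection:
    """Generate records, lexicon, queries and graded qrels (see module docs)."""
    rng = np.random.default_rng(config.seed)
    probs = _zipf_probs(config)
    lexicon = _make_lexicon(config)

    records: list[DatasetRecord] = []
    by_repo: dict[str, list[int]] = {}
    for repo in config.repositories:
        for j in range(repo.n_docs):
            doc_id = f"{repo.name}-{j:05d}"
            by_repo.setdefault(repo.name, []).append(len(records))
            records.append(_base_record(rng, probs, repo, doc_id, lexicon))

    unplanted = set(range(len(records)))
    queries: list[tuple[str, str]] = []
    grades: dict[str, dict[str, int]] = {}
    categories = [
        "Gene expression", "Protein structure", "Proteomic data",
        "Clinical trials", None,
    ]

    # Topic terms come from the mid-frequency range of the background
    # vocabulary: common enough to collide with non-relevant documents,
    # rare enough that co-occurrence of several is a relevance signal.
    topic_lo, topic_hi = 60, min(350, config.n_background_terms)

    for q in range(config.n_queries):
        qid = f"q{q + 1:02d}"
        category = categories[q % len(categories)]
        eligible_repos = [
            r for r in config.repositories
            if category is None
            or r.category == category
            or r.category == UNSPECIFIED_CATEGORY
        ]
        eligible = sorted(
            i for r in eligible_repos for i in by_repo[r.name] if i in unplanted
        )
        needed = config.n_relevant + config.n_partial
        if needed > len(eligible):
            raise BioqueryError(
                f"query {qid}: {needed} planted docs requested but only "
                f"{len(eligible)} eligible documents remain"
            )

        topic_idx = rng.choice(
            np.arange(topic_lo, topic_hi), size=config.n_topic_terms, replace=False
        )
        topic = [_background_word(int(i)) for i in topic_idx]
        gene = lexicon.entries[f"GENE:{int(rng.integers(config.n_genes))}"]
        organism = lexicon.entries[f"ORG:{int(rng.integers(config.n_organisms))}"]
        signal = [f"sig{q:02d}n{j}" for j in range(config.n_signal_terms)]

        phrase = _CATEGORY_PHRASES.get(category, "") if category else ""
        text = " ".join(
            w for w in (
                ["find"] + ([phrase] if phrase else []) + ["data on",
                 gene.canonical_name, "in", organism.canonical_name] + topic
            ) if w
        )
        queries.append((qid, text))

        chosen = rng.choice(len(eligible), size=needed, replace=False)
        planted = [eligible[int(i)] for i in chosen]
        rel_docs = planted[: config.n_relevant]
        partial_docs = planted[config.n_relevant:]
        unplanted.difference_update(planted)
        qgrades: dict[str, int] = {}

        for i in rel_docs:
            record = records[i]
            _append(record, "title", " ".join(topic[: config.injection_strength]))
            # Descriptions name the entities by canonical name or synonym,
            # the way real metadata mixes denominations; the lexicon
            # expansion method exists to bridge exactly this gap.
            gene_name = gene.all_names()[int(rng.integers(len(gene.all_names())))]
            org_names = organism.all_names()
            org_name = org_names[int(rng.integers(len(org_names)))]
            _append(
                record, "description",
                " ".join(topic) + " " + gene_name + " "
                + org_name + " " + " ".join(signal),
            )
            _append(record, "organisms", organism.canonical_name)
            _append(record, "genes", gene.canonical_name)
            _append(record, "article_title",
                    " ".join(topic[:2]) + " " + gene.canonical_name)
            qgrades[record.doc_id] = 2

        half = config.n_signal_terms // 2
        for i in partial_docs:
            record = records[i]
            _append(record, "description", topic[0] + " " + " ".join(signal[:half]))
            qgrades[record.doc_id] = 1

        pool = sorted(
            i for r in eligible_repos for i in by_repo[r.name]
            if records[i].doc_id not in qgrades
        )
        n_nonrel = min(config.n_judged_nonrelevant, len(pool))
        for i in rng.choice(len(pool), size=n_nonrel, replace=False):
            qgrades[records[pool[int(i)]].doc_id] = 0
        grades[qid] = qgrades

    qrels = Qrels(grades)
    rates = {qid: 1.0 for qid, _ in queries}
    if config.sampling_rate < 1.0:
        qrels, rates = sample_judgments(
            qrels, config.sampling_rate, int(rng.integers(2**31))
        )
    return SyntheticCollection(records, lexicon, queries, qrels, rates)


def sample_judgments(
    qrels: Qrels, rate: float, seed: int
) -> tuple[Qrels, dict[str, float]]:
    """Keep each judged pair independently with probability ``rate``;
    dropped pairs stay in the pool with grade -1.  Returns the sampled
    qrels and the per-query rate sidecar; rate = 1 is the identity."""
    if not 0 < rate <= 1:
        raise BioqueryError("sampling rate must be in (0, 1]")
    rng = np.random.default_rng(seed)
    sampled: dict[str, dict[str, int]] = {}
    for qid in qrels.query_ids():
        docs = qrels.grades[qid]
        sampled[qid] = {}
        for doc_id in sorted(docs):
            grade = docs[doc_id]
            if grade == -1 or rng.random() < rate:
                sampled[qid][doc_id] = grade
            else:
                sampled[qid][doc_id] = -1
    return Qrels(sampled), {qid: rate for qid in sampled}


def write_queries(queries: Sequence[tuple[str, str]], path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for qid, text in queries:
            fh.write(f"{qid}\t{text}\n")


def read_queries(path: str | Path) -> list[tuple[str, str]]:
    queries = []
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line:
                continue
            qid, text = line.split("\t", 1)
            queries.append((qid, text))
    return queries
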