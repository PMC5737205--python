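"""Query understanding: category identification, entity tagging, and the
boosted multi-field query builder.

A free-text keyword query is (i) scanned for category key-phrases ("gene
expression", "clinical trial", ...) that reveal which data category it
targets, (ii) tagged for gene/organism/disease mentions by longest-match
dictionary lookup against a biomedical lexicon (names and synonyms drawn
from resources of the NCBI-gene / NCBI-taxonomy / UMLS kind), and then
(iii) compiled into a multi-field query:

* title, description and article_title are always targeted with the full
  set of analyzed query terms;
* the organisms field is targeted with the organism names when organisms
  are mentioned, the genes field with the gene names when genes are
  mentioned, each with boost 2;
* concept (entity-mention) terms inside the three always-on clauses also
  carry boost 2;
* an identified category becomes a hard category filter.

Disease mentions do not add a diseases-field clause by default: querying
the sparsely and generically populated disease-based fields consistently
degrades retrieval, so disease terms only receive the concept boost (the
clause can be re-enabled via :class:`BuilderOptions`).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

from .analysis import AnalyzerConfig, DEFAULT_ANALYZER, analyze, tokenize_with_spans
from .errors import BioqueryError, ParseError
from .search import MultiFieldQuery, QueryClause

ENTITY_TYPES = ("gene", "organism", "disease")


@dataclass(frozen=True)
class LexiconEntry:
    entry_id: str
    entity_type: str
    canonical_name: str
    synonyms: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.entity_type not in ENTITY_TYPES:
            raise BioqueryError(f"unknown entity type: {self.entity_type!r}")
        if not self.canonical_name:
            raise BioqueryError("canonical_name must be non-empty")

    def all_names(self) -> tuple[str, ...]:
        return (self.canonical_name,) + self.synonyms


class Lexicon:
    """Dictionary of biomedical entities keyed by lowercased name phrases."""

    def __init__(self, entries: Iterable[LexiconEntry]):
        self.entries: dict[str, LexiconEntry] = {}
        # lowercased word-tuple -> entry_id (canonical names and synonyms)
        self._phrases: dict[tuple[str, ...], str] = {}
        for entry in entries:
            if entry.entry_id in self.entries:
                raise BioqueryError(f"duplicate lexicon entry: {entry.entry_id!r}")
            self.entries[entry.entry_id] = entry
            for name in entry.all_names():
                words = tuple(w.lower() for w, _, _ in tokenize_with_spans(name))
                if words:
                    self._phrases.setdefault(words, entry.entry_id)
        self.max_phrase_len = max((len(p) for p in self._phrases), default=0)

    def __len__(self) -> int:
        return len(self.entries)

    def lookup(self, words: tuple[str, ...]) -> LexiconEntry | None:
        entry_id = self._phrases.get(words)
        return self.entries[entry_id] if entry_id is not None else None

    @classmethod
    def from_tsv(cls, path: str | Path) -> "Lexicon":
        """Load from TSV: entry_id, entity_type, canonical_name,
        pipe-separated synonyms (the 4th column may be empty)."""
        entries = []
        with open(path, encoding="utf-8") as fh:
            for lineno, line in enumerate(fh, 1):
                line = line.rstrip("\n")
                if not line or line.startswith("#"):
                    continue
                parts = line.split("\t")
                if len(parts) < 3:
                    raise ParseError("expected >= 3 tab-separated columns", lineno)
                entry_id, entity_type, canonical = parts[0], parts[1], parts[2]
                synonyms: tuple[str, ...] = ()
                if len(parts) > 3 and parts[3]:
                    synonyms = tuple(s for s in parts[3].split("|") if s)
                entries.append(
                    LexiconEntry(entry_id, entity_type, canonical, synonyms)
                )
        return cls(entries)

    def write_tsv(self, path: str | Path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            for entry_id in sorted(self.entries):
                e = self.entries[entry_id]
                fh.write(
                    f"{e.entry_id}\t{e.entity_type}\t{e.canonical_name}\t"
                    f"{'|'.join(e.synonyms)}\n"
                )


@dataclass(frozen=True)
class EntityMention:
    surface: str
    start: int
    end: int
    entity_type: str
    entry_id: str


@dataclass
class TaggedQuery:
    raw_text: str
    analyzed_terms: list[str]
    mentions: list[EntityMention] = field(default_factory=list)
    category: str | None = None

    def mentions_of(self, entity_type: str) -> list[EntityMention]:
        return [m for m in self.mentions if m.entity_type == entity_type]


@dataclass
class CategoryRuleSet:
    """Ordered (key-phrase, category) rules; the first match wins."""

    rules: list[tuple[str, str]]

    def __post_init__(self) -> None:
        self.rules = [(phrase.lower(), cat) for phrase, cat in self.rules]


#: Default key-phrase -> category rules for the stock data categories.
DEFAULT_CATEGORY_RULES = CategoryRuleSet(
    [
        ("gene expression", "Gene expression"),
        ("clinical trial", "Clinical trials"),
        ("protein structure", "Protein structure"),
        ("proteomic data", "Proteomic data"),
        ("protein sequencing", "Proteomic data"),
        ("imaging data", "Imaging data"),
        ("physiological signal", "Physiological signals"),
        ("phenotype data", "Phenotype"),
    ]
)


def identify_category(
    raw_text: str, rules: CategoryRuleSet = DEFAULT_CATEGORY_RULES
) -> str | None:
    """First rule whose key-phrase occurs as a case-insensitive substring of
    the whitespace-normalized query, or None."""
    normalized = " ".join(raw_text.lower().split())
    for phrase, category in rules.rules:
        if phrase in normalized:
            return category
    return None


def tag_entities(
    raw_text: str,
    lexicon: Lexicon,
    config: AnalyzerConfig = DEFAULT_ANALYZER,
    rules: CategoryRuleSet = DEFAULT_CATEGORY_RULES,
) -> TaggedQuery:
    """Longest-match, case-insensitive dictionary tagging over the lexicon.

    Matching proceeds left to right over the query's tokens; at each
    position the longest name phrase in the dictionary wins and shorter
    overlapping matches are suppressed.
    """
    tokens = tokenize_with_spans(raw_text)
    words = [w.lower() for w, _, _ in tokens]
    mentions: list[EntityMention] = []
    i = 0
    while i < len(tokens):
        match = None
        for length in range(min(lexicon.max_phrase_len, len(tokens) - i), 0, -1):
            entry = lexicon.lookup(tuple(words[i : i + length]))
            if entry is not None:
                match = (length, entry)
                break
        if match is None:
            i += 1
            continue
        length, entry = match
        start = tokens[i][1]
        end = tokens[i + length - 1][2]
        mentions.append(
            EntityMention(raw_text[start:end], start, end, entry.entity_type, entry.entry_id)
        )
        i += length
    return TaggedQuery(
        raw_text=raw_text,
        analyzed_terms=analyze(raw_text, config),
        mentions=mentions,
        category=identify_category(raw_text, rules),
    )


@dataclass(frozen=True)
class BuilderOptions:
    """Multi-field builder knobs.

    concept_boost is the multiplicative boost on entity-mention terms (and
    on the dedicated entity-field clauses); target_disease_field re-enables
    the diseases-field clause for disease mentions.
    """

    concept_boost: float = 2.0
    target_disease_field: bool = False
    always_on_fields: tuple[str, ...] = ("title", "description", "article_title")


def build_query(
    tagged: TaggedQuery,
    config: AnalyzerConfig = DEFAULT_ANALYZER,
    options: BuilderOptions = BuilderOptions(),
) -> MultiFieldQuery:
    """Compile a tagged query into the boosted multi-field query."""
    if not tagged.analyzed_terms:
        raise BioqueryError("cannot build a query from an empty analyzed query")

    def mention_terms(entity_type: str) -> list[str]:
        terms: list[str] = []
        for mention in tagged.mentions_of(entity_type):
            for term in analyze(mention.surface, config):
                if term not in terms:
                    terms.append(term)
        return terms

    concept_terms: set[str] = set()
    for etype in ENTITY_TYPES:
        concept_terms.update(mention_terms(etype))

    term_boosts = {
        t: options.concept_boost for t in concept_terms if t in tagged.analyzed_terms
    }
    clauses = [
        QueryClause(
            field=name,
            terms=tuple(tagged.analyzed_terms),
            boost=1.0,
            term_boosts=dict(term_boosts),
        )
        for name in options.always_on_fields
    ]
    organism_terms = mention_terms("organism")
    if organism_terms:
        clauses.append(
            QueryClause("organisms", tuple(organism_terms), boost=options.concept_boost)
        )
    gene_terms = mention_terms("gene")
    if gene_terms:
        clauses.append(
            QueryClause("genes", tuple(gene_terms), boost=options.concept_boost)
        )
    if options.target_disease_field:
        disease_terms = mention_terms("disease")
        if disease_terms:
            clauses.append(
                QueryClause("diseases", tuple(disease_terms), boost=options.concept_boost)
            )
    category_filter = frozenset({tagged.category}) if tagged.category else None
    return MultiFieldQuery(clauses=clauses, category_filter=category_filter)


def format_query(query: MultiFieldQuery) -> str:
    """Readable clause syntax, e.g. ``title:(protein chey^2)^1 ...``."""
    parts = []
    for clause in query.clauses:
        terms = " ".join(
            f"{t}^{clause.term_boosts[t]:g}" if t in clause.term_boosts else t
            for t in clause.unique_terms()
        )
        parts.append(f"{clause.field}:({terms})^{clause.boost:g}")
    if query.category_filter:
        cats = ",".join(sorted(query.category_filter))
        parts.append(f"category_filter:[{cats}]")
    return " ".join(parts)
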