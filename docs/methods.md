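# Methods

This note documents the models and procedures `bioquery` implements, the
parameters that matter, the numerical choices that were genuinely open,
and what the synthetic-data experiments do and do not demonstrate.

## Data model

A dataset record is one repository entry described by a subset of a closed
11-field vocabulary: nine analyzable text fields (`title`, `description`,
`keywords`, `organisms`, `article_title`, `article_abstract`, `genes`,
`diseases`, `treatment`) and two stored labels (`repository`, `category`).
Fields a repository does not provide are *absent* from the record rather
than empty, so field-presence statistics over a collection reflect the
schema registry's masks.  `keywords`, `organisms` and `genes` are phrase
lists in the canonical JSON-lines format and are space-joined only at
analysis time, which preserves phrase boundaries for dictionary tagging.

Parsing heterogeneous source layouts is configuration, not code: a YAML
schema registry maps per-repository source paths (JSON keys or XML tags)
to canonical field names and assigns each repository exactly one category.
Records with associated article identifiers (PMIDs) can be joined against
a three-column article table; when several articles link to one record
their titles and abstracts are concatenated in ascending PMID string
order, a deterministic convention chosen because no natural ordering
exists among a record's articles.

## Analysis and indexing

Analysis is: split on non-alphanumeric characters, lowercase, remove the
classic 33-word English stop list, Porter-stem.  Pure-digit and mixed
alphanumeric tokens are kept so gene symbols like `BeF3` survive.  The
stemmer is the classic 1980 Porter algorithm, implemented in-package and
pinned by a table of known stem pairs; stop list and stemmer are
configurable (`AnalyzerConfig`) since reasonable engines differ here.

The index keeps, per field: postings `term → {doc → tf}`, document
frequency, field length in tokens, and the collection size `N`.
`idf(t, f) = 1 + ln(N / (df(t, f) + 1))`, the classic practical form,
defined for unseen terms (df = 0) and strictly positive for every
`N ≥ 1`.  Persistence is a directory of sorted-key JSON/TSV files, so
identical indexes serialize byte-identically; `stats_dump()` is the
canonical fingerprint used for determinism checks.

## Scoring

The ranking function is the classic practical vector-space formula of the
Lucene family, written out so every score is reproducible by hand:

    score(q, d) = coord(q, d) · Σ_{c, t matched} √tf(t,d,c.field)
                  · idf(t, c.field)² · boost(c, t) · 1/√len(d, c.field)

where `coord` is the fraction of (clause, term) pairs matching the
document.  Two deliberate deviations from the engine tradition, both
documented because they affect absolute scores but not conclusions: the
per-query normalization constant is omitted (it is constant within a
query, hence rank-invariant), and the field-length norm is the exact
`1/√len` rather than a byte-quantized approximation (reproducibility over
bug-compatibility).  Semantics are purely disjunctive; ties are broken by
ascending doc_id.

The category filter is a hard candidate filter that always admits
documents whose category is `Unspecified`: repositories of unknown data
type can hold relevant datasets for any query, so excluding them only
loses recall.

## Query formulation

Category identification is a first-match-wins scan of ordered
(key-phrase, category) rules over the whitespace-normalized, lowercased
query.  Entity tagging is longest-match, case-insensitive dictionary
lookup over the lexicon's canonical names and synonyms; overlapping
shorter matches are suppressed.  A dictionary tagger (rather than
statistical NER) keeps the artifact self-contained and deterministic, and
operates over exactly the same lexicon the expansion method uses.

The builder emits clauses: the three always-on fields (`title`,
`description`, `article_title`) with all query terms; `organisms` and
`genes` clauses with the respective mention terms when present; concept
(entity) terms carry a ×2 boost both inside the always-on clauses and as
clause boosts.  The boost factor defaults to 2 and is configurable.
Disease mentions deliberately do **not** target the `diseases` field by
default: the disease-oriented fields are sparsely populated and dominated
by generic terms ("cancer", "tumor"), and routing disease terms at them
degrades retrieval sharply; disease terms still receive the concept boost
in the always-on clauses.  The clause is available behind
`BuilderOptions(target_disease_field=True)` for ablation.

## Query expansion

Rocchio combines the query vector (raw term counts) with feedback
centroids:

    Q' = α·Q + (β/|DR|)·Σ d_r − (γ/|DNR|)·Σ d_nr

with α = 1, β = 0.5, γ = 0.1 — the standard parameterization for this
formula.  Document vectors are raw-tf × idf over a single source field,
`description` by default (the best expansion source; `title` and the
lexicon are the alternatives).  Negative coordinates after combination are
clamped to zero, the standard convention for query vectors.  PRF feedback
takes the top k = 10 documents of an initial run as DR and leaves DNR
empty (pseudo-relevance semantics); oracle feedback partitions judged
documents by grade (≥ 1 relevant, 0 irrelevant, −1 excluded) and bounds
from above what expansion could achieve.

The top m = 5 candidate terms by Q' weight — excluding original query
terms, ties broken lexicographically — are appended *unweighted* to the
three always-on clauses.  Appending rather than weighting keeps expanded
queries expressible in any engine's plain query syntax; the Q' weights
serve only for selection.  Expansion terms are analyzed (stemmed) terms,
matching the index vocabulary.

Lexicon expansion skips retrieval entirely: all names associated with
entities mentioned in the query are analyzed and ranked by
`idf(term, source_field)` — frequent collection terms are of low utility,
rare ones of high utility — and the top m new terms are appended the same
way.  It is by construction cheaper than Rocchio (no initial run, no
feedback vectors), the trade-off being that it can only bridge
vocabulary gaps the lexicon knows about.

## Evaluation

Grades: 2 relevant, 1 partially relevant, 0 judged irrelevant, −1
unjudged.  Binary metrics (P@k, Recall, AP) treat grade ≥ 1 as relevant
and everything else as non-relevant.  NDCG uses gain `2^g − 1` and
discount `1/log₂(rank+1)`, the common convention, with the ideal ranking
drawn from the judged pool.  Rankings shorter than a cutoff are padded
with non-relevant; queries without relevant documents are excluded from
AP/Recall means with a warning.

### Inferred metrics

When only a uniform random fraction `p` of the judgment pool is graded
(unsampled pool members are marked −1), two estimators recover the
fully-judged values in expectation:

* **infAP** replaces the precision at each sampled relevant rank by its
  expectation: pool documents above the rank that were not sampled are
  relevant with probability estimated from the sampled pool documents
  above that rank (0 if none); documents outside the pool are
  non-relevant.  The per-query value averages these expected precisions
  over sampled relevant documents.
* **infNDCG** estimates DCG by inverse-probability weighting — each
  sampled pool document contributes `gain/(p·log₂(rank+1))`, which is
  exactly unbiased for the pool DCG under uniform sampling — and
  estimates the ideal DCG from the pool's grade counts scaled by `1/p`,
  interpolating fractional counts across ideal rank positions.

Both reduce *exactly* to AP/NDCG at `p = 1` (verified to 1e-12), and
Monte-Carlo means over 10,000 half-sampled judgment sets on a fixed
200-document query land within 0.02 (infAP) and 0.03 (infNDCG) of the
fully-judged values.  These two properties — exact reduction and
approximate unbiasedness — are the estimators' contract; they are ratio
estimators, so exact unbiasedness is not claimed.

Term-set similarity throughout is the overlap coefficient
`|X1∩X2| / min(|X1|,|X2|)`, undefined (an error) on empty sets.

## Synthetic collections

The generator emulates the *structure* of a heterogeneous dataset
collection, not biomedical language.  Defaults (the study conditions for
all directional experiments): five repositories × 400 documents with
repository-specific field masks and categories (clinical trials, gene expression,
protein structure, proteomics, unspecified); a 600-word background
vocabulary of pseudo-words sampled Zipf(1.1); an entity lexicon (40
genes, 25 organisms, 20 diseases, each with synonyms) on a disjoint
alphabet so planted signal never collides with background text; 20
queries, each mentioning one gene and one organism, four mid-frequency
topic terms, and (in four of five queries) a category key-phrase; per
query 8 relevant, 6 partially relevant and 25 judged-irrelevant
documents, full judgment sampling unless configured otherwise.

Relevance is planted, not discovered: relevant documents receive 3 topic
terms in the title, all topic terms plus entity names in the description
(naming entities by canonical name or synonym at random — the gap lexicon
expansion exists to bridge), entity names in the matching entity fields,
and a six-term per-query *signal vocabulary* shared across the query's
relevant documents; partially relevant documents receive a strict subset
(one topic term, half the signal terms, description only); judged
irrelevant documents receive nothing.  The signal vocabulary models the
topical vocabulary relevant datasets share but queries lack — precisely
the quantity relevance feedback can discover — and the mid-frequency topic
terms guarantee enough background collisions that the baselines retrieve
false positives for the builder and the expansion to beat.

Because signal is planted on a disjoint alphabet, the directional
comparisons (baseline < builder < builder+PRF; oracle ≥ PRF) are reliable
across seeds rather than flaky.  That is the intended trade-off: passing
these experiments shows the pipeline exploits field structure, entity
mentions, category filters and shared relevant-document vocabulary when
they exist; it does not show how large those effects are on real
collections, where the effects are entangled with real language and much
lower signal-to-noise.  Absolute metric values on synthetic collections
are far higher than any real collection would yield and are meaningful
only relative to each other.

Problem sizes (2,000 documents, 20 queries, 10 seeds for directional
checks) were chosen so the complete harness runs in seconds on one CPU
while leaving each query ~100 judged documents — large enough for stable
MAP differences.

## Known limitations

* The scorer implements one fixed TF-IDF variant; BM25 and probabilistic
  models are out of scope, as are phrase/proximity operators and
  re-ranking.
* Entity tagging is dictionary lookup: no disambiguation, no
  abbreviation resolution, no fuzzy matching.
* The inferred estimators assume uniform sampling within the judgment
  pool; stratified pools are supported only through per-query rates.
* The synthetic generator does not model realistic biomedical language,
  collection-scale vocabulary distributions, or judgment noise.
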