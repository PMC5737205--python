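"""Per-field inverted index with the collection statistics scoring needs.

Each of the nine analyzable text fields gets its own postings so fields can
be queried and boosted independently; repository and category are stored as
per-document labels used for filtering.  Statistics kept per field: postings
term -> {doc -> tf}, document frequency, field length (token count) per
document, and the collection size N.

idf uses the classic practical form ``1 + ln(N / (df + 1))``; df = 0 is
allowed (unseen terms still get a finite weight).
"""

from __future__ import annotations

import json
import math
from collections import Counter
from pathlib import Path
from typing import Iterable

from .analysis import AnalyzerConfig, DEFAULT_ANALYZER, analyze
from .corpus import TEXT_FIELDS, DatasetRecord
from .errors import BioqueryError, UndefinedStatisticsError


class FieldedIndex:
    """In-memory fielded inverted index over a dataset collection."""

    def __init__(self) -> None:
        # field -> term -> {doc_id: tf}
        self.postings: dict[str, dict[str, dict[str, int]]] = {}
        # field -> doc_id -> token count
        self.field_lengths: dict[str, dict[str, int]] = {}
        # doc_id -> (repository, category)
        self.labels: dict[str, tuple[str, str]] = {}
        # field -> doc_id -> Counter(term -> tf); forward view for vectors
        self._forward: dict[str, dict[str, Counter]] = {}

    # -- construction ----------------------------------------------------

    def add_document(
        self,
        record: DatasetRecord,
        config: AnalyzerConfig = DEFAULT_ANALYZER,
    ) -> None:
        if record.doc_id in self.labels:
            raise BioqueryError(f"duplicate doc_id: {record.doc_id!r}")
        self.labels[record.doc_id] = (record.repository, record.category)
        for name in record.fields:
            tokens = analyze(record.field_text(name), config)
            self.field_lengths.setdefault(name, {})[record.doc_id] = len(tokens)
            counts = Counter(tokens)
            self._forward.setdefault(name, {})[record.doc_id] = counts
            field_postings = self.postings.setdefault(name, {})
            for term, tf in counts.items():
                field_postings.setdefault(term, {})[record.doc_id] = tf

    # -- statistics ------------------------------------------------------

    @property
    def n_docs(self) -> int:
        return len(self.labels)

    def df(self, term: str, field: str) -> int:
        return len(self.postings.get(field, {}).get(term, {}))

    def idf(self, term: str, field: str) -> float:
        if self.n_docs == 0:
            raise UndefinedStatisticsError("idf undefined on an empty index")
        return 1.0 + math.log(self.n_docs / (self.df(term, field) + 1))

    def tf(self, term: str, doc_id: str, field: str) -> int:
        return self.postings.get(field, {}).get(term, {}).get(doc_id, 0)

    def field_length(self, doc_id: str, field: str) -> int | None:
        """Token count of (doc, field); None if the field is absent."""
        return self.field_lengths.get(field, {}).get(doc_id)

    def vocabulary(self, field: str) -> list[str]:
        return sorted(self.postings.get(field, {}))

    def doc_terms(self, doc_id: str, field: str) -> Counter:
        if doc_id not in self.labels:
            raise BioqueryError(f"unknown doc_id: {doc_id!r}")
        return self._forward.get(field, {}).get(doc_id, Counter())

    def doc_vector(self, doc_id: str, field: str) -> dict[str, float]:
        """TF-IDF document vector of one field (raw tf times idf).

        This is the document representation fed to the Rocchio relevance
        feedback combination; an absent or empty field yields an empty map.
        """
        return {
            term: tf * self.idf(term, field)
            for term, tf in self.doc_terms(doc_id, field).items()
        }

    def category(self, doc_id: str) -> str:
        return self.labels[doc_id][1]

    # -- persistence -----------------------------------------------------

    def save(self, directory: str | Path) -> None:
        """Persist to a directory: postings.json, lengths.json, labels.tsv,
        meta.json.  All maps are emitted with sorted keys so identical
        indexes serialize byte-identically."""
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        with open(directory / "postings.json", "w") as fh:
            json.dump(self.postings, fh, sort_keys=True)
        with open(directory / "lengths.json", "w") as fh:
            json.dump(self.field_lengths, fh, sort_keys=True)
        with open(directory / "labels.tsv", "w") as fh:
            for doc_id in sorted(self.labels):
                repo, category = self.labels[doc_id]
                fh.write(f"{doc_id}\t{repo}\t{category}\n")
        with open(directory / "meta.json", "w") as fh:
            json.dump({"n_docs": self.n_docs, "fields": sorted(self.postings)}, fh)

    @classmethod
    def load(cls, directory: str | Path) -> "FieldedIndex":
        directory = Path(directory)
        index = cls()
        with open(directory / "postings.json") as fh:
            index.postings = json.load(fh)
        with open(directory / "lengths.json") as fh:
            index.field_lengths = json.load(fh)
        with open(directory / "labels.tsv") as fh:
            for line in fh:
                doc_id, repo, category = line.rstrip("\n").split("\t")
                index.labels[doc_id] = (repo, category)
        for name, by_term in index.postings.items():
            forward: dict[str, Counter] = {}
            for term, docs in by_term.items():
                for doc_id, tf in docs.items():
                    forward.setdefault(doc_id, Counter())[term] = tf
            index._forward[name] = forward
        return index

    def stats_dump(self) -> str:
        """Deterministic TSV dump of collection statistics.

        First a header block (N, per-field vocabulary size and total
        length), then the per-field df table.  Used both by the ``stats``
        CLI subcommand and as the byte-comparable index fingerprint.
        """
        lines = [f"#n_docs\t{self.n_docs}"]
        for name in sorted(self.postings):
            vocab = self.vocabulary(name)
            total_len = sum(self.field_lengths.get(name, {}).values())
            lines.append(f"#field\t{name}\t{len(vocab)}\t{total_len}")
        for name in sorted(self.postings):
            for term in self.vocabulary(name):
                lines.append(f"{name}\t{term}\t{self.df(term, name)}")
        return "\n".join(lines) + "\n"


def build_index(
    records: Iterable[DatasetRecord],
    config: AnalyzerConfig = DEFAULT_ANALYZER,
) -> FieldedIndex:
    """Index a collection; duplicate doc_ids raise an error."""
    index = FieldedIndex()
    for record in records:
        index.add_document(record, config)
    return index
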