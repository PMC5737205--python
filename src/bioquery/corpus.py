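"""Dataset-record data model and heterogeneous metadata parsing.

A *dataset record* is the unit of retrieval: one repository entry (a gene
expression series, a protein structure deposition, a clinical trial, ...)
described by a repository-specific subset of a closed 11-field vocabulary.
Nine fields hold analyzable text; ``repository`` and ``category`` are kept
as stored labels used for filtering, never analyzed.

Repositories expose wildly different source layouts, so parsing is driven
by a declarative :class:`SchemaRegistry` mapping source-document paths to
canonical field names, one mapping per repository, plus the repository's
data category.  Fields a repository does not provide are *absent* from the
record (not empty strings), so field-presence statistics over a parsed
collection reflect the registry's masks.
"""

from __future__ import annotations

import json
import xml.etree.ElementTree as ET
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Mapping

import yaml

from .errors import ConfigurationError, MalformedRecordError

#: Analyzable text fields, in canonical order.
TEXT_FIELDS = (
    "title",
    "description",
    "keywords",
    "organisms",
    "article_title",
    "article_abstract",
    "genes",
    "diseases",
    "treatment",
)

#: Fields whose canonical value is a list of phrases.
LIST_FIELDS = frozenset({"keywords", "organisms", "genes"})

#: The full closed field vocabulary of the index (9 text + 2 label fields).
ALL_FIELDS = TEXT_FIELDS + ("repository", "category")

UNSPECIFIED_CATEGORY = "Unspecified"


@dataclass
class DatasetRecord:
    """One dataset's metadata.

    ``fields`` maps canonical field names to text (or phrase lists for the
    list-valued fields); absent fields have no entry.  ``pmids`` carries the
    linked-article identifiers used by :func:`link_articles`.
    """

    doc_id: str
    repository: str
    category: str
    fields: dict[str, str | list[str]] = field(default_factory=dict)
    pmids: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.doc_id:
            raise MalformedRecordError("doc_id must be non-empty")
        bad = set(self.fields) - set(TEXT_FIELDS)
        if bad:
            raise MalformedRecordError(
                f"record {self.doc_id}: non-canonical fields {sorted(bad)}"
            )

    def field_text(self, name: str) -> str:
        """Field content as a single string (phrase lists space-joined)."""
        value = self.fields.get(name, "")
        if isinstance(value, list):
            return " ".join(value)
        return value

    def to_json(self) -> str:
        return json.dumps(
            {
                "doc_id": self.doc_id,
                "repository": self.repository,
                "category": self.category,
                "pmids": self.pmids,
                "fields": self.fields,
            },
            sort_keys=True,
            ensure_ascii=False,
        )

    @classmethod
    def from_json(cls, line: str) -> "DatasetRecord":
        obj = json.loads(line)
        return cls(
            doc_id=obj["doc_id"],
            repository=obj["repository"],
            category=obj["category"],
            fields=obj.get("fields", {}),
            pmids=list(obj.get("pmids", [])),
        )


@dataclass
class RepositorySchema:
    """Source-path -> canonical-field mapping for one repository."""

    category: str
    doc_id_path: str
    field_paths: dict[str, str]  # canonical field name -> dotted source path
    pmid_path: str | None = None

    def __post_init__(self) -> None:
        bad = set(self.field_paths) - set(TEXT_FIELDS)
        if bad:
            raise ConfigurationError(f"non-canonical schema fields {sorted(bad)}")


class SchemaRegistry:
    """Per-repository schemas plus category labels.

    Loadable from a YAML document::

        repositories:
          pdb_like:
            category: Protein structure
            doc_id: DocID
            pmids: METADATA.pmids
            fields:
              title: TITLE
              description: METADATA.description
              genes: METADATA.genes
    """

    def __init__(self, schemas: Mapping[str, RepositorySchema]):
        self._schemas = dict(schemas)

    def __contains__(self, repository: str) -> bool:
        return repository in self._schemas

    def __iter__(self) -> Iterator[str]:
        return iter(self._schemas)

    def schema(self, repository: str) -> RepositorySchema:
        try:
            return self._schemas[repository]
        except KeyError:
            raise ConfigurationError(f"unknown repository: {repository!r}") from None

    def category(self, repository: str) -> str:
        return self.schema(repository).category

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SchemaRegistry":
        with open(path) as fh:
            doc = yaml.safe_load(fh)
        return cls.from_dict(doc)

    @classmethod
    def from_dict(cls, doc: Mapping) -> "SchemaRegistry":
        repos = doc.get("repositories")
        if not isinstance(repos, Mapping):
            raise ConfigurationError("registry must contain a 'repositories' map")
        schemas = {}
        for name, entry in repos.items():
            schemas[name] = RepositorySchema(
                category=entry.get("category", UNSPECIFIED_CATEGORY),
                doc_id_path=entry.get("doc_id", "DocID"),
                field_paths=dict(entry.get("fields", {})),
                pmid_path=entry.get("pmids"),
            )
        return cls(schemas)


def _resolve_json(node, path: str):
    for key in path.split("."):
        if not isinstance(node, Mapping) or key not in node:
            return None
        node = node[key]
    return node


def _resolve_xml(node: ET.Element, path: str):
    parts = path.split(".")
    current = [node]
    for key in parts:
        nxt: list[ET.Element] = []
        for el in current:
            nxt.extend(el.findall(key))
        if not nxt:
            return None
        current = nxt
    texts = [(el.text or "").strip() for el in current]
    texts = [t for t in texts if t]
    if not texts:
        return None
    return texts if len(texts) > 1 else texts[0]


def _resolve(raw, path: str):
    if isinstance(raw, ET.Element):
        return _resolve_xml(raw, path)
    return _resolve_json(raw, path)


def _as_phrases(value) -> list[str]:
    if isinstance(value, (list, tuple)):
        out = []
        for item in value:
            s = str(item).strip()
            if s:
                out.append(s)
        return out
    return [s for s in (str(value).strip(),) if s]


def parse_record(raw_document, registry: SchemaRegistry, repository: str) -> DatasetRecord:
    """Parse one source document (JSON mapping or XML element) into a record.

    Only the fields the repository's schema provides are populated; the
    category comes from the registry.  A missing DocID raises
    :class:`MalformedRecordError`, an unregistered repository raises
    :class:`ConfigurationError`.
    """
    schema = registry.schema(repository)
    doc_id = _resolve(raw_document, schema.doc_id_path)
    if doc_id is None or not str(doc_id).strip():
        raise MalformedRecordError(f"document has no DocID at {schema.doc_id_path!r}")
    fields: dict[str, str | list[str]] = {}
    for name, path in schema.field_paths.items():
        value = _resolve(raw_document, path)
        if value is None:
            continue
        if name in LIST_FIELDS:
            phrases = _as_phrases(value)
            if phrases:
                fields[name] = phrases
        else:
            if isinstance(value, (list, tuple)):
                text = " ".join(str(v).strip() for v in value if str(v).strip())
            else:
                text = str(value).strip()
            if text:
                fields[name] = text
    pmids: list[str] = []
    if schema.pmid_path is not None:
        value = _resolve(raw_document, schema.pmid_path)
        if value is not None:
            pmids = _as_phrases(value)
    return DatasetRecord(
        doc_id=str(doc_id).strip(),
        repository=repository,
        category=schema.category,
        fields=fields,
        pmids=pmids,
    )


class ArticleTable:
    """PMID -> (article title, abstract) lookup table.

    Unknown PMIDs are misses, not errors.  Loadable from a 3-column TSV
    (pmid, title, abstract).
    """

    def __init__(self, entries: Mapping[str, tuple[str, str]] | None = None):
        self._entries: dict[str, tuple[str, str]] = dict(entries or {})

    def __len__(self) -> int:
        return len(self._entries)

    def __contains__(self, pmid: str) -> bool:
        return pmid in self._entries

    def get(self, pmid: str) -> tuple[str, str] | None:
        return self._entries.get(pmid)

    @classmethod
    def from_tsv(cls, path: str | Path) -> "ArticleTable":
        entries: dict[str, tuple[str, str]] = {}
        with open(path, encoding="utf-8") as fh:
            for line in fh:
                line = line.rstrip("\n")
                if not line:
                    continue
                parts = line.split("\t")
                if len(parts) < 3:
                    parts = parts + [""] * (3 - len(parts))
                pmid, title, abstract = parts[0], parts[1], parts[2]
                if pmid:
                    entries[pmid] = (title, abstract)
        return cls(entries)


@dataclass
class LinkStatistics:
    """Outcome summary of an article-linking pass."""

    records_linked: int = 0
    pmid_hits: int = 0
    pmid_misses: int = 0


def link_articles(
    records: Iterable[DatasetRecord], articles: ArticleTable
) -> tuple[list[DatasetRecord], LinkStatistics]:
    """Populate article_title/article_abstract from each record's PMIDs.

    Multiple linked articles are concatenated in ascending PMID string
    order.  Records with no table hits are returned unchanged; misses are
    counted in the returned statistics.
    """
    stats = LinkStatistics()
    out = []
    for record in records:
        titles, abstracts = [], []
        for pmid in sorted(record.pmids):
            hit = articles.get(pmid)
            if hit is None:
                stats.pmid_misses += 1
                continue
            stats.pmid_hits += 1
            title, abstract = hit
            if title:
                titles.append(title)
            if abstract:
                abstracts.append(abstract)
        if titles or abstracts:
            stats.records_linked += 1
            fields = dict(record.fields)
            if titles:
                fields["article_title"] = " ".join(titles)
            if abstracts:
                fields["article_abstract"] = " ".join(abstracts)
            record = DatasetRecord(
                doc_id=record.doc_id,
                repository=record.repository,
                category=record.category,
                fields=fields,
                pmids=record.pmids,
            )
        out.append(record)
    return out, stats


def write_collection(records: Iterable[DatasetRecord], path: str | Path) -> None:
    """Write records as canonical JSON-lines, one record per line."""
    with open(path, "w", encoding="utf-8") as fh:
        for record in records:
            fh.write(record.to_json())
            fh.write("\n")


def read_collection(path: str | Path) -> list[DatasetRecord]:
    records = []
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            line = line.strip()
            if line:
                records.append(DatasetRecord.from_json(line))
    return records


def field_presence_census(records: Iterable[DatasetRecord]) -> dict[str, Counter]:
    """Per-repository counts of populated fields (a Table-1-style census)."""
    census: dict[str, Counter] = {}
    for record in records:
        counter = census.setdefault(record.repository, Counter())
        counter["_docs"] += 1
        for name in record.fields:
            counter[name] += 1
    return census
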