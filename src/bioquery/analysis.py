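"""Text analysis: tokenization, stopword removal and stemming.

The analysis chain mirrors the standard analyzer of classic Lucene-family
engines: split on non-alphanumeric characters, lowercase, drop the fixed
33-word English stop list, then Porter-stem.  Pure-digit and mixed tokens
are kept so that gene symbols such as "BeF3" survive analysis.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Iterable

from . import porter

#: The classic 33-word English stop list of the standard analyzer.
STANDARD_STOPWORDS = frozenset(
    """a an and are as at be but by for if in into is it no not of on or
    such that the their then there these they this to was will with""".split()
)

_TOKEN_RE = re.compile(r"[A-Za-z0-9]+")


@dataclass(frozen=True)
class AnalyzerConfig:
    """Deterministic analysis settings.

    Parameters
    ----------
    stopwords
        Lowercase words removed after tokenization.
    stemmer
        ``"porter"`` (default) or ``"none"``.
    lowercase
        Lowercase tokens before stopword removal and stemming.
    """

    stopwords: frozenset[str] = STANDARD_STOPWORDS
    stemmer: str = "porter"
    lowercase: bool = True

    def __post_init__(self) -> None:
        if self.stemmer not in ("porter", "none"):
            raise ValueError(f"unknown stemmer: {self.stemmer!r}")


DEFAULT_ANALYZER = AnalyzerConfig()


def tokenize(text: str) -> list[str]:
    """Maximal runs of ASCII letters/digits, in order of appearance."""
    return _TOKEN_RE.findall(text)


def tokenize_with_spans(text: str) -> list[tuple[str, int, int]]:
    """Tokens together with their (start, end) character offsets."""
    return [(m.group(0), m.start(), m.end()) for m in _TOKEN_RE.finditer(text)]


def analyze(text: str, config: AnalyzerConfig = DEFAULT_ANALYZER) -> list[str]:
    """Analyze free text into index terms.

    Tokens are lowercased, stopwords removed and stems applied; the original
    token order is preserved.  Empty or whitespace-only input yields an
    empty list.
    """
    out: list[str] = []
    for tok in tokenize(text):
        if config.lowercase:
            tok = tok.lower()
        if tok in config.stopwords:
            continue
        if config.stemmer == "porter":
            tok = porter.stem(tok)
        out.append(tok)
    return out


def analyze_phrases(
    phrases: Iterable[str], config: AnalyzerConfig = DEFAULT_ANALYZER
) -> list[str]:
    """Analyze a list of phrases as one space-joined text."""
    return analyze(" ".join(phrases), config)
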