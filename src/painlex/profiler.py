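"""Corpus exploration: term rates, length statistics, sampling and KWIC.

Mention rates are reported per 10,000 tokens, the convention used when
comparing keyword frequency across clinical-note collections of very
different sizes. Three pattern kinds cover the common cases for a symptom
keyword: a literal token ("pain"), a phrase ("chronic pain"), and a suffix
("algia", hitting neuralgia, arthralgia, ...).
"""

from __future__ import annotations

import random
from dataclasses import dataclass
from typing import Literal

from .corpus import Corpus, Document, tokenize
from .errors import ZeroTokenCorpusError

__all__ = [
    "TermPattern", "TermRateReport", "LengthStats", "KwicLine",
    "term_rate", "doc_length_stats", "sample_keyword_docs", "kwic",
]


@dataclass(frozen=True)
class TermPattern:
    """A countable keyword pattern.

    kind
        ``literal`` — a single token, matched by equality;
        ``phrase`` — a multi-token sequence matched against consecutive
        tokens (so counts for "pain" include every "chronic pain");
        ``suffix`` — single tokens ending in ``value`` (the bare token
        itself also counts, e.g. a document saying just "algia").
    """

    kind: Literal["literal", "phrase", "suffix"]
    value: str

    def __post_init__(self) -> None:
        if self.kind == "phrase" and len(self.value.split()) < 2:
            raise ValueError("phrase patterns need at least two tokens")


@dataclass(frozen=True)
class TermRateReport:
    pattern: TermPattern
    raw_count: int
    rate_per_10k: float


@dataclass(frozen=True)
class LengthStats:
    """Character-length statistics over keyword-containing documents.

    Lengths are raw Unicode code-point counts of the document text, before
    tokenization. When no document matches, ``n_docs`` is 0 and the stats
    are ``None`` rather than raising.
    """

    keyword: str
    n_docs: int
    mean_chars: float | None
    min_chars: int | None
    max_chars: int | None


@dataclass(frozen=True)
class KwicLine:
    doc_id: str
    left: tuple[str, ...]
    node: str
    right: tuple[str, ...]


def _count_pattern(tokens: list[str], pattern: TermPattern) -> int:
    if pattern.kind == "literal":
        needle = pattern.value.lower()
        return sum(1 for t in tokens if t == needle)
    if pattern.kind == "phrase":
        seq = tokenize(pattern.value)
        n = len(seq)
        return sum(1 for i in range(len(tokens) - n + 1) if tokens[i:i + n] == seq)
    if pattern.kind == "suffix":
        suf = pattern.value.lower()
        return sum(1 for t in tokens if t.endswith(suf))
    raise ValueError(f"unknown pattern kind {pattern.kind!r}")


def term_rate(corpus: Corpus, pattern: TermPattern) -> TermRateReport:
    """Count pattern matches and normalise to mentions per 10,000 tokens."""
    n_tokens = corpus.token_count
    if n_tokens == 0:
        raise ZeroTokenCorpusError("cannot compute a rate over zero tokens")
    raw = sum(_count_pattern(doc.tokens, pattern) for doc in corpus)
    return TermRateReport(pattern=pattern, raw_count=raw,
                          rate_per_10k=raw * 10_000 / n_tokens)


def _keyword_docs(corpus: Corpus, keyword: str, substring: bool) -> list[Document]:
    kw = keyword.lower()
    if substring:
        return [d for d in corpus if kw in d.text.lower()]
    return [d for d in corpus if kw in d.tokens]


def doc_length_stats(corpus: Corpus, keyword: str,
                     substring: bool = True) -> LengthStats:
    """Length stats (chars) over documents containing ``keyword``.

    Selection is a case-insensitive raw-text substring test by default (so
    "painful" contains "pain"); pass ``substring=False`` for exact-token
    matching.
    """
    if not keyword:
        raise ValueError("keyword must be nonempty")
    matched = _keyword_docs(corpus, keyword, substring)
    if not matched:
        return LengthStats(keyword=keyword, n_docs=0, mean_chars=None,
                           min_chars=None, max_chars=None)
    lengths = [d.n_chars for d in matched]
    return LengthStats(keyword=keyword, n_docs=len(lengths),
                       mean_chars=sum(lengths) / len(lengths),
                       min_chars=min(lengths), max_chars=max(lengths))


def sample_keyword_docs(corpus: Corpus, keyword: str, n: int, seed: int,
                        substring: bool = True) -> tuple[list[Document], bool]:
    """Uniform sample without replacement of keyword-containing documents.

    Returns ``(documents, short_sample)``; ``short_sample`` is True when
    fewer than ``n`` documents matched and all of them were returned.
    Reproducible for a fixed seed.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    matched = _keyword_docs(corpus, keyword, substring)
    rng = random.Random(seed)
    if len(matched) <= n:
        return list(matched), len(matched) < n
    return rng.sample(matched, n), False


def kwic(corpus: Corpus, keyword: str, window: int = 5) -> list[KwicLine]:
    """Keyword-in-context concordance: one line per token match.

    Contexts are truncated at document boundaries, so an occurrence at the
    start of a note has an empty left context.
    """
    if window < 1:
        raise ValueError("window must be >= 1")
    kw = keyword.lower()
    lines: list[KwicLine] = []
    for doc_id, tokens in corpus.iter_token_streams():
        for i, tok in enumerate(tokens):
            if tok == kw:
                lines.append(KwicLine(
                    doc_id=doc_id,
                    left=tuple(tokens[max(0, i - window):i]),
                    node=tok,
                    right=tuple(tokens[i + 1:i + 1 + window])))
    return lines
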