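"""Document collections and the canonical tokenization contract.

Every downstream statistic in the package — mention rates per 10,000 tokens,
collocation windows, wildcard searches — is defined over one shared tokenizer
so that denominators and window offsets are mutually consistent. The tokenizer
is deliberately simple: Unicode-aware, lowercase-folding, splitting on any
non-alphanumeric character except apostrophes internal to a token (so
"don't" survives but "back-pain" splits into two tokens). Punctuation never
yields tokens.
"""

from __future__ import annotations

import csv
import json
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Sequence

from .errors import ConfigurationError, EmptyCorpusError, FormatError

__all__ = ["Document", "Corpus", "tokenize", "read_corpus", "corpus_token_count"]

# One or more alphanumeric runs joined by single internal apostrophes.
# Hyphens, underscores and all punctuation are separators.
_TOKEN_RE = re.compile(r"[^\W_]+(?:['’][^\W_]+)*", re.UNICODE)


def tokenize(text: str) -> list[str]:
    """Lowercase and split ``text`` into the canonical token sequence.

    Splits on whitespace and punctuation (hyphens included); apostrophes
    internal to a word are retained. Empty text gives an empty list.

    >>> tokenize("Chronic back-pain!")
    ['chronic', 'back', 'pain']
    """
    return _TOKEN_RE.findall(text.lower())


@dataclass(frozen=True)
class Document:
    """A single tokenizable text unit with a stable id and a source tag."""

    id: str
    text: str
    source_tag: str = ""

    @property
    def tokens(self) -> list[str]:
        return tokenize(self.text)

    @property
    def n_chars(self) -> int:
        """Raw character length in Unicode code points (pre-tokenization)."""
        return len(self.text)


@dataclass
class Corpus:
    """An ordered document collection with a cached total token count."""

    documents: list[Document]
    _token_count: int | None = field(default=None, repr=False)

    def __iter__(self) -> Iterator[Document]:
        return iter(self.documents)

    def __len__(self) -> int:
        return len(self.documents)

    @property
    def token_count(self) -> int:
        if self._token_count is None:
            self._token_count = sum(len(d.tokens) for d in self.documents)
        return self._token_count

    def iter_token_streams(self) -> Iterator[tuple[str, list[str]]]:
        """Yield (document id, token list) pairs in stable corpus order."""
        for doc in self.documents:
            yield doc.id, doc.tokens


def corpus_token_count(corpus: Corpus) -> int:
    """Total tokens across the corpus under the canonical tokenizer."""
    return corpus.token_count


def _check_ids(documents: Sequence[Document]) -> None:
    seen: set[str] = set()
    for doc in documents:
        if doc.id in seen:
            raise ConfigurationError(f"duplicate document id {doc.id!r}")
        seen.add(doc.id)


def _from_textdir(path: Path) -> list[Document]:
    files = sorted(p for p in path.iterdir() if p.is_file())
    return [Document(id=p.stem, text=p.read_text(encoding="utf-8"), source_tag="file")
            for p in files]


def _from_jsonl(path: Path, text_field: str) -> list[Document]:
    docs = []
    with path.open(encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            try:
                rec = json.loads(line)
            except json.JSONDecodeError as exc:
                raise FormatError(f"{path}:{lineno}: invalid JSON ({exc})") from exc
            if text_field not in rec:
                raise FormatError(
                    f"{path}:{lineno}: record missing text field {text_field!r}")
            doc_id = str(rec.get("id", lineno))
            docs.append(Document(id=doc_id, text=str(rec[text_field]),
                                 source_tag=str(rec.get("source", ""))))
    return docs


def _from_csv(path: Path, text_field: str) -> list[Document]:
    docs = []
    with path.open(encoding="utf-8", newline="") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames is None or text_field not in reader.fieldnames:
            raise FormatError(f"{path}: CSV has no column {text_field!r}")
        for rowno, row in enumerate(reader, start=1):
            if row.get(text_field) is None:
                raise FormatError(f"{path}: row {rowno}: missing {text_field!r}")
            doc_id = str(row.get("id") or rowno)
            docs.append(Document(id=doc_id, text=row[text_field],
                                 source_tag=str(row.get("source", ""))))
    return docs


def read_corpus(path: str | Path, format: str = "jsonl",
                text_field: str = "text") -> Corpus:
    """Read a document collection from disk.

    Parameters
    ----------
    path
        Directory of ``.txt`` files (``format="textdir"``), a JSONL file with
        one record per document (``format="jsonl"``), or a CSV file
        (``format="csv"``).
    text_field
        Name of the text field/column for jsonl and csv inputs.

    Raises
    ------
    FormatError
        A record is missing the text field, naming the record.
    EmptyCorpusError
        The input contains no documents.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if format == "textdir":
        docs = _from_textdir(path)
    elif format == "jsonl":
        docs = _from_jsonl(path, text_field)
    elif format == "csv":
        docs = _from_csv(path, text_field)
    else:
        raise ConfigurationError(f"unknown corpus format {format!r}")
    if not docs:
        raise EmptyCorpusError(f"no documents found in {path}")
    _check_ids(docs)
    return Corpus(documents=docs)


def corpus_from_texts(texts: Iterable[str], source_tag: str = "mem") -> Corpus:
    """Build an in-memory corpus from raw strings (ids are positional)."""
    docs = [Document(id=f"d{i}", text=t, source_tag=source_tag)
            for i, t in enumerate(texts)]
    if not docs:
        raise EmptyCorpusError("no documents given")
    return Corpus(documents=docs)


def write_corpus_jsonl(corpus: Corpus, path: str | Path) -> None:
    """Write a corpus as JSONL, one ``{"id", "text", "source"}`` per line."""
    path = Path(path)
    with path.open("w", encoding="utf-8") as fh:
        for doc in corpus:
            fh.write(json.dumps({"id": doc.id, "text": doc.text,
                                 "source": doc.source_tag}) + "\n")
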