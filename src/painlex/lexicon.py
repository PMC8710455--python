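"""Building a provenance-tracked lexicon from multiple term sources.

Raw term lists arrive from three source classes — literature (published
symptom-term lists), ontologies (UMLS / SNOMED-CT / ICD-10 style synonym
exports, supplied as flat files), and embedding models (harvested
neighbours) — plus "review" for clinician-supplied edits. Each raw term is
normalised, then passed through two filters that mirror the curation rules
for a symptom lexicon:

* token filter — keep only one- and two-token terms ("pain of jaw" goes,
  "jaw pain" stays: longer phrases are mostly redundant with their bigram
  cores);
* length filter — drop single-token terms shorter than four characters
  ("hip" alone is too ambiguous a string to search on; "ache" is the
  shortest useful head word). Bigrams are exempt, otherwise every
  "<short anatomy> pain" compound would vanish with them.

Surviving terms are merged into entries keyed by normalised term, each
carrying a multiset of source ids, so duplicate frequency across sources
("pain" arriving from dozens of lists) is preserved for profiling.

Source-id convention: ``"<class>:<name>"`` or bare ``"<class>"``, e.g.
``literature:ePAT``, ``ontology:SNOMED-CT``, ``embeddings:mimic3-w2v``,
``review``. The class prefix is what coverage reports aggregate over.
"""

from __future__ import annotations

import csv
import difflib
import re
from collections import Counter
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

from .errors import ConfigurationError, FormatError

__all__ = [
    "RawTermList", "LexiconEntry", "Lexicon", "ReviewDecision",
    "normalize_term", "token_filter", "length_filter", "merge_sources",
    "term_frequency_profile", "apply_review_decisions", "read_decisions",
    "write_lexicon", "read_lexicon", "read_term_list",
]

_WORD_RE = re.compile(r"[^\W_]+(?:['’][^\W_]+)*", re.UNICODE)

REMOVAL_CATEGORIES = {"ambiguous", "not-pain", "vague"}


def normalize_term(raw: str) -> str:
    """Canonical term form: lowercase, punctuation stripped, spaces collapsed.

    Hyphens split (matching the corpus tokenizer, so "back-pain" and
    "back pain" collapse to one entry); internal apostrophes survive. An
    all-symbol input normalises to the empty string, which callers treat as
    a dropped-term signal.
    """
    return " ".join(_WORD_RE.findall(raw.lower()))


def token_filter(term: str, max_tokens: int = 2) -> bool:
    """Keep terms of at most ``max_tokens`` whitespace tokens."""
    return len(term.split()) <= max_tokens


def length_filter(term: str, min_chars: int = 4) -> bool:
    """Reject single-token terms shorter than ``min_chars``; keep the rest."""
    toks = term.split()
    if len(toks) != 1:
        return True
    return len(term) >= min_chars


@dataclass
class RawTermList:
    """An ordered raw term list from one source; duplicates are meaningful."""

    source_id: str
    terms: list[str]
    source_class: str = ""

    def __post_init__(self) -> None:
        prefix = self.source_id.split(":", 1)[0]
        if not self.source_class:
            self.source_class = prefix
        elif self.source_class != prefix:
            raise ConfigurationError(
                f"source_id {self.source_id!r} does not start with class "
                f"{self.source_class!r}")


@dataclass
class LexiconEntry:
    term: str
    n_tokens: int
    sources: Counter = field(default_factory=Counter)  # source_id -> count
    status: str = "candidate"        # candidate | kept | removed | added
    removal_category: str | None = None

    @property
    def total_count(self) -> int:
        return sum(self.sources.values())

    @property
    def source_classes(self) -> set[str]:
        return {sid.split(":", 1)[0] for sid in self.sources}


@dataclass
class ReviewDecision:
    term: str
    action: str                      # add | remove | keep
    category: str | None = None


@dataclass
class Lexicon:
    entries: dict[str, LexiconEntry] = field(default_factory=dict)
    build_meta: dict = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.entries)

    def __contains__(self, term: str) -> bool:
        return term in self.entries

    def sorted_entries(self) -> list[LexiconEntry]:
        return [self.entries[t] for t in sorted(self.entries)]

    def active_entries(self) -> list[LexiconEntry]:
        """Entries not struck out by review, lexicographic order."""
        return [e for e in self.sorted_entries() if e.status != "removed"]

    def active_terms(self) -> set[str]:
        return {e.term for e in self.entries.values() if e.status != "removed"}

    @property
    def unique_size(self) -> int:
        return len(self.active_terms())

    @property
    def total_multiset_count(self) -> int:
        """Pre-dedup total: sum of source occurrences over active entries."""
        return sum(e.total_count for e in self.entries.values()
                   if e.status != "removed")


def merge_sources(lists: Sequence[RawTermList]) -> Lexicon:
    """Normalise, filter and merge raw term lists into one lexicon.

    Every raw term passes normalise → token filter (≤2 tokens) → length
    filter (≥4 chars for unigrams); survivors accumulate per-source
    occurrence counts on their entry. Dropped terms are logged in
    ``build_meta["dropped"]`` with a reason. Entry order is lexicographic
    and independent of input order.
    """
    seen_ids = [tl.source_id for tl in lists]
    if len(set(seen_ids)) != len(seen_ids):
        dupes = sorted({s for s in seen_ids if seen_ids.count(s) > 1})
        raise ConfigurationError(f"duplicate source ids: {dupes}")

    entries: dict[str, LexiconEntry] = {}
    dropped: list[dict] = []
    per_source: dict[str, dict] = {}
    for tl in lists:
        surviving = 0
        for raw in tl.terms:
            term = normalize_term(raw)
            reason = None
            if not term:
                reason = "empty-after-normalization"
            elif not token_filter(term):
                reason = "more-than-two-tokens"
            elif not length_filter(term):
                reason = "under-four-characters"
            if reason:
                dropped.append({"source_id": tl.source_id, "raw": raw,
                                "reason": reason})
                continue
            surviving += 1
            entry = entries.get(term)
            if entry is None:
                entry = LexiconEntry(term=term, n_tokens=len(term.split()))
                entries[term] = entry
            entry.sources[tl.source_id] += 1
        per_source[tl.source_id] = {
            "source_class": tl.source_class,
            "raw_terms": len(tl.terms),
            "surviving_terms": surviving,
        }

    lex = Lexicon(entries={t: entries[t] for t in sorted(entries)},
                  build_meta={"sources": per_source, "dropped": dropped,
                              "decisions": []})
    if not entries:
        lex.build_meta["warning"] = "empty lexicon: no terms survived"
    return lex


def term_frequency_profile(lexicon: Lexicon,
                           top_n: int | None = None) -> list[tuple[str, int]]:
    """Active terms ranked by total multiset count, ties lexicographic."""
    rows = [(e.term, e.total_count) for e in lexicon.active_entries()]
    rows.sort(key=lambda r: (-r[1], r[0]))
    return rows if top_n is None else rows[:top_n]


def read_decisions(path: str | Path) -> list[ReviewDecision]:
    """Read a reviewer-decision TSV with columns term, action[, category]."""
    path = Path(path)
    decisions = []
    with path.open(encoding="utf-8", newline="") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        if reader.fieldnames is None or not {"term", "action"} <= set(reader.fieldnames):
            raise FormatError(f"{path}: decision file needs 'term' and 'action' columns")
        for lineno, row in enumerate(reader, start=2):
            action = (row.get("action") or "").strip().lower()
            if action not in {"add", "remove", "keep"}:
                raise FormatError(f"{path}:{lineno}: unknown action {action!r}")
            decisions.append(ReviewDecision(
                term=normalize_term(row["term"]), action=action,
                category=(row.get("category") or "").strip() or None))
    return decisions


def apply_review_decisions(
        lexicon: Lexicon,
        decisions: Sequence[ReviewDecision] | str | Path) -> Lexicon:
    """Apply clinician review decisions, keeping a full audit trail.

    ``remove`` marks an existing entry removed (a category is required);
    ``add`` introduces a new entry sourced ``review``; ``keep`` confirms an
    entry. The input lexicon is not mutated. Removing a term that is not in
    the lexicon is a hard error listing near matches; duplicate decisions on
    one term are rejected.
    """
    if isinstance(decisions, (str, Path)):
        decisions = read_decisions(decisions)

    seen: dict[str, str] = {}
    for d in decisions:
        if d.term in seen:
            kind = "conflicting" if seen[d.term] != d.action else "duplicate"
            raise ConfigurationError(
                f"{kind} decisions for term {d.term!r}")
        seen[d.term] = d.action

    new_entries = {t: replace(e, sources=Counter(e.sources))
                   for t, e in lexicon.entries.items()}
    audit: list[dict] = []
    for d in decisions:
        if d.action == "remove":
            entry = new_entries.get(d.term)
            if entry is None or entry.status == "removed":
                near = difflib.get_close_matches(
                    d.term, list(new_entries), n=3, cutoff=0.0)
                raise ConfigurationError(
                    f"cannot remove {d.term!r}: not an active lexicon term; "
                    f"near matches: {near}")
            if not d.category:
                raise ConfigurationError(
                    f"removal of {d.term!r} needs a category "
                    f"({'/'.join(sorted(REMOVAL_CATEGORIES))})")
            entry.status = "removed"
            entry.removal_category = d.category
            audit.append({"action": "remove", "term": d.term,
                          "category": d.category, "prior_status": "active"})
        elif d.action == "add":
            existing = new_entries.get(d.term)
            if existing is not None and existing.status != "removed":
                raise ConfigurationError(
                    f"cannot add {d.term!r}: already an active lexicon term")
            entry = LexiconEntry(term=d.term, n_tokens=len(d.term.split()),
                                 sources=Counter({"review": 1}), status="added")
            new_entries[d.term] = entry
            audit.append({"action": "add", "term": d.term,
                          "replaced_removed": existing is not None})
        else:  # keep
            entry = new_entries.get(d.term)
            if entry is None:
                raise ConfigurationError(f"cannot keep unknown term {d.term!r}")
            entry.status = "kept"
            audit.append({"action": "keep", "term": d.term})

    meta = dict(lexicon.build_meta)
    meta["decisions"] = list(meta.get("decisions", [])) + audit
    return Lexicon(entries={t: new_entries[t] for t in sorted(new_entries)},
                   build_meta=meta)


_LEXICON_COLUMNS = ["term", "n_tokens", "sources", "count", "status", "category"]


def _encode_sources(sources: Counter) -> str:
    return ";".join(f"{sid}={n}" for sid, n in sorted(sources.items()))


def _decode_sources(text: str, where: str) -> Counter:
    out: Counter = Counter()
    if not text:
        return out
    for part in text.split(";"):
        if "=" not in part:
            raise FormatError(f"{where}: malformed sources field {part!r}")
        sid, _, n = part.partition("=")
        try:
            out[sid] = int(n)
        except ValueError as exc:
            raise FormatError(f"{where}: bad count in {part!r}") from exc
    return out


def write_lexicon(lexicon: Lexicon, path: str | Path) -> None:
    """Write the lexicon as a header-bearing TSV in lexicographic order."""
    path = Path(path)
    with path.open("w", encoding="utf-8", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(_LEXICON_COLUMNS)
        for e in lexicon.sorted_entries():
            writer.writerow([e.term, e.n_tokens, _encode_sources(e.sources),
                             e.total_count, e.status, e.removal_category or ""])


def read_lexicon(path: str | Path) -> Lexicon:
    """Read a lexicon TSV written by :func:`write_lexicon` (lossless)."""
    path = Path(path)
    entries: dict[str, LexiconEntry] = {}
    with path.open(encoding="utf-8", newline="") as fh:
        reader = csv.reader(fh, delimiter="\t")
        header = next(reader, None)
        if header != _LEXICON_COLUMNS:
            raise FormatError(f"{path}:1: bad header {header!r}")
        for lineno, row in enumerate(reader, start=2):
            if len(row) != len(_LEXICON_COLUMNS):
                raise FormatError(f"{path}:{lineno}: expected "
                                  f"{len(_LEXICON_COLUMNS)} fields, got {len(row)}")
            term, n_tokens, sources, count, status, category = row
            if term in entries:
                raise FormatError(f"{path}:{lineno}: duplicate term {term!r}")
            srcs = _decode_sources(sources, f"{path}:{lineno}")
            entry = LexiconEntry(term=term, n_tokens=int(n_tokens), sources=srcs,
                                 status=status, removal_category=category or None)
            if entry.total_count != int(count):
                raise FormatError(f"{path}:{lineno}: count column disagrees "
                                  f"with sources multiset")
            entries[term] = entry
    return Lexicon(entries={t: entries[t] for t in sorted(entries)},
                   build_meta={"read_from": str(path)})


def read_term_list(path: str | Path, source_id: str) -> RawTermList:
    """Read a raw term list: plain text (one term per line) or two-column TSV.

    A TSV needs columns ``term`` and optionally ``source_id``; rows whose
    ``source_id`` differs from the requested one are skipped.
    """
    path = Path(path)
    lines = path.read_text(encoding="utf-8").splitlines()
    if lines and "\t" in lines[0] and "term" in lines[0].split("\t"):
        header = lines[0].split("\t")
        ti = header.index("term")
        si = header.index("source_id") if "source_id" in header else None
        terms = []
        for line in lines[1:]:
            if not line.strip():
                continue
            parts = line.split("\t")
            if si is not None and parts[si] != source_id:
                continue
            terms.append(parts[ti])
        return RawTermList(source_id=source_id, terms=terms)
    return RawTermList(source_id=source_id,
                       terms=[ln for ln in lines if ln.strip()])
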