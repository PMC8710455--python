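"""Structural patterns in pain terms and wildcard stem searches.

Most multi-word pain terms are built from a small set of slots: an anatomy
word ("chest", "back"), a quality word ("chronic", "burning") and a head
word — the core pain term ("pain", "ache", "colic") that anchors the
compound. "chest pain" is <anatomy><head>, "chronic back pain" is
<quality><anatomy><head>, and fused compounds such as "headache" are an
anatomy prefix glued onto a head suffix. Recognising these templates lets a
short list of head terms stand in for the whole lexicon in coarse searches,
which is what the SQL-style wildcard stems (%ache%, %pain%, ...) measure
over a corpus.
"""

from __future__ import annotations

from dataclasses import dataclass

from .corpus import Corpus
from .errors import ConfigurationError
from .lexicon import Lexicon, normalize_term

__all__ = [
    "PatternAssignment", "WildcardReport",
    "assign_patterns", "extract_head_terms", "wildcard_search",
]


@dataclass(frozen=True)
class PatternAssignment:
    """A lexicon term mapped onto a slot template.

    ``template`` is a rendered slot sequence such as ``"<anatomy><head>"``,
    or one of the special labels ``head-only``, ``fused-compound``,
    ``unmatched``. ``bindings`` pairs each slot with the bound surface form;
    joining the bound forms (spaces for slotted templates, direct
    concatenation for fused compounds) reconstructs the term exactly.
    """

    term: str
    template: str
    bindings: tuple[tuple[str, str], ...]


@dataclass(frozen=True)
class WildcardReport:
    pattern: str
    matched_docs: int
    total_docs: int
    percent: float
    unit: str = "document"


def _norm_set(terms: set[str]) -> set[str]:
    return {normalize_term(t) for t in terms}


def _classify_token(tok: str, anatomy: set[str], quality: set[str],
                    heads: set[str]) -> str | None:
    if tok in heads:
        return "head"
    if tok in anatomy:
        return "anatomy"
    if tok in quality:
        return "quality"
    return None


def assign_patterns(lexicon: Lexicon, anatomy: set[str], quality: set[str],
                    heads: set[str]) -> list[PatternAssignment]:
    """Assign every active lexicon term to a structural template.

    Tokens are matched greedily against the gazetteers (head takes
    precedence, then anatomy, then quality). A valid slotted template binds
    exactly one head. Single-token terms ending in a head word become
    ``fused-compound`` with the prefix bound as anatomy when the anatomy
    gazetteer knows it (otherwise as a bare prefix slot); anything else is
    ``unmatched``.
    """
    if not heads:
        raise ConfigurationError("head gazetteer must be nonempty")
    anatomy, quality, heads = _norm_set(anatomy), _norm_set(quality), _norm_set(heads)
    out: list[PatternAssignment] = []
    for entry in lexicon.active_entries():
        term = entry.term
        toks = term.split()
        if len(toks) == 1:
            out.append(_assign_single(term, anatomy, heads))
            continue
        slots = [_classify_token(t, anatomy, quality, heads) for t in toks]
        if None in slots or slots.count("head") != 1:
            out.append(PatternAssignment(term=term, template="unmatched",
                                         bindings=()))
        else:
            out.append(PatternAssignment(
                term=term,
                template="".join(f"<{s}>" for s in slots),
                bindings=tuple(zip(slots, toks))))
    return out


def _assign_single(term: str, anatomy: set[str],
                   heads: set[str]) -> PatternAssignment:
    if term in heads:
        return PatternAssignment(term=term, template="head-only",
                                 bindings=(("head", term),))
    # longest head suffix wins: "backache" binds "ache", not a shorter head
    for h in sorted(heads, key=len, reverse=True):
        if term.endswith(h) and len(term) > len(h):
            prefix = term[:-len(h)]
            slot = "anatomy" if prefix in anatomy else "prefix"
            return PatternAssignment(term=term, template="fused-compound",
                                     bindings=((slot, prefix), ("head", h)))
    return PatternAssignment(term=term, template="unmatched", bindings=())


def extract_head_terms(lexicon: Lexicon,
                       heads: set[str]) -> list[tuple[str, int]]:
    """Rank head words by how many active lexicon terms they participate in.

    A head participates in a term when it appears as a whole token or as a
    suffix of a token ("ache" in "headache"). Heads with zero participation
    stay in the report.
    """
    if not heads:
        raise ConfigurationError("head set must be nonempty")
    heads = _norm_set(heads)
    counts = {h: 0 for h in heads}
    for entry in lexicon.active_entries():
        toks = entry.term.split()
        for h in heads:
            if any(t == h or t.endswith(h) for t in toks):
                counts[h] += 1
    rows = sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))
    return rows


def _parse_stem(pattern: str) -> tuple[str, str]:
    """Return (mode, stem): mode ∈ contains | prefix | suffix | exact."""
    core = pattern.strip("%")
    if "%" in core or not core:
        raise ConfigurationError(
            f"unsupported wildcard pattern {pattern!r}: '%' may only anchor "
            f"the ends")
    starts, ends = pattern.startswith("%"), pattern.endswith("%")
    if starts and ends:
        return "contains", core.lower()
    if ends:
        return "prefix", core.lower()
    if starts:
        return "suffix", core.lower()
    return "exact", core.lower()


def _token_matches(tok: str, mode: str, stem: str) -> bool:
    if mode == "contains":
        return stem in tok
    if mode == "prefix":
        return tok.startswith(stem)
    if mode == "suffix":
        return tok.endswith(stem)
    return tok == stem


def wildcard_search(corpus: Corpus, stems: list[str],
                    raw_substring: bool = False,
                    groups: dict[str, str] | None = None) -> list[WildcardReport]:
    """Per-stem fraction of documents (or patient groups) with a match.

    SQL-style patterns: ``%x%`` any token containing x, ``x%`` token
    starting with x, ``%x`` token ending with x, bare ``x`` exact token;
    case-insensitive. ``raw_substring=True`` applies the pattern to the raw
    document text instead of tokens (character-level SQL LIKE semantics).
    ``groups`` maps document id → group id (e.g. patient); with it, the
    denominator is groups and a group matches when any of its documents
    does.
    """
    parsed = [(p, *_parse_stem(p)) for p in stems]
    if groups is not None:
        units = sorted(set(groups.values()))
        unit_name = "group"
    else:
        units = [d.id for d in corpus]
        unit_name = "document"
    matched: dict[str, set[str]] = {p: set() for p in stems}

    for doc in corpus:
        unit = groups[doc.id] if groups is not None else doc.id
        text = doc.text.lower()
        toks = doc.tokens
        for pattern, mode, stem in parsed:
            if raw_substring:
                hit = _token_matches(text, mode, stem)
            else:
                hit = any(_token_matches(t, mode, stem) for t in toks)
            if hit:
                matched[pattern].add(unit)

    total = len(units)
    return [WildcardReport(pattern=p, matched_docs=len(matched[p]),
                           total_docs=total,
                           percent=100.0 * len(matched[p]) / total if total else 0.0,
                           unit=unit_name)
            for p in stems]
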