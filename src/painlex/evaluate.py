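"""Coverage, Venn-region and reference-overlap evaluation of a lexicon.

Three views of the same question — where did the lexicon's terms come from,
and how well do they line up with an external reference vocabulary:

* per-source coverage (unique vs total term counts per source class),
* Venn region counts over two or three labelled term sets,
* overlap against a reference term list (e.g. a pain sub-ontology or a MeSH
  heading/entry-term export), in an exact string-match mode or a
  "head-credit" mode that additionally credits reference terms containing a
  known pain head word (cramp, colic, ache, ...) as a token or suffix.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

from .errors import ConfigurationError
from .lexicon import Lexicon, RawTermList, normalize_term

__all__ = [
    "CoverageRow", "VennReport", "OverlapReport",
    "source_coverage", "venn_counts", "compare_reference",
]


@dataclass(frozen=True)
class CoverageRow:
    source_class: str
    unique_terms: int      # distinct active terms carrying this class
    total_terms: int       # multiset occurrences from this class


@dataclass(frozen=True)
class VennReport:
    set_labels: tuple[str, ...]
    region_counts: dict[frozenset, int] = field(hash=False)

    def region(self, *labels: str) -> int:
        """Count of the exclusive region belonging to exactly these labels."""
        return self.region_counts[frozenset(labels)]

    @property
    def union_size(self) -> int:
        return sum(self.region_counts.values())


@dataclass(frozen=True)
class OverlapReport:
    reference_label: str
    reference_size: int
    matched_count: int
    matched_percent: float
    matched_terms: tuple[str, ...]
    unmatched_terms: tuple[str, ...]
    match_mode: str        # exact | head-credit


def source_coverage(lexicon: Lexicon) -> list[CoverageRow]:
    """Unique/total term counts per source class over active entries."""
    unique: dict[str, int] = {}
    total: dict[str, int] = {}
    for entry in lexicon.active_entries():
        for sid, n in entry.sources.items():
            cls = sid.split(":", 1)[0]
            total[cls] = total.get(cls, 0) + n
        for cls in entry.source_classes:
            unique[cls] = unique.get(cls, 0) + 1
    return [CoverageRow(source_class=cls, unique_terms=unique[cls],
                        total_terms=total[cls])
            for cls in sorted(unique)]


def venn_counts(term_sets: dict[str, set[str]]) -> VennReport:
    """Exclusive Venn region cardinalities for 2 or 3 labelled term sets.

    Regions are keyed by the frozenset of labels whose sets (and no others)
    contain the terms; counts sum to the size of the union.
    """
    if len(term_sets) not in (2, 3):
        raise ConfigurationError("venn_counts needs 2 or 3 labelled sets")
    labels = tuple(term_sets)
    regions: dict[frozenset, int] = {}
    for r in range(1, len(labels) + 1):
        for combo in itertools.combinations(labels, r):
            inside = set.intersection(*(term_sets[l] for l in combo))
            outside = set.union(set(), *(term_sets[l] for l in labels
                                         if l not in combo))
            regions[frozenset(combo)] = len(inside - outside)
    return VennReport(set_labels=labels, region_counts=regions)


def _head_credit_match(term: str, head_inventory: set[str]) -> bool:
    toks = term.split()
    if any(t in head_inventory for t in toks):
        return True
    return any(t.endswith(h) for t in toks for h in head_inventory)


def compare_reference(lexicon: Lexicon, reference: RawTermList,
                      mode: str = "exact",
                      head_inventory: set[str] | None = None) -> OverlapReport:
    """Fraction of a reference term list present in the lexicon.

    ``exact`` — a reference term matches iff, after the shared
    normalisation, it is an active lexicon term. ``head-credit`` —
    additionally matches reference terms carrying a head-inventory word as a
    token or token suffix (so "episodic abdominal cramps" gets credit for
    "cramp" when "cramp"/"cramps" is in the inventory).
    """
    if not reference.terms:
        raise ConfigurationError("reference term list is empty")
    if mode not in ("exact", "head-credit"):
        raise ConfigurationError(f"unknown match mode {mode!r}")
    heads = {normalize_term(h) for h in (head_inventory or set())}
    active = lexicon.active_terms()

    ref_terms = []
    seen: set[str] = set()
    for raw in reference.terms:
        term = normalize_term(raw)
        if term and term not in seen:
            seen.add(term)
            ref_terms.append(term)

    matched, unmatched = [], []
    for term in ref_terms:
        ok = term in active
        if not ok and mode == "head-credit":
            ok = _head_credit_match(term, heads)
        (matched if ok else unmatched).append(term)
    size = len(ref_terms)
    return OverlapReport(
        reference_label=reference.source_id, reference_size=size,
        matched_count=len(matched),
        matched_percent=100.0 * len(matched) / size,
        matched_terms=tuple(matched), unmatched_terms=tuple(unmatched),
        match_mode=mode)
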