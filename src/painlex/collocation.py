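"""Windowed collocation analysis with span-adjusted mutual information.

A collocate of a node word (here typically "pain") is any token occurring
within ±window tokens of a node occurrence, windows never crossing document
boundaries. Association strength is scored with span-adjusted pointwise
mutual information (Church–Hanks style, as corpus tools such as LancsBox
compute it):

    MI = log2( O * N / (f_n * f_c * S) ),   S = 2 * window

where O is the observed co-occurrence count, f_n and f_c the corpus
frequencies of node and collocate, and N the corpus token count. MI is in
bits; 0 means co-occurrence at chance level.

Counting rule: each collocate token *position* is counted at most once, and
is attributed to its nearest node occurrence (ties go to the earlier node),
so that O never exceeds the collocate's corpus frequency even when node
occurrences fall close together. A node token inside another node's window
counts as a collocate of the node — "pain" can be its own collocate.
"""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass
from typing import Literal

from .corpus import Corpus

__all__ = ["CollocateRecord", "extract_collocates", "mi_score", "filter_collocates"]

NEG_INF = float("-inf")


@dataclass(frozen=True)
class CollocateRecord:
    term: str
    joint_freq: int        # O: windowed co-occurrences with the node
    node_freq: int         # f_n: node occurrences in the corpus
    coll_freq: int         # f_c: collocate occurrences in the corpus
    left_freq: int
    right_freq: int
    mi: float              # bits; -inf sentinel when O == 0
    dominant_side: Literal["L", "R", "tie"]


def mi_score(O: int, f_n: int, f_c: int, N: int, window: int) -> float:
    """Span-adjusted pointwise mutual information, base-2.

    Expected co-occurrence under independence within a span of S = 2*window
    token slots per node occurrence is E = f_n * f_c * S / N.
    """
    if min(f_n, f_c, N, window) <= 0:
        raise ValueError("f_n, f_c, N and window must be positive")
    if N < f_n or N < f_c:
        raise ValueError("corpus size N must be >= each marginal frequency")
    if O == 0:
        return NEG_INF
    expected = f_n * f_c * (2 * window) / N
    return math.log2(O / expected)


def extract_collocates(corpus: Corpus, node: str,
                       window: int = 5) -> list[CollocateRecord]:
    """Collect all windowed collocates of ``node`` across the corpus.

    Returns one record per distinct collocate term, in lexicographic order;
    an absent node gives an empty list.
    """
    if window < 1:
        raise ValueError("window must be >= 1")
    node = node.lower()
    N = corpus.token_count
    corpus_freq: Counter[str] = Counter()
    left: Counter[str] = Counter()
    right: Counter[str] = Counter()
    f_n = 0

    for _, tokens in corpus.iter_token_streams():
        corpus_freq.update(tokens)
        node_pos = [i for i, t in enumerate(tokens) if t == node]
        f_n += len(node_pos)
        if not node_pos:
            continue
        for p, tok in enumerate(tokens):
            # nearest node occurrence other than this position itself
            best: int | None = None
            for i in node_pos:
                if i == p:
                    continue
                d = abs(p - i)
                if d > window:
                    continue
                if best is None or d < abs(p - best) or (
                        d == abs(p - best) and i < best):
                    best = i
            if best is None:
                continue
            if p < best:
                left[tok] += 1
            else:
                right[tok] += 1

    records = []
    for term in sorted(set(left) | set(right)):
        O = left[term] + right[term]
        records.append(CollocateRecord(
            term=term, joint_freq=O, node_freq=f_n,
            coll_freq=corpus_freq[term],
            left_freq=left[term], right_freq=right[term],
            mi=mi_score(O, f_n, corpus_freq[term], N, window),
            dominant_side=("L" if left[term] > right[term]
                           else "R" if right[term] > left[term] else "tie")))
    return records


def filter_collocates(records: list[CollocateRecord], min_freq: int = 10,
                      min_mi: float = 6.0,
                      top_k: int | None = None) -> list[CollocateRecord]:
    """Apply the frequency and MI cut-offs and rank the survivors.

    Both thresholds are strict (``O > min_freq``, ``mi > min_mi``), matching
    the "frequency > 10" / "MI score > 6" reading. Ranking is MI descending,
    ties broken by O descending then term lexicographic.
    """
    kept = [r for r in records if r.joint_freq > min_freq and r.mi > min_mi]
    kept.sort(key=lambda r: (-r.mi, -r.joint_freq, r.term))
    return kept if top_k is None else kept[:top_k]
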