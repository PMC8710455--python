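"""Independent brute-force oracles used to check the implementation.

These deliberately re-derive each quantity from first principles (quadratic
scans, direct formula evaluation, explicit membership enumeration) without
touching the package's own counting code paths.
"""

from __future__ import annotations

import math
from collections import Counter


def brute_force_collocates(token_docs: list[list[str]], node: str, window: int):
    """Quadratic window scan over every document.

    Returns {term: (O, left, right, f_c)} plus the node frequency and corpus
    size. Counting definition: each collocate token position counts once,
    attributed to the nearest node position (ties to the earlier node).
    """
    left: Counter[str] = Counter()
    right: Counter[str] = Counter()
    freq: Counter[str] = Counter()
    f_n = 0
    N = 0
    for tokens in token_docs:
        N += len(tokens)
        freq.update(tokens)
        nodes = [i for i, t in enumerate(tokens) if t == node]
        f_n += len(nodes)
        for p in range(len(tokens)):
            candidates = [i for i in nodes
                          if i != p and abs(i - p) <= window]
            if not candidates:
                continue
            dmin = min(abs(i - p) for i in candidates)
            nearest = min(i for i in candidates if abs(i - p) == dmin)
            if p < nearest:
                left[tokens[p]] += 1
            else:
                right[tokens[p]] += 1
    out = {}
    for term in set(left) | set(right):
        O = left[term] + right[term]
        out[term] = (O, left[term], right[term], freq[term])
    return out, f_n, N


def brute_force_mi(O: int, f_n: int, f_c: int, N: int, window: int) -> float:
    """Direct evaluation of span-adjusted pointwise MI in bits."""
    expected = f_n * f_c * (2 * window) / N
    return math.log(O / expected, 2)


def brute_force_cosine_ranking(terms, vectors, seed):
    """Pairwise cosine against the seed by explicit dot products."""
    idx = terms.index(seed)
    sv = vectors[idx]

    def cos(a, b):
        num = sum(x * y for x, y in zip(a, b))
        den = math.sqrt(sum(x * x for x in a)) * math.sqrt(sum(y * y for y in b))
        return num / den

    pairs = [(t, cos(v, sv)) for t, v in zip(terms, vectors) if t != seed]
    pairs.sort(key=lambda p: (-p[1], p[0]))
    return pairs


def brute_force_venn(sets: dict[str, set[str]]):
    """Region counts by enumerating every member of the union."""
    labels = list(sets)
    regions: Counter[frozenset] = Counter()
    for term in set().union(*sets.values()):
        membership = frozenset(l for l in labels if term in sets[l])
        regions[membership] += 1
    return regions
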