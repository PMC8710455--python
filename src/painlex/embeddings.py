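"""Embedding-neighbour harvesting with elbow-based similarity cut-offs.

Pre-trained word-vector tables (word2vec text format) are queried for the
cosine-nearest neighbours of a seed term such as "pain". The descending
similarity curve of the top neighbours typically shows a knee: a short head
of genuinely related terms followed by a long flat tail of noise. The knee
is located geometrically — ranks and similarities are min-max normalised to
the unit square and the knee is the point of maximum perpendicular
deviation *below* the chord joining the first and last points (the Kneedle
construction for decreasing curves). Terms strictly above the similarity at
the knee are retained as lexicon candidates; only unigrams survive.

Model training is out of scope here: hyperparameters travel along as
provenance metadata and play no part in the computation.
"""

from __future__ import annotations

import difflib
import gzip
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from .errors import CurveTooShortError, FormatError, MissingSeedError

__all__ = [
    "EmbeddingModelMeta", "VectorTable", "ElbowResult", "CandidateTerm",
    "load_vectors", "write_vectors", "similarity_ranking", "elbow_threshold",
    "harvest_candidates",
]


@dataclass(frozen=True)
class EmbeddingModelMeta:
    """Provenance of a vector table; recorded verbatim, never computed on."""

    model_id: str = "unknown"
    algorithm: str = "other"          # w2v | fasttext | other
    size: int | None = None
    window: int | None = None
    min_count: int | None = None


@dataclass
class VectorTable:
    dimension: int
    terms: list[str]
    vectors: np.ndarray               # shape (n_terms, dimension)
    meta: EmbeddingModelMeta = field(default_factory=EmbeddingModelMeta)
    _index: dict[str, int] = field(default_factory=dict, repr=False)

    def __post_init__(self) -> None:
        if not self._index:
            self._index = {t: i for i, t in enumerate(self.terms)}

    def __len__(self) -> int:
        return len(self.terms)

    def __contains__(self, term: str) -> bool:
        return term in self._index

    def vector(self, term: str) -> np.ndarray:
        return self.vectors[self._index[term]]


@dataclass(frozen=True)
class ElbowResult:
    """Knee location on a descending similarity curve.

    ``elbow_rank`` is 1-based; candidates are the ``retained_count ==
    elbow_rank - 1`` terms strictly above ``threshold`` (the similarity at
    the knee itself, which is excluded). A collinear curve has no knee and
    retains everything but the final point.
    """

    elbow_rank: int
    threshold: float
    retained_count: int


@dataclass(frozen=True)
class CandidateTerm:
    term: str
    similarity: float
    model_id: str


def _open_maybe_gzip(path: Path):
    if path.suffix == ".gz":
        return gzip.open(path, "rt", encoding="utf-8")
    return path.open(encoding="utf-8")


def load_vectors(path: str | Path,
                 meta: EmbeddingModelMeta | None = None) -> VectorTable:
    """Read a word2vec text-format table (header "V D", then V rows).

    Raises :class:`FormatError` naming the offending line on header/row
    count mismatches, wrong dimension, duplicate terms or non-numeric
    values. ``.gz`` files are read transparently.
    """
    path = Path(path)
    with _open_maybe_gzip(path) as fh:
        header = fh.readline().split()
        if len(header) != 2:
            raise FormatError(f"{path}:1: expected header 'V D', got {header!r}")
        try:
            n, dim = int(header[0]), int(header[1])
        except ValueError as exc:
            raise FormatError(f"{path}:1: non-integer header {header!r}") from exc
        if n < 1 or dim < 1:
            raise FormatError(f"{path}:1: header counts must be positive")
        terms: list[str] = []
        seen: set[str] = set()
        rows = np.empty((n, dim), dtype=np.float64)
        lineno = 1
        for lineno, line in enumerate(fh, start=2):
            if lineno - 2 >= n:
                raise FormatError(f"{path}:{lineno}: more rows than header declares")
            parts = line.rstrip("\n").split(" ")
            if len(parts) != dim + 1:
                raise FormatError(
                    f"{path}:{lineno}: expected term + {dim} floats, "
                    f"got {len(parts) - 1} values")
            term = parts[0]
            if term in seen:
                raise FormatError(f"{path}:{lineno}: duplicate term {term!r}")
            seen.add(term)
            try:
                rows[lineno - 2] = [float(x) for x in parts[1:]]
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: non-numeric value") from exc
            terms.append(term)
        if len(terms) != n:
            raise FormatError(
                f"{path}: header declares {n} rows but file has {len(terms)}")
    return VectorTable(dimension=dim, terms=terms, vectors=rows,
                       meta=meta or EmbeddingModelMeta(model_id=path.stem))


def write_vectors(table: VectorTable, path: str | Path,
                  precision: int = 8) -> None:
    """Write a table in word2vec text format (round-trips with load_vectors)."""
    path = Path(path)
    with path.open("w", encoding="utf-8") as fh:
        fh.write(f"{len(table)} {table.dimension}\n")
        fmt = f"%.{precision}f"
        for term, vec in zip(table.terms, table.vectors):
            fh.write(term + " " + " ".join(fmt % x for x in vec) + "\n")


def similarity_ranking(table: VectorTable, seed: str,
                       top_k: int = 100) -> list[tuple[str, float]]:
    """Cosine-nearest neighbours of ``seed``, descending, seed excluded.

    Ties are broken lexicographically for determinism. A missing seed
    raises :class:`MissingSeedError` carrying the closest orthographic
    matches in the vocabulary.
    """
    if top_k < 2:
        raise ValueError("top_k must be >= 2")
    if seed not in table:
        raise MissingSeedError(
            seed, difflib.get_close_matches(seed, table.terms, n=3, cutoff=0.0))
    sv = table.vector(seed)
    sn = np.linalg.norm(sv)
    norms = np.linalg.norm(table.vectors, axis=1)
    norms[norms == 0] = np.nan
    sims = table.vectors @ sv / (norms * (sn if sn else np.nan))
    sims = np.nan_to_num(sims, nan=-2.0)  # zero vectors sink to the bottom
    pairs = [(t, float(s)) for t, s in zip(table.terms, sims) if t != seed]
    pairs.sort(key=lambda p: (-p[1], p[0]))
    return pairs[:top_k]


def elbow_threshold(curve: Sequence[float]) -> ElbowResult:
    """Locate the knee of a non-increasing similarity curve.

    Ranks and similarities are min-max normalised to [0, 1]; the knee is the
    rank maximising the perpendicular distance below the chord from the first
    to the last point. Ties pick the smallest rank. A collinear (or concave)
    curve, where no point falls below the chord, yields ``elbow_rank ==
    len(curve)`` so that all but the final point are retained.

    The construction is invariant to affine rescaling of the similarities.
    """
    n = len(curve)
    if n < 3:
        raise CurveTooShortError(f"need >= 3 points, got {n}")
    y = np.asarray(curve, dtype=np.float64)
    if np.any(np.diff(y) > 1e-12):
        raise ValueError("curve must be non-increasing")
    x = np.linspace(0.0, 1.0, n)
    span = y[0] - y[-1]
    if span <= 0:  # perfectly flat
        return ElbowResult(elbow_rank=n, threshold=float(y[-1]), retained_count=n - 1)
    yn = (y - y[-1]) / span
    # chord runs from (0, 1) to (1, 0); below-chord distance ∝ 1 - x - y
    below = 1.0 - x - yn
    best = int(np.argmax(below))
    if below[best] <= 1e-12:
        best = n - 1
    return ElbowResult(elbow_rank=best + 1, threshold=float(y[best]),
                       retained_count=best)


def _is_unigram(term: str) -> bool:
    return " " not in term.strip() and any(c.isalnum() for c in term)


def harvest_candidates(table: VectorTable, seed: str,
                       top_k: int = 100) -> tuple[list[CandidateTerm], ElbowResult]:
    """Rank neighbours of ``seed``, cut at the elbow, keep unigram terms.

    Returns the candidates (similarity strictly above the elbow threshold,
    multi-token and symbol-only terms dropped, seed never included) together
    with the :class:`ElbowResult` used for the cut.
    """
    ranking = similarity_ranking(table, seed, top_k=top_k)
    elbow = elbow_threshold([s for _, s in ranking])
    return ([CandidateTerm(term=t, similarity=s, model_id=table.meta.model_id)
             for t, s in ranking if s > elbow.threshold and _is_unigram(t)],
            elbow)
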