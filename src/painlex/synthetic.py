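"""Synthetic clinical-note-like corpora, vector tables and term lists.

Every generator here emits its ground truth alongside its data, so each
pipeline stage can be checked against exact planted quantities without any
external download:

* :func:`generate_corpus` — a document collection with an exact planted
  seed-term rate per 10,000 tokens, collocates planted at designed joint and
  marginal frequencies inside a ±window, bigram pain terms, misspellings and
  metaphorical idiom mentions, all recorded in a
  :class:`GroundTruthManifest`;
* :func:`generate_vector_table` — a word-vector table whose cosine curve
  around the seed term has a planted knee (high plateau, drop, low plateau,
  bounded noise);
* :func:`generate_reference_pair` — a lexicon file and reference term list
  with a known exact-match overlap;
* :func:`generate_source_fixture` — three raw term lists engineered to hit
  chosen per-source unique/total counts and a chosen triple overlap.

The filler text uses a closed vocabulary with Zipf-like frequencies so that
planted association statistics stay controllable; no attempt is made at
clinical realism beyond the structural features above.
"""

from __future__ import annotations

import json
import random
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from .collocation import mi_score
from .corpus import Corpus, Document, write_corpus_jsonl
from .embeddings import EmbeddingModelMeta, VectorTable, write_vectors
from .errors import InfeasibleSpecError
from .lexicon import Lexicon, LexiconEntry, RawTermList
from collections import Counter

__all__ = [
    "CollocatePlan", "CorpusSpec", "GroundTruthManifest", "SimilarityProfile",
    "generate_corpus", "generate_vector_table", "max_noise",
    "generate_reference_pair", "generate_source_fixture", "FILLER_VOCAB",
]

# Closed background vocabulary, Zipf-weighted during generation. Neutral
# ward-note filler; anything colliding with planted material is excluded.
FILLER_VOCAB = [
    "patient", "seen", "today", "ward", "review", "plan", "notes", "well",
    "stable", "continue", "home", "team", "nurse", "doctor", "clinic",
    "meeting", "family", "morning", "evening", "sleep", "meals", "mood",
    "settled", "calm", "visit", "report", "letter", "follow", "week",
    "month", "care", "support", "staff", "room", "walk", "rest", "diet",
    "fluids", "obs", "normal", "routine", "checked", "given", "taken",
    "noted", "discussed", "agreed", "referred", "arranged", "attended",
]


@dataclass(frozen=True)
class CollocatePlan:
    """One planted collocate: joint frequency O inside the window, corpus
    marginal f_c, and the fraction of in-window occurrences on the right."""

    term: str
    joint_freq: int
    coll_freq: int
    right_fraction: float = 0.5


@dataclass
class CorpusSpec:
    """Design of a synthetic corpus; all planted counts are exact."""

    n_tokens: int = 10_000
    seed_term: str = "pain"
    planted_rate_per_10k: float = 30.0
    window: int = 5
    collocate_plan: list[CollocatePlan] = field(default_factory=list)
    bigram_plan: list[tuple[str, int]] = field(default_factory=list)
    misspelling_plan: list[tuple[str, str, int]] = field(default_factory=list)
    idiom_plan: list[tuple[str, int]] = field(default_factory=list)
    vocabulary_size: int = 40
    rng_seed: int = 0


@dataclass
class GroundTruthManifest:
    """Exact planted quantities; every value is recomputable by brute force
    on the emitted corpus."""

    n_tokens: int
    seed_term: str
    seed_count: int
    rate_per_10k: float
    window: int
    collocates: dict[str, dict]
    bigrams: dict[str, dict]
    misspellings: dict[str, dict]
    idioms: dict[str, dict]
    rng_seed: int

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=1),
                              encoding="utf-8")


def _validate_corpus_spec(spec: CorpusSpec) -> tuple[int, int, int, list[str]]:
    if spec.n_tokens <= 0 or spec.window < 1:
        raise InfeasibleSpecError("n_tokens and window must be positive")
    f_n = round(spec.planted_rate_per_10k * spec.n_tokens / 10_000)
    if f_n < 1:
        raise InfeasibleSpecError("planted rate yields zero seed occurrences")
    n_bigram = sum(c for _, c in spec.bigram_plan)
    n_idiom = sum(c for _, c in spec.idiom_plan)
    if f_n < n_bigram + n_idiom:
        raise InfeasibleSpecError(
            "bigram + idiom occurrences exceed the planted seed count")
    planted = {spec.seed_term}
    for cp in spec.collocate_plan:
        if cp.joint_freq > cp.coll_freq:
            raise InfeasibleSpecError(
                f"collocate {cp.term!r}: O={cp.joint_freq} > f_c={cp.coll_freq}")
        if cp.joint_freq < 1 or not 0 <= cp.right_fraction <= 1:
            raise InfeasibleSpecError(f"collocate {cp.term!r}: bad plan")
        if cp.term in planted:
            raise InfeasibleSpecError(f"duplicate planted term {cp.term!r}")
        planted.add(cp.term)
    for mod, c in spec.bigram_plan:
        if mod in planted or c < 1:
            raise InfeasibleSpecError(f"bigram modifier {mod!r} clashes or count < 1")
        planted.add(mod)
    for term, variant, c in spec.misspelling_plan:
        if variant in planted or c < 1:
            raise InfeasibleSpecError(f"misspelling {variant!r} clashes or count < 1")
        planted.add(variant)
    for phrase, c in spec.idiom_plan:
        toks = phrase.split()
        if toks.count(spec.seed_term) != 1:
            raise InfeasibleSpecError(
                f"idiom {phrase!r} must contain the seed term exactly once")
        if c < 1:
            raise InfeasibleSpecError(f"idiom {phrase!r}: count < 1")
    vocab = [w for w in FILLER_VOCAB[:spec.vocabulary_size] if w not in planted]
    if len(vocab) < 10:
        raise InfeasibleSpecError("background vocabulary too small after "
                                  "removing planted terms")
    return f_n, n_bigram, n_idiom, vocab


def generate_corpus(spec: CorpusSpec) -> tuple[Corpus, GroundTruthManifest]:
    """Emit a corpus realising ``spec`` exactly, plus its manifest.

    Layout: each seed occurrence lives in its own document with the seed at
    the centre, so collocation windows never interact and planted joint
    frequencies are exact. Planned collocates fill designated in-window
    slots of plain seed documents; marginal top-ups, misspellings and the
    rest of the token budget go into seed-free filler documents. Output is
    byte-reproducible for a fixed ``rng_seed``.
    """
    f_n, n_bigram, n_idiom, vocab = _validate_corpus_spec(spec)
    rng = random.Random(spec.rng_seed)
    w = spec.window
    doc_len = 2 * w + 11
    zipf_weights = [1.0 / (i + 1) for i in range(len(vocab))]

    def fillers(n: int) -> list[str]:
        return rng.choices(vocab, weights=zipf_weights, k=n)

    n_plain = f_n - n_bigram - n_idiom
    seed_pos = doc_len // 2

    # capacity check: planned collocates only go into plain seed documents
    need_left = need_right = 0
    placements: list[tuple[str, str]] = []   # (term, side) per occurrence
    for cp in spec.collocate_plan:
        n_right = round(cp.joint_freq * cp.right_fraction)
        n_left = cp.joint_freq - n_right
        need_left += n_left
        need_right += n_right
        placements += [(cp.term, "L")] * n_left + [(cp.term, "R")] * n_right
    if need_left > n_plain * w or need_right > n_plain * w:
        raise InfeasibleSpecError(
            f"window capacity exceeded: need {need_left}L/{need_right}R slots, "
            f"have {n_plain * w} per side across {n_plain} plain seed documents")

    # build plain seed documents with free in-window slot queues
    plain_docs = [fillers(doc_len) for _ in range(n_plain)]
    for toks in plain_docs:
        toks[seed_pos] = spec.seed_term
    free = {"L": [(b, seed_pos - 1 - k) for k in range(w) for b in range(n_plain)],
            "R": [(b, seed_pos + 1 + k) for k in range(w) for b in range(n_plain)]}
    for term, side in placements:
        b, pos = free[side].pop(0)
        plain_docs[b][pos] = term

    token_budget = spec.n_tokens - (f_n - n_idiom) * doc_len
    docs: list[tuple[list[str], str]] = [(t, "seed") for t in plain_docs]

    for mod, count in spec.bigram_plan:
        for _ in range(count):
            toks = fillers(doc_len)
            toks[seed_pos] = spec.seed_term
            toks[seed_pos - 1] = mod
            docs.append((toks, "seed"))

    for phrase, count in spec.idiom_plan:
        ptoks = phrase.split()
        idoc_len = max(doc_len, len(ptoks) + 2 * w)
        token_budget -= count * idoc_len
        start = (idoc_len - len(ptoks)) // 2
        for _ in range(count):
            toks = fillers(idoc_len)
            toks[start:start + len(ptoks)] = ptoks
            docs.append((toks, f"idiom:{phrase}"))

    # filler documents: marginal top-ups + misspellings + remaining budget
    extras: list[str] = []
    for cp in spec.collocate_plan:
        extras += [cp.term] * (cp.coll_freq - cp.joint_freq)
    for _, variant, count in spec.misspelling_plan:
        extras += [variant] * count
    if token_budget < len(extras):
        raise InfeasibleSpecError(
            f"n_tokens={spec.n_tokens} leaves {token_budget} filler tokens "
            f"but {len(extras)} planted extras are required")
    filler_stream = fillers(token_budget - len(extras)) + extras
    rng.shuffle(filler_stream)
    for i in range(0, len(filler_stream), doc_len):
        docs.append((filler_stream[i:i + doc_len], "filler"))

    rng.shuffle(docs)
    documents = [Document(id=f"doc{i:05d}", text=" ".join(toks),
                          source_tag="synthetic")
                 for i, (toks, _) in enumerate(docs)]
    corpus = Corpus(documents=documents)
    assert corpus.token_count == spec.n_tokens

    N = spec.n_tokens
    collocates = {}
    for cp in spec.collocate_plan:
        n_right = round(cp.joint_freq * cp.right_fraction)
        collocates[cp.term] = {
            "O": cp.joint_freq, "left": cp.joint_freq - n_right,
            "right": n_right, "f_c": cp.coll_freq,
            "expected_mi": mi_score(cp.joint_freq, f_n, cp.coll_freq, N, w)}
    bigrams = {}
    for mod, count in spec.bigram_plan:
        bigrams[f"{mod} {spec.seed_term}"] = {
            "count": count, "modifier": mod,
            "modifier_mi": mi_score(count, f_n, count, N, w)}
    idioms = {}
    for phrase, count in spec.idiom_plan:
        idioms[phrase] = {
            "count": count,
            "doc_ids": [d.id for d, (_, tag) in zip(documents, docs)
                        if tag == f"idiom:{phrase}"]}
    manifest = GroundTruthManifest(
        n_tokens=N, seed_term=spec.seed_term, seed_count=f_n,
        rate_per_10k=f_n * 10_000 / N, window=w, collocates=collocates,
        bigrams=bigrams,
        misspellings={v: {"of": t, "count": c}
                      for t, v, c in spec.misspelling_plan},
        idioms=idioms, rng_seed=spec.rng_seed)
    return corpus, manifest


def write_corpus(corpus: Corpus, manifest: GroundTruthManifest,
                 corpus_path: str | Path, manifest_path: str | Path) -> None:
    write_corpus_jsonl(corpus, corpus_path)
    manifest.to_json(manifest_path)


# ---------------------------------------------------------------------------
# vector tables with a planted similarity knee


@dataclass
class SimilarityProfile:
    """Plateau–knee–plateau cosine profile around a seed term.

    Ranks 1..knee_rank-1 descend through [high_bottom, high_top]; ranks
    knee_rank..n_neighbors form a gently sloping low plateau starting at
    ``low_top``. The high plateau must clear the low one by more than twice
    the noise amplitude (see :func:`max_noise` for the recovery bound).
    """

    n_neighbors: int = 20
    knee_rank: int = 5
    high_top: float = 0.90
    high_bottom: float = 0.75
    low_top: float = 0.25
    slope_frac: float = 0.3     # low-plateau slope as a fraction of rank pitch
    noise: float = 0.0
    dim: int = 16
    seed_term: str = "pain"
    rng_seed: int = 0


def max_noise(profile: SimilarityProfile) -> float:
    """Largest noise amplitude with guaranteed knee-ordering margin.

    Below this bound the below-chord distance at the knee dominates every
    other rank (adjacent low-plateau ranks are the binding constraint), so
    elbow detection recovers the planted rank.
    """
    n = profile.n_neighbors
    curve_range = profile.high_top - max(
        0.0, profile.low_top - (n - profile.knee_rank)
        * profile.slope_frac * (profile.high_top - profile.low_top) / (n - 1))
    margin = curve_range * (1.0 - profile.slope_frac) / (2 * (n - 1))
    separation = (profile.high_bottom - profile.low_top) / 2
    return 0.9 * min(margin, separation)


def _target_curve(profile: SimilarityProfile, rng: random.Random) -> list[float]:
    n, r = profile.n_neighbors, profile.knee_rank
    pitch = profile.slope_frac * (profile.high_top - profile.low_top) / (n - 1)
    ys = []
    for i in range(1, n + 1):
        if i < r:
            frac = (i - 1) / max(1, r - 2)
            y = profile.high_top - frac * (profile.high_top - profile.high_bottom)
        else:
            y = profile.low_top - (i - r) * pitch
        if profile.noise:
            y += rng.uniform(-profile.noise, profile.noise)
        ys.append(y)
    return ys


def generate_vector_table(
        profile: SimilarityProfile,
        path: str | Path | None = None) -> tuple[VectorTable, dict]:
    """Build a vector table realising ``profile``'s cosine curve exactly
    (up to write precision) and return it with its ground-truth manifest."""
    n, r = profile.n_neighbors, profile.knee_rank
    if n < 3 or not 2 <= r <= n - 1:
        raise InfeasibleSpecError("need n_neighbors >= 3 and 2 <= knee_rank "
                                  "<= n_neighbors - 1")
    if profile.high_bottom - profile.low_top <= 2 * profile.noise:
        raise InfeasibleSpecError("plateaus must be separated by more than "
                                  "twice the noise amplitude")
    if profile.noise > max_noise(profile):
        raise InfeasibleSpecError(
            f"noise {profile.noise} above recovery bound {max_noise(profile):.4f}")
    rng = random.Random(profile.rng_seed)
    targets = _target_curve(profile, rng)
    if any(abs(t) >= 1 for t in targets):
        raise InfeasibleSpecError("profile produces cosines outside (-1, 1)")

    np_rng = np.random.default_rng(profile.rng_seed)
    u = np_rng.normal(size=profile.dim)
    u /= np.linalg.norm(u)
    vectors = [u]
    terms = [profile.seed_term]
    for i, c in enumerate(targets, start=1):
        v = np_rng.normal(size=profile.dim)
        v -= (v @ u) * u
        v /= np.linalg.norm(v)
        vectors.append(c * u + np.sqrt(1 - c * c) * v)
        terms.append(f"term{i:03d}")
    table = VectorTable(dimension=profile.dim, terms=terms,
                        vectors=np.asarray(vectors),
                        meta=EmbeddingModelMeta(
                            model_id=f"synthetic-knee{r}", algorithm="other",
                            size=profile.dim))
    if path is not None:
        write_vectors(table, path)
    manifest = {"knee_rank": r, "threshold": targets[r - 1],
                "n_neighbors": n, "target_similarities": targets,
                "noise": profile.noise, "rng_seed": profile.rng_seed}
    return table, manifest


# ---------------------------------------------------------------------------
# reference pairs and engineered multi-source fixtures


def generate_reference_pair(lexicon_size: int, reference_size: int,
                            overlap: int,
                            rng_seed: int = 0) -> tuple[Lexicon, RawTermList]:
    """A lexicon and a reference list with a known exact-match overlap.

    All generated terms survive the standard normalisation and filters, so
    ``compare_reference(..., mode="exact")`` reports exactly ``overlap``
    matches out of ``reference_size``.
    """
    if overlap > min(lexicon_size, reference_size) or min(
            lexicon_size, reference_size) < 1 or overlap < 0:
        raise InfeasibleSpecError("infeasible sizes/overlap")
    rng = random.Random(rng_seed)
    shared = [f"shared{i:04d}" for i in range(overlap)]
    lex_only = [f"lexterm{i:04d}" for i in range(lexicon_size - overlap)]
    ref_only = [f"refterm{i:04d}" for i in range(reference_size - overlap)]
    lex_terms = shared + lex_only
    ref_terms = shared + ref_only
    rng.shuffle(lex_terms)
    rng.shuffle(ref_terms)
    entries = {t: LexiconEntry(term=t, n_tokens=1,
                               sources=Counter({"synthetic": 1}), status="kept")
               for t in sorted(lex_terms)}
    lexicon = Lexicon(entries=entries,
                      build_meta={"synthetic": True, "rng_seed": rng_seed,
                                  "planted_overlap": overlap})
    reference = RawTermList(source_id="reference:synthetic", terms=ref_terms,
                            source_class="reference")
    return lexicon, reference


def generate_source_fixture(
        unique_counts: dict[str, int],
        total_counts: dict[str, int],
        triple_overlap: int,
        rng_seed: int = 0) -> list[RawTermList]:
    """Three raw term lists hitting exact per-source unique/total counts and
    an exact three-way overlap (all other overlap regions empty).

    Keys of both dicts are source ids whose class prefixes label the Venn
    sets (e.g. ``literature``, ``ontology:all``, ``embeddings:all``).
    Duplicates within a source are realised by repeating that source's own
    terms, so totals are exact while unique counts are untouched.
    """
    ids = list(unique_counts)
    if set(ids) != set(total_counts) or len(ids) != 3:
        raise InfeasibleSpecError("need matching unique/total counts for "
                                  "exactly three sources")
    for sid in ids:
        if unique_counts[sid] < triple_overlap or \
                total_counts[sid] < unique_counts[sid]:
            raise InfeasibleSpecError(f"infeasible counts for {sid!r}")
    rng = random.Random(rng_seed)
    shared = [f"common{i:04d}" for i in range(triple_overlap)]
    lists = []
    for k, sid in enumerate(ids):
        own = [f"src{k}term{i:04d}" for i in range(unique_counts[sid]
                                                   - triple_overlap)]
        terms = shared + own
        dupes = total_counts[sid] - unique_counts[sid]
        terms = terms + [terms[i % len(terms)] for i in range(dupes)]
        rng.shuffle(terms)
        lists.append(RawTermList(source_id=sid, terms=terms))
    return lists
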