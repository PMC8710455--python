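"""Vector-table I/O, cosine ranking, elbow thresholds, harvesting."""

import numpy as np
import pytest

from painlex import (VectorTable, elbow_threshold, harvest_candidates,
                     load_vectors, similarity_ranking, write_vectors)
from painlex.embeddings import EmbeddingModelMeta
from painlex.errors import CurveTooShortError, FormatError, MissingSeedError

from oracles import brute_force_cosine_ranking


def _write(tmp_path, content, name="m.vec"):
    path = tmp_path / name
    path.write_text(content)
    return path


def test_load_valid_table(tmp_path):
    path = _write(tmp_path, "3 4\na 1 0 0 0\nb 0 1 0 0\nc 0 0 1 0\n")
    table = load_vectors(path)
    assert (len(table), table.dimension) == (3, 4)
    assert list(table.vector("b")) == [0, 1, 0, 0]


@pytest.mark.parametrize("content,match", [
    ("3 4\na 1 0 0 0\nb 0 1 0\nc 0 0 1 0\n", ":3"),        # short row
    ("2 3\na 1 0 0\na 0 1 0\n", "duplicate"),
    ("2 3\na 1 0 0\nb 0 x 0\n", "non-numeric"),
    ("2 3\na 1 0 0\n", "declares 2"),                       # row shortfall
    ("bad header\n", "header"),
])
def test_malformed_tables_name_the_line(tmp_path, content, match):
    with pytest.raises(FormatError, match=match):
        load_vectors(_write(tmp_path, content))


def test_round_trip_preserves_similarities(tmp_path):
    rng = np.random.default_rng(3)
    table = VectorTable(dimension=8, terms=[f"t{i}" for i in range(10)],
                        vectors=rng.normal(size=(10, 8)))
    path = tmp_path / "rt.vec"
    write_vectors(table, path)
    reloaded = load_vectors(path)
    before = similarity_ranking(table, "t0", top_k=9)
    after = similarity_ranking(reloaded, "t0", top_k=9)
    assert [t for t, _ in before] == [t for t, _ in after]
    for (_, a), (_, b) in zip(before, after):
        assert abs(a - b) < 1e-6


def test_identical_vector_ranks_first_with_similarity_one():
    table = VectorTable(dimension=2, terms=["pain", "twin", "ortho"],
                        vectors=np.array([[1.0, 0.0], [2.0, 0.0], [0.0, 1.0]]))
    ranking = similarity_ranking(table, "pain", top_k=2)
    assert ranking[0] == ("twin", pytest.approx(1.0))
    assert ranking[1] == ("ortho", pytest.approx(0.0))


def test_ranking_matches_brute_force_pairwise_cosine():
    rng = np.random.default_rng(7)
    terms = ["pain"] + [f"w{i}" for i in range(9)]
    vectors = rng.normal(size=(10, 5))
    table = VectorTable(dimension=5, terms=terms, vectors=vectors)
    expected = brute_force_cosine_ranking(terms, vectors.tolist(), "pain")
    got = similarity_ranking(table, "pain", top_k=9)
    assert [t for t, _ in got] == [t for t, _ in expected]
    for (_, a), (_, b) in zip(got, expected):
        assert abs(a - b) < 1e-9


def test_missing_seed_lists_orthographic_neighbours():
    table = VectorTable(dimension=2, terms=["pains", "ache"],
                        vectors=np.eye(2))
    with pytest.raises(MissingSeedError) as exc:
        similarity_ranking(table, "pain", top_k=2)
    assert "pains" in exc.value.suggestions


def test_elbow_hand_geometry_example():
    result = elbow_threshold([0.95, 0.90, 0.85, 0.40, 0.38, 0.36, 0.34])
    assert result.elbow_rank == 4
    assert result.threshold == pytest.approx(0.40)
    assert result.retained_count == 3


def test_elbow_collinear_curve_retains_all():
    curve = list(np.linspace(0.9, 0.1, 9))
    result = elbow_threshold(curve)
    assert result.elbow_rank == 9
    assert result.retained_count == 8


def test_elbow_contract_violations():
    with pytest.raises(CurveTooShortError):
        elbow_threshold([0.9, 0.1])
    with pytest.raises(ValueError):
        elbow_threshold([0.1, 0.5, 0.9])


def test_elbow_invariant_to_affine_rescaling():
    curve = [0.95, 0.90, 0.85, 0.40, 0.38, 0.36, 0.34]
    rescaled = [0.2 * y + 3.0 for y in curve]
    assert elbow_threshold(rescaled).elbow_rank == elbow_threshold(curve).elbow_rank


def test_harvest_is_order_preserving_subset_without_seed(tmp_path):
    rng = np.random.default_rng(11)
    terms = ["pain"] + [f"w{i}" for i in range(19)]
    table = VectorTable(dimension=6, terms=terms, vectors=rng.normal(size=(20, 6)))
    ranking = similarity_ranking(table, "pain", top_k=19)
    candidates, elbow = harvest_candidates(table, "pain", top_k=19)
    ranked_terms = [t for t, _ in ranking]
    cand_terms = [c.term for c in candidates]
    assert "pain" not in cand_terms
    # subset, order preserved
    positions = [ranked_terms.index(t) for t in cand_terms]
    assert positions == sorted(positions)
    for c in candidates:
        assert c.similarity > elbow.threshold
        assert " " not in c.term


def test_harvest_drops_multi_token_and_symbol_terms():
    vecs = np.array([[1, 0], [0.99, 0.1], [0.98, 0.15], [0.97, 0.2],
                     [0.1, 1.0], [0.05, 1.0], [0.0, 1.0]])
    terms = ["pain", "sore_ness", "!!", "ache", "far1", "far2", "far3"]
    table = VectorTable(dimension=2, terms=terms, vectors=vecs,
                        meta=EmbeddingModelMeta(model_id="toy"))
    candidates, _ = harvest_candidates(table, "pain", top_k=6)
    assert all(any(ch.isalnum() for ch in c.term) for c in candidates)
    assert all(c.model_id == "toy" for c in candidates)
    assert "!!" not in {c.term for c in candidates}
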