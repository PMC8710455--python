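"""Ground-truth generators: manifests must equal brute-force recomputation."""

import json

import pytest

from painlex import (CollocatePlan, CorpusSpec, SimilarityProfile, TermPattern,
                     compare_reference, elbow_threshold, extract_collocates,
                     generate_corpus, generate_reference_pair,
                     generate_source_fixture, generate_vector_table,
                     load_vectors, max_noise, read_corpus, similarity_ranking,
                     term_rate, write_corpus_jsonl)
from painlex.errors import InfeasibleSpecError

from oracles import brute_force_collocates


def _spec(**kw):
    defaults = dict(
        n_tokens=10_000, planted_rate_per_10k=30.0,
        collocate_plan=[CollocatePlan("killers", 3, 4, right_fraction=1.0),
                        CollocatePlan("fibromyalgia", 12, 20, right_fraction=0.5)],
        bigram_plan=[("chronic", 4)],
        misspelling_plan=[("pain", "pian", 3)],
        idiom_plan=[("pain in the neck", 2)],
        rng_seed=7)
    defaults.update(kw)
    return CorpusSpec(**defaults)


def test_manifest_matches_brute_force_recomputation():
    corpus, manifest = generate_corpus(_spec())
    assert corpus.token_count == manifest.n_tokens == 10_000

    rate = term_rate(corpus, TermPattern("literal", "pain"))
    assert rate.raw_count == manifest.seed_count
    assert rate.rate_per_10k == manifest.rate_per_10k == 30.0

    token_docs = [d.tokens for d in corpus]
    oracle, f_n, N = brute_force_collocates(token_docs, "pain",
                                            manifest.window)
    assert f_n == manifest.seed_count
    for term, truth in manifest.collocates.items():
        O, L, R, f_c = oracle[term]
        assert (O, L, R, f_c) == (truth["O"], truth["left"], truth["right"],
                                  truth["f_c"])

    recs = {r.term: r for r in extract_collocates(corpus, "pain",
                                                  manifest.window)}
    for term, truth in manifest.collocates.items():
        assert recs[term].joint_freq == truth["O"]
        assert recs[term].mi == pytest.approx(truth["expected_mi"])


def test_planted_bigram_misspelling_and_idiom_counts():
    corpus, manifest = generate_corpus(_spec())
    phrase = term_rate(corpus, TermPattern("phrase", "chronic pain"))
    assert phrase.raw_count == manifest.bigrams["chronic pain"]["count"] == 4
    pian = term_rate(corpus, TermPattern("literal", "pian"))
    assert pian.raw_count == manifest.misspellings["pian"]["count"] == 3
    idiom = manifest.idioms["pain in the neck"]
    assert len(idiom["doc_ids"]) == idiom["count"] == 2
    by_id = {d.id: d for d in corpus}
    for doc_id in idiom["doc_ids"]:
        assert "pain in the neck" in by_id[doc_id].text


def test_generation_deterministic_and_round_trips(tmp_path):
    c1, m1 = generate_corpus(_spec())
    c2, m2 = generate_corpus(_spec())
    assert [(d.id, d.text) for d in c1] == [(d.id, d.text) for d in c2]
    assert m1 == m2
    p1, p2 = tmp_path / "a.jsonl", tmp_path / "b.jsonl"
    write_corpus_jsonl(c1, p1)
    write_corpus_jsonl(c2, p2)
    assert p1.read_bytes() == p2.read_bytes()
    reread = read_corpus(p1, format="jsonl")
    assert [(d.id, d.text) for d in reread] == [(d.id, d.text) for d in c1]


@pytest.mark.parametrize("bad", [
    dict(collocate_plan=[CollocatePlan("x-term", 5, 4)]),   # O > f_c
    dict(planted_rate_per_10k=0.0),
    dict(n_tokens=700),                                     # budget too small
    dict(idiom_plan=[("no seed here", 1)]),
])
def test_infeasible_specs_rejected_before_generation(bad):
    with pytest.raises(InfeasibleSpecError):
        generate_corpus(_spec(**bad))


def test_vector_table_knee_recovery_zero_noise(tmp_path):
    profile = SimilarityProfile(n_neighbors=20, knee_rank=4, noise=0.0,
                                rng_seed=3)
    path = tmp_path / "knee.vec"
    table, manifest = generate_vector_table(profile, path)
    reloaded = load_vectors(path)
    curve = [s for _, s in similarity_ranking(reloaded, "pain", top_k=20)]
    result = elbow_threshold(curve)
    assert result.elbow_rank == manifest["knee_rank"] == 4
    assert result.retained_count == 3


def test_vector_table_knee_recovery_under_noise_bound():
    """>=95% recovery over 100 seeded tables with noise at the bound."""
    hits = 0
    for seed in range(100):
        profile = SimilarityProfile(n_neighbors=24, knee_rank=3 + seed % 18,
                                    rng_seed=seed)
        profile.noise = 0.99 * max_noise(profile)
        table, manifest = generate_vector_table(profile)
        curve = [s for _, s in similarity_ranking(table, "pain", top_k=24)]
        hits += elbow_threshold(curve).elbow_rank == manifest["knee_rank"]
    assert hits >= 95


def test_vector_profile_validation():
    with pytest.raises(InfeasibleSpecError):
        generate_vector_table(SimilarityProfile(n_neighbors=10, knee_rank=10))
    p = SimilarityProfile(n_neighbors=20, knee_rank=5)
    p.noise = 2 * max_noise(p)
    with pytest.raises(InfeasibleSpecError):
        generate_vector_table(p)


def test_reference_pair_overlap_by_construction():
    lex, ref = generate_reference_pair(382, 26, 18, rng_seed=2)
    report = compare_reference(lex, ref, mode="exact")
    assert report.matched_count == 18
    assert report.matched_percent == pytest.approx(100 * 18 / 26)
    zero = compare_reference(*generate_reference_pair(50, 10, 0), mode="exact")
    assert zero.matched_percent == 0.0
    full = compare_reference(*generate_reference_pair(50, 10, 10), mode="exact")
    assert full.matched_percent == 100.0


def test_reference_pair_infeasible_sizes():
    with pytest.raises(InfeasibleSpecError):
        generate_reference_pair(10, 5, 7)


def test_source_fixture_counts_exact():
    lists = generate_source_fixture(
        unique_counts={"literature": 12, "ontology": 9, "embeddings": 7},
        total_counts={"literature": 15, "ontology": 20, "embeddings": 7},
        triple_overlap=3, rng_seed=1)
    for tl, (u, t) in zip(lists, [(12, 15), (9, 20), (7, 7)]):
        assert len(set(tl.terms)) == u
        assert len(tl.terms) == t
    shared = set(lists[0].terms) & set(lists[1].terms) & set(lists[2].terms)
    assert len(shared) == 3
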