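"""Harvest lexicon candidates from a word-vector table with an elbow cut.

Builds a vector table whose cosine curve around "pain" has a planted knee
at rank 6 (five genuinely similar terms, then a noise plateau), writes it in
word2vec text format, reloads it, and harvests candidates.
"""

from painlex import (SimilarityProfile, generate_vector_table,
                     harvest_candidates, load_vectors, similarity_ranking)

profile = SimilarityProfile(n_neighbors=20, knee_rank=6, noise=0.01,
                            rng_seed=5)
table, manifest = generate_vector_table(profile, "/tmp/pain_model.vec")
reloaded = load_vectors("/tmp/pain_model.vec")

ranking = similarity_ranking(reloaded, "pain", top_k=20)
print("top neighbours of 'pain':")
for term, sim in ranking[:8]:
    print(f"  {term:10s} cos={sim:.3f}")

candidates, elbow = harvest_candidates(reloaded, "pain", top_k=20)
print(f"elbow at rank {elbow.elbow_rank} (planted {manifest['knee_rank']}), "
      f"similarity threshold {elbow.threshold:.3f}")
print(f"{len(candidates)} unigram candidates retained:",
      [c.term for c in candidates])
# Everything strictly above the knee similarity joins the candidate pool;
# the flat tail below it is discarded as noise.
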