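"""Structural patterns in pain terms and wildcard stem frequencies.

Most compound pain terms decompose into anatomy / quality / head slots
("chest pain" = <anatomy><head>, "headache" = head+ache fused). The short
head-term list then drives SQL-style wildcard searches (%ache%, %pain%)
over a corpus.
"""

from painlex import (CorpusSpec, RawTermList, assign_patterns,
                     extract_head_terms, generate_corpus, merge_sources,
                     wildcard_search)

lexicon = merge_sources([RawTermList("literature:demo", [
    "chest pain", "burning pain", "headache", "belly ache",
    "head discomfort", "pain", "soreness"])])

anatomy = {"chest", "back", "head", "belly"}
quality = {"burning", "chronic", "severe"}
heads = {"pain", "ache", "discomfort", "colic"}

print("template assignments:")
for a in assign_patterns(lexicon, anatomy, quality, heads):
    print(f"  {a.term:16s} -> {a.template:18s} {dict(a.bindings)}")

print("head-term participation:", extract_head_terms(lexicon, heads))
# "pain" anchors the most compounds, then "ache" — a two-head shortlist
# already covers most of this lexicon.

spec = CorpusSpec(n_tokens=5_000, planted_rate_per_10k=24.0,
                  misspelling_plan=[("ache", "headache", 6),
                                    ("ache", "backache", 3)],
                  rng_seed=2)
corpus, _ = generate_corpus(spec)
print("wildcard document frequencies:")
for report in wildcard_search(corpus, ["%ache%", "%pain%", "pain"]):
    print(f"  {report.pattern:8s} {report.matched_docs:3d}/{report.total_docs} "
          f"docs = {report.percent:.1f}%")
# %pain% >= pain by construction: the contains pattern also hits compounds.
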