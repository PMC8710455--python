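"""Merge literature, ontology and embedding terms into a reviewed lexicon.

Shows the full curation path: normalisation, the ≤2-token and ≥4-character
filters, provenance-tracked merging, duplicate-frequency profiling, and a
clinician-style decision file adding and removing terms.
"""

from painlex import (RawTermList, ReviewDecision, apply_review_decisions,
                     merge_sources, term_frequency_profile, write_lexicon)

lists = [
    RawTermList("literature:symptoms", [
        "Pain", "ache", "sore", "tenderness", "head discomfort",
        "pain of jaw",          # three tokens -> filtered
        "backache", "pain"]),
    RawTermList("ontology:flat-export", [
        "pain", "chest pain", "colic", "hip",   # "hip" too short -> filtered
        "neuralgia", "abdominal pain"]),
    RawTermList("embeddings:mimic-w2v", [
        "pain", "pians",        # a captured misspelling stays in
        "soreness", "discomfort"]),
]
lexicon = merge_sources(lists)
print(f"merged: {lexicon.unique_size} unique terms, "
      f"{lexicon.total_multiset_count} total occurrences")
for raw in lexicon.build_meta["dropped"]:
    print(f"  dropped {raw['raw']!r}: {raw['reason']}")

print("most frequent terms:", term_frequency_profile(lexicon, top_n=3))

reviewed = apply_review_decisions(lexicon, [
    ReviewDecision("tenderness", "remove", "vague"),
    ReviewDecision("lbp", "add"),           # clinician-added acronym
    ReviewDecision("antalgic gait", "add"),
])
print(f"after review: {reviewed.unique_size} active terms "
      f"({len(reviewed.build_meta['decisions'])} audited decisions)")

write_lexicon(reviewed, "/tmp/pain_lexicon.tsv")
print("written to /tmp/pain_lexicon.tsv")
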