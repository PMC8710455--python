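"""Evaluate a lexicon: source coverage, Venn regions, reference overlap.

Uses an engineered three-source fixture whose coverage and overlap numbers
are known by construction, then compares a 382-term lexicon against a
26-term reference list sharing 18 terms — the shape of a validation against
a small curated pain sub-ontology.
"""

from painlex import (compare_reference, generate_reference_pair,
                     generate_source_fixture, merge_sources, source_coverage,
                     venn_counts)

lists = generate_source_fixture(
    unique_counts={"literature": 218, "ontology": 291, "embeddings": 68},
    total_counts={"literature": 241, "ontology": 523, "embeddings": 171},
    triple_overlap=6, rng_seed=9)
lexicon = merge_sources(lists)

print("coverage (unique / total) per source:")
for row in source_coverage(lexicon):
    print(f"  {row.source_class:12s} {row.unique_terms:4d} / {row.total_terms}")
print("total term occurrences incl. duplicates:",
      lexicon.total_multiset_count)

venn = venn_counts({tl.source_id: set(tl.terms) for tl in lists})
print("three-way overlap:",
      venn.region("literature", "ontology", "embeddings"),
      "| union:", venn.union_size)

lex, reference = generate_reference_pair(lexicon_size=382, reference_size=26,
                                         overlap=18, rng_seed=9)
report = compare_reference(lex, reference, mode="exact")
print(f"reference check: {report.matched_count}/{report.reference_size} "
      f"terms matched ({report.matched_percent:.1f}%), "
      f"{len(report.unmatched_terms)} left for manual inspection")
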