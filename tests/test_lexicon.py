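"""Normalisation, filters, merging, review decisions, lexicon I/O."""

import pytest
from hypothesis import given, settings, strategies as st

from painlex import (Lexicon, RawTermList, ReviewDecision,
                     apply_review_decisions, length_filter, merge_sources,
                     normalize_term, read_decisions, read_lexicon,
                     term_frequency_profile, token_filter, write_lexicon)
from painlex.errors import ConfigurationError, FormatError


@pytest.mark.parametrize("raw,expected", [
    (" Chronic  Pain!! ", "chronic pain"),
    ("PAIN", "pain"),
    ("++--", ""),
    ("back-pain", "back pain"),
])
def test_normalize_examples(raw, expected):
    assert normalize_term(raw) == expected


@given(st.text(max_size=80))
@settings(max_examples=200, deadline=None)
def test_normalize_idempotent(raw):
    once = normalize_term(raw)
    assert normalize_term(once) == once


@pytest.mark.parametrize("term,keep", [
    ("pain of jaw", False),   # three tokens
    ("chest pain", True),
    ("pain", True),
])
def test_token_filter(term, keep):
    assert token_filter(term) is keep


@pytest.mark.parametrize("term,keep", [
    ("hip", False),           # 3 chars
    ("ache", True),           # exactly at the 4-char boundary
    ("jaw pain", True),       # bigram exemption from the length rule
])
def test_length_filter(term, keep):
    assert length_filter(term) is keep


def test_merge_hand_example(toy_lexicon):
    assert len(toy_lexicon) == 4
    assert toy_lexicon.entries["pain"].total_count == 3
    assert toy_lexicon.total_multiset_count == 6


def test_merge_conservation_and_permutation_invariance():
    lists = [
        RawTermList("literature:a", ["pain", "Hip", "pain of jaw", "ache!",
                                     "chest pain"]),
        RawTermList("ontology:b", ["pain", "colic", "++"]),
        RawTermList("embeddings:c", ["soreness", "pain"]),
    ]
    lex = merge_sources(lists)
    surviving = sum(s["surviving_terms"]
                    for s in lex.build_meta["sources"].values())
    assert lex.total_multiset_count == surviving
    # "Hip" (short), "pain of jaw" (long), "++" (empty) were dropped with reasons
    reasons = {d["raw"]: d["reason"] for d in lex.build_meta["dropped"]}
    assert reasons == {"Hip": "under-four-characters",
                       "pain of jaw": "more-than-two-tokens",
                       "++": "empty-after-normalization"}
    permuted = merge_sources(list(reversed(lists)))
    assert [e.term for e in lex.sorted_entries()] == \
        [e.term for e in permuted.sorted_entries()]
    assert {t: e.sources for t, e in lex.entries.items()} == \
        {t: e.sources for t, e in permuted.entries.items()}


def test_duplicate_source_id_rejected():
    with pytest.raises(ConfigurationError, match="duplicate source ids"):
        merge_sources([RawTermList("literature:a", ["pain"]),
                       RawTermList("literature:a", ["ache"])])


def test_empty_merge_warns():
    lex = merge_sources([RawTermList("literature:a", [])])
    assert len(lex) == 0
    assert "warning" in lex.build_meta


def test_frequency_profile_ranking(toy_lexicon):
    profile = term_frequency_profile(toy_lexicon)
    assert profile[0] == ("pain", 3)
    assert [c for _, c in profile[1:]] == [1, 1, 1]
    assert term_frequency_profile(toy_lexicon, top_n=100) == profile


def test_frequency_profile_recovers_planted_counts():
    lists = [RawTermList("literature:x",
                         ["pain"] * 46 + ["discomfort"] * 10 + ["headache"] * 8)]
    profile = term_frequency_profile(merge_sources(lists), top_n=3)
    assert profile == [("pain", 46), ("discomfort", 10), ("headache", 8)]


def _fixture_lexicon(n_unique=410):
    terms = [f"fixture{i:04d}" for i in range(n_unique)]
    return merge_sources([RawTermList("literature:fx", terms)])


def test_review_arithmetic_410_minus_39_plus_11():
    lex = _fixture_lexicon(410)
    decisions = (
        [ReviewDecision(f"fixture{i:04d}", "remove", "not-pain")
         for i in range(39)]
        + [ReviewDecision(f"added{i:02d}", "add") for i in range(10)]
        + [ReviewDecision("lbp", "add")])
    reviewed = apply_review_decisions(lex, decisions)
    assert reviewed.unique_size == 382
    assert reviewed.entries["lbp"].status == "added"
    assert reviewed.entries["lbp"].sources == {"review": 1}
    audit = reviewed.build_meta["decisions"]
    assert len(audit) == 50
    assert sum(1 for a in audit if a["action"] == "remove") == 39
    # the original lexicon is untouched
    assert lex.unique_size == 410


def test_review_is_reversible_from_audit_trail():
    lex = _fixture_lexicon(20)
    decisions = [ReviewDecision("fixture0001", "remove", "vague"),
                 ReviewDecision("newterm", "add")]
    reviewed = apply_review_decisions(lex, decisions)
    restored = set(reviewed.active_terms())
    for event in reviewed.build_meta["decisions"]:
        if event["action"] == "remove":
            restored.add(event["term"])
        elif event["action"] == "add":
            restored.discard(event["term"])
    assert restored == lex.active_terms()


def test_empty_decision_list_is_identity(toy_lexicon):
    reviewed = apply_review_decisions(toy_lexicon, [])
    assert reviewed.active_terms() == toy_lexicon.active_terms()


def test_removing_unknown_term_lists_near_matches(toy_lexicon):
    with pytest.raises(ConfigurationError, match="akhe"):
        apply_review_decisions(
            toy_lexicon, [ReviewDecision("ahke", "remove", "not-pain")])


def test_conflicting_decisions_rejected(toy_lexicon):
    with pytest.raises(ConfigurationError, match="conflicting"):
        apply_review_decisions(toy_lexicon, [
            ReviewDecision("pain", "keep"),
            ReviewDecision("pain", "remove", "vague")])


def test_removal_requires_category(toy_lexicon):
    with pytest.raises(ConfigurationError, match="category"):
        apply_review_decisions(toy_lexicon, [ReviewDecision("pain", "remove")])


def test_decision_file_round_trip(tmp_path, toy_lexicon):
    path = tmp_path / "decisions.tsv"
    path.write_text("term\taction\tcategory\n"
                    "akhe\tremove\tnot-pain\n"
                    "LBP\tadd\t\n")
    decisions = read_decisions(path)
    assert decisions[1].term == "lbp"  # normalized on load
    reviewed = apply_review_decisions(toy_lexicon, path)
    assert "lbp" in reviewed.active_terms()
    assert "akhe" not in reviewed.active_terms()


def test_lexicon_tsv_round_trip(tmp_path, toy_lexicon):
    reviewed = apply_review_decisions(
        toy_lexicon, [ReviewDecision("akhe", "remove", "ambiguous")])
    path = tmp_path / "lex.tsv"
    write_lexicon(reviewed, path)
    back = read_lexicon(path)
    assert [e.term for e in back.sorted_entries()] == \
        [e.term for e in reviewed.sorted_entries()]
    for term, entry in reviewed.entries.items():
        b = back.entries[term]
        assert (b.sources, b.status, b.removal_category) == \
            (entry.sources, entry.status, entry.removal_category)


def test_duplicate_term_rows_rejected(tmp_path):
    path = tmp_path / "bad.tsv"
    path.write_text("term\tn_tokens\tsources\tcount\tstatus\tcategory\n"
                    "pain\t1\tliterature:a=1\t1\tcandidate\t\n"
                    "pain\t1\tontology:b=1\t1\tcandidate\t\n")
    with pytest.raises(FormatError, match="duplicate term"):
        read_lexicon(path)
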