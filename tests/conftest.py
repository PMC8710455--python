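import random

import pytest

from painlex import Corpus, Document, RawTermList, corpus_from_texts, merge_sources


@pytest.fixture
def toy_corpus() -> Corpus:
    return corpus_from_texts([
        "Severe pain today in the lower back.",
        "No complaints, patient settled and calm.",
        "Chronic pain. The pain is in my shoulder and painful to touch.",
    ])


@pytest.fixture
def toy_lexicon():
    """The three-source hand-merge example: 4 unique terms, 'pain' seen 3x."""
    return merge_sources([
        RawTermList(source_id="literature:lit1", terms=["pain", "ache"]),
        RawTermList(source_id="ontology:onto1", terms=["pain", "colic"]),
        RawTermList(source_id="embeddings:emb1", terms=["pain", "akhe"]),
    ])


def random_token_docs(rng: random.Random, n_docs: int, max_len: int,
                      vocab: list[str]) -> list[list[str]]:
    """Small random corpora for oracle-equivalence checks."""
    return [[rng.choice(vocab) for _ in range(rng.randint(1, max_len))]
            for _ in range(n_docs)]


def docs_to_corpus(token_docs: list[list[str]]) -> Corpus:
    return Corpus(documents=[
        Document(id=f"d{i}", text=" ".join(toks), source_tag="test")
        for i, toks in enumerate(token_docs)])
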