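import numpy as np
import pytest

from forumtopics.preprocess import build_dictionary, encode_corpus
from forumtopics.synthetic import SyntheticSpec, generate_token_docs, pseudo_word


@pytest.fixture(scope="session")
def small_spec():
    """A small, fast synthetic corpus spec shared by the cheaper tests."""
    return SyntheticSpec(
        K_true=3,
        vocab_size=120,
        n_docs={"synthetic_A": 250, "synthetic_B": 250},
        doc_length_mean=40.0,
        topic_separation=0.9,
        seed=42,
    )


@pytest.fixture(scope="session")
def small_corpus(small_spec):
    """(token docs, dictionary, bows, truth, truth-aligned column order)."""
    docs, truth = generate_token_docs(small_spec)
    dictionary = build_dictionary(docs, min_collection_count=1, max_doc_fraction=1.0)
    bows, _ = encode_corpus(docs, dictionary)
    col_of = [
        dictionary.word2id[pseudo_word(i)] for i in range(small_spec.vocab_size)
    ]
    return docs, dictionary, bows, truth, np.array(col_of)
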