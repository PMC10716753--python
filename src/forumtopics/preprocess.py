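"""Bag-of-words preprocessing for topic modeling.

The chain mirrors common practice for forum-text LDA: split on
non-alphanumeric boundaries, drop purely numeric tokens, lowercase, remove
stopwords, drop tokens shorter than four characters, Porter-stem the rest,
merge frequent adjacent pairs into single ``a_b`` bigram tokens, then build
a vocabulary filtered by total occurrence count and document frequency.
"""

from __future__ import annotations

import json
import re
from collections import Counter
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import scipy.io
import scipy.sparse

from .stemming import porter_stem

__all__ = [
    "TokenDoc",
    "Dictionary",
    "BowDoc",
    "BigramConfig",
    "default_stopwords",
    "tokenize_and_normalize",
    "detect_bigrams",
    "build_dictionary",
    "encode_bow",
    "encode_corpus",
    "corpus_to_sparse",
]

_TOKEN_RE = re.compile(r"[A-Za-z0-9]+")
_MIN_TOKEN_LEN = 4


def default_stopwords() -> frozenset[str]:
    """The vendored 179-word standard English stopword list."""
    text = (
        resources.files("forumtopics.data")
        .joinpath("stopwords_english.txt")
        .read_text(encoding="utf-8")
    )
    return frozenset(w.strip() for w in text.splitlines() if w.strip())


@dataclass(slots=True)
class TokenDoc:
    """A tokenized post: lowercase stemmed tokens, bigrams joined by ``_``."""

    post_id: str
    tokens: list[str]


@dataclass(slots=True)
class BowDoc:
    """A post as sparse word-id counts against a :class:`Dictionary`."""

    post_id: str
    counts: dict[int, int]

    @property
    def is_empty(self) -> bool:
        return not self.counts

    @property
    def n_tokens(self) -> int:
        return sum(self.counts.values())


@dataclass(slots=True)
class BigramConfig:
    """Collocation-detection settings.

    score(a, b) = (count(a,b) - min_count) * N_tokens / (count(a) * count(b));
    adjacent pairs scoring above ``threshold`` are merged into ``a_b``.
    """

    min_count: int = 5
    threshold: float = 10.0

    def __post_init__(self) -> None:
        if self.min_count < 1:
            raise ValueError("min_count must be >= 1")
        if self.threshold <= 0:
            raise ValueError("threshold must be positive")


class Dictionary:
    """Word ↔ dense-integer-id bijection with corpus frequency statistics."""

    def __init__(
        self,
        words: Sequence[str],
        collection_count: dict[str, int],
        doc_count: dict[str, int],
        n_docs: int,
    ) -> None:
        self.id2word: list[str] = list(words)
        self.word2id: dict[str, int] = {w: i for i, w in enumerate(self.id2word)}
        self.collection_count = {w: collection_count[w] for w in self.id2word}
        self.doc_count = {w: doc_count[w] for w in self.id2word}
        self.n_docs = n_docs

    def __len__(self) -> int:
        return len(self.id2word)

    def __contains__(self, word: str) -> bool:
        return word in self.word2id

    def save_tsv(self, path: str | Path) -> None:
        with Path(path).open("w", encoding="utf-8") as fh:
            fh.write(f"# n_docs={self.n_docs}\n")
            fh.write("id\tword\tcollection_count\tdoc_count\n")
            for i, w in enumerate(self.id2word):
                fh.write(f"{i}\t{w}\t{self.collection_count[w]}\t{self.doc_count[w]}\n")

    @classmethod
    def load_tsv(cls, path: str | Path) -> "Dictionary":
        words, cc, dc = [], {}, {}
        n_docs = 0
        with Path(path).open(encoding="utf-8") as fh:
            for line in fh:
                line = line.rstrip("\n")
                if line.startswith("# n_docs="):
                    n_docs = int(line.split("=", 1)[1])
                    continue
                if not line or line.startswith("id\t"):
                    continue
                idx, word, c, d = line.split("\t")
                assert int(idx) == len(words), "dictionary ids must be dense"
                words.append(word)
                cc[word] = int(c)
                dc[word] = int(d)
        return cls(words, cc, dc, n_docs)


def tokenize_and_normalize(
    text: str, stopwords: frozenset[str] | set[str] | None = None
) -> list[str]:
    """Tokenize one text into lowercase Porter-stemmed tokens.

    Stopwords and tokens shorter than four characters are removed before
    stemming; purely numeric tokens are removed.
    """
    if stopwords is None:
        stopwords = default_stopwords()
    out = []
    for raw in _TOKEN_RE.findall(text):
        token = raw.lower()
        if token.isdigit():
            continue
        if token in stopwords:
            continue
        if len(token) < _MIN_TOKEN_LEN:
            continue
        out.append(porter_stem(token))
    return out


def detect_bigrams(
    docs: Sequence[TokenDoc], cfg: BigramConfig | None = None
) -> list[TokenDoc]:
    """Merge high-scoring adjacent token pairs into single ``a_b`` tokens.

    One left-to-right pass per document; a token participates in at most
    one merge, so no token ever contains more than one underscore.
    """
    cfg = cfg or BigramConfig()
    unigram = Counter()
    pair = Counter()
    n_tokens = 0
    for doc in docs:
        unigram.update(doc.tokens)
        n_tokens += len(doc.tokens)
        pair.update(zip(doc.tokens, doc.tokens[1:]))

    def score(a: str, b: str) -> float:
        return (pair[(a, b)] - cfg.min_count) * n_tokens / (unigram[a] * unigram[b])

    merge = {
        (a, b)
        for (a, b) in pair
        if pair[(a, b)] > cfg.min_count and score(a, b) > cfg.threshold
    }

    out = []
    for doc in docs:
        tokens = doc.tokens
        merged: list[str] = []
        i = 0
        while i < len(tokens):
            if i + 1 < len(tokens) and (tokens[i], tokens[i + 1]) in merge:
                merged.append(f"{tokens[i]}_{tokens[i + 1]}")
                i += 2
            else:
                merged.append(tokens[i])
                i += 1
        out.append(TokenDoc(doc.post_id, merged))
    return out


def build_dictionary(
    docs: Sequence[TokenDoc],
    min_collection_count: int = 50,
    max_doc_fraction: float = 0.5,
) -> Dictionary:
    """Build the filtered vocabulary with deterministic lexicographic ids.

    Words with fewer than ``min_collection_count`` total occurrences, or
    appearing in more than ``max_doc_fraction`` of documents, are removed.
    """
    if not docs:
        raise ValueError("cannot build a dictionary from an empty corpus")
    collection = Counter()
    doc_freq = Counter()
    for doc in docs:
        collection.update(doc.tokens)
        doc_freq.update(set(doc.tokens))
    n_docs = len(docs)
    kept = sorted(
        w
        for w in collection
        if collection[w] >= min_collection_count
        and doc_freq[w] / n_docs <= max_doc_fraction
    )
    if not kept:
        raise ValueError("vocabulary is empty after frequency filtering")
    return Dictionary(kept, dict(collection), dict(doc_freq), n_docs)


def encode_bow(doc: TokenDoc, dictionary: Dictionary) -> BowDoc:
    """Encode one document as word-id counts; OOV tokens are dropped."""
    counts = Counter(
        dictionary.word2id[t] for t in doc.tokens if t in dictionary.word2id
    )
    return BowDoc(doc.post_id, dict(sorted(counts.items())))


def encode_corpus(
    docs: Sequence[TokenDoc], dictionary: Dictionary
) -> tuple[list[BowDoc], list[str]]:
    """Encode all documents; returns (non-empty BowDocs, empty post_ids)."""
    bows, empty = [], []
    for doc in docs:
        bow = encode_bow(doc, dictionary)
        if bow.is_empty:
            empty.append(doc.post_id)
        else:
            bows.append(bow)
    return bows, empty


def corpus_to_sparse(
    corpus: Sequence[BowDoc], n_words: int
) -> scipy.sparse.csr_matrix:
    """Stack BowDocs into a documents × vocabulary CSR count matrix."""
    data, indices, indptr = [], [], [0]
    for bow in corpus:
        for wid, cnt in bow.counts.items():
            indices.append(wid)
            data.append(cnt)
        indptr.append(len(indices))
    return scipy.sparse.csr_matrix(
        (np.asarray(data, dtype=np.float64), indices, indptr),
        shape=(len(corpus), n_words),
    )


def save_token_docs(docs: Iterable[TokenDoc], path: str | Path) -> None:
    with Path(path).open("w", encoding="utf-8") as fh:
        for doc in docs:
            fh.write(json.dumps({"post_id": doc.post_id, "tokens": doc.tokens}) + "\n")


def load_token_docs(path: str | Path) -> list[TokenDoc]:
    docs = []
    with Path(path).open(encoding="utf-8") as fh:
        for line in fh:
            if line.strip():
                rec = json.loads(line)
                docs.append(TokenDoc(rec["post_id"], rec["tokens"]))
    return docs


def save_corpus_mtx(
    corpus: Sequence[BowDoc], dictionary: Dictionary, path: str | Path
) -> None:
    """Export the document-term counts as a MatrixMarket sparse matrix."""
    scipy.io.mmwrite(str(path), corpus_to_sparse(corpus, len(dictionary)))
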