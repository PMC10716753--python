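"""Post-to-topic assignment, association-based labeling and topic structure.

A post belongs to a topic when its inferred topic probability exceeds a
strict threshold (default 0.75).  Topics are named by their four most
*associated* words, where association rewards words that are probable in
the topic but rare in the corpus overall:

    a = log(φ) + log(φ) / P,

with φ the probability of the word given the topic and P its probability
in the bag-of-words corpus.  An alternative reading a = log(φ) + log(φ/P)
(the "relevance" form) is available behind a flag.  Topic structure is
summarized as a graph (cosine-similar or top-word-sharing topics linked),
a 2-D classical-MDS projection of Jensen–Shannon divergences, and
per-source topic proportion tables.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import networkx as nx
import numpy as np
import pandas as pd
from scipy.spatial.distance import jensenshannon

from .corpus_io import Post
from .lda import LdaModel, TopicDistribution, infer_corpus, topic_word_dist
from .preprocess import BowDoc, Dictionary

__all__ = [
    "TopicAssignment",
    "assign_posts",
    "word_association",
    "corpus_word_probs",
    "label_topic",
    "label_all_topics",
    "topic_graph",
    "topic_distance_projection",
    "source_topic_proportions",
]


@dataclass(slots=True)
class TopicAssignment:
    """A post's best topic (present only above the threshold)."""

    post_id: str
    topic: int | None
    probability: float


def assign_posts(
    model: LdaModel,
    corpus: Sequence[BowDoc],
    threshold: float = 0.75,
    distributions: Sequence[TopicDistribution] | None = None,
) -> list[TopicAssignment]:
    """Assign each post to its argmax topic when max θ exceeds ``threshold``.

    The threshold is strict: a post at exactly 0.75 stays unassigned.  The
    maximal probability is always reported, assigned or not.
    """
    if distributions is None:
        distributions = infer_corpus(model, corpus)
    out = []
    for dist in distributions:
        k = int(np.argmax(dist.theta))
        p = float(dist.theta[k])
        out.append(TopicAssignment(dist.post_id, k if p > threshold else None, p))
    return out


def word_association(phi: float, P: float, form: str = "literal") -> float:
    """Association between a word and a topic.

    ``literal`` evaluates a = log(φ) + log(φ)/P; ``relevance`` evaluates
    a = log(φ) + log(φ/P).  Natural logarithms throughout.
    """
    if phi <= 0 or P <= 0:
        raise ValueError("word_association requires phi > 0 and P > 0")
    if form == "literal":
        return math.log(phi) + math.log(phi) / P
    if form == "relevance":
        return math.log(phi) + math.log(phi / P)
    raise ValueError(f"unknown association form: {form!r}")


def corpus_word_probs(corpus: Sequence[BowDoc], n_words: int) -> np.ndarray:
    """Empirical word probabilities over the bag-of-words corpus (sum 1)."""
    counts = np.zeros(n_words)
    for bow in corpus:
        for wid, cnt in bow.counts.items():
            counts[wid] += cnt
    total = counts.sum()
    if total == 0:
        raise ValueError("corpus has no tokens")
    return counts / total


def label_topic(
    model: LdaModel,
    k: int,
    corpus_word_probs: np.ndarray,
    n_label_words: int = 4,
    dictionary: Dictionary | None = None,
    form: str = "literal",
) -> list[str]:
    """The ``n_label_words`` most topic-associated words, best first.

    Ranked by :func:`word_association` descending with lexicographic
    tie-breaks.  Words with zero corpus probability are excluded (the
    association is undefined for them).
    """
    d = dictionary if dictionary is not None else model.dictionary
    if n_label_words > model.n_words:
        raise ValueError("n_label_words exceeds the vocabulary size")
    phi = topic_word_dist(model, k)
    scored = []
    for wid in range(model.n_words):
        P = corpus_word_probs[wid]
        if P <= 0 or phi[wid] <= 0:
            continue
        word = d.id2word[wid] if d is not None else str(wid)
        scored.append((-word_association(float(phi[wid]), float(P), form), word))
    scored.sort()
    return [word for _, word in scored[:n_label_words]]


def format_label(words: Sequence[str]) -> str:
    """Join label words for display, e.g. ``sleep+night+wake+feed``."""
    return "+".join(words)


def label_all_topics(
    model: LdaModel,
    corpus: Sequence[BowDoc],
    n_label_words: int = 4,
    dictionary: Dictionary | None = None,
    form: str = "literal",
) -> list[list[str]]:
    P = corpus_word_probs(corpus, model.n_words)
    return [
        label_topic(model, k, P, n_label_words, dictionary, form)
        for k in range(model.n_topics)
    ]


def _top_word_set(model: LdaModel, k: int, top_n: int) -> set[int]:
    dist = topic_word_dist(model, k)
    return set(np.argsort(-dist, kind="stable")[:top_n].tolist())


def topic_graph(
    model: LdaModel,
    assignments: Sequence[TopicAssignment],
    cosine_threshold: float = 0.4,
    top_n: int = 10,
) -> nx.Graph:
    """Topic relatedness graph.

    Nodes are topics sized by assigned-post counts.  An edge of type
    ``similarity`` joins topics whose word distributions have cosine
    similarity strictly above ``cosine_threshold``; ``shared_word`` joins
    topics whose top-``top_n`` word lists intersect; ``both`` marks edges
    satisfying both.
    """
    K = model.n_topics
    sizes = {k: 0 for k in range(K)}
    for a in assignments:
        if a.topic is not None:
            sizes[a.topic] += 1
    g = nx.Graph()
    rows = [topic_word_dist(model, k) for k in range(K)]
    tops = [_top_word_set(model, k, top_n) for k in range(K)]
    for k in range(K):
        g.add_node(k, size=sizes[k])
    for i in range(K):
        for j in range(i + 1, K):
            cos = float(
                rows[i] @ rows[j]
                / (np.linalg.norm(rows[i]) * np.linalg.norm(rows[j]))
            )
            shared = sorted(tops[i] & tops[j])
            similar = cos > cosine_threshold
            if similar and shared:
                g.add_edge(i, j, type="both", cosine=cos, shared_words=shared)
            elif similar:
                g.add_edge(i, j, type="similarity", cosine=cos, shared_words=[])
            elif shared:
                g.add_edge(i, j, type="shared_word", cosine=cos, shared_words=shared)
    return g


def topic_distance_projection(model: LdaModel) -> np.ndarray:
    """K × 2 classical-MDS embedding of pairwise Jensen–Shannon divergence.

    Coordinates are centered at the origin.  Identical topics land on the
    same point.
    """
    K = model.n_topics
    if K < 2:
        raise ValueError("projection requires at least 2 topics")
    rows = [topic_word_dist(model, k) for k in range(K)]
    D = np.zeros((K, K))
    for i in range(K):
        for j in range(i + 1, K):
            # JS distance (square root of the divergence) is a metric
            D[i, j] = D[j, i] = jensenshannon(rows[i], rows[j])
    # classical MDS: double-center the squared dissimilarities
    J = np.eye(K) - np.ones((K, K)) / K
    B = -0.5 * J @ (D**2) @ J
    eigvals, eigvecs = np.linalg.eigh(B)
    order = np.argsort(eigvals)[::-1][:2]
    coords = eigvecs[:, order] * np.sqrt(np.maximum(eigvals[order], 0.0))
    return coords - coords.mean(axis=0, keepdims=True)


def source_topic_proportions(
    assignments: Sequence[TopicAssignment],
    posts: Sequence[Post],
    n_topics: int | None = None,
) -> pd.DataFrame:
    """Source × topic table of within-source assigned-post proportions.

    Cell (s, k) is the number of source-s posts assigned to topic k divided
    by the total assigned posts from source s, so each row sums to 1 for
    sources with any assigned post.  Sources without assigned posts get an
    all-zero row (with a warning).
    """
    import warnings

    source_of = {p.post_id: p.source for p in posts}
    missing = [a.post_id for a in assignments if a.post_id not in source_of]
    if missing:
        raise KeyError(f"assignments reference unknown post_ids: {missing[:3]}")
    topics = sorted(
        {a.topic for a in assignments if a.topic is not None}
        | (set(range(n_topics)) if n_topics else set())
    )
    sources = sorted({p.source for p in posts})
    table = pd.DataFrame(0.0, index=sources, columns=topics)
    counts = pd.DataFrame(0, index=sources, columns=topics)
    for a in assignments:
        if a.topic is not None:
            counts.loc[source_of[a.post_id], a.topic] += 1
    for s in sources:
        total = counts.loc[s].sum()
        if total == 0:
            warnings.warn(f"source {s!r} has no assigned posts; row is all zero")
        else:
            table.loc[s] = counts.loc[s] / total
    table.index.name = "source"
    return table
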