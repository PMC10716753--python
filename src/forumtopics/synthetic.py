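"""Synthetic two-source forum corpora with known topic structure.

The generator emulates the statistical shape of a scraped parenting-forum
corpus so every pipeline stage can be exercised against ground truth: a
planted K × V topic-word matrix (each topic concentrates a configurable
fraction of its mass on a private vocabulary block), Dirichlet document
mixtures with optional per-source prevalence tilts, planted adjacent word
pairs (bigrams), deleted-post placeholders, a high-frequency single-token
spam post, and occasional US spellings of dialect-mapped words.  Word ids
are rendered as pronounceable ≥4-character pseudo-words so the stopword
and length filters pass tokens through unchanged.

It does not attempt to mimic real forum language, thread structure or
reply chains — only the count statistics the model sees.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import linear_sum_assignment

from .corpus_io import DEFAULT_PLACEHOLDERS, Post

__all__ = [
    "SyntheticSpec",
    "GroundTruth",
    "generate_corpus",
    "generate_token_docs",
    "match_topics",
    "pseudo_word",
    "DEFAULT_SPAM_TOKEN",
]

DEFAULT_SPAM_TOKEN = "vuzafestivalz"

_CONSONANTS = "bdfgklmnprstvz"
_FINAL_VOWELS = "aou"  # avoid e/i/y endings so Porter stemming is a no-op


def pseudo_word(word_id: int) -> str:
    """Deterministic pronounceable ≥6-character pseudo-word for a word id.

    Three consonant-vowel syllables drawn from an alphabet chosen so the
    words survive tokenization, stopword removal, the 4-character filter
    and Porter stemming unchanged.
    """
    syllables = []
    n = word_id
    for _ in range(3):
        n, r = divmod(n, len(_CONSONANTS) * len(_FINAL_VOWELS))
        c, v = divmod(r, len(_FINAL_VOWELS))
        syllables.append(_CONSONANTS[c] + _FINAL_VOWELS[v])
    return "".join(syllables)


@dataclass(slots=True)
class SyntheticSpec:
    """Generator settings; the defaults define the standard test corpus."""

    K_true: int = 4
    vocab_size: int = 400
    n_docs: dict[str, int] = field(
        default_factory=lambda: {"synthetic_A": 1000, "synthetic_B": 1000}
    )
    doc_length_mean: float = 60.0
    doc_length_dispersion: float = 5.0  # negative-binomial shape
    min_doc_length: int = 5
    alpha_true: float = 0.2
    topic_separation: float = 0.9
    planted_bigrams: list[tuple[int, int, float]] = field(default_factory=list)
    placeholder_rate: float = 0.03
    spam_rate: float = 0.02
    us_spelling_rate: float = 0.05
    spam_token: str = DEFAULT_SPAM_TOKEN
    source_topic_bias: dict[str, dict[int, float]] = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.K_true < 2:
            raise ValueError("K_true must be >= 2")
        if self.vocab_size < 2 * self.K_true:
            raise ValueError("vocab_size too small for disjoint topic blocks")
        for rate in (
            self.placeholder_rate, self.spam_rate, self.us_spelling_rate,
            self.topic_separation,
        ):
            if not 0.0 <= rate <= 1.0:
                raise ValueError("rates and separation must lie in [0, 1]")
        for a, b, rate in self.planted_bigrams:
            if not (0 <= a < self.vocab_size and 0 <= b < self.vocab_size):
                raise ValueError("planted bigram word ids exceed the vocabulary")
            if not 0.0 <= rate <= 1.0:
                raise ValueError("bigram adjacency rates must lie in [0, 1]")


@dataclass(slots=True)
class GroundTruth:
    """What the generator actually did, for recovery tests."""

    topic_word_true: np.ndarray  # K_true × V, rows sum to 1
    doc_topic_true: dict[str, np.ndarray]  # clean posts only
    noise_labels: dict[str, str]  # post_id -> clean | placeholder | spam
    vocabulary: list[str]  # pseudo-word per word id


def _planted_topics(spec: SyntheticSpec) -> np.ndarray:
    """Disjoint private blocks plus a uniform background floor."""
    K, V = spec.K_true, spec.vocab_size
    block = V // K
    topics = np.full((K, V), (1.0 - spec.topic_separation) / V)
    for k in range(K):
        topics[k, k * block : (k + 1) * block] += spec.topic_separation / block
    return topics / topics.sum(axis=1, keepdims=True)


def generate_corpus(spec: SyntheticSpec) -> tuple[list[Post], GroundTruth]:
    """Generate posts and their ground truth, reproducibly under the seed."""
    rng = np.random.default_rng(spec.seed)
    topics = _planted_topics(spec)
    vocab = [pseudo_word(i) for i in range(spec.vocab_size)]
    us_by_uk = _us_spelling_choices()

    posts: list[Post] = []
    doc_topic: dict[str, np.ndarray] = {}
    noise: dict[str, str] = {}
    counter = 0
    for source in sorted(spec.n_docs):
        tilt = np.ones(spec.K_true)
        for k, mult in spec.source_topic_bias.get(source, {}).items():
            tilt[k] = mult
        for _ in range(spec.n_docs[source]):
            post_id = f"{source}-{counter:06d}"
            counter += 1
            u = rng.random()
            if u < spec.placeholder_rate:
                body = DEFAULT_PLACEHOLDERS[counter % len(DEFAULT_PLACEHOLDERS)]
                noise[post_id] = "placeholder"
                posts.append(Post(post_id, source, body, timestamp=counter))
                continue
            if u < spec.placeholder_rate + spec.spam_rate:
                noise[post_id] = "spam"
                posts.append(
                    Post(post_id, source, spec.spam_token, timestamp=counter)
                )
                continue
            theta = rng.dirichlet(np.full(spec.K_true, spec.alpha_true)) * tilt
            theta = theta / theta.sum()
            length = spec.min_doc_length + rng.negative_binomial(
                spec.doc_length_dispersion,
                spec.doc_length_dispersion
                / (spec.doc_length_dispersion + spec.doc_length_mean - spec.min_doc_length),
            )
            z = rng.choice(spec.K_true, size=length, p=theta)
            word_ids = [int(rng.choice(spec.vocab_size, p=topics[k])) for k in z]
            tokens: list[str] = []
            followers = {a: (b, rate) for a, b, rate in spec.planted_bigrams}
            for wid in word_ids:
                tokens.append(vocab[wid])
                if wid in followers:
                    b, rate = followers[wid]
                    if rng.random() < rate:
                        tokens.append(vocab[b])
            if rng.random() < spec.us_spelling_rate:
                us, _uk = us_by_uk[rng.integers(len(us_by_uk))]
                tokens.insert(int(rng.integers(len(tokens) + 1)), us)
            noise[post_id] = "clean"
            doc_topic[post_id] = theta
            posts.append(
                Post(post_id, source, " ".join(tokens) + ".", timestamp=counter)
            )
    truth = GroundTruth(topics, doc_topic, noise, vocab)
    return posts, truth


def _us_spelling_choices() -> list[tuple[str, str]]:
    """US spellings (≥4 letters so they survive the length filter)."""
    from .corpus_io import default_dialect_map

    return sorted(
        (us, uk) for us, uk in default_dialect_map().items() if len(us) >= 4
    )


def generate_token_docs(
    spec: SyntheticSpec,
) -> tuple[list, GroundTruth]:
    """Convenience: clean posts only, already tokenized on whitespace.

    Bypasses the text round-trip for tests that exercise the model layers
    directly; pseudo-words pass the real tokenizer unchanged, so the two
    routes agree on clean posts without dialect insertions.
    """
    from .preprocess import TokenDoc

    spec_no_noise = SyntheticSpec(
        K_true=spec.K_true,
        vocab_size=spec.vocab_size,
        n_docs=dict(spec.n_docs),
        doc_length_mean=spec.doc_length_mean,
        doc_length_dispersion=spec.doc_length_dispersion,
        min_doc_length=spec.min_doc_length,
        alpha_true=spec.alpha_true,
        topic_separation=spec.topic_separation,
        planted_bigrams=list(spec.planted_bigrams),
        placeholder_rate=0.0,
        spam_rate=0.0,
        us_spelling_rate=0.0,
        spam_token=spec.spam_token,
        source_topic_bias={k: dict(v) for k, v in spec.source_topic_bias.items()},
        seed=spec.seed,
    )
    posts, truth = generate_corpus(spec_no_noise)
    docs = [TokenDoc(p.post_id, p.body.rstrip(".").split()) for p in posts]
    return docs, truth


def match_topics(
    est: np.ndarray, truth: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Optimal one-to-one topic matching by total-variation distance.

    Returns ``(perm, distances)`` where ``perm[i]`` is the truth row
    matched to estimated row i and ``distances[i]`` the corresponding
    total-variation distance, minimizing the total cost.
    """
    est = np.asarray(est, dtype=float)
    truth = np.asarray(truth, dtype=float)
    if est.shape != truth.shape:
        raise ValueError(f"shape mismatch: {est.shape} vs {truth.shape}")
    K = est.shape[0]
    cost = np.zeros((K, K))
    for i in range(K):
        for j in range(K):
            cost[i, j] = 0.5 * np.abs(est[i] - truth[j]).sum()
    rows, cols = linear_sum_assignment(cost)
    perm = np.empty(K, dtype=int)
    perm[rows] = cols
    return perm, cost[rows, cols]
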