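"""C_v topic coherence and coherence-driven topic-number selection.

C_v combines four ingredients: boolean sliding windows over the reference
corpus (a word "occurs" in a window or not), normalized pointwise mutual
information (NPMI) between topic words estimated from window co-occurrence,
one-set segmentation (each topic word is compared against the whole top-word
set), and cosine similarity between NPMI context vectors.  It tracks human
judgements of topic interpretability better than perplexity-style scores,
which is why it drives the choice of the topic-number parameter here.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

from .lda import TrainingConfig, train_lda, topic_word_dist
from .preprocess import BowDoc, Dictionary, TokenDoc

__all__ = [
    "CoherenceConfig",
    "ScanResult",
    "compute_cv",
    "scan_topic_number",
    "top_words",
]


@dataclass(slots=True)
class CoherenceConfig:
    """window_size-110 boolean windows over the top 20 words per topic."""

    window_size: int = 110
    top_n_words: int = 20
    epsilon: float = 1e-12

    def __post_init__(self) -> None:
        if self.window_size < 2:
            raise ValueError("window_size must be >= 2")
        if self.top_n_words < 1:
            raise ValueError("top_n_words must be >= 1")
        if self.epsilon <= 0:
            raise ValueError("epsilon must be positive")


@dataclass(slots=True)
class ScanResult:
    """Coherence per (K, repeat) with the selected topic number."""

    k_values: list[int]
    coherence: np.ndarray  # |k_values| × repeats
    mean_coherence: np.ndarray = field(init=False)
    selected_k: int = field(init=False)

    def __post_init__(self) -> None:
        if self.coherence.shape[0] != len(self.k_values):
            raise ValueError("coherence matrix rows must match k_values")
        if np.isnan(self.coherence).any():
            raise ValueError("coherence matrix has missing entries")
        self.mean_coherence = self.coherence.mean(axis=1)
        # argmax returns the first (smallest-k) maximizer on ties
        self.selected_k = int(self.k_values[int(np.argmax(self.mean_coherence))])


def top_words(
    model, k: int, n: int, dictionary: Dictionary | None = None
) -> list[str]:
    """The n highest-probability words of topic k (ids if no dictionary)."""
    dist = topic_word_dist(model, k)
    order = np.argsort(-dist, kind="stable")[:n]
    d = dictionary if dictionary is not None else model.dictionary
    if d is None:
        return [str(i) for i in order]
    return [d.id2word[i] for i in order]


def _window_probabilities(
    words: list[str], reference_docs: Sequence[TokenDoc], window_size: int
) -> tuple[np.ndarray, np.ndarray]:
    """Boolean-sliding-window marginal and joint occurrence probabilities.

    Windows of the given width slide by one token over each document;
    documents shorter than the window contribute one window covering the
    whole document.  Returns (p of length n, P of shape n × n) where the
    diagonal of P holds the marginals (p(w, w) = p(w)).
    """
    index = {w: i for i, w in enumerate(words)}
    n = len(words)
    occur = np.zeros(n, dtype=np.int64)
    joint = np.zeros((n, n), dtype=np.int64)
    n_windows = 0
    for doc in reference_docs:
        tokens = doc.tokens
        if not tokens:
            continue
        positions: dict[int, list[int]] = {}
        for pos, tok in enumerate(tokens):
            i = index.get(tok)
            if i is not None:
                positions.setdefault(i, []).append(pos)
        n_win = max(len(tokens) - window_size + 1, 1)
        n_windows += n_win
        if not positions:
            continue
        # word i occurs in window starting at s iff s <= pos <= s+w-1 for
        # some occurrence; collect the window-start interval per word
        starts: dict[int, np.ndarray] = {}
        for i, poss in positions.items():
            covered = np.zeros(n_win, dtype=bool)
            for pos in poss:
                lo = max(pos - window_size + 1, 0)
                hi = min(pos, n_win - 1)
                covered[lo : hi + 1] = True
            starts[i] = covered
        present = list(starts)
        for a_idx, i in enumerate(present):
            ci = starts[i]
            occur[i] += int(ci.sum())
            joint[i, i] += int(ci.sum())
            for j in present[a_idx + 1 :]:
                c = int((ci & starts[j]).sum())
                joint[i, j] += c
                joint[j, i] += c
    if n_windows == 0:
        raise ValueError("reference corpus is empty")
    return occur / n_windows, joint / n_windows


def _npmi_matrix(
    p: np.ndarray, joint: np.ndarray, epsilon: float
) -> np.ndarray:
    """NPMI(wi, wj) = log((p_ij + ε) / (p_i p_j)) / (−log(p_ij + ε))."""
    marg = np.where(p > 0, p, epsilon)
    pj = joint + epsilon
    denom = -np.log(pj)
    npmi = np.log(pj / np.outer(marg, marg))
    # a pair present in every window has NPMI at its upper limit of 1
    with np.errstate(divide="ignore", invalid="ignore"):
        npmi = np.where(denom > 0, npmi / denom, 1.0)
    return npmi


def compute_cv(
    top_words_per_topic: Sequence[Sequence[str]],
    reference_docs: Sequence[TokenDoc],
    cfg: CoherenceConfig | None = None,
) -> float:
    """C_v coherence of a set of topics against a tokenized reference corpus.

    For each topic, every top word wi gets a context vector
    v_i = (NPMI(wi, wj))_j over the topic's word set; the topic score is the
    mean cosine similarity between each v_i and the set vector Σ_j v_j, and
    the returned value is the mean over topics.  Lies in [−1, 1].
    """
    cfg = cfg or CoherenceConfig()
    topic_scores = []
    for topic in top_words_per_topic:
        words = list(dict.fromkeys(topic))  # dedupe, order preserved
        p, joint = _window_probabilities(words, reference_docs, cfg.window_size)
        npmi = _npmi_matrix(p, joint, cfg.epsilon)
        set_vector = npmi.sum(axis=0)
        sims = []
        for i in range(len(words)):
            vi = npmi[i]
            denom = np.linalg.norm(vi) * np.linalg.norm(set_vector)
            sims.append(float(vi @ set_vector / denom) if denom > 0 else 0.0)
        topic_scores.append(float(np.mean(sims)))
    return float(np.mean(topic_scores))


def scan_topic_number(
    corpus: Sequence[BowDoc],
    reference_docs: Sequence[TokenDoc],
    k_range: Sequence[int],
    repeats: int = 10,
    base_seed: int = 0,
    train_cfg: TrainingConfig | None = None,
    coh_cfg: CoherenceConfig | None = None,
    dictionary: Dictionary | None = None,
) -> ScanResult:
    """Fit models over a grid of topic numbers and pick the most coherent.

    For each candidate K the model is refit from ``repeats`` random starts
    (seed = base_seed + repeat) and C_v is computed from each fit's top
    words; the K with the highest mean coherence wins, ties going to the
    smallest K.
    """
    k_values = list(k_range)
    if not k_values:
        raise ValueError("k_range must be non-empty")
    if sorted(k_values) != k_values:
        raise ValueError("k_range must be ascending")
    coh_cfg = coh_cfg or CoherenceConfig()
    coherence = np.full((len(k_values), repeats), np.nan)
    for ki, k in enumerate(k_values):
        for r in range(repeats):
            if train_cfg is None:
                cfg = TrainingConfig(n_topics=k, seed=base_seed + r)
            else:
                cfg = replace(
                    train_cfg, n_topics=k, alpha=None, eta=None,
                    seed=base_seed + r,
                )
            try:
                model = train_lda(corpus, cfg, dictionary)
                tops = [
                    top_words(model, t, coh_cfg.top_n_words, dictionary)
                    for t in range(k)
                ]
                coherence[ki, r] = compute_cv(tops, reference_docs, coh_cfg)
            except Exception as exc:
                raise RuntimeError(
                    f"coherence scan failed at k={k}, repeat={r}"
                ) from exc
    return ScanResult(k_values, coherence)
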