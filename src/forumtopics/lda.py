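"""Latent Dirichlet allocation fitted by online variational Bayes.

The model: each document d draws a topic mixture θ_d ~ Dirichlet(α), each
token draws a topic z ~ θ_d and a word w ~ φ_z, with φ_k ~ Dirichlet(η).
Inference maintains a variational Dirichlet λ over each topic-word row and
a per-document variational Dirichlet γ over topic mixtures, optimized
stochastically: documents are processed in chunks, the per-chunk sufficient
statistics form a noisy estimate λ̂ of the batch update, and λ is blended as

    λ ← (1 − ρ_t) λ + ρ_t λ̂,   ρ_t = (τ0 + t)^(−κ),

where t counts chunk updates.  The per-document E-step iterates

    γ_k = α + Σ_w n_w φ̂_wk,   φ̂_wk ∝ exp(E[log θ_k] + E[log φ_kw]),

until the mean absolute change in γ falls below ``gamma_threshold``.
Expectations of log-Dirichlet variables use the digamma-difference form
E[log θ_k] = ψ(γ_k) − ψ(Σ γ).  Document order is never shuffled and λ is
initialized from seeded Gamma(100, 1/100) noise, so identical seeds give
bitwise-identical fits.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import scipy.sparse
from scipy.special import psi  # digamma

from .preprocess import BowDoc, Dictionary, corpus_to_sparse

__all__ = [
    "TrainingConfig",
    "LdaModel",
    "TopicDistribution",
    "train_lda",
    "infer_topics",
    "topic_word_dist",
    "e_step",
]

_LAMBDA_FLOOR = 1e-12


@dataclass(slots=True)
class TrainingConfig:
    """All fitting hyperparameters.

    ``alpha`` and ``eta`` default to the symmetric prior 1/K.  The remaining
    defaults (20 passes, chunks of 1000 documents, decay 0.5, offset 64, up
    to 1000 E-step iterations, γ tolerance 0.001) are the standard online
    variational Bayes settings for forum-scale corpora.
    """

    n_topics: int
    alpha: float | None = None
    eta: float | None = None
    passes: int = 20
    chunksize: int = 1000
    decay: float = 0.5
    offset: float = 64.0
    iterations: int = 1000
    gamma_threshold: float = 0.001
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_topics < 1:
            raise ValueError("n_topics must be >= 1")
        if not (0.5 <= self.decay <= 1.0):
            raise ValueError("decay must lie in [0.5, 1] for convergence")
        if min(self.passes, self.chunksize, self.iterations) < 1:
            raise ValueError("passes, chunksize and iterations must be positive")
        if self.alpha is None:
            self.alpha = 1.0 / self.n_topics
        if self.eta is None:
            self.eta = 1.0 / self.n_topics


@dataclass(slots=True)
class TopicDistribution:
    """Normalized per-document topic mixture (γ / Σγ)."""

    post_id: str
    theta: np.ndarray


class LdaModel:
    """A fitted topic model: K × V variational parameters λ plus config."""

    def __init__(
        self,
        lam: np.ndarray,
        cfg: TrainingConfig,
        dictionary: Dictionary | None = None,
        training_log: list[float] | None = None,
    ) -> None:
        if np.any(lam <= 0):
            raise ValueError("lambda must be strictly positive")
        self.lam = lam
        self.cfg = cfg
        self.dictionary = dictionary
        self.training_log = training_log or []

    @property
    def n_topics(self) -> int:
        return self.lam.shape[0]

    @property
    def n_words(self) -> int:
        return self.lam.shape[1]

    def topic_word(self) -> np.ndarray:
        """K × V matrix of word probabilities given each topic."""
        return self.lam / self.lam.sum(axis=1, keepdims=True)

    def expected_log_topic_word(self) -> np.ndarray:
        return _dirichlet_expectation(self.lam)

    def save(self, directory: str | Path) -> None:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        np.savetxt(directory / "lambda.tsv", self.lam, delimiter="\t")
        with (directory / "config.txt").open("w", encoding="utf-8") as fh:
            for key in (
                "n_topics", "alpha", "eta", "passes", "chunksize",
                "decay", "offset", "iterations", "gamma_threshold", "seed",
            ):
                fh.write(f"{key}={getattr(self.cfg, key)!r}\n")
        if self.dictionary is not None:
            self.dictionary.save_tsv(directory / "dictionary.tsv")

    @classmethod
    def load(cls, directory: str | Path) -> "LdaModel":
        directory = Path(directory)
        lam = np.atleast_2d(np.loadtxt(directory / "lambda.tsv", delimiter="\t"))
        kwargs: dict = {}
        with (directory / "config.txt").open(encoding="utf-8") as fh:
            for line in fh:
                key, value = line.strip().split("=", 1)
                kwargs[key] = eval(value)  # noqa: S307 - trusted local artifact
        cfg = TrainingConfig(**kwargs)
        dictionary = None
        if (directory / "dictionary.tsv").exists():
            dictionary = Dictionary.load_tsv(directory / "dictionary.tsv")
        return cls(lam, cfg, dictionary)


def _dirichlet_expectation(param: np.ndarray) -> np.ndarray:
    """E[log X] for X ~ Dirichlet(param), rows treated independently."""
    if param.ndim == 1:
        return psi(param) - psi(param.sum())
    return psi(param) - psi(param.sum(axis=1, keepdims=True))


def e_step(
    X: scipy.sparse.spmatrix | np.ndarray,
    exp_elog_beta: np.ndarray,
    alpha: float,
    iterations: int,
    gamma_threshold: float,
) -> tuple[np.ndarray, np.ndarray]:
    """Variational E-step for a batch of documents.

    Parameters
    ----------
    X:
        documents × vocabulary count matrix.
    exp_elog_beta:
        exp(E[log φ]) of shape K × V.
    iterations:
        Maximum number of γ update sweeps; each document stops early once
        the mean absolute change in its γ drops below ``gamma_threshold``.

    Returns
    -------
    gamma:
        documents × K variational Dirichlet parameters.
    sstats:
        K × V sufficient statistics Σ_d n_dw φ̂_dwk (unscaled).
    """
    X = scipy.sparse.csr_matrix(X)
    n_docs = X.shape[0]
    K = exp_elog_beta.shape[0]
    doc_len = np.asarray(X.sum(axis=1)).ravel()

    # γ initialized from the prior plus an even split of the document mass
    gamma = alpha + (doc_len[:, None] / K) * np.ones((n_docs, K))
    exp_elog_theta = np.exp(_dirichlet_expectation(gamma))

    active = np.ones(n_docs, dtype=bool)
    for _ in range(iterations):
        if not active.any():
            break
        idx = np.flatnonzero(active)
        Xa = X[idx]
        theta_a = exp_elog_theta[idx]
        # φ normalizer per (doc, word); zero count entries are irrelevant
        phinorm = theta_a @ exp_elog_beta + 1e-100
        ratio = Xa.multiply(1.0 / phinorm)  # n_dw / phinorm, sparse
        gamma_new = alpha + theta_a * (ratio @ exp_elog_beta.T)
        change = np.abs(gamma_new - gamma[idx]).mean(axis=1)
        gamma[idx] = gamma_new
        exp_elog_theta[idx] = np.exp(_dirichlet_expectation(gamma_new))
        active[idx] = change > gamma_threshold

    phinorm = exp_elog_theta @ exp_elog_beta + 1e-100
    ratio = scipy.sparse.csr_matrix(X.multiply(1.0 / phinorm))
    sstats = exp_elog_theta.T @ ratio  # K × V
    sstats = np.asarray(sstats) * exp_elog_beta
    return gamma, sstats


def train_lda(
    corpus: Sequence[BowDoc] | scipy.sparse.spmatrix,
    cfg: TrainingConfig,
    dictionary: Dictionary | None = None,
) -> LdaModel:
    """Fit LDA by online variational Bayes.

    ``corpus`` may be a list of :class:`BowDoc` or a prebuilt sparse count
    matrix.  Word ids must all be smaller than the vocabulary size.
    """
    if scipy.sparse.issparse(corpus):
        X = scipy.sparse.csr_matrix(corpus)
    else:
        if len(corpus) == 0:
            raise ValueError("cannot train on an empty corpus")
        V = len(dictionary) if dictionary is not None else (
            max(max(bow.counts) for bow in corpus if bow.counts) + 1
        )
        X = corpus_to_sparse(corpus, V)
    n_docs, V = X.shape
    if n_docs == 0 or V == 0:
        raise ValueError("cannot train on an empty corpus")

    rng = np.random.default_rng(cfg.seed)
    lam = rng.gamma(100.0, 1.0 / 100.0, (cfg.n_topics, V))
    n_updates = 0
    log: list[float] = []
    for _ in range(cfg.passes):
        pass_ll = 0.0
        for start in range(0, n_docs, cfg.chunksize):
            chunk = X[start : start + cfg.chunksize]
            exp_elog_beta = np.exp(_dirichlet_expectation(lam))
            gamma, sstats = e_step(
                chunk, exp_elog_beta, cfg.alpha, cfg.iterations, cfg.gamma_threshold
            )
            rho = (cfg.offset + n_updates) ** (-cfg.decay)
            lam_hat = cfg.eta + (n_docs / chunk.shape[0]) * sstats
            lam = (1.0 - rho) * lam + rho * lam_hat
            np.maximum(lam, _LAMBDA_FLOOR, out=lam)
            n_updates += 1
            # per-token log-likelihood proxy for the training log
            theta = gamma / gamma.sum(axis=1, keepdims=True)
            phinorm = theta @ (lam / lam.sum(axis=1, keepdims=True))
            pass_ll += float(chunk.multiply(np.log(phinorm + 1e-100)).sum())
        log.append(pass_ll / max(X.sum(), 1.0))
    return LdaModel(lam, replace(cfg), dictionary, log)


def infer_topics(model: LdaModel, doc: BowDoc) -> TopicDistribution:
    """Infer the topic mixture of one document under a trained model."""
    if doc.counts and max(doc.counts) >= model.n_words:
        raise ValueError(
            f"document {doc.post_id!r} contains word id "
            f"{max(doc.counts)} outside the model vocabulary"
        )
    X = corpus_to_sparse([doc], model.n_words)
    exp_elog_beta = np.exp(model.expected_log_topic_word())
    gamma, _ = e_step(
        X, exp_elog_beta, model.cfg.alpha, model.cfg.iterations,
        model.cfg.gamma_threshold,
    )
    theta = gamma[0] / gamma[0].sum()
    return TopicDistribution(doc.post_id, theta)


def infer_corpus(
    model: LdaModel, corpus: Sequence[BowDoc]
) -> list[TopicDistribution]:
    """Batch inference of per-document topic mixtures."""
    X = corpus_to_sparse(corpus, model.n_words)
    exp_elog_beta = np.exp(model.expected_log_topic_word())
    gamma, _ = e_step(
        X, exp_elog_beta, model.cfg.alpha, model.cfg.iterations,
        model.cfg.gamma_threshold,
    )
    theta = gamma / gamma.sum(axis=1, keepdims=True)
    return [
        TopicDistribution(bow.post_id, theta[i]) for i, bow in enumerate(corpus)
    ]


def topic_word_dist(model: LdaModel, k: int) -> np.ndarray:
    """Row k of λ normalized to a probability vector over the vocabulary."""
    if not 0 <= k < model.n_topics:
        raise IndexError(f"topic index {k} out of range [0, {model.n_topics})")
    row = model.lam[k]
    return row / row.sum()
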