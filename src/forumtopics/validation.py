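"""Statistics supporting human coding of topic samples.

Fifty posts per topic are sampled for qualitative coding; a concern voiced
three or more times in such a sample is taken forward.  The machinery here
quantifies that rule: a one-sample proportion z test (Wald standard error,
one-sided) gives the confidence that a concern seen x times in n posts
occurs in more than a fraction p0 of the topic — with x = 3, n = 50 and
p0 = 0.01 the confidence is 93.2% — and Wald confidence intervals (bounds
reported as percentages truncated to one decimal) bound its prevalence.
Tallies over coded samples and the cross-topic category table summarize
the human coding itself.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from importlib import resources
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.stats import norm

from .topics import TopicAssignment

__all__ = [
    "ProportionTest",
    "CodedPost",
    "TopicCodingSummary",
    "CATEGORY_NAMES",
    "sample_for_coding",
    "concern_threshold_confidence",
    "proportion_ci",
    "summarize_coding",
    "cross_topic_category_table",
]


def _load_categories() -> tuple[str, ...]:
    text = (
        resources.files("forumtopics.data")
        .joinpath("parenting_question_categories.txt")
        .read_text(encoding="utf-8")
    )
    return tuple(line.strip() for line in text.splitlines() if line.strip())


#: The 11 fixed parenting-question categories used for deductive coding.
CATEGORY_NAMES: tuple[str, ...] = _load_categories()


@dataclass(slots=True)
class ProportionTest:
    """One-sided one-sample proportion z test with Wald standard error."""

    x: int
    n: int
    p0: float
    p_hat: float
    z: float
    confidence: float
    p_value: float


@dataclass(slots=True)
class CodedPost:
    """A human-coded post: free-text concerns plus fixed categories."""

    post_id: str
    topic: int
    concerns: list[str] = field(default_factory=list)
    categories: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        unknown = [c for c in self.categories if c not in CATEGORY_NAMES]
        if unknown:
            raise ValueError(f"unknown categories: {unknown}")


@dataclass(slots=True)
class TopicCodingSummary:
    topic: int
    n_coded: int
    concern_counts: dict[str, int]
    retained_concerns: list[str]
    category_proportions: dict[str, float]
    majority_category: str | None
    any_category_proportion: float = 0.0
    coherence_class: str | None = None


def sample_for_coding(
    assignments: Sequence[TopicAssignment],
    topic: int,
    n: int = 50,
    seed: int = 0,
) -> list[str]:
    """Uniform without-replacement sample of post ids assigned to a topic.

    If fewer than ``n`` posts are assigned, all of them are returned (with
    a warning); a topic with no assigned posts is an error.
    """
    import warnings

    pool = [a.post_id for a in assignments if a.topic == topic]
    if not pool:
        raise ValueError(f"topic {topic} has no assigned posts")
    if len(pool) <= n:
        if len(pool) < n:
            warnings.warn(
                f"topic {topic} has only {len(pool)} assigned posts (< {n})"
            )
        return list(pool)
    rng = np.random.default_rng(seed)
    idx = rng.choice(len(pool), size=n, replace=False)
    return [pool[i] for i in sorted(idx)]


def concern_threshold_confidence(x: int, n: int, p0: float) -> ProportionTest:
    """Confidence that a concern seen x of n times has prevalence above p0.

    Uses the sample-proportion (Wald) standard error
    sqrt(p̂(1−p̂)/n); confidence = Φ(z) with z = (p̂ − p0)/SE, and the
    one-sided p value is its complement.
    """
    if not 0 < x < n:
        raise ValueError("x must satisfy 0 < x < n (degenerate SE otherwise)")
    if not 0 < p0 < 1:
        raise ValueError("p0 must lie strictly between 0 and 1")
    p_hat = x / n
    se = math.sqrt(p_hat * (1 - p_hat) / n)
    z = (p_hat - p0) / se
    confidence = float(norm.cdf(z))
    return ProportionTest(x, n, p0, p_hat, z, confidence, 1.0 - confidence)


def _truncate_percent(p: float) -> float:
    """Express a proportion as a percentage truncated to one decimal."""
    return math.floor(p * 1000.0) / 10.0


def proportion_ci(
    x: int, n: int, level: float = 0.90
) -> tuple[float, float]:
    """Wald interval for x/n, as percentages truncated to one decimal.

    p̂ ± z_{(1+level)/2} · sqrt(p̂(1−p̂)/n), clipped to [0, 1]; bounds are
    reported in percent, truncated (not rounded) to one decimal place —
    e.g. (3, 50, 0.90) → (0.4, 11.5).  Use :func:`proportion_ci_exact` for
    the untruncated bounds.
    """
    lower, upper = proportion_ci_exact(x, n, level)
    return _truncate_percent(lower), _truncate_percent(upper)


def proportion_ci_exact(x: int, n: int, level: float = 0.90) -> tuple[float, float]:
    """Untruncated Wald bounds as proportions in [0, 1]."""
    if not 0 < x < n:
        raise ValueError("x must satisfy 0 < x < n")
    if not 0 < level < 1:
        raise ValueError("level must lie strictly between 0 and 1")
    p_hat = x / n
    se = math.sqrt(p_hat * (1 - p_hat) / n)
    half = float(norm.ppf((1 + level) / 2)) * se
    return max(p_hat - half, 0.0), min(p_hat + half, 1.0)


def _normalize_code(code: str) -> str:
    return " ".join(code.lower().split())


def summarize_coding(
    coded: Sequence[CodedPost], topic: int, min_count: int = 3
) -> TopicCodingSummary:
    """Tally one topic's coded sample.

    Concern codes are matched exactly after case-folding and whitespace
    normalization; codes seen at least ``min_count`` times are retained.
    A category tagged on more than half of the coded posts becomes the
    majority category.
    """
    if not coded:
        raise ValueError("no coded posts supplied")
    wrong = [c.post_id for c in coded if c.topic != topic]
    if wrong:
        raise ValueError(f"coded posts not from topic {topic}: {wrong[:3]}")
    concern_counts: dict[str, int] = {}
    category_counts: dict[str, int] = {c: 0 for c in CATEGORY_NAMES}
    n_any = 0
    for post in coded:
        for concern in post.concerns:
            key = _normalize_code(concern)
            if key:
                concern_counts[key] = concern_counts.get(key, 0) + 1
        if post.categories:
            n_any += 1
        for cat in set(post.categories):
            category_counts[cat] += 1
    n = len(coded)
    proportions = {c: category_counts[c] / n for c in CATEGORY_NAMES}
    majority = [c for c, p in proportions.items() if p > 0.5]
    return TopicCodingSummary(
        topic=topic,
        n_coded=n,
        concern_counts=concern_counts,
        retained_concerns=sorted(
            c for c, k in concern_counts.items() if k >= min_count
        ),
        category_proportions=proportions,
        majority_category=majority[0] if majority else None,
        any_category_proportion=n_any / n,
    )


def cross_topic_category_table(
    summaries: Iterable[TopicCodingSummary],
) -> tuple[pd.DataFrame, dict[str, int]]:
    """Topic × category proportion matrix plus headline counts.

    Returns the matrix and a dict with the number of topics having a
    majority category, the number with under 25% of posts attributable to
    any category, and the number of categories represented anywhere.
    """
    summaries = list(summaries)
    topics = [s.topic for s in summaries]
    if len(set(topics)) != len(topics):
        raise ValueError("duplicate topic summaries")
    table = pd.DataFrame(
        [[s.category_proportions[c] for c in CATEGORY_NAMES] for s in summaries],
        index=topics,
        columns=list(CATEGORY_NAMES),
    )
    table.index.name = "topic"
    counts = {
        "topics_with_majority": int(
            sum(s.majority_category is not None for s in summaries)
        ),
        "topics_under_25pct": int(
            sum(s.any_category_proportion < 0.25 for s in summaries)
        ),
        "categories_represented": int((table.sum(axis=0) > 0).sum()),
    }
    return table, counts
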