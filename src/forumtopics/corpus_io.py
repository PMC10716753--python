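"""Reading, cleaning and standardizing raw forum-post records.

A corpus is a list of :class:`Post` records loaded from JSON-lines or CSV.
Cleaning removes placeholder bodies left behind by deleted posts (for
example ``[removed]`` or ``Message withdrawn at poster's request.``) and
single-word spam posts; standardization maps US spellings to their UK
equivalents and collapses typographic apostrophe variants to ``'``.
"""

from __future__ import annotations

import csv
import json
import re
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable

__all__ = [
    "Post",
    "CleaningConfig",
    "load_posts",
    "write_posts",
    "clean_posts",
    "standardize_text",
    "default_dialect_map",
    "DEFAULT_PLACEHOLDERS",
]

DEFAULT_PLACEHOLDERS = (
    "[removed]",
    "[deleted]",
    "Message withdrawn at poster's request.",
)

# Characters commonly used in place of the ASCII apostrophe.
DEFAULT_APOSTROPHES = ("’", "‘", "ʼ", "`", "´")

_REQUIRED_FIELDS = ("post_id", "source", "body")
_OPTIONAL_FIELDS = ("timestamp", "title")


@dataclass(slots=True)
class Post:
    """One forum message; the atomic unit of the corpus."""

    post_id: str
    source: str
    body: str
    title: str | None = None
    timestamp: int | None = None

    def full_text(self) -> str:
        """Title and body joined by a single space (title first, if any)."""
        if self.title:
            return f"{self.title} {self.body}"
        return self.body


def default_dialect_map() -> dict[str, str]:
    """The shipped ~60-entry US→UK spelling table (lowercase keys)."""
    text = (
        resources.files("forumtopics.data")
        .joinpath("dialect_us_to_uk.tsv")
        .read_text(encoding="utf-8")
    )
    mapping: dict[str, str] = {}
    for line in text.splitlines():
        if not line.strip():
            continue
        us, uk = line.split("\t")
        mapping[us.strip().lower()] = uk.strip()
    return mapping


@dataclass
class CleaningConfig:
    placeholder_patterns: list[str] = field(
        default_factory=lambda: list(DEFAULT_PLACEHOLDERS)
    )
    spam_terms: list[str] = field(default_factory=list)
    dialect_map: dict[str, str] = field(default_factory=default_dialect_map)
    apostrophe_chars: tuple[str, ...] = DEFAULT_APOSTROPHES

    def __post_init__(self) -> None:
        if not self.placeholder_patterns:
            raise ValueError("placeholder_patterns must be non-empty")
        for key in self.dialect_map:
            if key != key.lower() or len(key.split()) != 1:
                raise ValueError(
                    f"dialect_map keys must be lowercase single tokens: {key!r}"
                )


def _post_from_record(record: dict, where: str) -> Post:
    for name in _REQUIRED_FIELDS:
        if record.get(name) in (None, ""):
            if name == "body" and record.get(name) == "":
                break  # empty body is permitted; cleaning handles it
            raise ValueError(f"{where}: missing required field {name!r}")
    ts = record.get("timestamp")
    if ts in ("", None):
        ts = None
    else:
        ts = int(float(ts))
    title = record.get("title")
    if title == "":
        title = None
    return Post(
        post_id=str(record["post_id"]),
        source=str(record["source"]),
        body=str(record.get("body", "")),
        title=title,
        timestamp=ts,
    )


def load_posts(path: str | Path, format: str | None = None) -> list[Post]:
    """Load posts from a JSON-lines or CSV file, preserving record order.

    Parameters
    ----------
    path:
        Input file.
    format:
        ``"jsonl"`` or ``"csv"``; inferred from the suffix when omitted.
    """
    path = Path(path)
    if format is None:
        format = "csv" if path.suffix.lower() == ".csv" else "jsonl"
    if format not in ("jsonl", "csv"):
        raise ValueError(f"unknown corpus format: {format!r}")

    posts: list[Post] = []
    if format == "jsonl":
        with path.open(encoding="utf-8") as fh:
            for lineno, line in enumerate(fh, start=1):
                if not line.strip():
                    continue
                try:
                    record = json.loads(line)
                except json.JSONDecodeError as exc:
                    raise ValueError(
                        f"{path}: malformed JSON on line {lineno}: {exc.msg}"
                    ) from exc
                posts.append(_post_from_record(record, f"{path}:{lineno}"))
    else:
        with path.open(encoding="utf-8", newline="") as fh:
            reader = csv.DictReader(fh)
            header = reader.fieldnames or []
            for name in _REQUIRED_FIELDS:
                if name not in header:
                    raise ValueError(f"{path}: missing required column {name!r}")
            for lineno, record in enumerate(reader, start=2):
                posts.append(_post_from_record(record, f"{path}:{lineno}"))
    return posts


def write_posts(posts: Iterable[Post], path: str | Path) -> None:
    """Write posts as JSON-lines with a fixed field order."""
    path = Path(path)
    with path.open("w", encoding="utf-8") as fh:
        for post in posts:
            record: dict = {"post_id": post.post_id, "source": post.source}
            if post.timestamp is not None:
                record["timestamp"] = post.timestamp
            if post.title is not None:
                record["title"] = post.title
            record["body"] = post.body
            fh.write(json.dumps(record, ensure_ascii=False) + "\n")


def clean_posts(posts: list[Post], cfg: CleaningConfig | None = None) -> list[Post]:
    """Drop placeholder-only and spam-only posts, preserving order.

    A post is a placeholder when its whitespace-trimmed body equals one of
    the configured placeholder patterns exactly, so quoted placeholders
    inside genuine posts survive.  A spam post is one whose body consists
    solely of a configured spam term.
    """
    cfg = cfg or CleaningConfig()
    placeholders = {p.strip() for p in cfg.placeholder_patterns}
    spam = {t.strip().lower() for t in cfg.spam_terms}
    kept = []
    for post in posts:
        body = post.body.strip()
        if body in placeholders:
            continue
        if body.lower() in spam:
            continue
        kept.append(post)
    return kept


def _preserve_case(original: str, replacement: str) -> str:
    if original[:1].isupper():
        return replacement[:1].upper() + replacement[1:]
    return replacement


def standardize_text(text: str, cfg: CleaningConfig | None = None) -> str:
    """Map US spellings to UK ones and normalize apostrophe variants.

    Dialect replacement is whole-word and case-insensitive, preserving the
    case of the first letter (``Diaper`` → ``Nappy``).  Every configured
    apostrophe-like character becomes ``'``.  Idempotent.
    """
    cfg = cfg or CleaningConfig()
    for ch in cfg.apostrophe_chars:
        text = text.replace(ch, "'")
    if cfg.dialect_map:
        pattern = re.compile(
            r"\b(" + "|".join(re.escape(k) for k in cfg.dialect_map) + r")\b",
            flags=re.IGNORECASE,
        )
        text = pattern.sub(
            lambda m: _preserve_case(m.group(0), cfg.dialect_map[m.group(0).lower()]),
            text,
        )
    return text


def standardize_posts(posts: list[Post], cfg: CleaningConfig | None = None) -> list[Post]:
    """Apply :func:`standardize_text` to every title and body."""
    cfg = cfg or CleaningConfig()
    out = []
    for p in posts:
        out.append(
            Post(
                post_id=p.post_id,
                source=p.source,
                body=standardize_text(p.body, cfg),
                title=None if p.title is None else standardize_text(p.title, cfg),
                timestamp=p.timestamp,
            )
        )
    return out
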