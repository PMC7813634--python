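"""Post corpus: NDJSON ingestion, filtering, preprocessing, term matching.

The corpus is the single in-memory container the whole pipeline runs on.
Posts arrive as newline-delimited JSON (one post per line, UTF-8) with the
keys ``id``, ``author``, ``subreddit``, ``created_utc``, ``body`` and
``kind``; an optional ``title`` on submissions is prepended to the body as
sentence 0.  Preprocessing is performed per calendar year: a per-year lemma
frequency table is built and rare lemmas are dropped year by year, so a term
fashionable only in one year never contaminates another year's vocabulary.
"""

from __future__ import annotations

import json
import logging
import math
from collections import Counter, defaultdict
from dataclasses import dataclass, field
from datetime import datetime, timezone
from pathlib import Path
from typing import TYPE_CHECKING, Iterable, Iterator

from .text import Tokenizer, default_tokenizer, segment_text

if TYPE_CHECKING:  # pragma: no cover
    from .taxonomy import Taxonomy

logger = logging.getLogger(__name__)

__all__ = [
    "DELETED",
    "Post",
    "Corpus",
    "MentionRecord",
    "load_corpus",
    "iter_ndjson_posts",
    "filter_low_activity_communities",
    "preprocess",
    "segment_sentences",
    "match_terms",
    "write_mentions_tsv",
]

#: Sentinel author for posts whose username was deleted.
DELETED = "[deleted]"

_REQUIRED_KEYS = ("id", "author", "subreddit", "created_utc", "body", "kind")
_KINDS = frozenset({"submission", "comment"})


def _year_quarter(ts: int) -> tuple[int, int]:
    dt = datetime.fromtimestamp(ts, tz=timezone.utc)
    return dt.year, (dt.month - 1) // 3 + 1


@dataclass
class Post:
    post_id: str
    author: str  # DELETED sentinel for removed usernames
    community: str
    timestamp: int  # UTC seconds
    kind: str  # "submission" | "comment"
    body: str
    title: str | None = None
    skipped: bool = False

    def __post_init__(self) -> None:
        self.year, self.quarter = _year_quarter(self.timestamp)

    @property
    def is_deleted_author(self) -> bool:
        return self.author == DELETED

    @property
    def text(self) -> str:
        """Body with the title (when present) prepended as its own sentence."""
        if self.title:
            t = self.title.strip()
            if t and t[-1] not in ".!?":
                t += "."
            return f"{t} {self.body}"
        return self.body


@dataclass
class MentionRecord:
    """One occurrence of a vocabulary term inside one sentence of one post."""

    post_id: str
    author: str
    term: str
    domain: str  # substance | roa | tampering
    class_label: str
    sentence_index: int
    year: int
    quarter: int
    community: str = ""
    kind: str = "comment"


@dataclass
class Corpus:
    """Posts plus the per-year statistics preprocessing maintains."""

    posts: dict[str, Post] = field(default_factory=dict)
    #: post_id -> ordered sentences, each a list of lemmas (after preprocess)
    sentences: dict[str, list[list[str]]] = field(default_factory=dict)
    #: year -> lemma -> count (built by preprocess, before rare-lemma removal)
    lemma_freq: dict[int, Counter] = field(default_factory=dict)
    skipped_count: int = 0
    preprocessed: bool = False

    def __len__(self) -> int:
        return len(self.posts)

    def __iter__(self) -> Iterator[Post]:
        return iter(self.posts.values())

    @property
    def years(self) -> list[int]:
        return sorted({p.year for p in self})

    @property
    def communities(self) -> set[str]:
        return {p.community for p in self}

    def comment_counts(self) -> dict[tuple[str, int], int]:
        """(community, year) -> number of comments."""
        counts: Counter = Counter()
        for p in self:
            if p.kind == "comment":
                counts[(p.community, p.year)] += 1
        return dict(counts)

    def post_sentences(self, post_id: str) -> list[list[str]]:
        return self.sentences.get(post_id, [])


def iter_ndjson_posts(path: str | Path) -> Iterator[tuple[int, dict]]:
    """Yield (line_number, record) for each line; raises OSError if unreadable."""
    with open(path, "r", encoding="utf-8") as fh:
        for i, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            yield i, line


def load_corpus(path: str | Path, years: Iterable[int] | None = None) -> Corpus:
    """Read an NDJSON post file into a Corpus.

    Malformed lines (bad JSON, missing keys, bad timestamp/kind) are skipped
    and counted.  More than 50% malformed lines aborts with ValueError — it
    almost always means the input is not in the expected dialect.  Posts
    outside ``years`` (when given) are ignored without counting as malformed.
    """
    years_set = set(years) if years is not None else None
    corpus = Corpus()
    n_lines = 0
    for _, line in iter_ndjson_posts(path):
        n_lines += 1
        try:
            rec = json.loads(line)
            post = _post_from_record(rec)
        except (json.JSONDecodeError, KeyError, TypeError, ValueError):
            corpus.skipped_count += 1
            continue
        if years_set is not None and post.year not in years_set:
            continue
        corpus.posts[post.post_id] = post
    if n_lines and corpus.skipped_count > 0.5 * n_lines:
        raise ValueError(
            f"{corpus.skipped_count}/{n_lines} lines malformed: "
            "input does not look like the expected NDJSON post dialect"
        )
    logger.info(
        "loaded %d posts (%d lines skipped) from %s",
        len(corpus),
        corpus.skipped_count,
        path,
    )
    return corpus


def _post_from_record(rec: dict) -> Post:
    for k in _REQUIRED_KEYS:
        if k not in rec:
            raise KeyError(k)
    kind = rec["kind"]
    if kind not in _KINDS:
        raise ValueError(f"bad kind {kind!r}")
    author = rec["author"]
    if author is None or author == DELETED or author == "deleted":
        author = DELETED
    ts = int(rec["created_utc"])
    body = rec["body"]
    if body is None:
        body = ""
    if not isinstance(body, str):
        raise TypeError("body must be a string")
    return Post(
        post_id=str(rec["id"]),
        author=str(author),
        community=str(rec["subreddit"]),
        timestamp=ts,
        kind=kind,
        body=body,
        title=rec.get("title"),
    )


def filter_low_activity_communities(corpus: Corpus, min_comments: int = 100) -> Corpus:
    """Drop every (community, year) block with fewer than ``min_comments`` comments.

    Submissions ride along with their block: a community-year whose comment
    count passes keeps its submissions too.  Idempotent.
    """
    counts = corpus.comment_counts()
    keep = {key for key, n in counts.items() if n >= min_comments}
    out = Corpus(skipped_count=corpus.skipped_count)
    for p in corpus:
        if (p.community, p.year) in keep:
            out.posts[p.post_id] = p
            if p.post_id in corpus.sentences:
                out.sentences[p.post_id] = corpus.sentences[p.post_id]
    out.lemma_freq = corpus.lemma_freq
    out.preprocessed = corpus.preprocessed
    return out


def segment_sentences(post: Post) -> list[str]:
    """Ordered sentence strings of a post (title prepended when present)."""
    return segment_text(post.text)


def preprocess(
    corpus: Corpus,
    min_lemma_freq: int = 100,
    tokenizer: Tokenizer | None = None,
) -> Corpus:
    """Segment, tokenize and frequency-filter the corpus in place.

    Each year is treated separately: the lemma frequency table is built per
    year and lemmas appearing fewer than ``min_lemma_freq`` times in a year
    are removed from that year's sentences.  A tokenizer failure on a post
    flags the post skipped rather than aborting the run.
    """
    tok = tokenizer if tokenizer is not None else default_tokenizer()
    raw: dict[str, list[list[str]]] = {}
    freq: dict[int, Counter] = defaultdict(Counter)
    for p in corpus:
        try:
            sents = [tok(s) for s in segment_sentences(p)]
        except Exception:  # pluggable backend: any failure skips the post
            logger.warning("tokenizer failed on post %s; skipping", p.post_id)
            p.skipped = True
            corpus.skipped_count += 1
            continue
        raw[p.post_id] = sents
        for sent in sents:
            freq[p.year].update(sent)
    kept: dict[str, list[list[str]]] = {}
    for p in corpus:
        if p.post_id not in raw:
            continue
        year_freq = freq[p.year]
        kept[p.post_id] = [
            [w for w in sent if year_freq[w] >= min_lemma_freq]
            for sent in raw[p.post_id]
        ]
    corpus.sentences = kept
    corpus.lemma_freq = dict(freq)
    corpus.preprocessed = True
    return corpus


def match_terms(corpus: Corpus, taxonomy: "Taxonomy") -> list[MentionRecord]:
    """One MentionRecord per (post, sentence, term occurrence).

    Matching is exact lowercase lemma equality against the taxonomy's
    single-token terms; a lemma hitting terms in several domains yields one
    record per domain.
    """
    if not corpus.preprocessed:
        raise ValueError("corpus must be preprocessed before matching")
    records: list[MentionRecord] = []
    lookup = taxonomy.term_index()  # term -> list[(domain, class_label)]
    for p in corpus:
        sents = corpus.post_sentences(p.post_id)
        for si, sent in enumerate(sents):
            for lemma in sent:
                for domain, class_label in lookup.get(lemma, ()):
                    records.append(
                        MentionRecord(
                            post_id=p.post_id,
                            author=p.author,
                            term=lemma,
                            domain=domain,
                            class_label=class_label,
                            sentence_index=si,
                            year=p.year,
                            quarter=p.quarter,
                            community=p.community,
                            kind=p.kind,
                        )
                    )
    return records


def write_mentions_tsv(records: list[MentionRecord], path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(
            "post_id\tauthor\tterm\tdomain\tclass\tsentence_index\tyear\tquarter\n"
        )
        for r in records:
            fh.write(
                f"{r.post_id}\t{r.author}\t{r.term}\t{r.domain}\t"
                f"{r.class_label}\t{r.sentence_index}\t{r.year}\t{r.quarter}\n"
            )


def sentence_distance(a: MentionRecord, b: MentionRecord) -> int | float:
    """|i - j| between two mentions of the same post; inf across posts."""
    if a.post_id != b.post_id:
        return math.inf
    return abs(a.sentence_index - b.sentence_index)
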