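from __future__ import annotations

import json

import pytest

from opiomine.corpus import Corpus, MentionRecord, Post, load_corpus, preprocess
from opiomine.taxonomy import Taxonomy, load_default_taxonomy


@pytest.fixture(scope="session")
def taxonomy() -> Taxonomy:
    return load_default_taxonomy()


def make_post(
    post_id="p1",
    author="alice",
    community="opi_talk",
    timestamp=1514764800,  # 2018-01-01T00:00Z
    kind="comment",
    body="hello world.",
    **kw,
):
    return Post(
        post_id=post_id,
        author=author,
        community=community,
        timestamp=timestamp,
        kind=kind,
        body=body,
        **kw,
    )


def make_corpus(posts: list[Post], min_lemma_freq: int = 1) -> Corpus:
    corpus = Corpus(posts={p.post_id: p for p in posts})
    return preprocess(corpus, min_lemma_freq=min_lemma_freq)


def make_mention(
    post_id="p1",
    term="heroin",
    domain="substance",
    class_label="heroin",
    sentence_index=0,
    author="alice",
    year=2018,
    quarter=1,
    **kw,
) -> MentionRecord:
    return MentionRecord(
        post_id=post_id,
        author=author,
        term=term,
        domain=domain,
        class_label=class_label,
        sentence_index=sentence_index,
        year=year,
        quarter=quarter,
        **kw,
    )


def write_ndjson_file(tmp_path, records: list[dict], name="corpus.ndjson"):
    path = tmp_path / name
    defaults = {
        "author": "alice",
        "subreddit": "opi_talk",
        "created_utc": 1514764800,
        "kind": "comment",
        "body": "hello.",
    }
    lines = []
    for i, rec in enumerate(records):
        full = {"id": f"p{i}", **defaults, **rec}
        lines.append(json.dumps(full))
    path.write_text("\n".join(lines) + "\n", encoding="utf-8")
    return path


@pytest.fixture
def ndjson_factory(tmp_path):
    def factory(records, name="corpus.ndjson"):
        return write_ndjson_file(tmp_path, records, name)

    return factory


def load_small(path, min_lemma_freq=1) -> Corpus:
    corpus = load_corpus(path)
    return preprocess(corpus, min_lemma_freq=min_lemma_freq)
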