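"""Deterministic, dependency-free text preprocessing.

Sentence segmentation and lemmatization are deliberately simple rule-based
procedures: the downstream statistics (term matching, sentence-distance
co-occurrence counting) only need a reproducible mapping from raw post bodies
to ordered lists of lemma sequences.  Both are pluggable contracts, so a
full NLP backend can be swapped in without touching any counting code.
"""

from __future__ import annotations

import re
from collections.abc import Callable
from importlib import resources

__all__ = [
    "load_stopwords",
    "segment_text",
    "SimpleLemmatizer",
    "default_tokenizer",
    "Tokenizer",
]

# A tokenizer maps one sentence string to a list of lemmas.
Tokenizer = Callable[[str], list[str]]

_URL_RE = re.compile(r"https?://\S+|www\.\S+")
# Terminal punctuation (possibly repeated) followed by whitespace or end.
_SENT_SPLIT_RE = re.compile(r"[.!?]+(?:\s+|$)")
_TOKEN_RE = re.compile(r"[a-z0-9']+")

# Suffixes tried in order; a strip is applied only when the stem keeps >= 3
# characters, which protects short slang forms ("30s", "ocs", "ivs" keep the
# plural only when the stem would collapse below 3 chars — "iv" survives via
# its bare form in the vocabulary).
_SUFFIXES = ("ing", "ed", "es", "s")

# Words the suffix rules would mangle into a different lemma.
_DEFAULT_EXCEPTIONS = frozenset(
    {
        "gas",
        "news",
        "species",
        "always",
        "perhaps",
        "bless",
        "less",
        "unless",
        "series",
        "anything",
        "something",
        "nothing",
        "everything",
        "morning",
        "evening",
        "bring",
        "thing",
        "sing",
        "king",
        "ring",
        "spring",
        "string",
        "wing",
        "red",
        "bed",
        "need",
        "feed",
        "speed",
        "weed",
        "indeed",
        "hundred",
    }
)


def load_stopwords() -> frozenset[str]:
    """Load the packaged English stop-word list."""
    text = (
        resources.files("opiomine.data").joinpath("stopwords.txt").read_text("utf-8")
    )
    words = [
        line.strip()
        for line in text.splitlines()
        if line.strip() and not line.startswith("#")
    ]
    return frozenset(words)


def segment_text(body: str) -> list[str]:
    """Split a post body into sentences.

    URLs are collapsed first (their dots are not sentence boundaries), then
    the text is split on terminal punctuation (., !, ?) followed by
    whitespace or end of text.  A body with no terminator is one sentence.
    Empty body -> empty list.
    """
    if not body or not body.strip():
        return []
    cleaned = _URL_RE.sub(" ", body)
    parts = [p.strip() for p in _SENT_SPLIT_RE.split(cleaned)]
    parts = [p for p in parts if p]
    if not parts:
        return []
    return parts


class SimpleLemmatizer:
    """Lowercasing + rule-based suffix stripping with an exception list.

    Strips one of ``ing``, ``ed``, ``es``, ``s`` (first match wins) when the
    remaining stem keeps at least three characters.  Stop words are removed
    after lemmatization of the raw surface form would not apply — the stop
    list is matched against the lowercased token before stripping, so
    function words never leak through as mangled stems.
    """

    def __init__(
        self,
        stopwords: frozenset[str] | None = None,
        exceptions: frozenset[str] = _DEFAULT_EXCEPTIONS,
    ) -> None:
        self.stopwords = load_stopwords() if stopwords is None else stopwords
        self.exceptions = exceptions

    def lemma(self, token: str) -> str:
        if token in self.exceptions:
            return token
        for suf in _SUFFIXES:
            if token.endswith(suf) and len(token) - len(suf) >= 3:
                return token[: -len(suf)]
        return token

    def __call__(self, sentence: str) -> list[str]:
        out: list[str] = []
        for raw in _TOKEN_RE.findall(sentence.lower()):
            tok = raw.strip("'")
            if not tok or tok in self.stopwords:
                continue
            lem = self.lemma(tok)
            if lem and lem not in self.stopwords:
                out.append(lem)
        return out


_DEFAULT: SimpleLemmatizer | None = None


def default_tokenizer() -> SimpleLemmatizer:
    """Shared default tokenizer instance (packaged stop list, default rules)."""
    global _DEFAULT
    if _DEFAULT is None:
        _DEFAULT = SimpleLemmatizer()
    return _DEFAULT
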