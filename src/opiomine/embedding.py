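"""Word-embedding training and cosine-neighborhood vocabulary expansion.

The lexicon-induction step maps corpus lemmas to vectors, then grows each
seed term's vocabulary with its *n* nearest neighbors by cosine similarity.
Two interchangeable backends implement the embedding contract:

* ``svd`` (default) — positive pointwise mutual information over a
  symmetric context window, factorized with a truncated SVD.  Count-based,
  exactly deterministic, and strong on small corpora, which makes it the
  reference backend for tests and desk-scale runs.
* ``sgns`` — skip-gram with negative sampling trained by vectorized SGD in
  numpy (unigram^0.75 noise distribution, linearly decaying learning rate).
  Deterministic under a fixed seed and single-threaded execution.

The curated vocabulary V is always the product of an explicit decision
file; the code never auto-accepts a candidate.
"""

from __future__ import annotations

import csv
import io
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy import sparse
from scipy.sparse.linalg import svds

from .corpus import Corpus

logger = logging.getLogger(__name__)

__all__ = [
    "TrainingParams",
    "EmbeddingModel",
    "LexiconExpansion",
    "ModelComparison",
    "train_embedding",
    "semantic_neighborhood",
    "build_candidate_set",
    "apply_curation",
    "coverage_gain",
    "compare_models",
]


@dataclass(frozen=True)
class TrainingParams:
    backend: str = "svd"  # "svd" | "sgns"
    dim: int = 100
    window: int = 5
    min_count: int = 5
    epochs: int = 5
    negative: int = 5
    seed: int = 0


@dataclass
class EmbeddingModel:
    terms: list[str]
    vectors: np.ndarray  # (n_terms, dim), rows L2-normalized
    params: TrainingParams
    index: dict[str, int] = field(init=False)

    def __post_init__(self) -> None:
        self.index = {t: i for i, t in enumerate(self.terms)}

    def __contains__(self, term: str) -> bool:
        return term in self.index

    @property
    def vocabulary(self) -> set[str]:
        return set(self.terms)

    def vector(self, term: str) -> np.ndarray:
        try:
            return self.vectors[self.index[term]]
        except KeyError:
            raise KeyError(f"term {term!r} not in embedding vocabulary") from None

    def export_text(self, path: str | Path) -> None:
        """Plain-text (term, vector) export, one term per line."""
        with open(path, "w", encoding="utf-8") as fh:
            for t in self.terms:
                vec = " ".join(f"{x:.6f}" for x in self.vector(t))
                fh.write(f"{t} {vec}\n")


@dataclass
class LexiconExpansion:
    seeds: set[str]
    neighborhoods: dict[str, list[tuple[str, float]]]
    candidate_set: set[str]
    oov_seeds: set[str]
    n: int
    accepted: dict[str, str] = field(default_factory=dict)  # term -> class


@dataclass
class ModelComparison:
    candidates_a: int
    candidates_b: int
    accepted_a: int
    accepted_b: int
    accepted_pct_a: float
    accepted_pct_b: float
    comments_a: int
    comments_b: int
    common_terms: int


def _corpus_token_sentences(corpus: Corpus) -> list[list[str]]:
    if not corpus.preprocessed:
        raise ValueError("corpus must be preprocessed before training")
    sents: list[list[str]] = []
    for pid in sorted(corpus.sentences):
        for sent in corpus.sentences[pid]:
            if sent:
                sents.append(sent)
    return sents


def _build_vocab(
    sentences: list[list[str]], min_count: int
) -> tuple[list[str], dict[str, int], np.ndarray]:
    from collections import Counter

    freq = Counter(w for s in sentences for w in s)
    terms = sorted(t for t, c in freq.items() if c >= min_count)
    if not terms:
        raise ValueError(
            "no lemma reaches min_count "
            f"({min_count}); lower the threshold for small corpora"
        )
    index = {t: i for i, t in enumerate(terms)}
    counts = np.array([freq[t] for t in terms], dtype=np.float64)
    return terms, index, counts


def _pairs(
    sentences: list[list[str]], index: dict[str, int], window: int
) -> tuple[np.ndarray, np.ndarray]:
    centers: list[int] = []
    contexts: list[int] = []
    for sent in sentences:
        ids = [index[w] for w in sent if w in index]
        for i, c in enumerate(ids):
            lo = max(0, i - window)
            for j in range(lo, min(len(ids), i + window + 1)):
                if j != i:
                    centers.append(c)
                    contexts.append(ids[j])
    return np.asarray(centers, dtype=np.int64), np.asarray(contexts, dtype=np.int64)


def _normalize(mat: np.ndarray) -> np.ndarray:
    norms = np.linalg.norm(mat, axis=1, keepdims=True)
    norms[norms == 0] = 1.0
    return mat / norms


def _train_svd(sentences: list[list[str]], params: TrainingParams) -> EmbeddingModel:
    terms, index, _ = _build_vocab(sentences, params.min_count)
    centers, contexts = _pairs(sentences, index, params.window)
    n = len(terms)
    cooc = sparse.coo_matrix(
        (np.ones(len(centers)), (centers, contexts)), shape=(n, n)
    ).tocsr()
    total = cooc.sum()
    row = np.asarray(cooc.sum(axis=1)).ravel()
    col = np.asarray(cooc.sum(axis=0)).ravel()
    # PPMI: log( p(w,c) / (p(w) p(c)) ), negatives clipped to 0
    coo = cooc.tocoo()
    with np.errstate(divide="ignore"):
        pmi = np.log((coo.data * total) / (row[coo.row] * col[coo.col]))
    pmi = np.maximum(pmi, 0.0)
    ppmi = sparse.coo_matrix((pmi, (coo.row, coo.col)), shape=(n, n)).tocsr()
    k = min(params.dim, n - 1)
    if k < 1:
        raise ValueError("vocabulary too small for SVD factorization")
    # fixed start vector makes ARPACK runs reproducible
    u, s, _ = svds(ppmi, k=k, v0=np.ones(n) / np.sqrt(n))
    order = np.argsort(-s)
    vecs = u[:, order] * np.sqrt(s[order])
    return EmbeddingModel(terms=terms, vectors=_normalize(vecs), params=params)


def _train_sgns(sentences: list[list[str]], params: TrainingParams) -> EmbeddingModel:
    terms, index, counts = _build_vocab(sentences, params.min_count)
    centers, contexts = _pairs(sentences, index, params.window)
    n, d = len(terms), params.dim
    rng = np.random.default_rng(params.seed)
    w_in = (rng.random((n, d)) - 0.5) / d
    w_out = np.zeros((n, d))
    noise = counts**0.75
    noise /= noise.sum()
    n_pairs = len(centers)
    if n_pairs == 0:
        raise ValueError("no training pairs; corpus too small")
    batch = 1024
    lr0, lr_min = 0.025, 1e-4
    total_steps = params.epochs * ((n_pairs + batch - 1) // batch)
    step = 0
    for _epoch in range(params.epochs):
        perm = rng.permutation(n_pairs)
        for start in range(0, n_pairs, batch):
            sel = perm[start : start + batch]
            c, o = centers[sel], contexts[sel]
            neg = rng.choice(n, size=(len(sel), params.negative), p=noise)
            lr = max(lr_min, lr0 * (1 - step / max(total_steps, 1)))
            step += 1
            vc = w_in[c]  # (b, d)
            targets = np.concatenate([o[:, None], neg], axis=1)  # (b, 1+neg)
            vt = w_out[targets]  # (b, 1+neg, d)
            score = np.einsum("bd,bkd->bk", vc, vt)
            label = np.zeros_like(score)
            label[:, 0] = 1.0
            g = (label - 1.0 / (1.0 + np.exp(-score))) * lr  # (b, 1+neg)
            grad_c = np.einsum("bk,bkd->bd", g, vt)
            grad_t = g[:, :, None] * vc[:, None, :]
            np.add.at(w_in, c, grad_c)
            np.add.at(w_out, targets.ravel(), grad_t.reshape(-1, d))
    return EmbeddingModel(terms=terms, vectors=_normalize(w_in), params=params)


_BACKENDS = {"svd": _train_svd, "sgns": _train_sgns}


def train_embedding(
    corpus: Corpus, params: TrainingParams | None = None
) -> EmbeddingModel:
    """Train an embedding on the preprocessed corpus sentences."""
    params = params or TrainingParams()
    if params.backend not in _BACKENDS:
        raise ValueError(f"unknown backend {params.backend!r}")
    sentences = _corpus_token_sentences(corpus)
    return _BACKENDS[params.backend](sentences, params)


def semantic_neighborhood(
    model: EmbeddingModel, seed: str, n: int = 20
) -> list[tuple[str, float]]:
    """Top-n terms by cosine similarity to the seed, seed excluded.

    Ties are broken lexicographically so the ranking is a total order.
    """
    if seed not in model:
        raise KeyError(f"seed {seed!r} not in embedding vocabulary")
    sims = model.vectors @ model.vector(seed)
    order = sorted(
        (i for i in range(len(model.terms)) if model.terms[i] != seed),
        key=lambda i: (-sims[i], model.terms[i]),
    )
    return [(model.terms[i], float(sims[i])) for i in order[:n]]


def build_candidate_set(
    model: EmbeddingModel, seeds: set[str] | list[str], n: int = 20
) -> LexiconExpansion:
    """Candidate set E: union of every in-vocabulary seed's top-n, plus K."""
    seed_set = set(seeds)
    if not seed_set:
        raise ValueError("seed set K must be non-empty")
    in_vocab = sorted(s for s in seed_set if s in model)
    oov = seed_set - set(in_vocab)
    if not in_vocab:
        raise ValueError("no seed term is in the embedding vocabulary")
    for s in sorted(oov):
        logger.warning("seed %r not in embedding vocabulary; skipped", s)
    neighborhoods = {s: semantic_neighborhood(model, s, n) for s in in_vocab}
    candidates: set[str] = set(seed_set)
    for nb in neighborhoods.values():
        candidates.update(t for t, _ in nb)
    return LexiconExpansion(
        seeds=seed_set,
        neighborhoods=neighborhoods,
        candidate_set=candidates,
        oov_seeds=oov,
        n=n,
    )


def _read_decisions(source) -> list[tuple[str, str, str]]:
    """Yield (term, class_label, decision) from a TSV path/text or tuples."""
    if isinstance(source, (str, Path)) and Path(str(source)).exists():
        text = Path(source).read_text("utf-8")
    elif isinstance(source, str):
        text = source
    else:
        return [(t, c, d) for t, c, d in source]
    rows = csv.DictReader(
        (ln for ln in io.StringIO(text) if not ln.startswith("#")), delimiter="\t"
    )
    return [(r["term"], r["class_label"], r["decision"]) for r in rows]


def apply_curation(expansion: LexiconExpansion, decisions) -> dict[str, str]:
    """Apply accept/reject decisions, producing the vocabulary V (term -> class).

    Every decision must reference a candidate term; accepting one term into
    two classes is an error.  The decision file is the single source of
    truth — terms without an accept decision stay out of V.
    """
    parsed = _read_decisions(decisions)
    unknown = sorted({t for t, _, _ in parsed} - expansion.candidate_set)
    if unknown:
        raise ValueError(f"decisions reference terms outside E: {unknown}")
    accepted: dict[str, str] = {}
    for term, class_label, decision in parsed:
        if decision == "reject":
            logger.debug("rejected candidate %r", term)
            continue
        if decision != "accept":
            raise ValueError(f"unknown decision {decision!r} for term {term!r}")
        if term in accepted and accepted[term] != class_label:
            raise ValueError(
                f"term {term!r} accepted into two classes: "
                f"{accepted[term]!r} and {class_label!r}"
            )
        accepted[term] = class_label
    expansion.accepted = accepted
    return accepted


def _comments_with_any(corpus: Corpus, terms: set[str]) -> int:
    n = 0
    for p in corpus:
        if p.kind != "comment":
            continue
        sents = corpus.post_sentences(p.post_id)
        if any(w in terms for sent in sents for w in sent):
            n += 1
    return n


def coverage_gain(
    corpus: Corpus, seed_terms: set[str], expanded_terms: set[str]
) -> float:
    """Percent growth in comments reached by the expanded vocabulary.

    100 * (hits(expanded) - hits(seeds)) / hits(seeds), where a hit is a
    comment containing at least one term of the set.  Undefined (ValueError)
    when the seeds reach no comment at all.
    """
    if not seed_terms or not expanded_terms:
        raise ValueError("both term sets must be non-empty")
    n_seed = _comments_with_any(corpus, set(seed_terms))
    if n_seed == 0:
        raise ValueError("seed terms reach zero comments; gain undefined")
    n_exp = _comments_with_any(corpus, set(expanded_terms))
    return 100.0 * (n_exp - n_seed) / n_seed


def accepted_percentage(accepted: int, candidates: int) -> float:
    """Share of candidates accepted, as a percentage rounded to 1 decimal."""
    if candidates <= 0:
        raise ValueError("candidate count must be positive")
    return round(100.0 * accepted / candidates, 1)


def compare_models(
    expansion_a: LexiconExpansion,
    expansion_b: LexiconExpansion,
    corpus: Corpus,
) -> ModelComparison:
    """Side-by-side comparison of two backends' expansions over the same seeds."""
    if expansion_a.seeds != expansion_b.seeds:
        raise ValueError("expansions must share the same seed set")
    ca, cb = len(expansion_a.candidate_set), len(expansion_b.candidate_set)
    aa, ab = len(expansion_a.accepted), len(expansion_b.accepted)
    return ModelComparison(
        candidates_a=ca,
        candidates_b=cb,
        accepted_a=aa,
        accepted_b=ab,
        accepted_pct_a=accepted_percentage(aa, ca),
        accepted_pct_b=accepted_percentage(ab, cb),
        comments_a=_comments_with_any(corpus, set(expansion_a.accepted)),
        comments_b=_comments_with_any(corpus, set(expansion_b.accepted)),
        common_terms=len(expansion_a.candidate_set & expansion_b.candidate_set),
    )
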