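"""Semiautomatic retrieval of topic-relevant communities.

Starting from a handful of literature-derived seed terms, communities are
ranked by how enriched their language is for the query, the query is grown
with the most over-represented lemmas of the top communities, and the two
steps alternate until the query reaches a fixed point.  The procedure is a
deterministic, fully specified reconstruction in the spirit of the
semiautomatic query-expansion retrieval family; the final
relevance judgment stays manual, represented here by a curation file plus
Fleiss-kappa interrater agreement.

Scoring: a community's relevance is the mean, over query terms, of the log
of its add-one-smoothed relative lemma frequency divided by the corpus-wide
relative frequency (log-lift).  Expansion: candidate lemmas are ranked by
add-one-smoothed log-odds of in-topic versus background occurrence.  Both
rankings break ties lexicographically so results are total orders.
"""

from __future__ import annotations

import logging
import math
from collections import Counter
from dataclasses import dataclass

import numpy as np
from statsmodels.stats.inter_rater import aggregate_raters
from statsmodels.stats.inter_rater import fleiss_kappa as _sm_fleiss_kappa

from .corpus import Corpus
from .text import load_stopwords

logger = logging.getLogger(__name__)

__all__ = [
    "RetrievalState",
    "RetrievalSummary",
    "AgreementResult",
    "score_communities",
    "expand_query",
    "iterate_retrieval",
    "merge_years",
    "fleiss_kappa",
]


@dataclass
class RetrievalState:
    year: int | None
    query_terms: list[str]
    ranked_communities: list[tuple[str, float]]
    iteration: int


@dataclass
class RetrievalSummary:
    merged_query: set[str]
    merged_communities: set[str]


@dataclass
class AgreementResult:
    kappa: float
    observed_agreement: float
    expected_agreement: float
    degenerate: bool = False


def _community_lemma_counts(
    corpus: Corpus, year: int | None = None
) -> tuple[dict[str, Counter], Counter]:
    """Per-community and global lemma counters (optionally one year)."""
    per_comm: dict[str, Counter] = {}
    total: Counter = Counter()
    for p in corpus:
        if year is not None and p.year != year:
            continue
        sents = corpus.post_sentences(p.post_id)
        if not sents:
            continue
        c = per_comm.setdefault(p.community, Counter())
        for sent in sents:
            c.update(sent)
            total.update(sent)
    return per_comm, total


def score_communities(
    corpus: Corpus,
    query_terms: list[str],
    year: int | None = None,
) -> list[tuple[str, float]]:
    """Rank communities by mean log-lift of the query terms.

    score(c) = mean_t log( ((n_c(t)+1)/(N_c+V)) / ((n(t)+1)/(N+V)) )
    with add-one smoothing over the corpus vocabulary of size V.  Query
    terms absent from the corpus are skipped with a warning; if none
    survive, raises ValueError.
    """
    if not query_terms:
        raise ValueError("query_terms must be non-empty")
    if not corpus.preprocessed:
        raise ValueError("corpus must be preprocessed")
    per_comm, total = _community_lemma_counts(corpus, year)
    vocab_size = max(len(total), 1)
    n_total = sum(total.values())
    live_terms = []
    for t in query_terms:
        if total.get(t, 0) > 0:
            live_terms.append(t)
        else:
            logger.warning("query term %r absent from corpus vocabulary; skipped", t)
    if not live_terms:
        raise ValueError("no query term occurs in the corpus vocabulary")
    scores: list[tuple[str, float]] = []
    for comm, counts in per_comm.items():
        n_comm = sum(counts.values())
        s = 0.0
        for t in live_terms:
            p_comm = (counts.get(t, 0) + 1) / (n_comm + vocab_size)
            p_bg = (total[t] + 1) / (n_total + vocab_size)
            s += math.log(p_comm / p_bg)
        scores.append((comm, s / len(live_terms)))
    scores.sort(key=lambda cs: (-cs[1], cs[0]))
    return scores


def expand_query(
    corpus: Corpus,
    top_communities: list[str],
    current_query: list[str],
    m: int,
    year: int | None = None,
) -> list[str]:
    """Top-m lemmas by log-odds enrichment of top communities vs background.

    Candidates already in the query and stop lemmas are excluded; only
    candidates with enrichment > 0 (odds ratio > 1) qualify, so a corpus
    with no enriched lemma yields an empty list (the fixed point).
    """
    if not top_communities:
        raise ValueError("top_communities must be non-empty")
    if m <= 0:
        return []
    stop = load_stopwords()
    per_comm, total = _community_lemma_counts(corpus, year)
    topic: Counter = Counter()
    for comm in top_communities:
        topic.update(per_comm.get(comm, Counter()))
    n_topic = sum(topic.values())
    n_bg = sum(total.values()) - n_topic
    current = set(current_query)
    scored: list[tuple[str, float]] = []
    for term, k in topic.items():
        if term in current or term in stop:
            continue
        k_bg = total[term] - k
        # add-one smoothed log-odds of appearing in topic vs background
        odds_topic = (k + 1) / (n_topic - k + 1)
        odds_bg = (k_bg + 1) / (n_bg - k_bg + 1)
        enrich = math.log(odds_topic / odds_bg)
        if enrich > 0:
            scored.append((term, enrich))
    scored.sort(key=lambda te: (-te[1], te[0]))
    return [t for t, _ in scored[:m]]


def iterate_retrieval(
    corpus: Corpus,
    seed_query: list[str],
    k: int = 150,
    m: int = 10,
    max_iter: int = 5,
    year: int | None = None,
) -> RetrievalState:
    """Alternate community scoring and query expansion until a fixed point.

    The query grows monotonically (terms are never removed); the loop stops
    when an expansion round adds nothing or after ``max_iter`` rounds.
    """
    if not seed_query:
        raise ValueError("seed_query must be non-empty")
    query = list(dict.fromkeys(seed_query))
    ranked = score_communities(corpus, query, year=year)
    iteration = 0
    for iteration in range(1, max_iter + 1):
        top = [c for c, _ in ranked[:k]]
        new_terms = expand_query(corpus, top, query, m, year=year)
        if not new_terms:
            break
        query.extend(new_terms)
        ranked = score_communities(corpus, query, year=year)
    return RetrievalState(
        year=year, query_terms=query, ranked_communities=ranked, iteration=iteration
    )


def merge_years(states: list[RetrievalState], k: int = 150) -> RetrievalSummary:
    """Union of per-year queries and per-year top-k communities."""
    if not states:
        raise ValueError("need at least one retrieval state")
    q: set[str] = set()
    s: set[str] = set()
    for st in states:
        q.update(st.query_terms)
        s.update(c for c, _ in st.ranked_communities[:k])
    return RetrievalSummary(merged_query=q, merged_communities=s)


def fleiss_kappa(matrix: list[list[str]] | np.ndarray) -> AgreementResult:
    """Fleiss kappa for an items x raters matrix of categorical labels.

    kappa = (P_bar - P_e_bar) / (1 - P_e_bar).  When every rating across all
    items falls in a single category, chance agreement is 1 and kappa is
    undefined; the result is flagged degenerate with observed agreement 1.
    """
    arr = np.asarray(matrix, dtype=object)
    if arr.ndim != 2:
        raise ValueError("rating matrix must be items x raters")
    n_items, n_raters = arr.shape
    if n_raters < 2:
        raise ValueError("need at least 2 raters")
    counts, _cats = aggregate_raters(arr)
    # observed / expected agreement reported alongside kappa
    n = counts.sum(axis=1)
    if not np.all(n == n[0]):
        raise ValueError("every item must have the same number of ratings")
    p_cat = counts.sum(axis=0) / counts.sum()
    p_i = ((counts**2).sum(axis=1) - n) / (n * (n - 1))
    p_bar = float(p_i.mean())
    p_e = float((p_cat**2).sum())
    if counts.shape[1] < 2 or math.isclose(p_e, 1.0):
        return AgreementResult(
            kappa=float("nan"),
            observed_agreement=p_bar,
            expected_agreement=p_e,
            degenerate=True,
        )
    kappa = float(_sm_fleiss_kappa(counts, method="fleiss"))
    return AgreementResult(
        kappa=kappa, observed_agreement=p_bar, expected_agreement=p_e
    )
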