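"""Independent brute-force oracles used to check the implementation.

Everything here is deliberately naive and coded separately from the package
internals: exhaustive double loops, direct formula evaluation, raw string
scans.  Oracles never import the code paths they are checking.
"""

from __future__ import annotations

import json
import math
from collections import defaultdict


def fleiss_kappa_direct(labels: list[list[str]]) -> float:
    """Direct-formula Fleiss kappa on an items x raters label matrix."""
    categories = sorted({l for row in labels for l in row})
    n_items = len(labels)
    n = len(labels[0])
    counts = [[row.count(c) for c in categories] for row in labels]
    p_j = [sum(counts[i][j] for i in range(n_items)) / (n_items * n)
           for j in range(len(categories))]
    p_i = [
        (sum(c * c for c in counts[i]) - n) / (n * (n - 1)) for i in range(n_items)
    ]
    p_bar = sum(p_i) / n_items
    p_e = sum(p * p for p in p_j)
    return (p_bar - p_e) / (1 - p_e)


def cosine_neighbors_bruteforce(
    terms: list[str], vectors, seed: str, n: int
) -> list[tuple[str, float]]:
    """Exhaustive pairwise-cosine ranking, ties broken lexicographically."""
    idx = {t: i for i, t in enumerate(terms)}
    sv = vectors[idx[seed]]

    def cos(u, v):
        nu = math.sqrt(sum(x * x for x in u))
        nv = math.sqrt(sum(x * x for x in v))
        return sum(a * b for a, b in zip(u, v)) / (nu * nv)

    scored = [(t, cos(sv, vectors[idx[t]])) for t in terms if t != seed]
    scored.sort(key=lambda tc: (-tc[1], tc[0]))
    return scored[:n]


def contingency_bruteforce(
    mentions_by_post: dict[str, list],
    class_a: str,
    domain_a: str,
    class_b: str,
    domain_b: str,
    rho: float,
    universe: str = "either",
) -> tuple[int, int, int, int]:
    """O(posts x mentions^2) recount of one pair's 2x2 event table."""
    n11 = n10 = n01 = n00 = 0
    for pms in mentions_by_post.values():
        dom_a = [m for m in pms if m.domain == domain_a]
        dom_b = [m for m in pms if m.domain == domain_b]
        if universe == "either":
            if not dom_a and not dom_b:
                continue
        else:
            if not dom_a or not dom_b:
                continue
        a_ms = [m for m in dom_a if m.class_label == class_a]
        b_ms = [m for m in dom_b if m.class_label == class_b]
        joint = False
        for ma in a_ms:
            for mb in b_ms:
                d = abs(ma.sentence_index - mb.sentence_index)
                if rho == math.inf or d <= rho:
                    joint = True
        if joint:
            n11 += 1
        else:
            if a_ms:
                n10 += 1
            if b_ms:
                n01 += 1
            if not a_ms and not b_ms:
                n00 += 1
    return (n11, n10, n01, n00)


def scan_ndjson_for_terms(
    lines: list[str], term_index: dict[str, tuple[str, str]]
) -> list[tuple[str, str, str, str, int]]:
    """Raw-string mention scan of emitted NDJSON, independent of the corpus
    reader: (post_id, term, domain, class, sentence_index) per occurrence.

    Assumes generator output: sentences end with '.' and terms appear as
    whitespace-separated raw tokens (the generator only plants lemma-stable
    single tokens).
    """
    hits = []
    for line in lines:
        rec = json.loads(line)
        sentences = [s for s in rec["body"].split(". ") if s.strip()]
        for si, sent in enumerate(sentences):
            for raw in sent.split():
                tok = raw.rstrip(".")
                if tok in term_index:
                    domain, cls = term_index[tok]
                    hits.append((rec["id"], tok, domain, cls, si))
    return hits


def or_from_cells(n11, n10, n01, n00) -> float:
    return (n11 * n00) / (n10 * n01)


def expand_enrichment_bruteforce(
    sentences_by_community: dict[str, list[list[str]]],
    top_communities: list[str],
    query: set[str],
    stopwords: set[str],
) -> list[tuple[str, float]]:
    """Exhaustive log-odds enrichment ranking over a small corpus."""
    topic = defaultdict(int)
    bg = defaultdict(int)
    for comm, sents in sentences_by_community.items():
        target = topic if comm in top_communities else bg
        for sent in sents:
            for w in sent:
                target[w] += 1
    n_topic = sum(topic.values())
    n_bg = sum(bg.values())
    scored = []
    for term, k in topic.items():
        if term in query or term in stopwords:
            continue
        k_bg = bg.get(term, 0)
        enrich = math.log(
            ((k + 1) / (n_topic - k + 1)) / ((k_bg + 1) / (n_bg - k_bg + 1))
        )
        if enrich > 0:
            scored.append((term, enrich))
    scored.sort(key=lambda te: (-te[1], te[0]))
    return scored
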