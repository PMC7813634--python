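"""Synthetic NDJSON corpora with planted, recoverable structure.

The generator emulates the statistical features of a large social-media
post dump that the pipeline's estimators actually consume — nothing more:

* heavy-tailed posts-per-author (discrete power law, exponent 2.1, capped);
* deleted-author fractions by post kind (defaults 25% of submissions, 7% of
  comments);
* a per-post sentence-count distribution with median 2, half of posts at
  two sentences or fewer and a fifth above ten;
* planted synonym classes emitted interchangeably inside shared context
  windows, the structure embedding neighborhoods recover;
* planted pairwise associations at specified true odds ratios, with
  co-mention sentence distances drawn from a configurable profile so the
  distance-threshold (rho) sensitivity analysis has something to detect;
* linear quarterly trends in per-author mention probability.

Sentences are templates of filler lemmas with vocabulary terms slotted in:
no linguistic realism is attempted.  Every random draw flows from one seed,
so a fixed spec yields a byte-identical corpus, and the :class:`GroundTruth`
bookkeeping doubles as the oracle for parameter-recovery tests.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from datetime import datetime, timezone
from pathlib import Path

import numpy as np

from .corpus import DELETED, MentionRecord

__all__ = [
    "PlantedAssociation",
    "IndependentMention",
    "PlantedTrend",
    "SynonymClass",
    "SyntheticSpec",
    "PostPlan",
    "PlantedMention",
    "GroundTruth",
    "solve_joint_probability",
    "generate_corpus",
    "plant_synonyms",
    "write_ndjson",
    "ground_truth_mentions",
]

#: sentence-count pmf over 1..20: P(<=2)=0.5, P(>10)=0.2, median 2
DEFAULT_SENTENCE_PMF: dict[int, float] = {
    1: 0.30,
    2: 0.20,
    **{k: 0.0375 for k in range(3, 11)},
    **{k: 0.02 for k in range(11, 21)},
}

DEFAULT_DISTANCE_PMF: dict[int, float] = {0: 0.5, 1: 0.3, 2: 0.1, 3: 0.05, 4: 0.03, 5: 0.02}


@dataclass(frozen=True)
class PlantedAssociation:
    """A class pair planted at a true post-level odds ratio."""

    class_a: str
    term_a: str
    class_b: str
    term_b: str
    p_a: float = 0.3
    p_b: float = 0.2
    true_or: float = 4.0
    domain_a: str = "substance"
    domain_b: str = "roa"
    distance_pmf: dict[int, float] = field(
        default_factory=lambda: dict(DEFAULT_DISTANCE_PMF)
    )


@dataclass(frozen=True)
class IndependentMention:
    """A class mentioned independently of everything else (background)."""

    term: str
    domain: str
    class_label: str
    p: float


@dataclass(frozen=True)
class PlantedTrend:
    """Linear quarterly trend in per-author mention probability."""

    term: str
    domain: str
    class_label: str
    p0: float
    slope_per_quarter: float


@dataclass(frozen=True)
class SynonymClass:
    """Terms emitted interchangeably inside a shared context distribution."""

    name: str
    terms: tuple[str, ...]
    n_context_words: int = 6


@dataclass
class SyntheticSpec:
    seed: int = 0
    years: tuple[int, int] = (2014, 2018)
    n_authors: int = 400
    posts_per_author_alpha: float = 2.1
    posts_per_author_cap: int = 300
    deleted_submission_frac: float = 0.25
    deleted_comment_frac: float = 0.07
    submission_frac: float = 0.10
    topical_communities: tuple[str, ...] = ("opi_talk", "opi_help")
    background_communities: tuple[str, ...] = ("pics_misc", "news_misc")
    filler_vocab_size: int = 50
    sentence_pmf: dict[int, float] = field(
        default_factory=lambda: dict(DEFAULT_SENTENCE_PMF)
    )
    # association channel
    n_association_posts: int = 0
    association_year: int = 2018
    associations: tuple[PlantedAssociation, ...] = ()
    independent_mentions: tuple[IndependentMention, ...] = ()
    anchor_classes: tuple[tuple[str, str, str], ...] = (
        ("morphine", "substance", "morphine"),
        ("methadone", "substance", "methadone"),
    )  # (term, domain, class): one drawn per association post to pin the universe
    # trend channel
    trends: tuple[PlantedTrend, ...] = ()
    # synonym channel
    synonym_classes: tuple[SynonymClass, ...] = ()
    n_context_windows: int = 0


@dataclass(frozen=True)
class PlantedMention:
    term: str
    domain: str
    class_label: str
    sentence_index: int


@dataclass
class PostPlan:
    post_id: str
    author: str  # DELETED when the username was removed
    true_author: str  # pre-deletion identity, for bookkeeping only
    community: str
    year: int
    quarter: int
    kind: str
    n_sentences: int
    mentions: list[PlantedMention] = field(default_factory=list)
    channel: str = "base"


@dataclass
class GroundTruth:
    spec: SyntheticSpec
    plans: list[PostPlan]
    #: (class_a, class_b) -> whole-post 2x2 event counts over the
    #: association-channel universe, plus the planted parameters
    pair_tables: dict[tuple[str, str], dict[str, float]] = field(default_factory=dict)
    cohort: set[str] = field(default_factory=set)
    #: category -> (year, quarter) -> planted mention probability
    trend_probs: dict[str, dict[tuple[int, int], float]] = field(default_factory=dict)
    deleted_submission_share: float = 0.0
    deleted_comment_share: float = 0.0
    sentence_counts: list[int] = field(default_factory=list)

    def mention_count(self) -> int:
        return sum(len(p.mentions) for p in self.plans)


def solve_joint_probability(p_a: float, p_b: float, or_true: float) -> float:
    """Joint probability p11 giving a 2x2 with the requested odds ratio.

    Solves OR = p11 (1 - pA - pB + p11) / ((pA - p11)(pB - p11)) for the
    root inside the Frechet bounds [max(0, pA+pB-1), min(pA, pB)]; for
    OR = 1 this is the independent product pA * pB.
    """
    if not (0 < p_a < 1 and 0 < p_b < 1):
        raise ValueError("marginals must lie strictly inside (0, 1)")
    if or_true <= 0:
        raise ValueError("true odds ratio must be positive")
    if math.isclose(or_true, 1.0):
        return p_a * p_b
    # (1 - OR) p^2 + [1 - pA - pB + OR (pA + pB)] p - OR pA pB = 0
    a = 1.0 - or_true
    b = 1.0 - p_a - p_b + or_true * (p_a + p_b)
    c = -or_true * p_a * p_b
    disc = b * b - 4 * a * c
    if disc < 0:
        raise ValueError("no real root for the requested odds ratio")
    lo, hi = max(0.0, p_a + p_b - 1.0), min(p_a, p_b)
    for sign in (-1.0, 1.0):
        root = (-b + sign * math.sqrt(disc)) / (2 * a)
        if lo - 1e-12 <= root <= hi + 1e-12:
            return float(min(max(root, lo), hi))
    raise ValueError(
        f"no feasible joint probability in [{lo:.6g}, {hi:.6g}] "
        f"for pA={p_a}, pB={p_b}, OR={or_true}"
    )


def _draw_from_pmf(rng: np.random.Generator, pmf: dict[int, float], size: int) -> np.ndarray:
    keys = np.array(sorted(pmf))
    probs = np.array([pmf[k] for k in keys], dtype=float)
    probs = probs / probs.sum()
    return rng.choice(keys, size=size, p=probs)


def _quarter_timestamp(rng: np.random.Generator, year: int, quarter: int) -> int:
    start = datetime(year, 3 * (quarter - 1) + 1, 1, tzinfo=timezone.utc)
    # stay well inside the quarter: up to ~89 days after its start
    return int(start.timestamp()) + int(rng.integers(0, 89 * 86400))


def _assign_kind_and_deletion(
    rng: np.random.Generator, spec: SyntheticSpec
) -> tuple[str, bool]:
    kind = "submission" if rng.random() < spec.submission_frac else "comment"
    frac = (
        spec.deleted_submission_frac
        if kind == "submission"
        else spec.deleted_comment_frac
    )
    return kind, bool(rng.random() < frac)


def _plan_base_channel(
    rng: np.random.Generator, spec: SyntheticSpec, authors: list[str]
) -> list[PostPlan]:
    """Author activity stream: heavy-tailed volumes, quarterly trends."""
    first, last = spec.years
    quarters = [(y, q) for y in range(first, last + 1) for q in (1, 2, 3, 4)]
    n_posts = np.minimum(
        rng.zipf(spec.posts_per_author_alpha, size=len(authors)),
        spec.posts_per_author_cap,
    )
    comms = list(spec.topical_communities) + list(spec.background_communities)
    plans: list[PostPlan] = []
    by_author_quarter: dict[tuple[str, tuple[int, int]], list[PostPlan]] = {}
    pid = 0
    for author, k in zip(authors, n_posts):
        for _ in range(int(k)):
            yq = quarters[int(rng.integers(0, len(quarters)))]
            community = comms[int(rng.integers(0, len(comms)))]
            kind, deleted = _assign_kind_and_deletion(rng, spec)
            n_sent = int(_draw_from_pmf(rng, spec.sentence_pmf, 1)[0])
            plan = PostPlan(
                post_id=f"b{pid}",
                author=DELETED if deleted else author,
                true_author=author,
                community=community,
                year=yq[0],
                quarter=yq[1],
                kind=kind,
                n_sentences=n_sent,
                channel="base",
            )
            pid += 1
            plans.append(plan)
            if community in spec.topical_communities:
                by_author_quarter.setdefault((author, yq), []).append(plan)
    # plant quarterly trends: one Bernoulli per (author, quarter, category)
    for trend in spec.trends:
        for qi, yq in enumerate(quarters):
            p = min(max(trend.p0 + trend.slope_per_quarter * qi, 0.0), 1.0)
            for (author, aq), posts in by_author_quarter.items():
                if aq != yq:
                    continue
                if rng.random() < p:
                    target = posts[int(rng.integers(0, len(posts)))]
                    sent = int(rng.integers(0, target.n_sentences))
                    target.mentions.append(
                        PlantedMention(
                            term=trend.term,
                            domain=trend.domain,
                            class_label=trend.class_label,
                            sentence_index=sent,
                        )
                    )
    return plans


def _plan_association_channel(
    rng: np.random.Generator, spec: SyntheticSpec, authors: list[str]
) -> list[PostPlan]:
    if spec.n_association_posts == 0:
        return []
    year = spec.association_year
    joints = {
        (pa.class_a, pa.class_b): solve_joint_probability(pa.p_a, pa.p_b, pa.true_or)
        for pa in spec.associations
    }
    max_d = max(
        (max(pa.distance_pmf) for pa in spec.associations), default=0
    )
    plans: list[PostPlan] = []
    for i in range(spec.n_association_posts):
        author = authors[int(rng.integers(0, len(authors)))]
        kind, deleted = _assign_kind_and_deletion(rng, spec)
        quarter = int(rng.integers(1, 5))
        # sentence count large enough for any planted distance
        n_sent = int(_draw_from_pmf(rng, spec.sentence_pmf, 1)[0])
        plan = PostPlan(
            post_id=f"a{i}",
            author=DELETED if deleted else author,
            true_author=author,
            community="assoc_talk",
            year=year,
            quarter=quarter,
            kind=kind,
            n_sentences=n_sent,
            channel="assoc",
        )
        # anchor pins the post into the either-domain universe
        if spec.anchor_classes:
            term, domain, cls = spec.anchor_classes[
                int(rng.integers(0, len(spec.anchor_classes)))
            ]
            plan.mentions.append(
                PlantedMention(term, domain, cls, int(rng.integers(0, n_sent)))
            )
        for pa in spec.associations:
            p11 = joints[(pa.class_a, pa.class_b)]
            u = rng.random()
            if u < p11:
                cell = "11"
            elif u < pa.p_a:
                cell = "10"
            elif u < pa.p_a + pa.p_b - p11:
                cell = "01"
            else:
                cell = "00"
            if cell == "11":
                d = int(_draw_from_pmf(rng, pa.distance_pmf, 1)[0])
                if plan.n_sentences < d + 1:
                    plan.n_sentences = d + 1
                i0 = int(rng.integers(0, plan.n_sentences - d))
                a_first = bool(rng.random() < 0.5)
                ia, ib = (i0, i0 + d) if a_first else (i0 + d, i0)
                plan.mentions.append(
                    PlantedMention(pa.term_a, pa.domain_a, pa.class_a, ia)
                )
                plan.mentions.append(
                    PlantedMention(pa.term_b, pa.domain_b, pa.class_b, ib)
                )
            elif cell == "10":
                plan.mentions.append(
                    PlantedMention(
                        pa.term_a, pa.domain_a, pa.class_a,
                        int(rng.integers(0, plan.n_sentences)),
                    )
                )
            elif cell == "01":
                plan.mentions.append(
                    PlantedMention(
                        pa.term_b, pa.domain_b, pa.class_b,
                        int(rng.integers(0, plan.n_sentences)),
                    )
                )
        for im in spec.independent_mentions:
            if rng.random() < im.p:
                plan.mentions.append(
                    PlantedMention(
                        im.term, im.domain, im.class_label,
                        int(rng.integers(0, plan.n_sentences)),
                    )
                )
        plans.append(plan)
        _ = max_d  # distances bounded by construction above
    return plans


def plant_synonyms(
    rng: np.random.Generator, spec: SyntheticSpec, start_id: int = 0
) -> list[PostPlan]:
    """Context-window posts in which class members are interchangeable.

    Each window is one sentence: two context words, a class term drawn
    uniformly from the class, two more context words.  Context vocabulary
    is class-specific, so members of a class share their co-occurrence
    profile and cross-class pairs do not.
    """
    if spec.n_context_windows == 0 or not spec.synonym_classes:
        return []
    for sc in spec.synonym_classes:
        if len(sc.terms) < 2:
            import logging

            logging.getLogger(__name__).warning(
                "synonym class %r has a single term; nothing to recover", sc.name
            )
    ctx_vocab = {
        sc.name: [f"ctx{si}w{j}" for j in range(sc.n_context_words)]
        for si, sc in enumerate(spec.synonym_classes)
    }
    first, last = spec.years
    plans: list[PostPlan] = []
    for i in range(spec.n_context_windows):
        sc = spec.synonym_classes[int(rng.integers(0, len(spec.synonym_classes)))]
        term = sc.terms[int(rng.integers(0, len(sc.terms)))]
        ctx = ctx_vocab[sc.name]
        words = [ctx[int(rng.integers(0, len(ctx)))] for _ in range(4)]
        plan = PostPlan(
            post_id=f"s{start_id + i}",
            author=f"syn_author{int(rng.integers(0, 50))}",
            true_author="",
            community="opi_talk",
            year=last,
            quarter=int(rng.integers(1, 5)),
            kind="comment",
            n_sentences=1,
            channel="synonym",
        )
        plan.true_author = plan.author
        plan.mentions.append(PlantedMention(term, "synonym", sc.name, 0))
        # context words carried via a fixed filler layout (see _realize_body)
        plan.context_words = words  # type: ignore[attr-defined]
        plans.append(plan)
    return plans


def _realize_body(
    rng: np.random.Generator, plan: PostPlan, fillers: list[str]
) -> str:
    by_sentence: dict[int, list[str]] = {}
    for m in plan.mentions:
        by_sentence.setdefault(m.sentence_index, []).append(m.term)
    sentences: list[str] = []
    ctx = getattr(plan, "context_words", None)
    for si in range(plan.n_sentences):
        terms = by_sentence.get(si, [])
        if ctx is not None:
            words = ctx[:2] + terms + ctx[2:]
        else:
            n_fill = 3
            words = [
                fillers[int(rng.integers(0, len(fillers)))] for _ in range(n_fill)
            ]
            # slot vocabulary terms at random positions
            for t in terms:
                words.insert(int(rng.integers(0, len(words) + 1)), t)
        sentences.append(" ".join(words) + ".")
    return " ".join(sentences)


def _pair_tables(spec: SyntheticSpec, plans: list[PostPlan]) -> dict:
    """Whole-post (rho = inf) 2x2 event recount for each planted pair."""
    tables: dict[tuple[str, str], dict[str, float]] = {}
    assoc_plans = [p for p in plans if p.channel == "assoc"]
    for pa in spec.associations:
        n11 = n10 = n01 = n00 = 0
        for plan in assoc_plans:
            has_a = any(
                m.domain == pa.domain_a and m.class_label == pa.class_a
                for m in plan.mentions
            )
            has_b = any(
                m.domain == pa.domain_b and m.class_label == pa.class_b
                for m in plan.mentions
            )
            if has_a and has_b:
                n11 += 1
            elif has_a:
                n10 += 1
            elif has_b:
                n01 += 1
            else:
                n00 += 1
        tables[(pa.class_a, pa.class_b)] = {
            "n11": n11,
            "n10": n10,
            "n01": n01,
            "n00": n00,
            "true_or": pa.true_or,
            "p_a": pa.p_a,
            "p_b": pa.p_b,
        }
    return tables


def _plan_all(spec: SyntheticSpec, rng: np.random.Generator) -> list[PostPlan]:
    authors = [f"author{i:05d}" for i in range(spec.n_authors)]
    plans = _plan_base_channel(rng, spec, authors)
    plans += _plan_association_channel(rng, spec, authors)
    plans += plant_synonyms(rng, spec, start_id=0)
    return plans


def _build_ground_truth(spec: SyntheticSpec, plans: list[PostPlan]) -> GroundTruth:
    n_sub = n_sub_del = n_com = n_com_del = 0
    for plan in plans:
        if plan.kind == "submission":
            n_sub += 1
            n_sub_del += plan.author == DELETED
        else:
            n_com += 1
            n_com_del += plan.author == DELETED
    topical = set(spec.topical_communities) | {"assoc_talk"}
    cohort = {
        p.author for p in plans if p.community in topical and p.author != DELETED
    }
    first, last = spec.years
    quarters = [(y, q) for y in range(first, last + 1) for q in (1, 2, 3, 4)]
    trend_probs = {
        t.class_label: {
            yq: min(max(t.p0 + t.slope_per_quarter * qi, 0.0), 1.0)
            for qi, yq in enumerate(quarters)
        }
        for t in spec.trends
    }
    return GroundTruth(
        spec=spec,
        plans=plans,
        pair_tables=_pair_tables(spec, plans),
        cohort=cohort,
        trend_probs=trend_probs,
        deleted_submission_share=n_sub_del / n_sub if n_sub else 0.0,
        deleted_comment_share=n_com_del / n_com if n_com else 0.0,
        sentence_counts=[p.n_sentences for p in plans],
    )


def generate_ground_truth(spec: SyntheticSpec) -> GroundTruth:
    """Plan a corpus without realizing its text (the fast path).

    Plans are identical to what :func:`generate_corpus` would emit for the
    same spec: text realization draws from the random stream only after
    planning is complete.
    """
    rng = np.random.default_rng(spec.seed)
    return _build_ground_truth(spec, _plan_all(spec, rng))


def generate_corpus(spec: SyntheticSpec) -> tuple[list[str], GroundTruth]:
    """Emit NDJSON lines plus the ground-truth bookkeeping.

    Deterministic: the same spec (including seed) yields identical lines.
    """
    rng = np.random.default_rng(spec.seed)
    fillers = [f"filler{i:03d}" for i in range(spec.filler_vocab_size)]
    plans = _plan_all(spec, rng)
    lines: list[str] = []
    for plan in plans:
        body = _realize_body(rng, plan, fillers)
        ts = _quarter_timestamp(rng, plan.year, plan.quarter)
        rec = {
            "id": plan.post_id,
            "author": None if plan.author == DELETED else plan.author,
            "subreddit": plan.community,
            "created_utc": ts,
            "kind": plan.kind,
            "body": body,
        }
        lines.append(json.dumps(rec, sort_keys=True))
    return lines, _build_ground_truth(spec, plans)


def write_ndjson(lines: list[str], path: str | Path) -> None:
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")


def ground_truth_mentions(gt: GroundTruth) -> list[MentionRecord]:
    """Planted mentions as MentionRecords (the generator's fast path).

    Used when an estimator should run directly on the planted mention
    structure without a text round trip; recount equality between this view
    and the full NDJSON pipeline is asserted separately on small corpora.
    """
    out: list[MentionRecord] = []
    for plan in gt.plans:
        for m in plan.mentions:
            out.append(
                MentionRecord(
                    post_id=plan.post_id,
                    author=plan.author,
                    term=m.term,
                    domain=m.domain,
                    class_label=m.class_label,
                    sentence_index=m.sentence_index,
                    year=plan.year,
                    quarter=plan.quarter,
                    community=plan.community,
                    kind=plan.kind,
                )
            )
    return out


def default_association_spec(
    seed: int,
    true_or: float = 4.0,
    n_posts: int = 2000,
    p_a: float = 0.30,
    p_b: float = 0.20,
) -> SyntheticSpec:
    """Study-condition spec for association runs: one planted pair plus
    independent background classes, universe pinned by neutral anchors."""
    return SyntheticSpec(
        seed=seed,
        n_authors=max(50, n_posts // 20),
        n_association_posts=n_posts,
        associations=(
            PlantedAssociation(
                class_a="heroin",
                term_a="heroin",
                class_b="Intravenous",
                term_b="vein",
                p_a=p_a,
                p_b=p_b,
                true_or=true_or,
            ),
        ),
        independent_mentions=(
            IndependentMention("oxy", "substance", "oxycodone", 0.15),
            IndependentMention("smoke", "roa", "Smoking", 0.12),
            IndependentMention("chew", "roa", "Chew", 0.08),
            IndependentMention("crush", "tampering", "Grind", 0.10),
        ),
    )
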