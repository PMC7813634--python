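"""Cohort construction, yearly summary statistics, quarterly popularity.

The cohort is the set of distinct non-deleted authors who posted at least
once in a selected (topical) community during the study span; posting there
is taken as a proxy for firsthand interest in the topic.  Prevalence for a
year is topical authors / all platform authors.  Popularity of a taxonomy
category in a quarter is the share of cohort authors mentioning it at least
once — a binary per-author characterization, so heavy posters count the
same as occasional ones.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass
from pathlib import Path

from .corpus import DELETED, Corpus, MentionRecord

__all__ = [
    "Cohort",
    "YearStats",
    "CohortStats",
    "PopularitySeries",
    "compute_prevalence",
    "identify_cohort",
    "cohort_stats",
    "popularity_series",
    "rank_by_average_share",
]

Quarter = tuple[int, int]  # (year, quarter)


@dataclass
class Cohort:
    authors: set[str]
    communities: set[str]
    years: list[int]

    def __post_init__(self) -> None:
        if DELETED in self.authors:
            raise ValueError("cohort must not contain the deleted-author sentinel")

    def __len__(self) -> int:
        return len(self.authors)


@dataclass
class YearStats:
    year: int
    total_comments: int
    total_authors: int
    topical_communities: int
    topical_comments: int
    topical_authors: int
    prevalence: float | None  # unrounded; None when total_authors == 0

    @property
    def prevalence_rounded(self) -> float | None:
        """Prevalence at report precision (4 decimals)."""
        return None if self.prevalence is None else round(self.prevalence, 4)


@dataclass
class CohortStats:
    rows: list[YearStats]

    def row(self, year: int) -> YearStats:
        for r in self.rows:
            if r.year == year:
                return r
        raise KeyError(year)

    def to_tsv(self, path: str | Path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            fh.write(
                "year\ttotal_comments\ttotal_authors\ttopical_communities\t"
                "topical_comments\ttopical_authors\tprevalence\n"
            )
            for r in self.rows:
                prev = "" if r.prevalence is None else f"{r.prevalence_rounded:.4f}"
                fh.write(
                    f"{r.year}\t{r.total_comments}\t{r.total_authors}\t"
                    f"{r.topical_communities}\t{r.topical_comments}\t"
                    f"{r.topical_authors}\t{prev}\n"
                )


@dataclass
class PopularitySeries:
    category: str
    shares: dict[Quarter, float]  # ordered by (year, quarter)
    denominator: str  # "active" | "cohort"

    def ordered(self) -> list[tuple[Quarter, float]]:
        return sorted(self.shares.items())

    def mean_share(self) -> float:
        vals = list(self.shares.values())
        return sum(vals) / len(vals) if vals else 0.0


def compute_prevalence(topical_authors: int, total_authors: int) -> float:
    """Topical authors as a fraction of all platform authors in a year."""
    if total_authors <= 0:
        raise ZeroDivisionError("no authors in year; prevalence undefined")
    return topical_authors / total_authors


def identify_cohort(corpus: Corpus, communities: set[str]) -> Cohort:
    """Distinct non-deleted authors posting in the selected communities."""
    if not communities:
        raise ValueError("community set must be non-empty")
    unknown = communities - corpus.communities
    if unknown:
        raise ValueError(f"communities not in corpus: {sorted(unknown)}")
    authors = {
        p.author
        for p in corpus
        if p.community in communities and not p.is_deleted_author
    }
    return Cohort(authors=authors, communities=set(communities), years=corpus.years)


def cohort_stats(
    corpus: Corpus, cohort: Cohort, communities: set[str]
) -> CohortStats:
    """Per-year totals, topical counts and prevalence.

    Deleted authors contribute to comment volumes but never to any
    author-distinct count.
    """
    per_year: dict[int, dict] = defaultdict(
        lambda: {
            "total_comments": 0,
            "total_authors": set(),
            "topical_communities": set(),
            "topical_comments": 0,
            "topical_authors": set(),
        }
    )
    for p in corpus:
        y = per_year[p.year]
        topical = p.community in communities
        if p.kind == "comment":
            y["total_comments"] += 1
            if topical:
                y["topical_comments"] += 1
        if topical:
            y["topical_communities"].add(p.community)
        if not p.is_deleted_author:
            y["total_authors"].add(p.author)
            if topical:
                y["topical_authors"].add(p.author)
    rows = []
    for year in sorted(per_year):
        y = per_year[year]
        n_total = len(y["total_authors"])
        n_topical = len(y["topical_authors"])
        rows.append(
            YearStats(
                year=year,
                total_comments=y["total_comments"],
                total_authors=n_total,
                topical_communities=len(y["topical_communities"]),
                topical_comments=y["topical_comments"],
                topical_authors=n_topical,
                prevalence=(
                    compute_prevalence(n_topical, n_total) if n_total else None
                ),
            )
        )
    return CohortStats(rows=rows)


def _span_quarters(span: tuple[int, int]) -> list[Quarter]:
    first, last = span
    return [(y, q) for y in range(first, last + 1) for q in (1, 2, 3, 4)]


def popularity_series(
    mentions: list[MentionRecord],
    cohort: Cohort,
    category: str,
    span: tuple[int, int],
    corpus: Corpus | None = None,
    denominator: str = "active",
    domain: str | None = None,
    communities: set[str] | None = None,
) -> PopularitySeries:
    """Quarterly share of cohort authors mentioning a taxonomy class.

    ``denominator="active"`` divides by the cohort authors posting in the
    quarter (requires ``corpus``); ``"cohort"`` divides by the full-span
    cohort size.  Repeated mentions by one author in a quarter count once.
    ``communities`` restricts which mentions count (default: the cohort's
    defining communities).
    """
    if not cohort.authors:
        raise ValueError("empty cohort")
    if denominator not in ("active", "cohort"):
        raise ValueError(f"unknown denominator policy {denominator!r}")
    if denominator == "active" and corpus is None:
        raise ValueError("'active' denominator needs the corpus")
    quarters = _span_quarters(span)
    valid = set(quarters)
    comm_filter = cohort.communities if communities is None else communities
    mentioners: dict[Quarter, set[str]] = defaultdict(set)
    for m in mentions:
        if m.class_label != category or m.author == DELETED:
            continue
        if domain is not None and m.domain != domain:
            continue
        if m.author not in cohort.authors:
            continue
        if comm_filter and m.community and m.community not in comm_filter:
            continue
        key = (m.year, m.quarter)
        if key not in valid:
            raise ValueError(f"mention in quarter {key} outside span {span}")
        mentioners[key].add(m.author)
    active: dict[Quarter, set[str]] = defaultdict(set)
    if denominator == "active":
        assert corpus is not None
        for p in corpus:
            if p.author in cohort.authors and (
                not comm_filter or p.community in comm_filter
            ):
                active[(p.year, p.quarter)].add(p.author)
    shares: dict[Quarter, float] = {}
    for q in quarters:
        denom = len(active[q]) if denominator == "active" else len(cohort.authors)
        shares[q] = len(mentioners[q]) / denom if denom else 0.0
    return PopularitySeries(category=category, shares=shares, denominator=denominator)


def rank_by_average_share(series: list[PopularitySeries]) -> list[str]:
    """Categories by descending mean share; lexicographic tie-break."""
    spans = {tuple(sorted(s.shares.keys())) for s in series}
    if len(spans) > 1:
        raise ValueError("all series must share the same span")
    return [
        s.category
        for s in sorted(series, key=lambda s: (-s.mean_share(), s.category))
    ]
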