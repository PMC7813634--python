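"""Sentence-distance-thresholded co-occurrence odds ratios.

A post co-mentions two classes (e.g. the substance class *heroin* and the
secondary route *Intravenous*) when a mention of each occurs within rho
sentences of the other: rho=0 means the same sentence, rho=1 allows the
adjacent sentences in both directions, rho=inf takes the whole post as the
window.  Mentions farther apart than rho are *separate events*: such a post
contributes one A-only and one B-only event, so the table counts events,
not a partition of posts.  For each class pair a 2x2 event table

    n11 (joint)   n10 (A only)
    n01 (B only)  n00 (neither)

is built over a universe of posts holding at least one mention from either
of the pair's two domains; the odds ratio (n11*n00)/(n10*n01) with a Woolf
log-normal confidence interval and a Pearson chi-square test of
independence quantifies association strength.  ORs are correlational
measures here, never causal claims.
"""

from __future__ import annotations

import math
from collections import defaultdict
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy import stats

from .corpus import MentionRecord
from .taxonomy import Taxonomy

__all__ = [
    "INF",
    "AnalysisConfig",
    "ContingencyTable",
    "AssociationResult",
    "pair_events",
    "build_contingency",
    "odds_ratio",
    "or_confidence_interval",
    "chi_square_test",
    "associate",
    "association_matrix",
    "sentence_count_profile",
    "write_grid_tsv",
]

#: Whole-post window (no distance restriction).
INF = math.inf

DEFAULT_RHOS = (0, 1, 2, 3, 4, 5, INF)


@dataclass(frozen=True)
class AnalysisConfig:
    rho: float = 1
    alpha: float = 0.01
    ci_level: float = 0.95
    zero_cell: str = "haldane"  # "haldane" | "undefined"
    universe: str = "either"  # "either" | "both"
    year: int | None = 2018
    include_low_support: bool = False

    def __post_init__(self) -> None:
        if not (0 < self.alpha < 1):
            raise ValueError("alpha must be in (0, 1)")
        if self.zero_cell not in ("haldane", "undefined"):
            raise ValueError(f"unknown zero-cell policy {self.zero_cell!r}")
        if self.universe not in ("either", "both"):
            raise ValueError(f"unknown universe policy {self.universe!r}")


@dataclass
class ContingencyTable:
    n11: int
    n10: int
    n01: int
    n00: int
    class_a: str = ""
    domain_a: str = ""
    class_b: str = ""
    domain_b: str = ""
    rho: float = INF

    @property
    def total(self) -> int:
        return self.n11 + self.n10 + self.n01 + self.n00

    def cells(self) -> tuple[int, int, int, int]:
        return (self.n11, self.n10, self.n01, self.n00)

    @property
    def degenerate(self) -> bool:
        """A margin is empty: one of the classes never occurs in the universe."""
        return (self.n11 + self.n10 == 0) or (self.n11 + self.n01 == 0)


@dataclass
class AssociationResult:
    table: ContingencyTable
    odds_ratio: float
    ci_low: float
    ci_high: float
    p_value: float
    significant: bool
    corrected: bool = False
    defined: bool = True
    alpha: float = 0.01


def group_mentions_by_post(
    mentions: list[MentionRecord],
) -> dict[str, list[MentionRecord]]:
    by_post: dict[str, list[MentionRecord]] = defaultdict(list)
    for m in mentions:
        by_post[m.post_id].append(m)
    return dict(by_post)


def _class_sentences(
    post_mentions: list[MentionRecord], class_label: str, domain: str
) -> set[int]:
    return {
        m.sentence_index
        for m in post_mentions
        if m.domain == domain and m.class_label == class_label
    }


def pair_events(
    post_mentions: list[MentionRecord],
    class_a: str,
    domain_a: str,
    class_b: str,
    domain_b: str,
    rho: float,
) -> tuple[int, int, int]:
    """Events one post contributes to the (A, B) pair at threshold rho.

    Returns (joint, a_only, b_only), each 0 or 1.  Joint requires some
    mention of A at sentence i and of B at sentence j with |i - j| <= rho.
    A post with A mentions but no qualifying pair yields an A-only event,
    and symmetrically for B — possibly both at once.
    """
    sa = _class_sentences(post_mentions, class_a, domain_a)
    sb = _class_sentences(post_mentions, class_b, domain_b)
    if not sa and not sb:
        return (0, 0, 0)
    joint = 0
    if sa and sb:
        if rho == INF:
            joint = 1
        else:
            joint = int(any(abs(i - j) <= rho for i in sa for j in sb))
    if joint:
        return (1, 0, 0)
    return (0, int(bool(sa)), int(bool(sb)))


def build_contingency(
    mentions_by_post: dict[str, list[MentionRecord]],
    class_a: str,
    domain_a: str,
    class_b: str,
    domain_b: str,
    rho: float,
    universe: str = "either",
) -> ContingencyTable:
    """Event table for one class pair over the domain-defined post universe.

    Universe policy "either": posts with >= 1 mention from domain A or
    domain B; "both": posts with mentions from both domains.  A universe
    post contributing no event is an n00 count.
    """
    n11 = n10 = n01 = n00 = 0
    n_universe = 0
    for pms in mentions_by_post.values():
        has_a_dom = any(m.domain == domain_a for m in pms)
        has_b_dom = any(m.domain == domain_b for m in pms)
        in_universe = (
            (has_a_dom or has_b_dom) if universe == "either" else (has_a_dom and has_b_dom)
        )
        if not in_universe:
            continue
        n_universe += 1
        joint, a_only, b_only = pair_events(
            pms, class_a, domain_a, class_b, domain_b, rho
        )
        n11 += joint
        n10 += a_only
        n01 += b_only
        if not (joint or a_only or b_only):
            n00 += 1
    if n_universe == 0:
        raise ValueError(
            f"empty universe for domains ({domain_a!r}, {domain_b!r})"
        )
    return ContingencyTable(
        n11=n11,
        n10=n10,
        n01=n01,
        n00=n00,
        class_a=class_a,
        domain_a=domain_a,
        class_b=class_b,
        domain_b=domain_b,
        rho=rho,
    )


def _corrected_cells(
    table: ContingencyTable, policy: str
) -> tuple[tuple[float, float, float, float], bool]:
    cells = table.cells()
    if 0 in cells:
        if policy == "undefined":
            raise ZeroDivisionError("zero cell with policy 'undefined'")
        return tuple(c + 0.5 for c in cells), True  # type: ignore[return-value]
    return cells, False


def odds_ratio(
    table: ContingencyTable, zero_cell: str = "haldane"
) -> tuple[float, bool]:
    """(OR, corrected) with the Haldane-Anscombe +0.5 fix on zero cells."""
    (a, b, c, d), corrected = _corrected_cells(table, zero_cell)
    return (a * d) / (b * c), corrected


def or_confidence_interval(
    table: ContingencyTable,
    level: float = 0.95,
    zero_cell: str = "haldane",
) -> tuple[float, float]:
    """Woolf log-normal interval exp(ln OR +/- z * sqrt(sum of 1/cell))."""
    if not (0 < level < 1):
        raise ValueError("confidence level must be in (0, 1)")
    (a, b, c, d), _ = _corrected_cells(table, zero_cell)
    log_or = math.log((a * d) / (b * c))
    se = math.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
    z = stats.norm.ppf(0.5 + level / 2)
    return math.exp(log_or - z * se), math.exp(log_or + z * se)


def chi_square_test(
    table: ContingencyTable, alpha: float = 0.01, correction: bool = False
) -> tuple[float, float, bool]:
    """Pearson chi-square of independence on the 2x2 (no Yates by default)."""
    arr = np.array([[table.n11, table.n10], [table.n01, table.n00]], dtype=float)
    if (arr.sum(axis=0) == 0).any() or (arr.sum(axis=1) == 0).any():
        raise ValueError("a margin is zero; expected counts undefined")
    res = stats.chi2_contingency(arr, correction=correction)
    return float(res.statistic), float(res.pvalue), bool(res.pvalue < alpha)


def associate(
    table: ContingencyTable, config: AnalysisConfig | None = None
) -> AssociationResult:
    """Full association result (OR, CI, p, significance) for one table."""
    config = config or AnalysisConfig()
    if table.total == 0:
        raise ValueError("empty contingency table")
    try:
        or_value, corrected = odds_ratio(table, config.zero_cell)
        ci_low, ci_high = or_confidence_interval(
            table, config.ci_level, config.zero_cell
        )
        statistic, p, significant = chi_square_test(table, config.alpha)
    except (ZeroDivisionError, ValueError):
        return AssociationResult(
            table=table,
            odds_ratio=float("nan"),
            ci_low=float("nan"),
            ci_high=float("nan"),
            p_value=float("nan"),
            significant=False,
            corrected=False,
            defined=False,
            alpha=config.alpha,
        )
    return AssociationResult(
        table=table,
        odds_ratio=or_value,
        ci_low=ci_low,
        ci_high=ci_high,
        p_value=p,
        significant=significant,
        corrected=corrected,
        alpha=config.alpha,
    )


def association_matrix(
    mentions: list[MentionRecord],
    taxonomy: Taxonomy,
    domain_a: str,
    domain_b: str,
    config: AnalysisConfig | None = None,
    classes_a: list[str] | None = None,
    classes_b: list[str] | None = None,
) -> dict[tuple[str, str], AssociationResult]:
    """One association result per class pair across two domains.

    Mentions are filtered to the configured year; low-support taxonomy
    classes are excluded unless the config overrides.  Degenerate pairs are
    reported with ``defined=False`` rather than silently dropped.
    """
    config = config or AnalysisConfig()
    if not mentions:
        raise ValueError("empty mention list")
    if config.year is not None:
        mentions = [m for m in mentions if m.year == config.year]
        if not mentions:
            raise ValueError(f"no mentions in year {config.year}")
    by_post = group_mentions_by_post(mentions)
    cls_a = classes_a or taxonomy.classes(domain_a, config.include_low_support)
    cls_b = classes_b or taxonomy.classes(domain_b, config.include_low_support)
    grid: dict[tuple[str, str], AssociationResult] = {}
    for ca in cls_a:
        for cb in cls_b:
            table = build_contingency(
                by_post, ca, domain_a, cb, domain_b, config.rho, config.universe
            )
            grid[(ca, cb)] = associate(table, config)
    return grid


def sentence_count_profile(
    sentence_counts: list[int],
) -> dict[str, float]:
    """Median sentence count and shares of short (<=2) and long (>10) posts."""
    if not sentence_counts:
        raise ValueError("no posts")
    arr = np.asarray(sentence_counts)
    return {
        "median": float(np.median(arr)),
        "share_le_2": float((arr <= 2).mean()),
        "share_gt_10": float((arr > 10).mean()),
    }


def write_grid_tsv(
    grid: dict[tuple[str, str], AssociationResult], path: str | Path
) -> None:
    cols = (
        "classA\tclassB\trho\tn11\tn10\tn01\tn00\tOR\tci_low\tci_high\t"
        "p\tsignificant\tcorrected\n"
    )
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(cols)
        for (ca, cb), r in sorted(grid.items()):
            t = r.table
            rho = "inf" if t.rho == INF else str(int(t.rho))
            fh.write(
                f"{ca}\t{cb}\t{rho}\t{t.n11}\t{t.n10}\t{t.n01}\t{t.n00}\t"
                f"{r.odds_ratio:.6g}\t{r.ci_low:.6g}\t{r.ci_high:.6g}\t"
                f"{r.p_value:.6g}\t{int(r.significant)}\t{int(r.corrected)}\n"
            )
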