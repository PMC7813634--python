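"""Controlled vocabularies: substances, routes of administration, tampering.

Three term -> class maps drive all matching and counting:

* **substances** — 12 classes (heroin ... methadone), flat;
* **roa** — a two-level taxonomy: primary route (Ingestion, Inhalation,
  Injection, Rectally, Other ROA) -> secondary route -> terms.  "Rectally"
  is both a primary and its own terminal secondary class;
* **tampering** — 11 transformation classes (Brew ... Wash), flat.

Each domain is a disjoint namespace: a surface term may appear in two
different domains but never under two classes of the same domain.  Terms are
single tokens; the fixtures ship as reviewable TSV under ``opiomine/data``.
Two secondary routes, Intrathecal and Urogenital, are loaded but flagged
low-support; association grids exclude flagged classes by default because
their mention volume is too thin to interpret.
"""

from __future__ import annotations

import csv
import io
from collections import defaultdict
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

from .corpus import MentionRecord

__all__ = [
    "DOMAINS",
    "LOW_SUPPORT_CLASSES",
    "TermEntry",
    "Lexicon",
    "Taxonomy",
    "load_taxonomy",
    "load_default_taxonomy",
    "classify_term",
    "aggregate_to_primary",
]

DOMAINS = ("substance", "roa", "tampering")

#: Secondary ROA classes with too little support for association analysis.
LOW_SUPPORT_CLASSES = frozenset({"Intrathecal", "Urogenital"})

_FIXTURES = {
    "substance": "substances.tsv",
    "roa": "roa.tsv",
    "tampering": "tampering.tsv",
}


@dataclass(frozen=True)
class TermEntry:
    term: str
    domain: str
    class_label: str
    primary: str | None  # primary ROA for roa domain, else None
    is_seed: bool


@dataclass
class Lexicon:
    """One domain's term -> class map."""

    domain: str
    entries: dict[str, TermEntry] = field(default_factory=dict)

    @property
    def classes(self) -> list[str]:
        seen: dict[str, None] = {}
        for e in self.entries.values():
            seen.setdefault(e.class_label, None)
        return list(seen)

    def terms_of(self, class_label: str) -> set[str]:
        return {t for t, e in self.entries.items() if e.class_label == class_label}

    def seeds(self) -> set[str]:
        return {t for t, e in self.entries.items() if e.is_seed}

    def add(self, entry: TermEntry) -> None:
        if " " in entry.term or "\t" in entry.term:
            raise ValueError(f"multi-token term not allowed: {entry.term!r}")
        prev = self.entries.get(entry.term)
        if prev is not None and prev.class_label != entry.class_label:
            raise ValueError(
                f"term {entry.term!r} listed under two {self.domain} classes: "
                f"{prev.class_label!r} and {entry.class_label!r}"
            )
        self.entries[entry.term] = entry


@dataclass
class Taxonomy:
    substance: Lexicon
    roa: Lexicon
    tampering: Lexicon
    version: str = "v1"

    def lexicon(self, domain: str) -> Lexicon:
        if domain not in DOMAINS:
            raise KeyError(f"unknown domain {domain!r}")
        return getattr(self, domain)

    def term_index(self) -> dict[str, list[tuple[str, str]]]:
        """term -> [(domain, class_label), ...] across all domains."""
        idx: dict[str, list[tuple[str, str]]] = defaultdict(list)
        for domain in DOMAINS:
            for term, e in self.lexicon(domain).entries.items():
                idx[term].append((domain, e.class_label))
        return dict(idx)

    def classes(self, domain: str, include_low_support: bool = False) -> list[str]:
        cls = self.lexicon(domain).classes
        if not include_low_support:
            cls = [c for c in cls if c not in LOW_SUPPORT_CLASSES]
        return cls

    def primary_of(self, secondary: str) -> str:
        for e in self.roa.entries.values():
            if e.class_label == secondary:
                assert e.primary is not None
                return e.primary
        raise KeyError(f"unknown secondary ROA {secondary!r}")

    def primary_roa_classes(self) -> list[str]:
        seen: dict[str, None] = {}
        for e in self.roa.entries.values():
            if e.primary:
                seen.setdefault(e.primary, None)
        return list(seen)


class TermNotFound(KeyError):
    """Raised when a term does not belong to the requested domain."""


def _parse_fixture(text: str, domain: str) -> Lexicon:
    lex = Lexicon(domain=domain)
    rows = [
        r
        for r in csv.DictReader(
            (ln for ln in io.StringIO(text) if not ln.startswith("#")),
            delimiter="\t",
        )
    ]
    for r in rows:
        if r["domain"] != domain:
            raise ValueError(f"fixture row domain {r['domain']!r}, expected {domain!r}")
        primary = r.get("primary") or None
        if domain == "roa" and primary is None:
            raise ValueError(f"roa term {r['term']!r} missing primary route")
        lex.add(
            TermEntry(
                term=r["term"],
                domain=domain,
                class_label=r["class"],
                primary=primary,
                is_seed=r["is_seed"] == "1",
            )
        )
    # a secondary route must have exactly one primary parent
    if domain == "roa":
        parents: dict[str, set[str]] = defaultdict(set)
        for e in lex.entries.values():
            parents[e.class_label].add(e.primary)  # type: ignore[arg-type]
        bad = {c: p for c, p in parents.items() if len(p) != 1}
        if bad:
            raise ValueError(f"secondary routes with multiple parents: {bad}")
    return lex


def load_taxonomy(
    substance_path: str | Path,
    roa_path: str | Path,
    tampering_path: str | Path,
    version: str = "custom",
) -> Taxonomy:
    """Load and validate a taxonomy from three TSV fixture files."""
    paths = {"substance": substance_path, "roa": roa_path, "tampering": tampering_path}
    lexicons = {
        d: _parse_fixture(Path(p).read_text("utf-8"), d) for d, p in paths.items()
    }
    return Taxonomy(
        substance=lexicons["substance"],
        roa=lexicons["roa"],
        tampering=lexicons["tampering"],
        version=version,
    )


def load_default_taxonomy() -> Taxonomy:
    """Load the packaged reference vocabularies."""
    lexicons = {}
    for domain, fname in _FIXTURES.items():
        text = resources.files("opiomine.data").joinpath(fname).read_text("utf-8")
        lexicons[domain] = _parse_fixture(text, domain)
    return Taxonomy(
        substance=lexicons["substance"],
        roa=lexicons["roa"],
        tampering=lexicons["tampering"],
        version="v1",
    )


def classify_term(
    taxonomy: Taxonomy, term: str, domain: str
) -> tuple[str, str | None]:
    """Resolve a term to its (class_label, primary ROA or None).

    Raises :class:`TermNotFound` when the term is not in the domain; callers
    scanning free text usually catch and ignore it.
    """
    entry = taxonomy.lexicon(domain).entries.get(term)
    if entry is None:
        raise TermNotFound(f"{term!r} not in {domain} vocabulary")
    return entry.class_label, entry.primary


def aggregate_to_primary(
    mentions: list[MentionRecord], taxonomy: Taxonomy
) -> list[MentionRecord]:
    """Relabel roa mentions at primary-route granularity (count conserving)."""
    out: list[MentionRecord] = []
    for m in mentions:
        if m.domain != "roa":
            raise ValueError("aggregate_to_primary expects roa-domain mentions")
        entry = taxonomy.roa.entries.get(m.term)
        primary = (
            entry.primary if entry is not None else taxonomy.primary_of(m.class_label)
        )
        out.append(
            MentionRecord(
                post_id=m.post_id,
                author=m.author,
                term=m.term,
                domain=m.domain,
                class_label=primary or m.class_label,
                sentence_index=m.sentence_index,
                year=m.year,
                quarter=m.quarter,
                community=m.community,
                kind=m.kind,
            )
        )
    return out
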