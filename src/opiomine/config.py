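"""Structured run configuration shared by the CLI stages.

One YAML file with per-stage sections; CLI flags override file values.
Unknown keys are rejected so typos fail loudly instead of silently running
with defaults.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

__all__ = ["RunConfig", "load_config"]


@dataclass
class RetrievalConfig:
    k: int = 150
    m: int = 10
    max_iter: int = 5


@dataclass
class CorpusConfig:
    min_comments: int = 100
    min_lemma_freq: int = 100
    years: list[int] = field(default_factory=lambda: list(range(2014, 2019)))


@dataclass
class ExpandConfig:
    n: int = 20
    backend: str = "svd"
    dim: int = 100
    window: int = 5
    min_count: int = 5
    epochs: int = 5


@dataclass
class TrendsConfig:
    denominator: str = "active"


@dataclass
class AssocConfig:
    rho: float = 1
    alpha: float = 0.01
    ci_level: float = 0.95
    universe: str = "either"
    zero_cell: str = "haldane"
    year: int = 2018


@dataclass
class RunConfig:
    seed: int = 0
    corpus: CorpusConfig = field(default_factory=CorpusConfig)
    retrieval: RetrievalConfig = field(default_factory=RetrievalConfig)
    expand: ExpandConfig = field(default_factory=ExpandConfig)
    trends: TrendsConfig = field(default_factory=TrendsConfig)
    assoc: AssocConfig = field(default_factory=AssocConfig)

    def to_dict(self) -> dict:
        return asdict(self)


_SECTIONS = {
    "corpus": CorpusConfig,
    "retrieval": RetrievalConfig,
    "expand": ExpandConfig,
    "trends": TrendsConfig,
    "assoc": AssocConfig,
}


def load_config(path: str | Path | None) -> RunConfig:
    cfg = RunConfig()
    if path is None:
        return cfg
    raw = yaml.safe_load(Path(path).read_text("utf-8")) or {}
    if not isinstance(raw, dict):
        raise ValueError("config root must be a mapping")
    for key, value in raw.items():
        if key == "seed":
            cfg.seed = int(value)
            continue
        if key not in _SECTIONS:
            raise ValueError(f"unknown config section {key!r}")
        section = getattr(cfg, key)
        for k, v in (value or {}).items():
            if not hasattr(section, k):
                raise ValueError(f"unknown config key {key}.{k}")
            setattr(section, k, v)
    return cfg
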