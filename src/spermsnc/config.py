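"""Pipeline configuration: nested dataclasses loadable from a YAML file.

Unknown keys are rejected up front so typos never silently fall back to
defaults. One global ``seed`` determines every stochastic choice in a run.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Mapping

import yaml

from .errors import ConfigError


def _build(cls, data: Mapping[str, Any]):
    names = {f.name for f in dataclasses.fields(cls)}
    unknown = set(data) - names
    if unknown:
        raise ConfigError(f"{cls.__name__}: unknown config key(s) {sorted(unknown)}")
    kwargs = {}
    for f in dataclasses.fields(cls):
        if f.name not in data:
            continue
        val = data[f.name]
        if dataclasses.is_dataclass(f.type) or (
            isinstance(f.type, str) and f.type in _SECTION_TYPES
        ):
            sub_cls = _SECTION_TYPES[f.type] if isinstance(f.type, str) else f.type
            val = _build(sub_cls, val or {})
        kwargs[f.name] = val
    return cls(**kwargs)


@dataclass
class CohortSection:
    n_high: int = 23
    n_low: int = 64
    depth_min: int = 100_000
    depth_max: int = 300_000
    dispersion: float = 0.1
    spike_log2fc: float = 2.0


@dataclass
class ReferencesSection:
    n_trna: int = 21
    n_mirna: int = 40
    n_pirna: int = 30


@dataclass
class PreprocessSection:
    adapter: str = ""                 # empty = no adapter trimming
    min_len: int = 15
    max_len: int = 45
    min_mean_qual: float = 20.0
    seed_len: int = 8
    max_mismatch: int = 1


@dataclass
class AnnotationSection:
    hierarchy: tuple = ("miRNA", "tRNA", "rRNA", "piRNA")
    kmer: int = 15
    mismatch_budget: int = 0


@dataclass
class TypingSection:
    loop_pad: int = 2
    anchor_tol: int = 3


@dataclass
class QuantifySection:
    rpm_floor: float = 10.0
    denominator: str = "annotated"


@dataclass
class DiffexpSection:
    test: str = "rank_sum"
    fdr: float = 0.05
    min_abs_log2fc: float = 1.0
    pseudocount: float = 1.0


@dataclass
class MultivariateSection:
    C: float = 1.0
    scale: bool = True
    max_panel: int = 10


_SECTION_TYPES = {
    "CohortSection": CohortSection,
    "ReferencesSection": ReferencesSection,
    "PreprocessSection": PreprocessSection,
    "AnnotationSection": AnnotationSection,
    "TypingSection": TypingSection,
    "QuantifySection": QuantifySection,
    "DiffexpSection": DiffexpSection,
    "MultivariateSection": MultivariateSection,
}


@dataclass
class PipelineConfig:
    seed: int = 1
    output_dir: str = "spermsnc_run"
    cohort: CohortSection = field(default_factory=CohortSection)
    references: ReferencesSection = field(default_factory=ReferencesSection)
    preprocess: PreprocessSection = field(default_factory=PreprocessSection)
    annotation: AnnotationSection = field(default_factory=AnnotationSection)
    typing: TypingSection = field(default_factory=TypingSection)
    quantify: QuantifySection = field(default_factory=QuantifySection)
    diffexp: DiffexpSection = field(default_factory=DiffexpSection)
    multivariate: MultivariateSection = field(default_factory=MultivariateSection)

    @classmethod
    def from_dict(cls, data: Mapping[str, Any]) -> "PipelineConfig":
        return _build(cls, data)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        if not isinstance(data, dict):
            raise ConfigError(f"{path}: config must be a mapping")
        return cls.from_dict(data)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)
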