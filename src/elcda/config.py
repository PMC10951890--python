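"""Nested pipeline configuration with strict key validation.

A YAML (or plain dict) configuration maps onto the dataclasses below;
unknown keys are rejected so typos never silently fall back to defaults.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field

import yaml

from .similarity import SimilarityConfig
from .synth import SynthConfig


@dataclass
class MetapathExtractorConfig:
    embed_dim: int = 64
    heads: int = 8
    encoder: str = "mean"
    instance_cap: int = 32
    epochs: int = 200
    lr: float = 1e-3


@dataclass
class MFExtractorConfig:
    rank: int = 64
    alpha: float = 0.01
    lam: float = 0.1
    max_iter: int = 500
    tol: float = 1e-6


@dataclass
class SageExtractorConfig:
    embed_dim: int = 64
    depth: int = 2
    fanouts: tuple[int, ...] = (10, 10)
    epochs: int = 150
    lr: float = 5e-3


@dataclass
class EvaluationConfig:
    k_folds: int = 5
    threshold: float = 0.5
    paper_mode: bool = False

    def __post_init__(self) -> None:
        if self.k_folds < 2:
            raise ValueError("k_folds must be >= 2")
        if not 0 < self.threshold < 1:
            raise ValueError("threshold must lie in (0, 1)")


@dataclass
class PipelineConfig:
    seed: int = 0
    similarity: SimilarityConfig = field(default_factory=SimilarityConfig)
    metapath: MetapathExtractorConfig = field(default_factory=MetapathExtractorConfig)
    mf: MFExtractorConfig = field(default_factory=MFExtractorConfig)
    sage: SageExtractorConfig = field(default_factory=SageExtractorConfig)
    evaluation: EvaluationConfig = field(default_factory=EvaluationConfig)
    synth: SynthConfig = field(default_factory=SynthConfig)

    def pipeline_params(self) -> dict:
        """Keyword overrides for :class:`~elcda.pipeline.AssociationPipeline`."""
        return {
            "metapath_params": dataclasses.asdict(self.metapath),
            "mf_params": dataclasses.asdict(self.mf),
            "sage_params": {**dataclasses.asdict(self.sage),
                            "fanouts": tuple(self.sage.fanouts)},
        }

    def config_hash(self) -> str:
        blob = json.dumps(dataclasses.asdict(self), sort_keys=True, default=str)
        return hashlib.md5(blob.encode()).hexdigest()[:12]


def _build(cls, mapping: dict):
    names = {f.name for f in dataclasses.fields(cls)}
    unknown = set(mapping) - names
    if unknown:
        raise ValueError(f"unknown {cls.__name__} keys: {sorted(unknown)}")
    kwargs = {}
    for f in dataclasses.fields(cls):
        if f.name not in mapping:
            continue
        value = mapping[f.name]
        if dataclasses.is_dataclass(f.type) or f.name in (
                "similarity", "metapath", "mf", "sage", "evaluation", "synth"):
            sub = {"similarity": SimilarityConfig, "metapath": MetapathExtractorConfig,
                   "mf": MFExtractorConfig, "sage": SageExtractorConfig,
                   "evaluation": EvaluationConfig, "synth": SynthConfig}[f.name]
            value = _build(sub, value)
        elif isinstance(value, list):
            value = tuple(value)
        kwargs[f.name] = value
    return cls(**kwargs)


def load_config(path_or_mapping) -> PipelineConfig:
    """Load a :class:`PipelineConfig` from a YAML file or a nested dict."""
    if isinstance(path_or_mapping, dict):
        mapping = path_or_mapping
    else:
        with open(path_or_mapping) as fh:
            mapping = yaml.safe_load(fh) or {}
    return _build(PipelineConfig, mapping)
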