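"""Run configuration: input paths, samples, and analysis thresholds.

Every threshold defaults to the published value: class-I localization
probability 0.75 (strict), prediction-score floor 2.0 with a 0.9 relative
fraction, scatter-plot fraction 0.1 of the top score, top-20 bar graphs, and
a two-spectral-count minimum for the out-of-scope bar.
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields
from pathlib import Path

import yaml

from .errors import InkaError


@dataclass
class RunConfig:
    """Aggregated settings for a pipeline run; loadable from YAML."""

    peptides: str | None = None
    sites: str | None = None
    psp: str | None = None
    networkin: str | None = None
    activation_loops: str | None = None
    kinome: str | None = None
    symbol_map: str | None = None
    samples: list[str] = field(default_factory=list)
    quant_mode: str = "counts"
    class_i_threshold: float = 0.75
    networkin_min_score: float = 2.0
    networkin_relative_fraction: float = 0.9
    plot_fraction: float = 0.1
    top_n: int = 20
    min_out_of_scope_counts: float = 2
    n_iterations: int = 100_000
    skew_formula: str = "sqrt"
    seed: int | None = None
    peptide_columns: dict = field(default_factory=dict)
    site_columns: dict = field(default_factory=dict)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text(encoding="utf-8")) or {}
        known = {f.name for f in fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise InkaError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def to_dict(self) -> dict:
        return {f.name: getattr(self, f.name) for f in fields(self)}
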