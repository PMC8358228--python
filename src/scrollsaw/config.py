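"""Analysis configuration: taxonomic groups, decision thresholds, model
parameters, seeds. One object drives every pipeline stage; defaults follow
the study design the pipeline implements (13 eukaryote-wide taxonomic
groups; dual branch-support thresholds 80/95; a 20-bit profile margin;
minimal-pair count 2 in the pan-eukaryotic mode, 1 in taxon-specific runs).
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import yaml

__all__ = ["DEFAULT_GROUPS", "AnalysisConfig"]

DEFAULT_GROUPS = [
    "Holozoa", "Holomycota", "Apusomonadida", "Breviatea", "Amoebozoa",
    "Malawimonadida", "Planomonadida", "Discoba", "Metamonada",
    "Archaeplastida", "Cryptista", "Haptista", "SAR",
]


@dataclass
class AnalysisConfig:
    groups: list[str] = field(default_factory=lambda: list(DEFAULT_GROUPS))
    # branch-support thresholds for tree-based paralog assignment
    sh_alrt_min: float = 80.0
    ufboot_min: float = 95.0
    # profile classification margin (bits)
    hmm_margin_bits: float = 20.0
    # minimal-distance-pair count filter per mode
    min_pair_count_pan: int = 2
    min_pair_count_taxon: int = 1
    # substitution model
    model_alpha: float = 1.0
    model_p_inv: float = 0.0
    model_n_cat: int = 4
    # distance estimation
    d_max: float = 10.0
    min_overlap: int = 30
    seed: int = 0

    def __post_init__(self):
        if not self.groups or len(set(self.groups)) != len(self.groups):
            raise ValueError("group list must be non-empty and unique")
        if not (0 <= self.sh_alrt_min <= 100 and 0 <= self.ufboot_min <= 100):
            raise ValueError("support thresholds must lie in [0, 100]")
        if self.hmm_margin_bits < 0:
            raise ValueError("margin threshold must be >= 0")
        if self.min_pair_count_pan < 1 or self.min_pair_count_taxon < 1:
            raise ValueError("pair-count thresholds must be >= 1")

    def build_model(self):
        from .evomodel import build_wag

        return build_wag(alpha=self.model_alpha, n_cat=self.model_n_cat,
                         p_inv=self.model_p_inv)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def dump(self) -> str:
        return yaml.safe_dump(self.to_dict(), sort_keys=False)

    @classmethod
    def load(cls, source) -> "AnalysisConfig":
        if hasattr(source, "read"):
            data = yaml.safe_load(source.read())
        else:
            with open(source) as fh:
                data = yaml.safe_load(fh)
        return cls(**(data or {}))
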