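"""Pipeline configuration: every mapping/synteny threshold as a named,
defaulted, range-checked key, YAML round-trippable. The defaults are the
study settings the pipeline targets (grouping at LOD 6 / rf 0.35, ripple
window 4, 90% locus call rate, MAF 0.05, Bonferroni at 5%, 5% synteny
order-mismatch tolerance, 20 cM gap threshold, 3 conflict-resolution
rounds)."""

from __future__ import annotations

from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml


@dataclass
class PipelineConfig:
    # marker QC
    call_rate: float = 0.90
    max_indiv_missing: float = 0.50
    maf: float = 0.05
    alpha: float = 0.05
    # linkage mapping
    min_lod: float = 6.0
    max_rf: float = 0.35
    ripple_window: int = 4
    mapping_function: str = "kosambi"
    gap_cM: float = 20.0
    xo_z: float = 3.0
    sex_maps: bool = True
    # consensus
    rounds: int = 3
    epsilon: float = 0.01
    # synteny
    tolerance_frac: float = 0.05
    min_block: int = 2
    min_evalue: float = 1e-10
    min_bitscore_margin: float = 0.1
    cluster_gap_cM: float = 1.0
    # misc
    seed: int = 0
    paths: dict = field(default_factory=dict)

    def __post_init__(self):
        fracs = {
            "call_rate": self.call_rate, "max_indiv_missing": self.max_indiv_missing,
            "maf": self.maf, "alpha": self.alpha, "tolerance_frac": self.tolerance_frac,
            "min_bitscore_margin": self.min_bitscore_margin,
        }
        for name, v in fracs.items():
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {v}")
        if not 0.0 <= self.max_rf <= 0.5:
            raise ValueError(f"max_rf must lie in [0, 0.5], got {self.max_rf}")
        if self.min_lod < 0:
            raise ValueError("min_lod must be >= 0")
        if self.ripple_window < 2:
            raise ValueError("ripple_window must be >= 2")
        if self.mapping_function not in ("kosambi", "haldane"):
            raise ValueError(f"unknown mapping function {self.mapping_function!r}")
        if self.gap_cM <= 0 or self.epsilon <= 0:
            raise ValueError("gap_cM and epsilon must be positive")
        if self.rounds < 0 or self.min_block < 1:
            raise ValueError("rounds must be >= 0 and min_block >= 1")

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self), sort_keys=True))

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        return cls(**data)
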