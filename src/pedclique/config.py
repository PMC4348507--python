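"""Pipeline configuration: every tunable threshold in one place.

Defaults are the method's published operating points: clique edge-weight /
affinity thresholds 0.85 / 0.9, PO informative / assignment cuts 0.25 /
0.75, a 2/3 majority for clique voting, and LD-merge gates of 0.99 maximum
genotype probability, 0.99 heterozygote concordance and 1% MAF.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .simulate import SimConfig


@dataclass
class PipelineConfig:
    # HMM
    eps: float = 0.005
    ibd_threshold: float = 0.5
    min_segment_markers: int = 10
    # clique partition
    w_min: float = 0.85
    a_min: float = 0.9
    # parental origin
    po_informative_cut: float = 0.25
    po_assign_cut: float = 0.75
    po_thin: int = 5
    # imputation
    majority_fraction: float = 2.0 / 3.0
    # LD merge
    ld_min_prob: float = 0.99
    ld_min_het_concordance: float = 0.99
    ld_min_maf: float = 0.01
    # framework QC
    qc_max_mendel: int = 5
    qc_hwe_threshold: float = 1e-3
    qc_min_call_rate: float = 0.95
    qc_min_maf: float = 0.05
    # cross validation
    cv_thin: int = 5
    # misc
    seed: int = 0
    surrogate_min_phi: float = 1.0 / 64.0
    sim: SimConfig = field(default_factory=SimConfig)

    def __post_init__(self) -> None:
        for name in ("ibd_threshold", "w_min", "a_min", "po_informative_cut",
                     "po_assign_cut", "majority_fraction", "ld_min_prob",
                     "ld_min_het_concordance", "ld_min_maf", "qc_min_call_rate",
                     "qc_min_maf"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must be within [0, 1]")
        if isinstance(self.sim, dict):
            self.sim = SimConfig(**self.sim)

    def to_yaml(self, path: str | Path) -> None:
        data = dataclasses.asdict(self)
        data["sim"]["framework_af"] = list(data["sim"]["framework_af"])
        data["sim"]["sequence_af"] = list(data["sim"]["sequence_af"])
        Path(path).write_text(yaml.safe_dump(data, sort_keys=True))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text())
        sim = data.pop("sim", {})
        for k in ("framework_af", "sequence_af"):
            if k in sim:
                sim[k] = tuple(sim[k])
        return cls(sim=SimConfig(**sim), **data)
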