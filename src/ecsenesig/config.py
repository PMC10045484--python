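"""Pipeline configuration: every stage threshold in one serializable object.

A copy of the exact configuration (plus its hash) is embedded in every
output directory so that runs are reproducible and auditable.  One global
seed fans out to per-stage seeds via name hashing (see
:func:`ecsenesig.simulate.stage_seed`) so stages can be re-run in isolation.
"""

from __future__ import annotations

import hashlib
from dataclasses import asdict, dataclass, field

import yaml

from .preprocess import QCThresholds

__all__ = ["PipelineConfig"]


@dataclass
class PipelineConfig:
    qc: QCThresholds = field(default_factory=QCThresholds)
    min_pct: float = 0.25
    min_logfc: float = 0.25
    logfc_inclusive: bool = False
    max_fdr: float = 0.05
    consensus_threshold: float = 0.2
    min_support: int = 1
    min_cells_expr: int = 10
    kernel: str = "ecdf"
    method: str = "maxdiff"
    tau: float = 1.0
    endothelial_type: str = "TEC"
    zscore_expression: bool = True
    cox_ties: str = "breslow"
    seed: int = 0

    def __post_init__(self) -> None:
        if isinstance(self.qc, dict):
            self.qc = QCThresholds(**self.qc)
        for name, lo, hi in (("min_pct", 0, 1), ("max_fdr", 0, 1),
                             ("consensus_threshold", 0, 1)):
            v = getattr(self, name)
            if not (lo <= v <= hi):
                raise ValueError(f"{name} must be in [{lo}, {hi}], got {v}")
        if self.min_support < 1:
            raise ValueError("min_support must be >= 1")
        if self.kernel not in ("ecdf", "gaussian"):
            raise ValueError(f"unknown kernel {self.kernel!r}")
        if self.method not in ("maxdiff", "maxdev"):
            raise ValueError(f"unknown method {self.method!r}")
        if self.cox_ties not in ("breslow", "efron"):
            raise ValueError(f"unknown ties method {self.cox_ties!r}")

    def to_yaml(self) -> str:
        return yaml.safe_dump(asdict(self), sort_keys=True)

    @classmethod
    def from_yaml(cls, text: str) -> "PipelineConfig":
        data = yaml.safe_load(text) or {}
        return cls(**data)

    @classmethod
    def from_file(cls, path: str) -> "PipelineConfig":
        with open(path) as fh:
            return cls.from_yaml(fh.read())

    def config_hash(self) -> str:
        return hashlib.sha256(self.to_yaml().encode()).hexdigest()[:16]

    def write(self, path: str) -> None:
        with open(path, "w") as fh:
            fh.write(f"# config_hash: {self.config_hash()}\n")
            fh.write(self.to_yaml())
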