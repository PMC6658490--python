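"""Pipeline configuration: every tunable threshold in one serialisable place.

The defaults are the analysis conditions of the pipeline: 95% identity for
C-terminal clustering and TPM aggregation, poly-alanine minimum run of 4,
GPGX wildcard alphabet {G, S, A, Q}, periodicity scan from 10 residues with
a 2-point harmonic-suppression window, a 500-base CTD trim window, and GOR
decision constants of 0. A YAML snapshot is written alongside every
pipeline run for provenance.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml


@dataclass
class PipelineConfig:
    identity_threshold: float = 95.0
    min_hit_identity: float = 40.0
    min_hit_length: int = 60
    polya_min_run: int = 4
    gpgx_alphabet: str = "GSAQ"
    masp4_gpgpq_min: float = 20.0
    min_period: int = 10
    max_period: int | None = None
    harmonic_window: float = 2.0
    trim_window: int = 500
    gor_decision_constants: dict[str, float] = field(
        default_factory=lambda: {"helix": 0.0, "sheet": 0.0, "turn": 0.0, "coil": 0.0}
    )
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 < self.identity_threshold <= 100.0:
            raise ValueError("identity_threshold must be in (0, 100]")
        if self.polya_min_run < 2:
            raise ValueError("polya_min_run must be >= 2")
        if self.min_period < 2:
            raise ValueError("min_period must be >= 2")
        if self.trim_window < 1:
            raise ValueError("trim_window must be >= 1")
        if self.harmonic_window < 0:
            raise ValueError("harmonic_window must be >= 0")

    def to_yaml(self, path: str | Path) -> Path:
        path = Path(path)
        path.write_text(yaml.safe_dump(asdict(self), sort_keys=True))
        return path

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        return cls(**data)

    def merged(self, **overrides) -> "PipelineConfig":
        data = asdict(self)
        data.update({k: v for k, v in overrides.items() if v is not None})
        return PipelineConfig(**data)
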