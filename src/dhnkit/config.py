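"""Pipeline configuration: every tunable threshold in one serializable place."""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field


@dataclass
class PipelineConfig:
    # segment annotation
    max_mismatch: int = 4
    relaxed_max_mismatch: int = 8
    dehydrin_mode: str = "extended"
    # duplication calling
    tandem_max_gap: int = 50_000
    # ecotype clustering
    cluster_threshold: float = 0.95
    cluster_min_size: int = 3
    # promoter scanning
    promoter_upstream: int = 500
    promoter_downstream: int = 200
    pwm_threshold: float = 9.0
    pwm_pseudocount: float = 0.01
    # statistics
    bh_alpha: float = 0.05
    n_permutations: int = 999
    climate_cutoff: float = 2.5
    climate_anchor: str = "bio11"
    # randomness
    seed: int = 0

    def __post_init__(self) -> None:
        checks = [
            (self.max_mismatch >= 0, "max_mismatch >= 0"),
            (self.relaxed_max_mismatch >= self.max_mismatch,
             "relaxed_max_mismatch >= max_mismatch"),
            (self.tandem_max_gap >= 0, "tandem_max_gap >= 0"),
            (0 < self.cluster_threshold <= 1, "cluster_threshold in (0, 1]"),
            (self.cluster_min_size >= 1, "cluster_min_size >= 1"),
            (0 < self.bh_alpha < 1, "bh_alpha in (0, 1)"),
            (self.n_permutations >= 1, "n_permutations >= 1"),
            (self.climate_cutoff > 0, "climate_cutoff > 0"),
        ]
        for ok, what in checks:
            if not ok:
                raise ValueError(f"config out of range: require {what}")

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=2, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "PipelineConfig":
        return cls(**json.loads(text))

    @property
    def digest(self) -> str:
        return hashlib.sha256(self.to_json().encode()).hexdigest()[:16]
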