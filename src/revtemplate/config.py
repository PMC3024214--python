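"""Run configuration: one flat, JSON-serializable record of every tunable."""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass


@dataclass
class RunConfig:
    # template generation / matching
    max_pair_dist: float = 5.0
    max_hydrophobic: int = 1
    rmsd_tol: float = 2.0
    ca_prefilter_tol: float = 2.0
    # local-similarity scoring
    radius: float = 10.0
    pair_dist: float = 3.0
    identical_weight: float = 4.0
    similar_weight: float = 1.0
    calibration_path: str = ""
    # annotation
    contact_cutoff: float = 4.0
    top_k: int = 4
    # novelty
    ssg_threshold: float = 5.0
    period_boundary: str = "2005-07-01"
    # run control
    seed: int = 0
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        positive = {
            "max_pair_dist": self.max_pair_dist,
            "rmsd_tol": self.rmsd_tol,
            "ca_prefilter_tol": self.ca_prefilter_tol,
            "radius": self.radius,
            "pair_dist": self.pair_dist,
            "contact_cutoff": self.contact_cutoff,
            "ssg_threshold": self.ssg_threshold,
        }
        for name, value in positive.items():
            if value <= 0:
                raise ValueError(f"{name} must be positive, got {value}")
        if self.max_hydrophobic < 0 or self.top_k < 1:
            raise ValueError("max_hydrophobic must be >= 0 and top_k >= 1")

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), indent=2, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "RunConfig":
        return cls(**json.loads(text))

    def with_overrides(self, **kwargs) -> "RunConfig":
        return dataclasses.replace(self, **{k: v for k, v in kwargs.items() if v is not None})

    @property
    def hash(self) -> str:
        return hashlib.sha1(self.to_json().encode()).hexdigest()[:12]
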