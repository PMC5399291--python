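"""Run configuration: thresholds, MCMC settings, transforms, provenance."""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field

from .nmixture import NmixtureSpec
from .phylo import BVSConfig
from .synthetic import ComparativeSimConfig, CountSimConfig


@dataclass
class RunConfig:
    """End-to-end pipeline settings.

    ``taxa`` lists the synthetic taxa to simulate and fit; each gets its own
    derived seed. Threshold constants are the indicator classification cuts
    (0.75 / 0.25) and the CRI level (0.95).
    """

    seed: int = 0
    n_taxa: int = 4
    variant: str = "flyway"
    count_sim: CountSimConfig = field(default_factory=CountSimConfig)
    comparative_sim: ComparativeSimConfig = field(
        default_factory=ComparativeSimConfig
    )
    nmixture: NmixtureSpec = field(default_factory=NmixtureSpec)
    bvs: BVSConfig = field(default_factory=BVSConfig)
    important_threshold: float = 0.75
    unimportant_threshold: float = 0.25
    cri_level: float = 0.95
    percent_transform: str = "linear"

    def __post_init__(self) -> None:
        for name in ("important_threshold", "unimportant_threshold", "cri_level"):
            v = getattr(self, name)
            if not 0 < v < 1:
                raise ValueError(f"{name} must lie in (0, 1), got {v}")

    def to_dict(self) -> dict:
        return asdict(self)

    def config_hash(self) -> str:
        payload = json.dumps(self.to_dict(), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:12]

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        for key, sub in (
            ("count_sim", CountSimConfig),
            ("comparative_sim", ComparativeSimConfig),
            ("nmixture", NmixtureSpec),
            ("bvs", BVSConfig),
        ):
            if key in d and isinstance(d[key], dict):
                sd = dict(d[key])
                for k, v in sd.items():
                    if isinstance(v, list):
                        sd[k] = tuple(v)
                d[key] = sub(**sd)
        return cls(**d)
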