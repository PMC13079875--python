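"""Run configuration, seed derivation, and config hashing.

One master seed drives the whole pipeline; every random stage derives its
own seed from it by hashing ``"<master>:<stage-name>"``, so stages can be
rerun in isolation and still reproduce.
"""

from __future__ import annotations

import hashlib
from dataclasses import asdict, dataclass, field

import yaml

from .dots import DotSamplingRule
from .materials import StimulusDesign
from .observers import ObserverModel


def derive_seed(master_seed: int, stage: str) -> int:
    """Stable per-stage seed derived from the master seed (< 2**31)."""
    digest = hashlib.sha256(f"{master_seed}:{stage}".encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2**31)


@dataclass
class AnalysisParams:
    n_perm: int = 999
    n_factors: int = 2
    k_clusters: int = 5
    variance_threshold: float = 0.80
    run_threshold: int = 14
    rt_threshold_ms: float = 350.0
    rt_window: int = 10
    n_resample_seeds: int = 100
    n_observers: int = 20
    trials_per_observer: int = 300
    mask_grid: int = 128
    dot_radius: int = 2
    flow_grid: int = 32


@dataclass
class RunConfig:
    design: StimulusDesign = field(default_factory=StimulusDesign)
    observer: ObserverModel = field(default_factory=ObserverModel)
    dot_rule: DotSamplingRule = field(default_factory=DotSamplingRule)
    analysis: AnalysisParams = field(default_factory=AnalysisParams)
    master_seed: int = 0
    log_level: str = "INFO"

    def seed_for(self, stage: str) -> int:
        return derive_seed(self.master_seed, stage)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["design"]["exemplars_per_class"] = dict(d["design"]["exemplars_per_class"])
        d["design"]["views_per_class"] = dict(d["design"]["views_per_class"])
        d["observer"]["archetypes"] = {
            k: list(map(float, v)) for k, v in d["observer"]["archetypes"].items()
        }
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        obs = dict(d.get("observer", {}))
        if "archetypes" in obs:
            obs["archetypes"] = {k: tuple(v) for k, v in obs["archetypes"].items()}
        return cls(
            design=StimulusDesign(**d.get("design", {})),
            observer=ObserverModel(**obs),
            dot_rule=DotSamplingRule(**d.get("dot_rule", {})),
            analysis=AnalysisParams(**d.get("analysis", {})),
            master_seed=int(d.get("master_seed", 0)),
            log_level=str(d.get("log_level", "INFO")),
        )

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))

    def config_hash(self) -> str:
        text = yaml.safe_dump(self.to_dict(), sort_keys=True)
        return hashlib.sha256(text.encode()).hexdigest()[:12]
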