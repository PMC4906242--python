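"""Run configuration: validated, fully serializable, hashable.

Every stage reads its parameters from one ``RunConfig`` so a run can be
reproduced from the config file alone; the effective config (defaults plus
overrides) and its hash are written next to the outputs.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import yaml
from pydantic import BaseModel, model_validator

from .protocol import StimProtocol
from .synthetic.calcium import CaParams
from .synthetic.experiment import HierarchyDesign
from .synthetic.kinetics import KineticParams
from .synthetic.render import RenderParams

__all__ = ["SegmentationConfig", "TraceConfig", "StatsConfig", "RunConfig", "config_hash"]


class SegmentationConfig(BaseModel):
    threshold: float = 1.0
    min_rel_df: float = 0.05
    dilation_radius: int = 1
    size_gate: tuple[int, int] = (8, 150)
    peak_window: int = 3
    smooth_sigma: float = 0.0
    realign: bool = True
    max_shift: int = 5
    # optional per-experiment threshold overrides; held within 10% of each
    # other because one threshold must serve all conditions of an experiment
    experiment_thresholds: dict[str, float] | None = None

    model_config = {"frozen": True}

    @model_validator(mode="after")
    def _check(self) -> "SegmentationConfig":
        if self.threshold <= 0:
            raise ValueError("threshold must be positive")
        if self.experiment_thresholds:
            vals = list(self.experiment_thresholds.values())
            if min(vals) <= 0:
                raise ValueError("experiment thresholds must be positive")
            if max(vals) / min(vals) > 1.10 + 1e-12:
                raise ValueError(
                    "experiment thresholds vary by more than 10%; the threshold "
                    "may only be minimally adjusted across experiments"
                )
        return self


class TraceConfig(BaseModel):
    drift_tol: float = 0.10
    n_norm_frames: int = 5
    endo_offset_frames: int = 9
    n_points: int = 6
    baf_mode: bool = True  # False: approximate exo rate from the no-Baf rise

    model_config = {"frozen": True}


class StatsConfig(BaseModel):
    use_prep: bool = True
    df_method: str = "satterthwaite"  # or "z" / "between_field"
    outcome: str = "exo_rate"
    holm: bool = False

    model_config = {"frozen": True}


class RunConfig(BaseModel):
    seed: int = 0
    protocol: StimProtocol = StimProtocol()
    kinetics: KineticParams = KineticParams()
    ca: CaParams = CaParams()
    hierarchy: HierarchyDesign = HierarchyDesign()
    render: RenderParams = RenderParams()
    segmentation: SegmentationConfig = SegmentationConfig()
    traces: TraceConfig = TraceConfig()
    stats: StatsConfig = StatsConfig()

    model_config = {"frozen": True}

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            payload = yaml.safe_load(fh) or {}
        return cls.model_validate(payload)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(json.loads(self.model_dump_json()), fh, sort_keys=True)


def config_hash(config: RunConfig) -> str:
    canon = json.dumps(json.loads(config.model_dump_json()), sort_keys=True)
    return hashlib.sha256(canon.encode()).hexdigest()[:16]
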