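"""Run configuration: validated blocks for schedule, denoiser, training,
sampler, and the synthetic-data simulator, loadable from YAML."""

from __future__ import annotations

from pathlib import Path
from typing import Optional

import yaml
from pydantic import BaseModel, Field, model_validator

from .nn.unet import DenoiserSpec
from .schedule import NoiseSchedule, build_schedule
from .synthetic import DegradeSpec, PhantomSpec
from .training import TrainSpec

__all__ = ["RunConfig", "load_config"]


class ScheduleConfig(BaseModel):
    T: int = 15
    p: float = 0.3
    gamma: float = 2.0
    kappa: float = 0.04
    beta_T: float = 0.9999

    def build(self) -> NoiseSchedule:
        return build_schedule(self.T, self.p, self.gamma, self.kappa, self.beta_T)


class DenoiserConfig(BaseModel):
    base_channels: int = 32
    depth: int = 3
    use_windowed_attention: bool = True
    window_size: int = 4
    time_embed_dim: int = 64
    seed: int = 0

    def build(self) -> DenoiserSpec:
        return DenoiserSpec(**self.model_dump())


class TrainConfig(BaseModel):
    lambda_fidelity: float = 10.0
    batch_size: int = 8
    total_steps: int = 2000
    warmup_steps: int = 200
    lr_init: float = 1e-3
    lr_floor: float = 0.0
    seed: int = 0
    checkpoint_every: int = 0
    log_every: int = 1

    def build(self) -> TrainSpec:
        return TrainSpec(**self.model_dump())


class SamplerConfig(BaseModel):
    steps: int = Field(4, description="number of reverse transitions")
    seed: int = 0


class SimulateConfig(BaseModel):
    n: int = 16
    size: int = 64
    n_ellipses: int = 6
    noise_sd: float = 0.01
    mask_radius_frac: float = 0.45
    factor_y: int = 4
    factor_x: int = 4
    antialias: bool = True
    seed: int = 0

    def phantom_spec(self) -> PhantomSpec:
        return PhantomSpec(
            size=self.size, n_ellipses=self.n_ellipses, noise_sd=self.noise_sd,
            mask_radius_frac=self.mask_radius_frac, seed=self.seed,
        )

    def degrade_spec(self) -> DegradeSpec:
        return DegradeSpec(factor_y=self.factor_y, factor_x=self.factor_x,
                           antialias=self.antialias)


class RunConfig(BaseModel):
    schedule: ScheduleConfig = ScheduleConfig()
    denoiser: DenoiserConfig = DenoiserConfig()
    train: TrainConfig = TrainConfig()
    sampler: SamplerConfig = SamplerConfig()
    simulate: SimulateConfig = SimulateConfig()
    workdir: str = "."
    log_level: str = "INFO"

    @model_validator(mode="after")
    def _cross_validate(self):
        # every block must realize against its owning module before any work
        self.schedule.build()
        self.denoiser.build()
        self.train.build()
        if not 1 <= self.sampler.steps <= self.schedule.T:
            raise ValueError(
                f"sampler.steps ({self.sampler.steps}) must lie in [1, T={self.schedule.T}]"
            )
        return self


def load_config(path: Optional[Path] = None, overrides: Optional[dict] = None) -> RunConfig:
    """Load YAML config (missing file/None = defaults) with flat overrides
    like ``{"train.total_steps": 100}``."""
    data: dict = {}
    if path is not None:
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
    for key, val in (overrides or {}).items():
        parts = key.split(".")
        node = data
        for part in parts[:-1]:
            node = node.setdefault(part, {})
        node[parts[-1]] = val
    return RunConfig(**data)
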