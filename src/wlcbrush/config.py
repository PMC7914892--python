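"""Validated run configuration (pydantic schema + YAML round trip).

A run is fully specified by the chain (N = L/a, Nm), the brush coupling and
optional walls / azo joint, the z x orientation grid resolutions, the
self-consistent schedule, and the sampler schedule including the base seed.
Unknown keys and constraint violations are rejected with the offending key
path in the message.
"""

from __future__ import annotations

import math
from pathlib import Path
from typing import List, Literal, Optional

import yaml
from pydantic import BaseModel, ConfigDict, Field, model_validator

from .chain import ChainParams
from .field import FieldGrid, build_orientation_grid
from .sampler import AzoConfig, BrushConfig

__all__ = ["RunConfig", "load_config", "save_config"]


class _Section(BaseModel):
    model_config = ConfigDict(extra="forbid", validate_assignment=True)


class ChainSection(_Section):
    N: float = Field(30.0, gt=0, description="contour length in Kuhn lengths")
    Nm: int = Field(100, ge=2, description="number of bonds")


class AzoSection(_Section):
    f: float = Field(..., gt=0, lt=1)
    state: Literal["trans", "cis"] = "trans"
    alpha_trans: float = Field(math.pi, gt=0)
    alpha_cis: float = Field(math.pi / 3, gt=0)


class BrushSection(_Section):
    sigma_eff: float = Field(2.0, ge=0,
                             description="effective grafting density 2daσ")
    compression_H: Optional[float] = Field(None, gt=0)
    azo: Optional[AzoSection] = None
    opposing_D: Optional[float] = Field(None, gt=0)


class GridSection(_Section):
    nz: int = Field(120, ge=4)
    z_max: Optional[float] = Field(None, gt=0,
                                   description="default 1.2 L")
    ntheta: int = Field(12, ge=2)
    nphi: int = Field(12, ge=4)


class ScfSection(_Section):
    m_per_iter: int = Field(20_000, ge=1)
    m_start: Optional[int] = Field(None, ge=1,
                                   description="initial M, doubled per "
                                               "iteration up to the cap")
    lam: float = Field(0.2, gt=0, le=1)
    tol: float = Field(1e-3, gt=0)
    max_iter: int = Field(60, ge=1)
    n_avg: int = Field(1, ge=1,
                       description="report density merged over the last "
                                   "n_avg iterations")


class SamplerSection(_Section):
    burn_in: int = Field(100, ge=0, description="sweeps (1 sweep = Nm pivots)")
    burn_in_warm: Optional[int] = Field(None, ge=0)
    stride: float = Field(1.0, gt=0, description="sweeps between records")
    max_angle: float = Field(math.pi / 2, gt=0, le=math.pi)
    streams: int = Field(4, ge=1)
    seed: int = Field(0, ge=0)


class OutputSection(_Section):
    directory: str = "wlcbrush_out"
    formats: List[str] = ["csv", "json"]


class RunConfig(_Section):
    chain: ChainSection = ChainSection()
    brush: BrushSection = BrushSection()
    grids: GridSection = GridSection()
    scf: ScfSection = ScfSection()
    sampler: SamplerSection = SamplerSection()
    output: OutputSection = OutputSection()

    @model_validator(mode="after")
    def _cross_checks(self):
        if (self.brush.compression_H is not None
                and self.brush.compression_H > 10 * self.chain.N):
            raise ValueError("compression_H far above the chain length")
        return self

    # -- factories ---------------------------------------------------------
    def chain_params(self) -> ChainParams:
        return ChainParams(N=self.chain.N, Nm=self.chain.Nm)

    def brush_config(self) -> BrushConfig:
        azo = None
        if self.brush.azo is not None:
            azo = AzoConfig(f=self.brush.azo.f, state=self.brush.azo.state,
                            alpha_trans=self.brush.azo.alpha_trans,
                            alpha_cis=self.brush.azo.alpha_cis)
        return BrushConfig(sigma_eff=self.brush.sigma_eff,
                           compression_H=self.brush.compression_H,
                           azo=azo, opposing_D=self.brush.opposing_D)

    def field_grid(self) -> FieldGrid:
        z_max = self.grids.z_max
        if z_max is None:
            z_max = 1.2 * self.chain.N
        if self.brush.opposing_D is not None:
            z_max = self.brush.opposing_D
        if z_max < self.chain.N and self.brush.opposing_D is None:
            raise ValueError("grids.z_max must cover the contour length L")
        ogrid = build_orientation_grid(self.grids.ntheta, self.grids.nphi)
        return FieldGrid.zeros(self.grids.nz, z_max, ogrid)

    def schedule(self) -> dict:
        sched = {
            "m_per_iter": self.scf.m_per_iter,
            "lam": self.scf.lam,
            "tol": self.scf.tol,
            "max_iter": self.scf.max_iter,
            "n_avg": self.scf.n_avg,
            "streams": self.sampler.streams,
            "burn_in": self.sampler.burn_in,
            "stride": self.sampler.stride,
            "max_angle": self.sampler.max_angle,
        }
        if self.scf.m_start is not None:
            sched["m_start"] = self.scf.m_start
        if self.sampler.burn_in_warm is not None:
            sched["burn_in_warm"] = self.sampler.burn_in_warm
        return sched


_FLAT_KEYS = {"N": ("chain", "N"), "Nm": ("chain", "Nm"),
              "sigma_eff": ("brush", "sigma_eff"),
              "seed": ("sampler", "seed")}


def load_config(path) -> RunConfig:
    """Load a YAML config; flat convenience keys (N, Nm, sigma_eff, seed)
    are mapped into their sections."""
    raw = yaml.safe_load(Path(path).read_text()) or {}
    if not isinstance(raw, dict):
        raise ValueError(f"config root must be a mapping, got {type(raw)}")
    for key, (sec, name) in _FLAT_KEYS.items():
        if key in raw:
            raw.setdefault(sec, {})[name] = raw.pop(key)
    return RunConfig.model_validate(raw)


def save_config(config: RunConfig, path) -> None:
    Path(path).write_text(
        yaml.safe_dump(config.model_dump(mode="json"), sort_keys=False))
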