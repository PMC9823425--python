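"""Run configuration: a validated, YAML-round-trippable schema.

Unknown keys are rejected so that a typo in a config file fails loudly
instead of silently running the defaults.
"""

from __future__ import annotations

from typing import List, Optional, Tuple

import yaml
from pydantic import BaseModel, ConfigDict, field_validator

from . import scenario as sc

__all__ = ["RunConfig", "load_config", "save_config"]


class _Strict(BaseModel):
    model_config = ConfigDict(extra="forbid")


class LayerConfig(_Strict):
    center: Tuple[float, float, float]
    semi_axes: Tuple[float, float, float]
    eps_r: float
    sigma: float


class PhantomConfig(_Strict):
    layers: List[LayerConfig]
    coupling_eps_r: float = 20.0
    coupling_sigma: float = 0.0
    frequency: float = 1.0e9
    domain: Tuple[float, float, float] = (0.14, 0.14, 0.14)


class StrokeConfig(_Strict):
    center: Tuple[float, float, float]
    semi_axes: Tuple[float, float, float]
    eps_r: float = 64.41
    sigma: float = 1.58


class AcquisitionConfig(_Strict):
    n_antennas: int = 8
    ring_radius: float = 0.060
    ring_center: Tuple[float, float, float] = (0.07, 0.07, 0.07)
    source_model: str = "dipole"
    data_h: float = 0.004
    inversion_h: float = 0.005
    dipole_moment: Tuple[float, float, float] = (0.0, 0.0, 1.0)
    port_ra: float = 0.001
    port_rb: float = 0.004

    @field_validator("source_model")
    @classmethod
    def _check_model(cls, v):
        if v not in ("dipole", "coax_port"):
            raise ValueError("source_model must be 'dipole' or 'coax_port'")
        return v


class InversionConfig(_Strict):
    variant: str = "edge"           # or "standard"
    eval_mode: Optional[str] = None
    iterations: int = 100
    doi: str = "phantom"            # or "half"
    solver: str = "auto"
    tolerance: float = 1.0e-12
    checkpoint_every: int = 10

    @field_validator("variant")
    @classmethod
    def _check_variant(cls, v):
        if v not in ("edge", "standard"):
            raise ValueError("variant must be 'edge' or 'standard'")
        return v


class RunConfig(_Strict):
    """Everything one simulate/invert run needs."""

    phantom: PhantomConfig
    stroke: Optional[StrokeConfig] = None
    acquisition: AcquisitionConfig = AcquisitionConfig()
    inversion: InversionConfig = InversionConfig()
    seed: Optional[int] = None
    snr_db: Optional[float] = None
    background: str = "phantom"
    allow_inverse_crime: bool = False

    # -- conversion to the runtime dataclasses -------------------------
    def phantom_spec(self):
        return sc.PhantomSpec(
            layers=[sc.Layer(tuple(l.center), tuple(l.semi_axes), l.eps_r, l.sigma)
                    for l in self.phantom.layers],
            coupling_eps_r=self.phantom.coupling_eps_r,
            coupling_sigma=self.phantom.coupling_sigma,
            frequency=self.phantom.frequency,
            domain=tuple(self.phantom.domain),
        )

    def stroke_spec(self):
        if self.stroke is None:
            return None
        return sc.StrokeSpec(
            center=tuple(self.stroke.center),
            semi_axes=tuple(self.stroke.semi_axes),
            eps_r=self.stroke.eps_r,
            sigma=self.stroke.sigma,
        )

    def acquisition_spec(self):
        a = self.acquisition
        return sc.AcquisitionSpec(
            n_antennas=a.n_antennas,
            ring_radius=a.ring_radius,
            ring_center=tuple(a.ring_center),
            source_model=a.source_model,
            data_h=a.data_h,
            inversion_h=a.inversion_h,
            dipole_moment=tuple(a.dipole_moment),
            port_ra=a.port_ra,
            port_rb=a.port_rb,
        )


def default_run_config():
    head = LayerConfig(center=(0.07, 0.07, 0.07), semi_axes=(0.05,) * 3,
                       eps_r=45.37, sigma=0.77)
    stroke = StrokeConfig(center=(0.085, 0.07, 0.07),
                          semi_axes=(0.015, 0.012, 0.012))
    return RunConfig(phantom=PhantomConfig(layers=[head]), stroke=stroke)


def load_config(path):
    with open(path) as f:
        raw = yaml.safe_load(f)
    return RunConfig.model_validate(raw)


def save_config(config: RunConfig, path):
    with open(path, "w") as f:
        yaml.safe_dump(config.model_dump(), f, sort_keys=False)
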