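"""Pipeline configuration: a validated YAML/JSON document.

The configuration gathers everything a virtual-surgery study needs —
tree geometry, stenosis, inlet waveform, fluid, Windkessel boundary
conditions with optional tuning targets, and solver settings. Unknown
keys are rejected, all physical values must be positive, and every
default applied during loading is logged.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path
from typing import Literal, Optional

import yaml
from pydantic import BaseModel, ConfigDict, Field, ValidationError, model_validator

from .units import mmhg_to_pa

__all__ = ["PipelineConfig", "ConfigError", "load_config", "save_config"]

log = logging.getLogger("pulmoflow")


class ConfigError(ValueError):
    """Raised for unreadable, invalid or unknown configuration content."""


class _Section(BaseModel):
    model_config = ConfigDict(extra="forbid", frozen=True)


class TreeConfig(_Section):
    """Idealized tree geometry (SI units)."""

    generations: int = Field(default=5, ge=2)
    left_outlets: int = Field(default=31, ge=1)
    right_outlets: int = Field(default=29, ge=1)
    root_diameter: float = Field(default=0.030337, gt=0)  # ≙ 722.88 mm² inlet
    # 0.56 per generation takes a 30 mm MPA to ~3 mm outlets over 4 steps,
    # giving ~420 mm² total outlet area — segmental-level calibers
    taper: float = Field(default=0.44, gt=0, lt=1)
    length_ratio: float = Field(default=3.0, gt=0)


class StenosisConfig(_Section):
    """Focal stenosis placement: segment id and fractional reduction."""

    segment_id: str = "RPA"
    diameter_reduction: float = Field(default=0.438, gt=0, lt=1)


class WaveformConfig(_Section):
    """Half-sine-systole inlet waveform parameters."""

    peak_velocity: float = Field(default=0.5732, gt=0)
    period: float = Field(default=0.925, gt=0)
    systole_end: float = Field(default=0.380, gt=0)
    diastolic_fraction: float = Field(default=0.05, ge=0, lt=1)
    n_samples: int = Field(default=1000, ge=4)
    inlet_area: Optional[float] = Field(default=None, gt=0)

    @model_validator(mode="after")
    def _phase_order(self):
        if not (self.systole_end < self.period):
            raise ValueError("systole_end must be smaller than period")
        return self


class FluidConfig(_Section):
    density: float = Field(default=1056.0, gt=0)
    viscosity: float = Field(default=3.5e-3, gt=0)


class WindkesselConfig(_Section):
    """Per-branch resistance totals and the compliance estimate.

    Branch resistances default to magnitudes representative of a
    stenosed-RPA CTEPH case (~10⁸ Pa·s/m³). Compliance is stroke volume
    over pulse pressure unless ``total_compliance`` overrides it.
    """

    left_resistance: float = Field(default=169.29e6, gt=0)
    right_resistance: float = Field(default=677.16e6, gt=0)
    stroke_volume: float = Field(default=8e-5, gt=0)
    pulse_pressure_mmhg: float = Field(default=40.0, gt=0)
    total_compliance: Optional[float] = Field(default=None, gt=0)

    def compliance(self) -> float:
        from .tuning import estimate_compliance

        if self.total_compliance is not None:
            return self.total_compliance
        return estimate_compliance(
            self.stroke_volume, float(mmhg_to_pa(self.pulse_pressure_mmhg))
        )


class TuningConfig(_Section):
    """Resistance-sweep settings; target from the size-ratio curve if unset."""

    enabled: bool = True
    target_flow_ratio: Optional[float] = Field(default=None, gt=0)
    beta: float = Field(default=0.9, gt=0)
    size_ratio_method: Literal["proximal", "outlet_total"] = "proximal"
    tolerance: float = Field(default=0.01, gt=0)
    mode: Literal["transient", "steady"] = "transient"


class SolverConfig(_Section):
    dt: float = Field(default=1e-3, gt=0)
    n_cycles: int = Field(default=3, ge=1)
    kt: float = Field(default=1.52, gt=0)
    tolerance: float = Field(default=1e-10, gt=0)
    maxiter: int = Field(default=200, ge=1)


class PipelineConfig(_Section):
    """Top-level configuration of the virtual-surgery pipeline."""

    tree: TreeConfig = TreeConfig()
    stenosis: Optional[StenosisConfig] = StenosisConfig()
    waveform: WaveformConfig = WaveformConfig()
    fluid: FluidConfig = FluidConfig()
    windkessel: WindkesselConfig = WindkesselConfig()
    tuning: TuningConfig = TuningConfig()
    solver: SolverConfig = SolverConfig()
    output_dir: str = "pulmoflow_out"
    seed: int = 0


def _log_defaults(model: BaseModel, prefix: str = "") -> None:
    for name in type(model).model_fields:
        value = getattr(model, name)
        if name not in model.model_fields_set:
            log.info("config: applied default %s%s = %r", prefix, name, value)
        elif isinstance(value, BaseModel):
            _log_defaults(value, prefix=f"{prefix}{name}.")


def load_config(path: str | Path) -> PipelineConfig:
    """Load and validate a YAML or JSON configuration file.

    Every default applied (key absent from the file) is logged at INFO
    level. Unknown keys and invalid values raise :class:`ConfigError`
    naming the offending key.
    """
    p = Path(path)
    if not p.is_file():
        raise ConfigError(f"configuration file not found: {p}")
    try:
        raw = yaml.safe_load(p.read_text())
    except yaml.YAMLError as exc:
        raise ConfigError(f"cannot parse {p}: {exc}") from exc
    if raw is None:
        raw = {}
    if not isinstance(raw, dict):
        raise ConfigError(f"configuration root must be a mapping, got {type(raw)}")
    try:
        cfg = PipelineConfig.model_validate(raw)
    except ValidationError as exc:
        first = exc.errors()[0]
        loc = ".".join(str(x) for x in first["loc"])
        raise ConfigError(f"invalid configuration key '{loc}': {first['msg']}") from exc
    _log_defaults(cfg)
    return cfg


def save_config(cfg: PipelineConfig, path: str | Path) -> None:
    """Write a configuration back to YAML (or JSON by extension)."""
    p = Path(path)
    data = cfg.model_dump()
    if p.suffix.lower() == ".json":
        p.write_text(json.dumps(data, indent=2) + "\n")
    else:
        p.write_text(yaml.safe_dump(data, sort_keys=False))
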