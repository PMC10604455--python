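"""Schema-validated run configuration (YAML).

The configuration mirrors the model setup: phantom geometry, electrode tip
length, perfusion scenario, solver controls, and either a fixed treatment
(power, duration) or an optimization block.  Unknown keys are rejected;
defaults reproduce the reference setup (480 kHz property table, 20 mL
nodule, 45-60 W, up to 1200 s, VRR target 65 %).
"""

from __future__ import annotations

from pathlib import Path

import yaml
from pydantic import BaseModel, ConfigDict, Field, model_validator

from .geometry import PRESETS

__all__ = ["RunConfig", "load_config", "dump_config", "ConfigError"]


class ConfigError(ValueError):
    pass


class _Strict(BaseModel):
    model_config = ConfigDict(extra="forbid", frozen=True)


class PhantomBlock(_Strict):
    nodule_volume_mL: float = Field(20.0, gt=0)
    nodule_shape: tuple[float, float, float] = (20.0, 15.9, 15.0)
    skin_mm: float = Field(1.0, gt=0)
    fat_mm: float = Field(6.0, gt=0)
    muscle_mm: float = Field(30.0, gt=0)
    thyroid_mm: float = Field(20.0, gt=0)
    domain_mm: tuple[float, float, float] = (120.0, 80.0, 80.0)


class ElectrodeBlock(_Strict):
    tip_length_mm: float = Field(10.0, gt=0)
    outer_diameter_mm: float = Field(1.27, gt=0)
    shaft_length_mm: float = Field(100.0, gt=0)


class SolverBlock(_Strict):
    dt_s: float = Field(1.0, ge=0.25, le=5.0)
    mesh_preset: str = "coarse"
    sigma_retol: float = Field(0.01, ge=0.0)
    perfusion_decay: bool = False
    damage_threshold_D: float = Field(1.0, gt=0)
    rf_frequency_kHz: float = 480.0  # metadata: labels the sigma table

    @model_validator(mode="after")
    def _check_preset(self):
        if self.mesh_preset not in PRESETS:
            raise ValueError(f"mesh_preset must be one of {sorted(PRESETS)}")
        return self


class TreatmentBlock(_Strict):
    power_W: float = Field(gt=0)
    duration_s: float = Field(gt=0, le=7200)


class OptimizeBlock(_Strict):
    vrr_target_pct: float = Field(65.0, gt=0, le=100)
    power_bounds_W: tuple[float, float] = (45.0, 60.0)
    max_duration_s: float = Field(1200.0, gt=0)
    penalty_weight: float = Field(10.0, ge=0)
    max_evaluations: int = Field(60, gt=0)

    @model_validator(mode="after")
    def _check_bounds(self):
        lo, hi = self.power_bounds_W
        if not lo < hi:
            raise ValueError("power bounds must satisfy lo < hi")
        return self


class SweepBlock(_Strict):
    tip_lengths_mm: tuple[float, ...] = (5, 10, 15, 20, 25, 30, 35, 40)
    scenarios: tuple[str, ...] = ("low", "high")


class OutputBlock(_Strict):
    directory: str = "out"
    snapshot_cadence_s: float = Field(600.0, gt=0)


class RunConfig(_Strict):
    phantom: PhantomBlock = PhantomBlock()
    electrode: ElectrodeBlock = ElectrodeBlock()
    scenario: str = "low"
    solver: SolverBlock = SolverBlock()
    treatment: TreatmentBlock | None = None
    optimize: OptimizeBlock | None = None
    sweep: SweepBlock | None = None
    output: OutputBlock = OutputBlock()
    seed: int = 0

    @model_validator(mode="after")
    def _check_scenario(self):
        if self.scenario not in ("low", "high"):
            raise ValueError("scenario must be 'low' or 'high'")
        return self

    def build_phantom(self):
        from .geometry import build_phantom
        p = self.phantom
        return build_phantom(
            nodule_volume=p.nodule_volume_mL * 1e-6,
            nodule_shape=p.nodule_shape,
            layer_thicknesses={
                "skin": p.skin_mm * 1e-3, "fat": p.fat_mm * 1e-3,
                "muscle": p.muscle_mm * 1e-3, "thyroid": p.thyroid_mm * 1e-3},
            domain_extent=tuple(d * 1e-3 for d in p.domain_mm))

    def build_electrode(self, phantom):
        from .geometry import ElectrodeSpec
        e = self.electrode
        return ElectrodeSpec.centered_in(
            phantom, e.tip_length_mm * 1e-3,
            outer_diameter=e.outer_diameter_mm * 1e-3,
            shaft_length=e.shaft_length_mm * 1e-3)


def load_config(path_or_text) -> RunConfig:
    """Parse and validate a YAML run configuration."""
    text = (Path(path_or_text).read_text()
            if isinstance(path_or_text, (str, Path))
            and "\n" not in str(path_or_text)
            and Path(path_or_text).exists()
            else str(path_or_text))
    try:
        raw = yaml.safe_load(text) or {}
        return RunConfig.model_validate(raw)
    except Exception as exc:
        raise ConfigError(str(exc)) from exc


def dump_config(cfg: RunConfig, path) -> Path:
    path = Path(path)
    path.write_text(yaml.safe_dump(cfg.model_dump(), sort_keys=False))
    return path
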