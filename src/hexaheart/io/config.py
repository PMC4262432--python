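"""Validated run configuration (YAML / dict -> typed model).

A :class:`RunConfig` fully specifies a simulation: geometry, fiber field,
cell model, solver, Purkinje system, pacing protocol and outputs, plus the
random seed. Unknown keys are rejected so typos fail loudly; all physical
quantities carry their unit in the field name (µm / ms / mV convention).
"""

from __future__ import annotations

from typing import Literal, Optional, Tuple

import yaml
from pydantic import BaseModel, ConfigDict, Field, ValidationError

from ..fem import SolverConfig
from ..protocols import PMJ_SEARCH_RADIUS, Protocol
from ..purkinje import DEFAULT_D_PURKINJE, DEFAULT_L_PMJ, DEFAULT_RADIUS


class ConfigError(ValueError):
    """Raised for unparseable or invalid run configurations."""


class _Section(BaseModel):
    model_config = ConfigDict(extra="forbid")


class GeometrySection(_Section):
    """Domain: biventricular phantom or rectangular slab."""

    kind: Literal["phantom", "slab"] = "phantom"
    edge_um: float = Field(400.0, gt=0)
    # phantom parameters
    outer_radii_um: Tuple[float, float, float] = (8000.0, 8000.0, 12000.0)
    wall_thickness_um: float = Field(2400.0, gt=0)
    septum_thickness_um: float = Field(2400.0, gt=0)
    base_height_um: float = Field(4000.0, gt=0)
    # slab parameters
    slab_extent_um: Tuple[float, float, float] = (9600.0, 600.0, 600.0)


class FiberSection(_Section):
    """Rule-based fiber architecture and tensor interpolation."""

    enabled: bool = False
    helix_endo_deg: float = 60.0
    helix_epi_deg: float = -60.0
    anisotropy: Tuple[float, float, float] = (4.0, 2.0, 1.0)
    scheme: Literal["nearest", "euclidean", "log_euclidean"] = "log_euclidean"


class CellSection(_Section):
    """Membrane model and regional heterogeneity."""

    model: Literal["mahajan", "twovar", "passive"] = "mahajan"
    regional: bool = True
    cycle_length_ms: float = Field(400.0, gt=0)
    calibration_beats: int = Field(20, ge=1)


class SolverSection(_Section):
    """Operator-splitting time integration."""

    dt_pde_ms: float = Field(0.1, gt=0)
    dt_ode_ms: float = Field(0.02, gt=0)
    splitting: Literal["godunov", "strang"] = "godunov"
    theta: float = Field(1.0, ge=0.5, le=1.0)
    linear_solver: Literal["auto", "direct", "cg"] = "auto"
    output_every_ms: float = Field(1.0, gt=0)

    def to_solver_config(self) -> SolverConfig:
        return SolverConfig(dt_pde=self.dt_pde_ms, dt_ode=self.dt_ode_ms,
                            splitting=self.splitting, theta=self.theta,
                            linear_solver=self.linear_solver,
                            output_every=self.output_every_ms)


class PurkinjeSection(_Section):
    """Synthetic conduction tree and junction coupling."""

    enabled: bool = False
    n_pmj: int = Field(54, ge=1)
    min_separation_um: float = Field(0.0, ge=0)
    radius_um: float = Field(DEFAULT_RADIUS, gt=0)
    l_pmj_um: float = Field(DEFAULT_L_PMJ, gt=0)
    diffusivity_um2_ms: float = Field(DEFAULT_D_PURKINJE, gt=0)
    search_radius_um: float = Field(PMJ_SEARCH_RADIUS, gt=0)


class ProtocolSection(_Section):
    """Pacing protocol."""

    kind: Literal["av_pacing", "endocardial_instant",
                  "s1s2_wedge", "custom"] = "av_pacing"
    s1_cycle_length_ms: float = Field(400.0, gt=0)
    n_beats: int = Field(1, ge=1)
    s2_coupling_ms: float = Field(219.0, gt=0)
    s2_wedge_angle_deg: float = Field(60.0, gt=0, le=360)
    s2_height_fraction: float = Field(0.5, gt=0, le=1)
    amplitude: float = Field(60.0, gt=0)
    duration_ms: float = Field(2.0, gt=0)
    conductivity_scale: float = Field(1.0, gt=0)

    def to_protocol(self) -> Protocol:
        return Protocol(kind=self.kind,
                        s1_cycle_length=self.s1_cycle_length_ms,
                        n_beats=self.n_beats,
                        s2_coupling=self.s2_coupling_ms,
                        s2_wedge_angle=self.s2_wedge_angle_deg,
                        s2_height_fraction=self.s2_height_fraction,
                        amplitude=self.amplitude,
                        duration=self.duration_ms,
                        conductivity_scale=self.conductivity_scale)


class OutputSection(_Section):
    """Simulated duration and artifacts."""

    duration_ms: float = Field(120.0, gt=0)
    store_series: bool = True
    ecg: bool = True
    chest_offset: float = Field(2.0, gt=0)


class RunConfig(_Section):
    """Complete, validated description of one simulation run."""

    seed: int = 0
    d_l_um2_ms: float = Field(1.84376225e5, gt=0,
                              description="longitudinal diffusivity")
    geometry: GeometrySection = Field(default_factory=GeometrySection)
    fibers: FiberSection = Field(default_factory=FiberSection)
    cells: CellSection = Field(default_factory=CellSection)
    solver: SolverSection = Field(default_factory=SolverSection)
    purkinje: PurkinjeSection = Field(default_factory=PurkinjeSection)
    protocol: ProtocolSection = Field(default_factory=ProtocolSection)
    output: OutputSection = Field(default_factory=OutputSection)


def _explain(exc: ValidationError) -> str:
    lines = []
    for err in exc.errors():
        loc = ".".join(str(p) for p in err["loc"]) or "<root>"
        lines.append(f"  {loc}: {err['msg']}")
    return "\n".join(lines)


def run_config_from_dict(data: dict) -> RunConfig:
    """Build a validated RunConfig; unknown keys are errors."""
    try:
        return RunConfig.model_validate(data or {})
    except ValidationError as exc:
        raise ConfigError("invalid run configuration:\n"
                          + _explain(exc)) from exc


def load_run_config(path) -> RunConfig:
    """Load and validate a YAML run configuration file."""
    try:
        with open(path) as fh:
            data = yaml.safe_load(fh)
    except OSError as exc:
        raise ConfigError(f"{path}: {exc}") from exc
    except yaml.YAMLError as exc:
        raise ConfigError(f"{path}: invalid YAML ({exc})") from exc
    if data is None:
        data = {}
    if not isinstance(data, dict):
        raise ConfigError(f"{path}: top level must be a mapping")
    try:
        return run_config_from_dict(data)
    except ConfigError as exc:
        raise ConfigError(f"{path}: {exc}") from exc


def dump_run_config(config: RunConfig, path=None) -> str:
    """Serialize a RunConfig to YAML; optionally write it to ``path``."""
    text = yaml.safe_dump(config.model_dump(mode="json"), sort_keys=True)
    if path is not None:
        with open(path, "w") as fh:
            fh.write(text)
    return text
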