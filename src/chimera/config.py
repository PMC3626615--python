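"""Run configuration: typed parameter blocks, strict validation, defaults.

A :class:`RunConfig` plus an integer seed fully determines a simulation.
All lengths are expressed in box units (the container side is 1.0 by
default, with the top face at height 0 and the floor at -1), masses in
units of the cell birth mass, and time in units of the integration step
count times ``dt``.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import yaml

__all__ = [
    "PhysicsParams",
    "AdhesionParams",
    "EcologyParams",
    "EvoParams",
    "MetricsParams",
    "RunParams",
    "RunConfig",
    "ConfigError",
    "load_config",
    "default_config",
    "config_to_dict",
    "config_hash",
    "defaults_yaml",
]


class ConfigError(ValueError):
    """Raised when a configuration file violates the schema or an invariant."""


@dataclass
class PhysicsParams:
    """Constants of the mechanical world.

    ``sigma`` is the strength of the spatially homogeneous random forcing
    (one shared draw per step), ``gamma`` the viscous drag coefficient,
    ``g`` the gravity vector, and the ``k_*`` constants the coefficients
    of the discrete-element contact force.  ``soft_core_strength`` /
    ``soft_core_exponent`` parameterise the repulsive soft-core potential
    U(d) = eps * ((R_i + R_j) / d) ** n, truncated at contact.
    """

    dt: float = 0.05
    sigma: float = 0.5
    gamma: float = 5.0
    g: tuple[float, float, float] = (0.0, 0.0, -2.5)
    k_shear: float = 1.0
    k_damp: float = 2.0
    k_spring: float = 50.0
    soft_core_strength: float = 0.1
    soft_core_exponent: float = 2.0
    restitution: float = 0.5
    bounce_mode: str = "full"  # "full": reverse the whole velocity; "normal": reflect the normal component only
    box_side: float = 1.0
    voxel_size: float = 0.175

    @property
    def grid_origin(self) -> tuple[float, float, float]:
        # x, y in [0, L]; z in [-L, 0] with the top face at z = 0.
        return (0.0, 0.0, -self.box_side)

    def validate(self) -> None:
        if self.dt <= 0:
            raise ConfigError("physics.dt must be positive")
        if self.sigma < 0:
            raise ConfigError("physics.sigma must be non-negative")
        if self.gamma < 0:
            raise ConfigError("physics.gamma must be non-negative")
        for name in ("k_shear", "k_damp", "k_spring"):
            if getattr(self, name) < 0:
                raise ConfigError(f"physics.{name} must be non-negative")
        if not 0.0 < self.restitution <= 1.0:
            raise ConfigError("physics.restitution must lie in (0, 1]")
        if self.bounce_mode not in ("full", "normal"):
            raise ConfigError("physics.bounce_mode must be 'full' or 'normal'")
        if self.box_side <= 0:
            raise ConfigError("physics.box_side must be positive")
        if not 0 < self.voxel_size <= self.box_side:
            raise ConfigError("physics.voxel_size must lie in (0, box_side]")


@dataclass
class AdhesionParams:
    """Spring constants and stochastic attach/detach rules for adhesion.

    Wall springs anchor a cell to its perpendicular projection on the
    closest boundary plane; cell-cell springs link two nearby cells.  Both
    kinds detach spontaneously per step and break deterministically when
    stretched past their maximal length.
    """

    r_adh: float = 0.12
    L0_wall: float = 0.07
    k_wall: float = 200.0
    Lmax_wall: float = 0.21
    p_detach_wall: float = 0.003
    L0_cell: float = 0.14
    k_cell: float = 100.0
    Lmax_cell: float = 0.28
    p_detach_cell: float = 0.005
    r_attach_cell: float = 0.175

    def validate(self) -> None:
        if self.r_adh <= 0:
            raise ConfigError("adhesion.r_adh must be positive")
        if self.r_attach_cell <= 0:
            raise ConfigError("adhesion.r_attach_cell must be positive")
        if not self.L0_wall < self.Lmax_wall:
            raise ConfigError("adhesion.L0_wall must be below Lmax_wall")
        if not self.L0_cell < self.Lmax_cell:
            raise ConfigError("adhesion.L0_cell must be below Lmax_cell")
        for name in ("p_detach_wall", "p_detach_cell"):
            if not 0.0 <= getattr(self, name) <= 1.0:
                raise ConfigError(f"adhesion.{name} must lie in [0, 1]")
        for name in ("k_wall", "k_cell"):
            if getattr(self, name) < 0:
                raise ConfigError(f"adhesion.{name} must be non-negative")


@dataclass
class EcologyParams:
    """Nutrient economy: inflow, particle geometry, degradation rates.

    ``eta`` particles enter per step through the top face, split uniformly
    over ``n_sources`` nutrient classes.  Nutrients degrade (memoryless,
    per-step probability ``delta``); detritus released by dead cells
    degrades at the strictly slower ``delta_detritus``.
    """

    eta: int = 6
    n_sources: int = 4
    particle_mass: float = 0.5
    particle_radius: float = 0.03
    delta: float = 0.01
    delta_detritus: float = 0.0025
    detritus_mass: float | None = None  # None: inherit particle_mass
    detritus_radius: float | None = None  # None: inherit particle_radius

    @property
    def n_classes(self) -> int:
        """Nutrient classes plus the detritus compartment."""
        return self.n_sources + 1

    @property
    def detritus_class(self) -> int:
        return self.n_sources

    def validate(self) -> None:
        if self.eta < 0:
            raise ConfigError("ecology.eta must be non-negative")
        if self.n_sources < 1:
            raise ConfigError("ecology.n_sources must be at least 1")
        if self.particle_mass <= 0 or self.particle_radius <= 0:
            raise ConfigError("ecology.particle_mass and particle_radius must be positive")
        if not 0.0 < self.delta < 1.0:
            raise ConfigError("ecology.delta must lie in (0, 1)")
        if not 0.0 < self.delta_detritus < 1.0:
            raise ConfigError("ecology.delta_detritus must lie in (0, 1)")
        if self.delta_detritus >= self.delta:
            raise ConfigError(
                "ecology.delta_detritus must be below ecology.delta: detritus "
                "persists longer than nutrients (slower degradation rate)"
            )


@dataclass
class EvoParams:
    """Cell life cycle: maintenance, death, division, mutation."""

    m0: float = 1.0
    m_min: float = 0.5
    maintenance_cost: float = 0.004
    n_detritus: int = 3
    rho_max: int = 9
    r_neighborhood: float = 0.175
    p_mut: float = 0.3
    sigma_mut: float = 0.1
    cell_radius: float = 0.07
    half_split: bool = False  # True: split mass evenly instead of transferring m0
    n_founders: int = 20
    founder_class: int = 0
    founder_wall_adhesion: float = 0.45
    founder_cell_adhesion: float = 0.35

    def validate(self) -> None:
        if self.m0 <= 0:
            raise ConfigError("evolution.m0 must be positive")
        if not 0 < self.m_min < self.m0:
            raise ConfigError("evolution.m_min must lie in (0, m0)")
        if self.maintenance_cost < 0:
            raise ConfigError("evolution.maintenance_cost must be non-negative")
        if self.n_detritus < 0:
            raise ConfigError("evolution.n_detritus must be non-negative")
        if self.rho_max < 0:
            raise ConfigError("evolution.rho_max must be non-negative")
        if self.r_neighborhood <= 0:
            raise ConfigError("evolution.r_neighborhood must be positive")
        if not 0.0 <= self.p_mut <= 1.0:
            raise ConfigError("evolution.p_mut must lie in [0, 1]")
        if self.sigma_mut <= 0:
            raise ConfigError("evolution.sigma_mut must be positive")
        if self.cell_radius <= 0:
            raise ConfigError("evolution.cell_radius must be positive")
        if self.n_founders < 0:
            raise ConfigError("evolution.n_founders must be non-negative")
        if not 0.0 <= self.founder_wall_adhesion <= 1.0:
            raise ConfigError("evolution.founder_wall_adhesion must lie in [0, 1]")
        if not 0.0 <= self.founder_cell_adhesion <= 1.0:
            raise ConfigError("evolution.founder_cell_adhesion must lie in [0, 1]")


@dataclass
class MetricsParams:
    """Observable definitions: top-layer detector, phase classifier, detritivore cutoff."""

    band_depth: float = 0.15  # roughly two cell radii below the top face
    coverage_threshold: float = 0.1
    min_top_count: int = 10
    detritivore_eps: float = 0.05
    layer_k: int = 2
    phase_window: int = 10  # records inspected at run end by the classifier
    include_detritus_in_entropy: bool = True

    def validate(self) -> None:
        if not 0.0 < self.coverage_threshold <= 1.0:
            raise ConfigError("metrics.coverage_threshold must lie in (0, 1]")
        if not 0.0 < self.band_depth <= 1.0:
            raise ConfigError("metrics.band_depth must lie in (0, 1]")
        if self.min_top_count < 0:
            raise ConfigError("metrics.min_top_count must be non-negative")
        if self.detritivore_eps < 0:
            raise ConfigError("metrics.detritivore_eps must be non-negative")
        if self.layer_k < 1:
            raise ConfigError("metrics.layer_k must be at least 1")
        if self.phase_window < 1:
            raise ConfigError("metrics.phase_window must be at least 1")


@dataclass
class RunParams:
    steps: int = 3000
    seed: int = 0
    record_interval: int = 25
    output_dir: str | None = None
    log_events: bool = True

    def validate(self) -> None:
        if self.steps < 0:
            raise ConfigError("run.steps must be non-negative")
        if self.record_interval < 1:
            raise ConfigError("run.record_interval must be at least 1")


_SECTIONS = {
    "physics": PhysicsParams,
    "adhesion": AdhesionParams,
    "ecology": EcologyParams,
    "evolution": EvoParams,
    "metrics": MetricsParams,
    "run": RunParams,
}


@dataclass
class RunConfig:
    physics: PhysicsParams = field(default_factory=PhysicsParams)
    adhesion: AdhesionParams = field(default_factory=AdhesionParams)
    ecology: EcologyParams = field(default_factory=EcologyParams)
    evolution: EvoParams = field(default_factory=EvoParams)
    metrics: MetricsParams = field(default_factory=MetricsParams)
    run: RunParams = field(default_factory=RunParams)

    def validate(self) -> None:
        for name in _SECTIONS:
            getattr(self, name).validate()
        self._validate_cross()

    def _validate_cross(self) -> None:
        p, e, ev = self.physics, self.ecology, self.evolution
        if max(ev.cell_radius, e.particle_radius) * 2 > p.box_side:
            raise ConfigError("body diameters must fit inside the box")
        # dt stability estimate: drag-limited terminal speed under gravity
        # plus peak noise must move a body less than its own radius per step.
        gmag = math.sqrt(sum(c * c for c in p.g))
        if p.gamma > 0:
            for name, mass, radius in (
                ("cell", ev.m0, ev.cell_radius),
                ("particle", e.particle_mass, e.particle_radius),
            ):
                v_est = (mass * gmag + math.sqrt(3.0) * p.sigma) / p.gamma
                if v_est * p.dt >= radius:
                    raise ConfigError(
                        f"physics.dt too large: estimated per-step {name} "
                        f"displacement {v_est * p.dt:.4g} exceeds its radius "
                        f"{radius:.4g}; reduce dt, sigma or gravity"
                    )
        if ev.founder_class >= e.n_sources:
            raise ConfigError("evolution.founder_class must index a nutrient source")
        # every pair-based interaction cutoff must fit inside one voxel,
        # or the 27-voxel broad phase would miss true pairs
        max_cut = max(
            2 * ev.cell_radius,
            ev.cell_radius + e.particle_radius,
            2 * e.particle_radius,
            self.adhesion.r_attach_cell,
            ev.r_neighborhood,
        )
        if max_cut > p.voxel_size + 1e-12:
            raise ConfigError(
                f"physics.voxel_size ({p.voxel_size}) must cover the largest "
                f"interaction cutoff ({max_cut:.4g})"
            )

    def replace(self, **section_updates: dict[str, Any]) -> "RunConfig":
        """Return a copy with per-section field overrides.

        Example: ``cfg.replace(physics={"sigma": 0.5}, run={"steps": 100})``.
        """
        sections = {}
        for name in _SECTIONS:
            block = getattr(self, name)
            updates = section_updates.pop(name, None)
            if updates:
                unknown = set(updates) - {f.name for f in dataclasses.fields(block)}
                if unknown:
                    raise ConfigError(f"unknown keys in section '{name}': {sorted(unknown)}")
                block = dataclasses.replace(block, **updates)
            sections[name] = block
        if section_updates:
            raise ConfigError(f"unknown config sections: {sorted(section_updates)}")
        cfg = RunConfig(**sections)
        cfg.validate()
        return cfg


def default_config() -> RunConfig:
    cfg = RunConfig()
    cfg.validate()
    return cfg


def _coerce(value: Any, target: Any) -> Any:
    if isinstance(target, tuple) and isinstance(value, (list, tuple)):
        return tuple(float(v) for v in value)
    return value


def _build_section(cls: type, name: str, data: dict[str, Any]):
    if not isinstance(data, dict):
        raise ConfigError(f"config section '{name}' must be a mapping")
    known = {f.name: f for f in dataclasses.fields(cls)}
    unknown = set(data) - set(known)
    if unknown:
        raise ConfigError(f"unknown keys in section '{name}': {sorted(unknown)}")
    defaults = cls()
    kwargs = {k: _coerce(v, getattr(defaults, k)) for k, v in data.items()}
    return cls(**kwargs)


def load_config(path: str | Path) -> RunConfig:
    """Load, default, and validate a YAML configuration file.

    An empty file yields the all-defaults configuration.  Unknown sections
    or keys are rejected, and every section invariant is checked; errors
    name the offending key.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"config file not found: {path}")
    raw = yaml.safe_load(path.read_text()) or {}
    if not isinstance(raw, dict):
        raise ConfigError("config root must be a mapping of sections")
    unknown = set(raw) - set(_SECTIONS)
    if unknown:
        raise ConfigError(f"unknown config sections: {sorted(unknown)}")
    sections = {
        name: _build_section(cls, name, raw.get(name, {}) or {})
        for name, cls in _SECTIONS.items()
    }
    cfg = RunConfig(**sections)
    cfg.validate()
    return cfg


def config_to_dict(cfg: RunConfig) -> dict[str, Any]:
    out: dict[str, Any] = {}
    for name in _SECTIONS:
        block = dataclasses.asdict(getattr(cfg, name))
        for k, v in block.items():
            if isinstance(v, tuple):
                block[k] = list(v)
        out[name] = block
    return out


def config_hash(cfg: RunConfig) -> str:
    """Stable content hash of a configuration (seed excluded)."""
    d = config_to_dict(cfg)
    d["run"].pop("seed", None)
    d["run"].pop("output_dir", None)
    blob = json.dumps(d, sort_keys=True, separators=(",", ":"))
    return hashlib.sha256(blob.encode()).hexdigest()[:16]


def defaults_yaml() -> str:
    """The full default configuration rendered as YAML."""
    return yaml.safe_dump(config_to_dict(default_config()), sort_keys=False)
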