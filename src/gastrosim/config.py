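"""Run configuration: schema, validation, YAML round-trip.

External units follow the reporting conventions: lengths in mm, time in s,
viscosity in mPa s, densities in kg/m^3 (fluid) and g/cm^3 (solids),
pressures in Pa, emptying rates in ml/min.  Conversion to the internal
mm-g-s system happens at assembly time.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field, asdict
from pathlib import Path

import yaml

__all__ = ["SimulationConfig", "WaveConfig", "ParticleConfig", "ContactConfig",
           "NumericsConfig", "ConfigError", "load_config", "save_config"]


class ConfigError(ValueError):
    """Invalid configuration; the message lists the offending keys."""


@dataclass
class WaveConfig:
    period_s: float = 20.0
    amplitude: float = 0.8           # peak relative occlusion (healthy)
    width_mm: float = 10.0
    chi_hypomotile: float = 0.5      # motility scale used when motility=hypomotile
    s_start_mm: float = 55.0         # antral origin of the contraction waves
    speed_mm_s: float | None = None  # default: traverse s_start in one period


@dataclass
class ParticleConfig:
    count: int = 8
    diameter_mm: float = 4.0
    density_g_cm3: float = 1.1
    initial_gap_mm: float = 0.2      # surface-to-surface spacing at release


@dataclass
class ContactConfig:
    k_n: float | None = None         # None: sized so peak overlap <= 0.05 r at 50 mm/s
    gamma_n: float | None = None     # None: sized for restitution ~0.3
    activation_gap_mm: float = 0.1
    friction: float = 0.0


@dataclass
class NumericsConfig:
    grid_h_mm: float = 0.4
    cfl: float = 0.4
    dt_cap_s: float = 2.0e-3
    output_dt_s: float = 0.1
    resolution_guard: bool = True


@dataclass
class SimulationConfig:
    scenario: str = "gastric"
    motility: str = "healthy"                 # healthy | hypomotile
    mu_mPas: float = 1.0
    rho_kg_m3: float = 1000.0
    include_particles: bool = True
    duration_s: float = 120.0
    tone_Pa: float = 0.2                      # fundic tone inlet pressure
    depth_mm: float = 4.0                     # nominal depth for 3D-equivalent output
    checkpoint_interval_s: float | None = None
    vtk_interval_s: float | None = None
    waves: WaveConfig = field(default_factory=WaveConfig)
    particles: ParticleConfig = field(default_factory=ParticleConfig)
    contact: ContactConfig = field(default_factory=ContactConfig)
    numerics: NumericsConfig = field(default_factory=NumericsConfig)

    # -- validation ---------------------------------------------------------

    def validate(self) -> None:
        bad: list[str] = []
        if self.scenario not in ("gastric",):
            bad.append(f"scenario={self.scenario!r} (expected 'gastric')")
        if self.motility not in ("healthy", "hypomotile"):
            bad.append(f"motility={self.motility!r}")
        for key in ("mu_mPas", "rho_kg_m3", "duration_s", "depth_mm"):
            if getattr(self, key) <= 0:
                bad.append(f"{key}={getattr(self, key)} (must be positive)")
        w = self.waves
        if w.period_s <= 0 or w.width_mm <= 0 or w.s_start_mm <= 0:
            bad.append("waves.period_s/width_mm/s_start_mm must be positive")
        if not (0.0 <= w.amplitude <= 1.0):
            bad.append(f"waves.amplitude={w.amplitude} (must lie in [0, 1])")
        if not (0.0 < w.chi_hypomotile <= 1.0):
            bad.append(f"waves.chi_hypomotile={w.chi_hypomotile} (must lie in (0, 1])")
        p = self.particles
        if p.count < 0 or p.diameter_mm <= 0 or p.density_g_cm3 <= 0:
            bad.append("particles.count/diameter_mm/density_g_cm3 invalid")
        c = self.contact
        if not (0.0 < c.activation_gap_mm < p.initial_gap_mm):
            bad.append(
                f"contact.activation_gap_mm={c.activation_gap_mm} (must lie in "
                f"(0, {p.initial_gap_mm}) so springs are inactive at release)"
            )
        n = self.numerics
        if n.grid_h_mm <= 0 or n.dt_cap_s <= 0 or n.output_dt_s <= 0:
            bad.append("numerics.grid_h_mm/dt_cap_s/output_dt_s must be positive")
        if not (0.0 < n.cfl <= 0.5):
            bad.append(f"numerics.cfl={n.cfl} (must lie in (0, 0.5])")
        if bad:
            raise ConfigError("invalid configuration: " + "; ".join(bad))

    @property
    def chi(self) -> float:
        return 1.0 if self.motility == "healthy" else self.waves.chi_hypomotile

    # -- serialisation --------------------------------------------------------

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "SimulationConfig":
        d = dict(d)
        unknown = []

        def build(dc_cls, sub: dict, prefix: str):
            names = {f.name for f in dataclasses.fields(dc_cls)}
            unknown.extend(f"{prefix}{k}" for k in sub if k not in names)
            return dc_cls(**{k: v for k, v in sub.items() if k in names})

        for key, dc_cls in (
            ("waves", WaveConfig),
            ("particles", ParticleConfig),
            ("contact", ContactConfig),
            ("numerics", NumericsConfig),
        ):
            if key in d and isinstance(d[key], dict):
                d[key] = build(dc_cls, d[key], key + ".")
        top = {f.name for f in dataclasses.fields(cls)}
        unknown.extend(k for k in d if k not in top)
        if unknown:
            raise ConfigError("unknown configuration keys: " + ", ".join(sorted(unknown)))
        cfg = cls(**{k: v for k, v in d.items() if k in top})
        cfg.validate()
        return cfg


def load_config(path) -> SimulationConfig:
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    return SimulationConfig.from_dict(data)


def save_config(cfg: SimulationConfig, path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        yaml.safe_dump(cfg.to_dict(), fh, sort_keys=False)
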