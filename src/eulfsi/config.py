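"""Case configuration: dimensionless groups, validation and TOML I/O.

All solver inputs are dimensionless: lengths in pipe diameters D, velocities
in U = 2 ubar, time in D/U, density rho = 1.  Dimensional inputs (mm, Pa,
Pa s, mm/s) are converted on load; an inconsistent Reynolds number versus
the dimensional viscosity must be resolved explicitly by pinning Re (the
published parameter table carries exactly this inconsistency).
"""
from __future__ import annotations

import hashlib
import json
import tomllib
from dataclasses import asdict, dataclass
from pathlib import Path

from .particles import ParticleSpec

__all__ = ["CaseConfig", "load_config", "save_config", "config_hash"]

_KNOWN_CASE_KEYS = {
    "kind", "re", "mean_velocity", "viscosity_ratio", "G", "co", "alpha_min",
    "btilde_reset", "grid_shape", "grid_lengths", "outer_correctors",
    "output_every", "t_end", "seed", "perturbation", "pin_re",
    "inlet_pressure", "stenosis_length", "stenosis_inlet_radius",
    "stenosis_throat_radius", "lid_velocity", "rdf_iterations",
}
_KNOWN_PARTICLE_KEYS = {"shape", "center", "psi0_deg", "r", "R", "h", "a",
                        "b", "c"}
_KNOWN_DIM_KEYS = {"rho", "mu_f", "mu_s", "D_mm", "u_mean_mm_s", "G_Pa"}


@dataclass
class CaseConfig:
    """Dimensionless physical and numerical parameters of one run."""
    kind: str = "pipe"              # pipe | cavity | poiseuille | stenosis
    re: float = 50.0                # Re = rho ubar D / mu_f
    mean_velocity: float = 0.5      # target bulk velocity (U scale)
    viscosity_ratio: float = 1.0    # mu_s / mu_f in [1, 10]
    G: float = 10.0                 # G / (rho U^2)
    co: float = 0.1
    alpha_min: float = 0.1
    btilde_reset: str = "unit"
    grid_shape: tuple = (96, 32, 32)
    grid_lengths: tuple = (3.0, 1.0, 1.0)
    particle: ParticleSpec | None = None
    outer_correctors: int = 1
    output_every: float = 0.1
    t_end: float = 8.0
    seed: int = 0
    perturbation: float = 0.0       # symmetry-breaking amplitude (x U)
    inlet_pressure: float = 5.5     # stenosis only (p_rgh units rho U^2)
    stenosis_length: float = 4.5
    stenosis_inlet_radius: float = 1.0
    stenosis_throat_radius: float = 0.5
    lid_velocity: float = 1.0       # cavity only
    rdf_iterations: int = 2

    def __post_init__(self):
        if self.re <= 0:
            raise ValueError("Re must be positive")
        if not (0 < self.co <= 0.5):
            raise ValueError("Co must lie in (0, 0.5]")
        if self.G < 0:
            raise ValueError("G must be non-negative")
        if self.viscosity_ratio < 1.0 or self.viscosity_ratio > 10.0:
            raise ValueError("viscosity ratio must lie in [1, 10]")
        if self.kind not in ("pipe", "cavity", "poiseuille", "stenosis"):
            raise ValueError(f"unknown case kind {self.kind!r}")

    @property
    def nu_f(self) -> float:
        """Dimensionless kinematic fluid viscosity 1/Re_U, Re_U = 2 Re."""
        return 1.0 / (2.0 * self.re)

    @property
    def nu_s(self) -> float:
        return self.nu_f * self.viscosity_ratio


def _particle_from_table(tbl: dict) -> ParticleSpec:
    unknown = set(tbl) - _KNOWN_PARTICLE_KEYS
    if unknown:
        raise ValueError(f"unknown particle keys: {sorted(unknown)}")
    shape = tbl["shape"]
    keys = {"torus": ("r", "R"), "disk": ("h", "r"), "sphere": ("r",),
            "ellipsoid": ("a", "b", "c")}[shape]
    params = {k: float(tbl[k]) for k in keys}
    return ParticleSpec(shape, params,
                        tuple(tbl.get("center", (0.0, 0.5, 0.5))),
                        float(tbl.get("psi0_deg", 0.0)))


def load_config(path) -> CaseConfig:
    """Read a TOML case file; convert dimensional inputs; reject unknown
    keys; enforce the Re consistency rule."""
    with open(path, "rb") as f:
        doc = tomllib.load(f)
    unknown_sections = set(doc) - {"case", "particle", "dimensional"}
    if unknown_sections:
        raise ValueError(f"unknown sections: {sorted(unknown_sections)}")
    case = dict(doc.get("case", {}))
    unknown = set(case) - _KNOWN_CASE_KEYS
    if unknown:
        raise ValueError(f"unknown case keys: {sorted(unknown)}")
    pin_re = bool(case.pop("pin_re", False))

    if "dimensional" in doc:
        dim = dict(doc["dimensional"])
        bad = set(dim) - _KNOWN_DIM_KEYS
        if bad:
            raise ValueError(f"unknown dimensional keys: {sorted(bad)}")
        rho = float(dim.get("rho", 1000.0))            # kg/m^3
        mu_f = float(dim.get("mu_f", 1.0e-3))          # Pa s
        D = float(dim.get("D_mm", 1.0)) * 1e-3         # m
        ubar = float(dim.get("u_mean_mm_s", 50.0)) * 1e-3
        re_dim = rho * ubar * D / mu_f
        if "re" in case:
            re_cfg = float(case["re"])
            if abs(re_dim - re_cfg) > 0.01 * re_cfg and not pin_re:
                raise ValueError(
                    f"Re from dimensional inputs ({re_dim:.4g}) contradicts "
                    f"the configured Re ({re_cfg:.4g}); the published "
                    "parameter tables carry this fluid-viscosity/Reynolds "
                    "inconsistency -- set pin_re = true to adopt the "
                    "configured Re")
        else:
            case["re"] = re_dim
        U = 2.0 * ubar
        if "G_Pa" in dim:
            case["G"] = float(dim["G_Pa"]) / (rho * U * U)
        if "mu_s" in dim:
            case["viscosity_ratio"] = float(dim["mu_s"]) / mu_f

    if "grid_shape" in case:
        case["grid_shape"] = tuple(int(v) for v in case["grid_shape"])
    if "grid_lengths" in case:
        case["grid_lengths"] = tuple(float(v) for v in case["grid_lengths"])
    particle = None
    if "particle" in doc:
        particle = _particle_from_table(doc["particle"])
    return CaseConfig(particle=particle, **case)


def _toml_value(v):
    if isinstance(v, bool):
        return "true" if v else "false"
    if isinstance(v, (int, float)):
        return repr(v)
    if isinstance(v, str):
        return json.dumps(v)
    if isinstance(v, (tuple, list)):
        return "[" + ", ".join(_toml_value(x) for x in v) + "]"
    raise TypeError(f"cannot serialize {type(v)}")


def save_config(cfg: CaseConfig, path):
    """Write a TOML file that round-trips through :func:`load_config`."""
    lines = ["[case]"]
    d = asdict(cfg)
    particle = d.pop("particle", None)
    for k, v in d.items():
        if v is None:
            continue
        lines.append(f"{k} = {_toml_value(v)}")
    if cfg.particle is not None:
        lines.append("")
        lines.append("[particle]")
        lines.append(f"shape = {_toml_value(cfg.particle.shape)}")
        for k, v in cfg.particle.params.items():
            lines.append(f"{k} = {_toml_value(v)}")
        lines.append(f"center = {_toml_value(list(cfg.particle.center))}")
        lines.append(f"psi0_deg = {_toml_value(cfg.particle.psi0_deg)}")
    Path(path).write_text("\n".join(lines) + "\n")
    return path


def config_hash(cfg: CaseConfig) -> str:
    d = asdict(cfg)
    blob = json.dumps(d, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:16]
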