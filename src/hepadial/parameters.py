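"""Physical parameters of the hollow-fiber albumin-dialysis module.

Every quantity is stored in the package's internal unit system —
lengths in cm, volumes in mL, times in min, concentrations in µmol/L,
masses in g — which matches the units the device's operating tables are
reported in.  All file I/O converts at the boundary.

Two module configurations are supported:

``"a"``
    hollow fibers immersed in a stirred beaker of albumin-rich dialysate
    with adsorbent microspheres suspended in it;
``"b"``
    no dialysate — the adsorbent microspheres are bound directly to the
    outer fiber surface as a thin solid layer.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict, replace
from pathlib import Path
from typing import Literal

import yaml

__all__ = [
    "ModuleGeometry",
    "EquilibriumParams",
    "OperatingConditions",
    "TransportParams",
    "NumericsConfig",
    "RunConfig",
    "SchemaError",
    "ValidationError",
    "load_config",
    "write_config",
    "default_config_a",
    "default_config_b",
    "um_to_cm",
    "cm_to_um",
    "mg_to_g",
    "g_to_mg",
]


class SchemaError(ValueError):
    """A run-config file is missing a key or carries an unknown one."""


class ValidationError(ValueError):
    """A parameter value violates a physical bound."""


# -- unit helpers (involutive by construction) --------------------------------

UM_PER_CM = 1e4
MG_PER_G = 1e3


def um_to_cm(x: float) -> float:
    return x / UM_PER_CM


def cm_to_um(x: float) -> float:
    return x * UM_PER_CM


def mg_to_g(x: float) -> float:
    return x / MG_PER_G


def g_to_mg(x: float) -> float:
    return x * MG_PER_G


def _require(cond: bool, field_name: str, msg: str) -> None:
    if not cond:
        raise ValidationError(f"{field_name}: {msg}")


@dataclass(frozen=True)
class ModuleGeometry:
    """Fiber-bundle geometry.

    Parameters
    ----------
    fiber_count :
        Number of hollow fibers in the rescaled module (dimensionless).
    fiber_inner_radius :
        Inner fiber radius Rf in cm.  The full-scale dialyzer the fibers
        were harvested from lists a 180 µm inner *diameter*, hence the
        default 0.009 cm radius.
    module_length :
        Active fiber length L in cm.
    adsorbent_layer_thickness :
        Thickness δ (cm) of the adsorbent microsphere layer bound to the
        outer fiber surface.  Only meaningful for configuration B; may be
        0 for configuration A.
    """

    fiber_count: int
    fiber_inner_radius: float
    module_length: float
    adsorbent_layer_thickness: float = 0.0

    def __post_init__(self) -> None:
        _require(self.fiber_count > 0, "fiber_count", "must be a positive integer")
        _require(self.fiber_inner_radius > 0, "fiber_inner_radius", "must be > 0")
        _require(self.module_length > 0, "module_length", "must be > 0")
        _require(
            self.adsorbent_layer_thickness >= 0,
            "adsorbent_layer_thickness",
            "must be >= 0",
        )

    @property
    def fiber_lumen_volume(self) -> float:
        """Total lumen volume nf·π·Rf²·L in mL (recomputed, never stored)."""
        return (
            self.fiber_count
            * math.pi
            * self.fiber_inner_radius**2
            * self.module_length
        )

    @property
    def layer_geometric_factor(self) -> float:
        """2Rf / ((Rf+δ)² − Rf²) in 1/cm — exchange-area over layer-volume
        ratio of the annular adsorbent shell (configuration B)."""
        rf = self.fiber_inner_radius
        d = self.adsorbent_layer_thickness
        if d <= 0:
            raise ValidationError(
                "adsorbent_layer_thickness: must be > 0 for the layer factor"
            )
        return 2.0 * rf / ((rf + d) ** 2 - rf**2)


@dataclass(frozen=True)
class EquilibriumParams:
    """Albumin-binding and adsorption-equilibrium constants.

    ``binding_constant`` kB is in L/µmol (1 L/µmol = 1e6 M⁻¹); bilirubin
    binds albumin with kB of order 1e7–1e8 M⁻¹, i.e. 10–100 L/µmol.
    ``isotherm_slope`` m′ is the linear-isotherm slope in L/g.
    Albumin concentrations are per compartment, in µmol/L; the solid-phase
    value is the effective albumin concentration the microsphere surface
    presents to the adsorbed liquid.
    """

    binding_constant: float
    isotherm_slope: float
    albumin_conc_blood: float
    albumin_conc_dialysate: float
    albumin_conc_solid: float

    def __post_init__(self) -> None:
        _require(self.binding_constant >= 0, "binding_constant", "must be >= 0")
        _require(self.isotherm_slope > 0, "isotherm_slope", "must be > 0")
        for name in ("albumin_conc_blood", "albumin_conc_dialysate", "albumin_conc_solid"):
            _require(getattr(self, name) >= 0, name, "must be >= 0")


@dataclass(frozen=True)
class OperatingConditions:
    """Flows, volumes and adsorbent inventory of one experiment."""

    inlet_toxin_conc: float  # CTB0, µmol/L
    blood_flow: float  # QB, mL/min
    dialysate_volume: float  # VD, mL (config A)
    adsorbent_mass: float  # MP, g
    particle_density: float  # ρP, g/mL
    particle_radius: float = 25e-4  # rP, cm (~25 µm microspheres)
    duration: float = 720.0  # min

    def __post_init__(self) -> None:
        _require(self.inlet_toxin_conc > 0, "inlet_toxin_conc", "must be > 0")
        _require(self.blood_flow > 0, "blood_flow", "must be > 0")
        _require(self.dialysate_volume > 0, "dialysate_volume", "must be > 0")
        _require(self.adsorbent_mass >= 0, "adsorbent_mass", "must be >= 0")
        _require(self.particle_density > 0, "particle_density", "must be > 0")
        _require(self.particle_radius > 0, "particle_radius", "must be > 0")
        _require(self.duration > 0, "duration", "must be > 0")


@dataclass(frozen=True)
class TransportParams:
    """Exchange coefficients, all in cm/min.

    ``global_exchange_coeff`` is PΣ (config A: blood film + membrane +
    dialysate film) or PΣ′ (config B: blood film + membrane + solid layer).
    ``solid_exchange_coeff`` k is the dialysate↔microsphere linear-driving-
    force coefficient; configuration A only.
    """

    global_exchange_coeff: float
    solid_exchange_coeff: float = 0.0

    def __post_init__(self) -> None:
        _require(self.global_exchange_coeff >= 0, "global_exchange_coeff", "must be >= 0")
        _require(self.solid_exchange_coeff >= 0, "solid_exchange_coeff", "must be >= 0")


@dataclass(frozen=True)
class NumericsConfig:
    """Discretization and solver controls (not physics)."""

    n_axial_cells: int = 60
    time_solver_rel_tol: float = 1e-8
    time_solver_abs_tol: float = 1e-10
    output_times: tuple[float, ...] | None = None

    def __post_init__(self) -> None:
        _require(self.n_axial_cells >= 2, "n_axial_cells", "must be an integer >= 2")
        _require(self.time_solver_rel_tol > 0, "time_solver_rel_tol", "must be > 0")
        _require(self.time_solver_abs_tol > 0, "time_solver_abs_tol", "must be > 0")
        if self.output_times is not None:
            ts = tuple(float(t) for t in self.output_times)
            _require(
                all(b > a for a, b in zip(ts, ts[1:])),
                "output_times",
                "must be strictly increasing",
            )
            _require(ts[0] >= 0, "output_times", "must start at >= 0")
            object.__setattr__(self, "output_times", ts)


AlphaMode = Literal["simplified", "exact"]


@dataclass(frozen=True)
class RunConfig:
    """Full parameter set for one simulated experiment."""

    configuration: Literal["a", "b"]
    geometry: ModuleGeometry
    equilibrium: EquilibriumParams
    operating: OperatingConditions
    transport: TransportParams
    numerics: NumericsConfig = field(default_factory=NumericsConfig)
    alpha_mode: AlphaMode = "simplified"

    def __post_init__(self) -> None:
        if self.configuration not in ("a", "b"):
            raise ValidationError("configuration: must be 'a' or 'b'")
        if self.alpha_mode not in ("simplified", "exact"):
            raise ValidationError("alpha_mode: must be 'simplified' or 'exact'")
        if self.configuration == "b":
            _require(
                self.geometry.adsorbent_layer_thickness > 0,
                "adsorbent_layer_thickness",
                "must be > 0 for configuration B",
            )
        if self.numerics.output_times is not None:
            _require(
                self.numerics.output_times[-1] <= self.operating.duration,
                "output_times",
                "must lie within [0, duration]",
            )

    def with_updates(self, **section_updates) -> "RunConfig":
        """Return a copy with named fields replaced, e.g.
        ``cfg.with_updates(operating={"adsorbent_mass": 0.03})``."""
        changes = {}
        for section, upd in section_updates.items():
            current = getattr(self, section)
            if isinstance(upd, dict):
                changes[section] = replace(current, **upd)
            else:
                changes[section] = upd
        return replace(self, **changes)


# -- defaults: the two experimental configurations ----------------------------

def default_config_a(adsorbent_mass: float = 0.7) -> RunConfig:
    """Configuration A: fibers immersed in 65 mL of albumin dialysate with
    suspended adsorbent microspheres (default inventory 700 mg).

    Blood: 14.3 µmol/L total bilirubin, 1.42 µmol/L albumin, 0.4 mL/min.
    Fitted transport: k = 2.04 cm/min, PΣ = 57.67 cm/min, m′ = 0.33 L/g.
    """
    return RunConfig(
        configuration="a",
        geometry=ModuleGeometry(
            fiber_count=45,
            fiber_inner_radius=0.009,
            module_length=4.0,
            adsorbent_layer_thickness=0.0,
        ),
        equilibrium=EquilibriumParams(
            binding_constant=10.0,  # 1e7 M^-1, lower end of the bilirubin-albumin range
            isotherm_slope=0.33,
            albumin_conc_blood=1.42,
            albumin_conc_dialysate=5.75,
            albumin_conc_solid=5.75,
        ),
        operating=OperatingConditions(
            inlet_toxin_conc=14.3,
            blood_flow=0.4,
            dialysate_volume=65.0,
            adsorbent_mass=adsorbent_mass,
            particle_density=0.2,
        ),
        transport=TransportParams(
            global_exchange_coeff=57.67,
            solid_exchange_coeff=2.04,
        ),
    )


def default_config_b() -> RunConfig:
    """Configuration B: no dialysate; microspheres bound to the outer fiber
    surface as a 50 µm layer (one particle diameter).

    Fitted transport: PΣ′ = 0.83 cm/min, m′ = 0.13 L/g.  The solid-phase
    free fraction defaults to the blood value (symmetric partitioning).
    """
    return RunConfig(
        configuration="b",
        geometry=ModuleGeometry(
            fiber_count=45,
            fiber_inner_radius=0.009,
            module_length=4.0,
            adsorbent_layer_thickness=50e-4,
        ),
        equilibrium=EquilibriumParams(
            binding_constant=10.0,
            isotherm_slope=0.13,
            albumin_conc_blood=1.42,
            albumin_conc_dialysate=0.0,
            albumin_conc_solid=1.42,
        ),
        operating=OperatingConditions(
            inlet_toxin_conc=14.3,
            blood_flow=0.4,
            dialysate_volume=65.0,
            adsorbent_mass=0.1,
            particle_density=0.2,
        ),
        transport=TransportParams(global_exchange_coeff=0.83),
    )


# -- file I/O -----------------------------------------------------------------

_SECTION_TYPES = {
    "geometry": ModuleGeometry,
    "equilibrium": EquilibriumParams,
    "operating": OperatingConditions,
    "transport": TransportParams,
    "numerics": NumericsConfig,
}
_TOP_KEYS = {"configuration", "alpha_mode", *_SECTION_TYPES}


def _build_section(name: str, cls, data: dict):
    if not isinstance(data, dict):
        raise SchemaError(f"section '{name}' must be a mapping")
    import dataclasses as _dc

    fields = {f.name for f in _dc.fields(cls)}
    required = {
        f.name
        for f in _dc.fields(cls)
        if f.default is _dc.MISSING and f.default_factory is _dc.MISSING
    }
    extra = set(data) - fields
    if extra:
        raise SchemaError(f"section '{name}': unknown key(s) {sorted(extra)}")
    missing = required - set(data)
    if missing:
        raise SchemaError(f"section '{name}': missing key(s) {sorted(missing)}")
    if "output_times" in data and data["output_times"] is not None:
        data = dict(data, output_times=tuple(data["output_times"]))
    return cls(**data)


def load_config(path: str | Path) -> RunConfig:
    """Read a YAML or JSON run-config file into a validated :class:`RunConfig`.

    The file must contain the blocks ``geometry`` / ``equilibrium`` /
    ``operating`` / ``transport`` (``numerics`` optional) plus the scalar
    keys ``configuration`` ("a" or "b") and optional ``alpha_mode``.
    Units are fixed by the schema: cm, mL, min, µmol/L, g, L/µmol, L/g.
    """
    path = Path(path)
    text = path.read_text()
    if path.suffix.lower() == ".json":
        raw = json.loads(text)
    else:
        raw = yaml.safe_load(text)
    if not isinstance(raw, dict):
        raise SchemaError("run config must be a mapping at top level")
    extra = set(raw) - _TOP_KEYS
    if extra:
        raise SchemaError(f"unknown top-level key(s) {sorted(extra)}")
    missing = ({"configuration"} | set(_SECTION_TYPES) - {"numerics"}) - set(raw)
    if missing:
        raise SchemaError(f"missing top-level key(s) {sorted(missing)}")
    sections = {
        name: _build_section(name, cls, dict(raw[name]))
        for name, cls in _SECTION_TYPES.items()
        if name in raw
    }
    return RunConfig(
        configuration=raw["configuration"],
        alpha_mode=raw.get("alpha_mode", "simplified"),
        **sections,
    )


def write_config(config: RunConfig, path: str | Path) -> Path:
    """Serialize a :class:`RunConfig` to YAML or JSON (by file suffix)."""
    path = Path(path)
    doc = {
        "configuration": config.configuration,
        "alpha_mode": config.alpha_mode,
        **{name: asdict(getattr(config, name)) for name in _SECTION_TYPES},
    }
    if doc["numerics"]["output_times"] is not None:
        doc["numerics"]["output_times"] = list(doc["numerics"]["output_times"])
    if path.suffix.lower() == ".json":
        path.write_text(json.dumps(doc, indent=2))
    else:
        header = (
            "# hepadial run configuration\n"
            "# units: lengths cm, volumes mL, time min, concentrations umol/L,\n"
            "#        masses g, binding constant L/umol, isotherm slope L/g\n"
        )
        path.write_text(header + yaml.safe_dump(doc, sort_keys=False))
    return path
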