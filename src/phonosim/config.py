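"""Run configuration: YAML parsing, unit conversion, validation, presets.

All internal quantities are SI; config files may give values either as
plain numbers (interpreted as SI) or as strings with a unit suffix
("0.8 kPa", "3.05 cm", "5 poise", "1.043 g/cm3", "45 deg").  Mixed-unit
conversion happens once at load time and every validation failure across
the whole file is reported together.

Two presets ship with the package: ``desk2d`` (the runnable desk-scale
2D phonation case) and ``paper3d`` (full-scale 3D constants for
documentation/reference; loading it works, running it is outside the
desk scope).
"""

from __future__ import annotations

import copy
import math
from dataclasses import dataclass, field

import numpy as np
import yaml

from .acoustics import AcousticProperties
from .coupling import ContactModel, CouplingConfig, SimulationSetup
from .flow import FluidProperties
from .geometry import DuctSpec, FoldSpec
from .grid import GridSpec, stretched_axis
from .solid import MaterialLayer

__all__ = ["RunConfig", "ConfigError", "load_config", "save_config", "PRESETS", "parse_quantity"]


_UNITS = {
    "m": 1.0, "cm": 1e-2, "mm": 1e-3, "um": 1e-6,
    "s": 1.0, "ms": 1e-3, "us": 1e-6,
    "hz": 1.0, "khz": 1e3,
    "pa": 1.0, "kpa": 1e3,
    "poise": 0.1, "p": 0.1, "pa.s": 1.0, "pa*s": 1.0,
    "g/cm3": 1e3, "kg/m3": 1.0,
    "m2/s": 1.0, "m/s": 1.0,
    "deg": math.pi / 180.0, "rad": 1.0,
}


class ConfigError(ValueError):
    """Aggregated configuration problems."""

    def __init__(self, problems):
        self.problems = list(problems)
        super().__init__(
            "invalid configuration:\n  - " + "\n  - ".join(self.problems)
        )


def parse_quantity(value):
    """Number -> SI float; '3.05 cm' style strings are unit-converted."""
    if isinstance(value, (int, float)):
        return float(value)
    if isinstance(value, str):
        parts = value.split()
        if len(parts) == 1:
            return float(parts[0])
        if len(parts) == 2:
            mag = float(parts[0])
            unit = parts[1].lower()
            if unit not in _UNITS:
                raise ValueError(f"unknown unit {parts[1]!r} in {value!r}")
            return mag * _UNITS[unit]
    raise ValueError(f"cannot parse quantity {value!r}")


def _convert(d: dict, skip=()) -> dict:
    out = {}
    for k, v in d.items():
        if k in skip:
            out[k] = v
        elif isinstance(v, (int, float, str)) and not isinstance(v, bool):
            try:
                out[k] = parse_quantity(v)
            except ValueError:
                out[k] = v
        else:
            out[k] = v
    return out


@dataclass
class GridParams:
    """Stretched tensor-grid description (built lazily into a GridSpec)."""

    nx: int = 40
    ny: int = 90
    nz: int = 0
    x_pad: float = 1.5e-3    # margin beyond the duct wall so it is immersed
    x_ratio: float = 10.0    # coarsest/finest cell ratio away from the midline
    y_ratio: float = 16.0    # coarsest/finest cell ratio away from the glottis
    x_width: float = 0.12    # relative extent of the refined x band
    y_width: float = 0.06    # relative extent of the refined y band

    def build(self, duct: DuctSpec, fold: FoldSpec) -> GridSpec:
        half = float(np.max(duct.profile(duct.stations()))) + self.x_pad
        gx = stretched_axis(-half, half, self.nx, focus=0.0, ratio=self.x_ratio,
                            width=self.x_width)
        gy = stretched_axis(
            duct.y_min, duct.y_max, self.ny, focus=fold.thickness / 2.0,
            ratio=self.y_ratio, width=self.y_width,
        )
        axes = [gx, gy]
        if duct.dimension == 3:
            gz = np.linspace(-self.x_pad, fold.length + self.x_pad, max(self.nz, 9))
            axes.append(gz)
        return GridSpec(axes)


@dataclass
class OutputConfig:
    probes: list = field(default_factory=list)       # (x, y) points
    outlet_plane: float | None = None
    effective_depth: float = 0.016
    record_every: int = 1
    snapshot_every: int = 10
    log_every: int = 200


@dataclass
class RunConfig:
    name: str = "custom"
    seed: int = 0
    duct: DuctSpec = field(default_factory=DuctSpec)
    fold: FoldSpec = field(default_factory=FoldSpec)
    grid: GridParams = field(default_factory=GridParams)
    fluid: FluidProperties = field(default_factory=FluidProperties)
    acoustic: AcousticProperties = field(default_factory=AcousticProperties)
    materials: dict = field(default_factory=dict)
    contact: ContactModel = field(default_factory=ContactModel)
    coupling: CouplingConfig = field(default_factory=CouplingConfig)
    outputs: OutputConfig = field(default_factory=OutputConfig)
    target_elements: int = 400
    upwind: float = 0.4
    filter_strength: float = 0.2
    include_viscous_traction: bool = True
    pressure_ramp: float = 1.0e-3
    rigid_folds: bool = False
    static_init_steps: int = 0

    def setup(self) -> SimulationSetup:
        """Materialize the grid and bundle everything for a Simulation."""
        grid = self.grid.build(self.duct, self.fold)
        return SimulationSetup(
            duct=self.duct,
            fold=self.fold,
            grid=grid,
            fluid=self.fluid,
            acoustic=self.acoustic,
            materials=self.materials,
            contact=self.contact,
            coupling=self.coupling,
            target_elements=self.target_elements,
            upwind=self.upwind,
            filter_strength=self.filter_strength,
            include_viscous_traction=self.include_viscous_traction,
            probes=tuple(tuple(p) for p in self.outputs.probes),
            outlet_plane=self.outputs.outlet_plane,
            effective_depth=self.outputs.effective_depth,
            rigid_folds=self.rigid_folds,
            pressure_ramp=self.pressure_ramp,
            static_init_steps=self.static_init_steps,
        )

    def as_dict(self) -> dict:
        def clean(obj):
            if hasattr(obj, "__dataclass_fields__"):
                return {
                    k: clean(getattr(obj, k)) for k in obj.__dataclass_fields__
                }
            if isinstance(obj, dict):
                return {k: clean(v) for k, v in obj.items()}
            if isinstance(obj, (list, tuple)):
                return [clean(v) for v in obj]
            if isinstance(obj, (np.floating, np.integer)):
                return obj.item()
            return obj

        d = {
            "name": self.name,
            "seed": self.seed,
            "geometry": {
                "duct": clean(self.duct),
                "fold": clean(self.fold),
                "target_elements": self.target_elements,
            },
            "grid": clean(self.grid),
            "fluid": clean(self.fluid),
            "acoustic": clean(self.acoustic),
            "materials": clean(self.materials),
            "contact": clean(self.contact),
            "coupling": clean(self.coupling),
            "outputs": clean(self.outputs),
            "numerics": {
                "upwind": self.upwind,
                "filter_strength": self.filter_strength,
                "include_viscous_traction": self.include_viscous_traction,
                "pressure_ramp": self.pressure_ramp,
                "rigid_folds": self.rigid_folds,
                "static_init_steps": self.static_init_steps,
            },
        }
        return d


# ---------------------------------------------------------------------------
# presets
# ---------------------------------------------------------------------------

# Reference material constants of the cover / ligament / body layers
# (stored in the mixed units conventional for tissue data; converted at load).
_MATERIALS = {
    "cover": {"rho": "1.043 g/cm3", "E_p": "2.01 kPa", "nu_p": 0.9,
              "E_pz": "40 kPa", "nu_pz": 0.0, "G_pz": "10 kPa", "eta": "5 poise"},
    "ligament": {"rho": "1.043 g/cm3", "E_p": "3.31 kPa", "nu_p": 0.9,
                 "E_pz": "66 kPa", "nu_pz": 0.0, "G_pz": "40 kPa", "eta": "7.5 poise"},
    "body": {"rho": "1.043 g/cm3", "E_p": "3.99 kPa", "nu_p": 0.9,
             "E_pz": "80 kPa", "nu_pz": 0.0, "G_pz": "20 kPa", "eta": "12.5 poise"},
}

_STIFFEN_2D = 5.0
_MATERIALS_2D = {
    name: {
        **props,
        "E_p": f"{float(props['E_p'].split()[0]) * _STIFFEN_2D:g} kPa",
        "E_pz": f"{float(props['E_pz'].split()[0]) * _STIFFEN_2D:g} kPa",
        "G_pz": f"{float(props['G_pz'].split()[0]) * _STIFFEN_2D:g} kPa",
    }
    for name, props in _MATERIALS.items()
}

PRESETS: dict = {
    # runnable desk-scale 2D phonation case
    "desk2d": {
        "name": "desk2d",
        "seed": 0,
        "geometry": {
            "duct": {"sub_length": "3.05 cm", "supra_length": "17.4 cm",
                     "half_width": "9 mm", "glottal_span": "6 mm", "dimension": 2},
            "fold": {"depth": "8.8 mm", "thickness": "6 mm", "length": "16 mm",
                     "half_gap": "0.2 mm", "entry_angle": "45 deg",
                     "exit_angle": "45 deg", "entry_frac": 0.5, "exit_frac": 0.2,
                     "cover": "0.5 mm", "ligament": "1.1 mm", "mount_x": "4 mm"},
            "target_elements": 400,
        },
        "grid": {"nx": 44, "ny": 96, "x_pad": "1.5 mm", "x_ratio": 10, "y_ratio": 16,
                 "x_width": 0.12, "y_width": 0.06},
        "fluid": {"rho0": "1.1455 kg/m3", "nu0": "6.6e-5 m2/s", "dp_drive": "0.8 kPa"},
        "acoustic": {"gamma": 1.4, "c": "352 m/s"},
        # 2D plane-strain equivalent stiffness: the reference transverse
        # moduli scaled x5 to stand in for the longitudinal-tension and
        # anterior/posterior-attachment stiffening of the 3D fold
        "materials": _MATERIALS_2D,
        "contact": {"plane_offset": "0.1 mm", "min_gap": "0.2 mm"},
        "coupling": {"dt_flow": "2.5e-6 s", "n_subcycles": 20, "n_steps": 20000,
                     "record_every": 1, "snapshot_every": 10, "seed": 0,
                     "perturb": 0.0},
        "outputs": {"probes": [["0 mm", "10 mm"]], "effective_depth": "16 mm",
                    "snapshot_every": 10, "log_every": 200},
        "numerics": {"upwind": 0.4, "filter_strength": 0.2,
                     "include_viscous_traction": True, "pressure_ramp": "1 ms",
                     "static_init_steps": 800},
    },
    # full-scale 3D constants (reference only: grid and cost are cluster scale)
    "paper3d": {
        "name": "paper3d",
        "seed": 0,
        "geometry": {
            "duct": {"sub_length": "3.05 cm", "supra_length": "17.4 cm",
                     "half_width": "9 mm", "glottal_span": "6 mm", "dimension": 3},
            "fold": {"depth": "8.8 mm", "thickness": "6 mm", "length": "16 mm",
                     "half_gap": "0.2 mm", "cover": "0.5 mm", "ligament": "1.1 mm"},
            "target_elements": 28997,
        },
        "grid": {"nx": 64, "ny": 256, "nz": 192, "x_pad": "1.5 mm",
                 "x_ratio": 8, "y_ratio": 14},
        "fluid": {"rho0": "1.1455 kg/m3", "nu0": "6.6e-5 m2/s", "dp_drive": "0.8 kPa"},
        "acoustic": {"gamma": 1.4, "c": "352 m/s"},
        "materials": _MATERIALS,
        "contact": {"plane_offset": "0.1 mm", "min_gap": "0.2 mm"},
        "coupling": {"dt_flow": "1.149e-6 s", "n_subcycles": 20, "n_steps": 60000,
                     "record_every": 1, "snapshot_every": 20, "seed": 0,
                     "perturb": 0.0},
        "outputs": {"probes": [["0 mm", "10 mm"]], "effective_depth": "16 mm"},
        "numerics": {"upwind": 0.4, "filter_strength": 0.2,
                     "include_viscous_traction": True, "pressure_ramp": "1 ms"},
    },
}


# ---------------------------------------------------------------------------
# loading
# ---------------------------------------------------------------------------


def load_config(source) -> RunConfig:
    """Load a RunConfig from a YAML path, YAML string, dict or preset name.

    All validation failures (unknown keys, bad units, violated invariants,
    cross-field inconsistencies) are collected and raised together.
    """
    if isinstance(source, dict):
        raw = copy.deepcopy(source)
    elif isinstance(source, str) and source in PRESETS:
        raw = copy.deepcopy(PRESETS[source])
    else:
        text = None
        try:
            with open(source) as fh:
                text = fh.read()
        except (OSError, TypeError):
            if isinstance(source, str):
                text = source
            else:
                raise
        raw = yaml.safe_load(text)
    if not isinstance(raw, dict):
        raise ConfigError(["configuration root must be a mapping"])

    problems: list = []
    known = {"name", "seed", "geometry", "grid", "fluid", "acoustic",
             "materials", "contact", "coupling", "outputs", "numerics"}
    for k in raw:
        if k not in known:
            problems.append(f"unknown top-level key {k!r}")

    def build(cls, data, label, skip=(), intfields=()):
        try:
            conv = _convert(data or {}, skip=skip)
            for f_ in intfields:
                if f_ in conv:
                    conv[f_] = int(conv[f_])
            return cls(**conv)
        except (TypeError, ValueError) as e:
            problems.append(f"{label}: {e}")
            return None

    geo = raw.get("geometry", {}) or {}
    duct_raw = dict(geo.get("duct", {}) or {})
    # half_width is either a scalar-with-unit or a (stations, values) table
    hw = duct_raw.get("half_width")
    try:
        if isinstance(hw, (list, tuple)) and len(hw) == 2:
            duct_raw["half_width"] = (
                [parse_quantity(v) for v in hw[0]],
                [parse_quantity(v) for v in hw[1]],
            )
        elif hw is not None:
            duct_raw["half_width"] = parse_quantity(hw)
    except ValueError as e:
        problems.append(f"geometry.duct.half_width: {e}")
    duct = build(DuctSpec, duct_raw, "geometry.duct",
                 skip=("half_width",), intfields=("dimension",))
    fold = build(FoldSpec, geo.get("fold", {}), "geometry.fold")
    grid = build(GridParams, raw.get("grid", {}), "grid",
                 intfields=("nx", "ny", "nz"))
    fluid = build(FluidProperties, raw.get("fluid", {}), "fluid")
    acoustic = build(AcousticProperties, raw.get("acoustic", {}), "acoustic")
    contact = build(ContactModel, raw.get("contact", {}), "contact")
    coupling = build(CouplingConfig, raw.get("coupling", {}), "coupling",
                     intfields=("n_subcycles", "n_steps", "record_every",
                                "snapshot_every", "seed"))
    materials = {}
    for name, props in (raw.get("materials") or {}).items():
        layer = build(MaterialLayer, props, f"materials.{name}")
        if layer is not None:
            materials[name] = layer
    for need in ("cover", "ligament", "body"):
        if raw.get("materials") and need not in materials and not any(
            p.startswith(f"materials.{need}") for p in problems
        ):
            problems.append(f"materials: missing layer {need!r}")

    out_raw = _convert(raw.get("outputs", {}) or {}, skip=("probes",))
    probes = []
    for p in out_raw.pop("probes", []) or []:
        try:
            probes.append(tuple(parse_quantity(v) for v in p))
        except ValueError as e:
            problems.append(f"outputs.probes: {e}")
    for f_ in ("record_every", "snapshot_every", "log_every"):
        if f_ in out_raw:
            out_raw[f_] = int(out_raw[f_])
    try:
        outputs = OutputConfig(probes=probes, **out_raw)
    except TypeError as e:
        problems.append(f"outputs: {e}")
        outputs = OutputConfig()

    num = _convert(raw.get("numerics", {}) or {})

    # cross-field checks
    if duct is not None and fold is not None:
        wall = float(np.min(duct.profile(np.linspace(0, duct.glottal_span, 9))))
        if fold.base_x < wall - 1e-9:
            problems.append(
                "geometry: fold base (half_gap + depth = "
                f"{fold.base_x:.4g} m) does not reach the duct wall at "
                f"{wall:.4g} m, leaving a gap behind the folds"
            )
        if abs(duct.glottal_span - fold.thickness) > 1e-9:
            problems.append(
                "geometry: duct glottal_span must equal the fold thickness"
            )
    if coupling is not None and acoustic is not None and grid is not None \
            and duct is not None and fold is not None:
        g = grid.build(duct, fold)
        dt_ac = coupling.dt_flow / coupling.n_subcycles
        inv = sum(1.0 / g.min_width(ax) for ax in range(g.dim))
        if dt_ac * acoustic.c * inv > 1.35:
            problems.append(
                f"coupling: acoustic CFL {dt_ac * acoustic.c * inv:.2f} "
                "exceeds the stability limit 1.35; reduce dt_flow or coarsen"
            )

    if problems:
        raise ConfigError(problems)

    return RunConfig(
        name=raw.get("name", "custom"),
        seed=int(raw.get("seed", 0)),
        duct=duct,
        fold=fold,
        grid=grid,
        fluid=fluid,
        acoustic=acoustic,
        materials=materials or None or {},
        contact=contact,
        coupling=coupling,
        outputs=outputs,
        target_elements=int(geo.get("target_elements", 400)),
        upwind=float(num.get("upwind", 0.15)),
        filter_strength=float(num.get("filter_strength", 0.2)),
        include_viscous_traction=bool(num.get("include_viscous_traction", True)),
        pressure_ramp=float(num.get("pressure_ramp", 1.0e-3)),
        rigid_folds=bool(num.get("rigid_folds", False)),
        static_init_steps=int(num.get("static_init_steps", 0)),
    )


def save_config(cfg: RunConfig, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(cfg.as_dict(), fh, sort_keys=False)
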