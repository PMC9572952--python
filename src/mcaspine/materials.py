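"""Tissue material presets, derived poroelastic constants and run configuration.

Each tissue is described by the elastic constants of its solid matrix
(``E``, ``nu``), the bulk modulus of the skeleton material ``Ks``, and the
pore-space parameters (porosity ``phi0``, intrinsic permeability ``k0``).
Secondary constants are derived on construction:

* bulk and shear moduli ``K = E/(3(1-2nu))``, ``G = E/(2(1+nu))``;
* Biot ratio ``a = 1 - K/Ks`` weighting the pore-pressure contribution to
  the effective stress;
* filtration-channel diameter ``d_ch = sqrt(k0/phi0)`` such that the
  permeability law ``k = phi * d_ch**2`` reproduces ``k0`` at ``phi0``.

The five-region preset table (annulus fibrosus AF, nucleus pulposus NP,
cartilaginous endplate CEP, cortical and cancellous bone) and the
degeneration-stage overrides are shipped as YAML data files.
"""

from __future__ import annotations

import enum
import json
import math
from dataclasses import dataclass, field, asdict
from importlib import resources
from pathlib import Path
from typing import Mapping

import yaml

from .errors import ConfigError, InvalidMaterialError

__all__ = [
    "Material",
    "FluidSpec",
    "DegenerationStage",
    "DegenerationMode",
    "derive_elastic_moduli",
    "derive_biot_ratio",
    "derive_channel_diameter",
    "tissue_presets",
    "degeneration_table",
    "load_presets",
    "dump_presets_json",
    "load_run_config",
    "RunConfig",
]

REGIONS = ("AF", "NP", "CEP", "cortical", "cancellous")
DISC_REGIONS = ("AF", "NP", "CEP")


def derive_elastic_moduli(E: float, nu: float) -> tuple[float, float]:
    """Return macroscopic bulk and shear moduli (K, G) of an isotropic solid."""
    if E <= 0:
        raise InvalidMaterialError(f"Young's modulus must be positive, got {E}")
    if not -1.0 < nu < 0.5:
        raise InvalidMaterialError(f"Poisson's ratio must be in (-1, 0.5), got {nu}")
    K = E / (3.0 * (1.0 - 2.0 * nu))
    G = E / (2.0 * (1.0 + nu))
    return K, G


def derive_biot_ratio(K: float, Ks: float) -> float:
    """Biot ratio a = 1 - K/Ks; zero for an incompressible-skeleton limit K = Ks."""
    if K <= 0 or Ks <= 0:
        raise InvalidMaterialError("bulk moduli must be positive")
    if K > Ks:
        raise InvalidMaterialError(
            f"macroscopic bulk modulus K={K:g} exceeds skeleton modulus Ks={Ks:g} "
            "(would give a negative Biot ratio)"
        )
    return 1.0 - K / Ks


def derive_channel_diameter(k0: float, phi0: float) -> float:
    """Filtration-channel diameter d_ch with k = phi * d_ch**2."""
    if phi0 <= 0:
        raise InvalidMaterialError(f"porosity must be positive, got {phi0}")
    if k0 < 0:
        raise InvalidMaterialError(f"permeability must be non-negative, got {k0}")
    return math.sqrt(k0 / phi0)


@dataclass(frozen=True)
class Material:
    """Elastic + poroelastic parameter bundle for one tissue.

    Parameters are SI throughout (Pa, kg/m^3, m^2).  Derived fields are
    computed in ``__post_init__`` and always satisfy the construction
    invariants (see module docstring).
    """

    name: str
    rho_matrix: float
    E: float
    nu: float
    Ks: float
    phi0: float
    k0: float
    # derived
    K: float = field(init=False)
    G: float = field(init=False)
    a: float = field(init=False)
    d_ch: float = field(init=False)

    def __post_init__(self) -> None:
        if self.rho_matrix <= 0:
            raise InvalidMaterialError(f"{self.name}: density must be positive")
        if not 0.0 < self.phi0 < 1.0:
            raise InvalidMaterialError(f"{self.name}: porosity must be in (0, 1)")
        K, G = derive_elastic_moduli(self.E, self.nu)
        if self.nu <= 0:
            raise InvalidMaterialError(f"{self.name}: Poisson's ratio must be positive")
        a = derive_biot_ratio(K, self.Ks)
        d_ch = derive_channel_diameter(self.k0, self.phi0)
        object.__setattr__(self, "K", K)
        object.__setattr__(self, "G", G)
        object.__setattr__(self, "a", a)
        object.__setattr__(self, "d_ch", d_ch)

    def replace(self, **kw) -> "Material":
        base = dict(
            name=self.name, rho_matrix=self.rho_matrix, E=self.E, nu=self.nu,
            Ks=self.Ks, phi0=self.phi0, k0=self.k0,
        )
        base.update(kw)
        return Material(**base)


@dataclass(frozen=True)
class FluidSpec:
    """Interstitial fluid: salt water with a linear equation of state."""

    rho0: float = 1000.0     # equilibrium density, kg/m^3
    P0: float = 0.0          # equilibrium (gauge) pore pressure, Pa
    K_fl: float = 2.4e9      # bulk modulus, Pa
    eta: float = 1.0e-3      # dynamic viscosity, Pa s

    def __post_init__(self) -> None:
        if self.rho0 <= 0 or self.K_fl <= 0 or self.eta <= 0:
            raise InvalidMaterialError("fluid density, bulk modulus and viscosity must be positive")
        if self.P0 < 0:
            raise InvalidMaterialError("equilibrium pore pressure must be non-negative")


class DegenerationStage(str, enum.Enum):
    healthy = "healthy"
    stage1 = "stage1"
    stage2 = "stage2"


class DegenerationMode(str, enum.Enum):
    """Which aspects of disc degeneration are applied.

    geometry_only   - disc height reduced, tissue properties healthy
    properties_only - AF/NP poroelastic properties degraded, height healthy
    combined        - both
    healthy         - neither (baseline)
    """

    healthy = "healthy"
    geometry_only = "geometry_only"
    properties_only = "properties_only"
    combined = "combined"


def _coerce_floats(obj):
    # YAML 1.1 reads exponents without a sign ("2.5e6") as strings
    if isinstance(obj, dict):
        return {k: _coerce_floats(v) for k, v in obj.items()}
    if isinstance(obj, str):
        try:
            return float(obj)
        except ValueError:
            return obj
    return obj


def _load_yaml_resource(name: str) -> dict:
    with resources.files("mcaspine.data").joinpath(name).open("r") as fh:
        return _coerce_floats(yaml.safe_load(fh))


def tissue_presets() -> dict[str, Material]:
    """The five-region healthy tissue table as Material objects."""
    raw = _load_yaml_resource("tissues.yaml")
    return {name: Material(name=name, **params) for name, params in raw.items()}


def degeneration_table() -> dict:
    """Raw degeneration-stage data (heights and AF/NP overrides)."""
    table = _load_yaml_resource("degeneration.yaml")
    # consistency guard: the stage-0 reference moduli of the degeneration data
    # set must equal the healthy tissue table
    tissues = _load_yaml_resource("tissues.yaml")
    for region in ("AF", "NP"):
        e0 = table["stage0"][region]["E"]
        if not math.isclose(e0, tissues[region]["E"], rel_tol=1e-12):
            raise ConfigError(
                f"degeneration stage-0 Young's modulus for {region} ({e0:g} Pa) "
                f"does not match the healthy tissue table ({tissues[region]['E']:g} Pa)"
            )
    return table


def disc_height_mm(stage: DegenerationStage | str) -> float:
    stage = DegenerationStage(stage)
    return float(degeneration_table()["stages"][stage.value]["disc_height"])


def load_presets(
    stage: DegenerationStage | str,
    mode: DegenerationMode | str,
) -> tuple[dict[str, Material], float]:
    """Resolve the per-region material table and disc height for a scenario.

    Returns ``(materials, disc_height_mm)``.  AF/NP are overridden with the
    degeneration-stage values when ``mode`` involves properties; CEP,
    cortical and cancellous always keep their healthy values.  The disc
    height departs from 10 mm only when ``mode`` involves geometry.
    """
    stage = DegenerationStage(stage)
    mode = DegenerationMode(mode)
    table = degeneration_table()
    mats = tissue_presets()

    if stage is DegenerationStage.healthy or mode is DegenerationMode.healthy:
        return mats, float(table["stages"]["healthy"]["disc_height"])

    stage_row = table["stages"][stage.value]
    if mode in (DegenerationMode.properties_only, DegenerationMode.combined):
        for region in ("AF", "NP"):
            ov = stage_row[region]
            mats[region] = mats[region].replace(E=ov["E"], phi0=ov["phi0"], k0=ov["k0"])
    if mode in (DegenerationMode.geometry_only, DegenerationMode.combined):
        height = float(stage_row["disc_height"])
    else:
        height = float(table["stages"]["healthy"]["disc_height"])
    return mats, height


def dump_presets_json(path: str | Path) -> Path:
    """Write the material presets (with derived constants) as JSON."""
    path = Path(path)
    payload = {name: asdict(mat) for name, mat in tissue_presets().items()}
    payload["_degeneration"] = degeneration_table()
    path.write_text(json.dumps(payload, indent=2, sort_keys=True))
    return path


# ----------------------------------------------------------------------------
# Run configuration
# ----------------------------------------------------------------------------

@dataclass
class RunConfig:
    """Resolved contents of a YAML run configuration.

    Sections: ``geometry`` (segment recipe fields), ``materials`` (optional
    per-region overrides), ``degeneration`` (stage + mode), ``loading``
    (speed m/s, stop force N, ramp s), ``output`` (directory, snapshot
    forces N).  Every driver writes a resolved copy next to its outputs.
    """

    geometry: dict = field(default_factory=dict)
    materials: dict = field(default_factory=dict)
    degeneration: dict = field(default_factory=lambda: {"stage": "healthy", "mode": "healthy"})
    loading: dict = field(default_factory=lambda: {"speed": 0.1, "stop_force": 500.0})
    output: dict = field(default_factory=dict)
    numerics: dict = field(default_factory=dict)
    seed: int = 0

    def resolved_yaml(self) -> str:
        return yaml.safe_dump(asdict(self), sort_keys=True)


_KNOWN_SECTIONS = {"geometry", "materials", "degeneration", "loading", "output", "numerics", "seed"}


def load_run_config(path: str | Path) -> RunConfig:
    raw = yaml.safe_load(Path(path).read_text()) or {}
    if not isinstance(raw, dict):
        raise ConfigError(f"run config must be a mapping, got {type(raw).__name__}")
    unknown = set(raw) - _KNOWN_SECTIONS
    if unknown:
        raise ConfigError(f"unknown config sections: {sorted(unknown)}")
    cfg = RunConfig(**raw)
    try:
        DegenerationStage(cfg.degeneration.get("stage", "healthy"))
        DegenerationMode(cfg.degeneration.get("mode", "healthy"))
    except ValueError as exc:
        raise ConfigError(str(exc)) from exc
    if cfg.loading.get("speed", 0.1) <= 0:
        raise ConfigError("loading speed must be positive")
    return cfg


def material_property_arrays(
    materials: Mapping[str, Material],
    region_of_particle,
    fluid: FluidSpec | None,
):
    """Per-particle property arrays used by the solver kernels.

    ``region_of_particle`` is an integer array indexing into REGIONS order of
    the supplied mapping; returns a dict of float64 arrays.
    """
    import numpy as np

    names = list(materials)
    lut = {n: i for i, n in enumerate(names)}
    idx = np.asarray([lut[n] if isinstance(n, str) else n for n in region_of_particle])

    def gather(attr):
        vals = np.array([getattr(materials[n], attr) for n in names])
        return vals[idx]

    props = {attr: gather(attr) for attr in ("rho_matrix", "E", "nu", "K", "G", "a", "phi0", "k0", "d_ch")}
    if fluid is not None:
        props["rho_eff"] = props["rho_matrix"] + props["phi0"] * fluid.rho0
    else:
        props["rho_eff"] = props["rho_matrix"].copy()
    return props
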