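"""Material specifications for drug-glass / mesoporous-silica mixtures.

The downstream analyses (loading geometry, fraction decomposition, CRR
sizing) all consume the same small set of material constants: the textural
properties of a mesoporous silica grade and the thermophysical properties
of the drug glass.  This module declares those bundles as validated
pydantic models and parses them from a flat YAML config.

Unit convention: config files use the units practitioners report
(m²/g, nm, mL/g, µm, g/mol, g/cm³, J/(g·K), °C).  Properties with an
``_si`` suffix expose SI values (m²/kg, m, m³/kg, kg/m³, J/(kg·K), K)
for computation, so Boltzmann-constant formulas never mix unit systems.
"""

from __future__ import annotations

import warnings
from typing import Optional

import yaml
from pydantic import BaseModel, ConfigDict, Field, model_validator

__all__ = [
    "MesoporousSilicaSpec",
    "GlassSubstanceSpec",
    "MixtureSpec",
    "ConfigError",
    "load_materials",
    "load_materials_file",
    "CELECOXIB_MOLAR_MASS",
    "BUILTIN_SILICAS",
    "BUILTIN_SUBSTANCES",
]

#: Molar mass of celecoxib, C17H14F3N3O2S, in g/mol.  A universal constant
#: shipped as a documented default; always overridable via config.
CELECOXIB_MOLAR_MASS = 381.37


class ConfigError(ValueError):
    """A materials config document is malformed (missing/unknown keys)."""


class MesoporousSilicaSpec(BaseModel):
    """Textural properties of one mesoporous silica grade.

    Parameters
    ----------
    name : str
        Grade label, e.g. ``"SYL350"``.
    surface_area : float
        Specific surface area in m²/g.
    pore_diameter : float
        Effective pore diameter in nm (treated as a single effective
        diameter; vendors may quote mean or mode).
    pore_volume : float
        Specific pore volume in mL/g.
    particle_diameter : float
        Particle diameter in µm.
    """

    model_config = ConfigDict(extra="forbid", frozen=True)

    name: str
    surface_area: float = Field(gt=0)
    pore_diameter: float = Field(gt=0)
    pore_volume: float = Field(gt=0)
    particle_diameter: float = Field(gt=0)

    @model_validator(mode="after")
    def _cylinder_consistency(self) -> "MesoporousSilicaSpec":
        # For cylindrical pores d = 4 V_p / SA.  A factor-of-two disagreement
        # with the declared diameter is tolerated (real pore-size
        # distributions are broad); outside that we warn but do not reject.
        d_cyl_nm = 4.0 * (self.pore_volume * 1e-6) / self.surface_area * 1e9
        if not (0.5 * self.pore_diameter <= d_cyl_nm <= 2.0 * self.pore_diameter):
            warnings.warn(
                f"{self.name}: cylindrical-pore diameter 4Vp/SA = {d_cyl_nm:.2f} nm "
                f"is inconsistent with declared pore_diameter = {self.pore_diameter} nm",
                UserWarning,
                stacklevel=2,
            )
        return self

    @property
    def surface_area_si(self) -> float:
        """Surface area in m²/kg."""
        return self.surface_area * 1e3

    @property
    def pore_volume_si(self) -> float:
        """Pore volume in m³/kg."""
        return self.pore_volume * 1e-3


class GlassSubstanceSpec(BaseModel):
    """Thermophysical properties of a glass-forming drug substance.

    ``cp_glass`` / ``cp_liquid`` are the specific heats of the glass and
    the supercooled liquid in J/(g·K); ``tg_onset`` the onset glass
    transition in °C; ``glass_density`` the glass true density in g/cm³.
    """

    model_config = ConfigDict(extra="forbid", frozen=True)

    name: str
    molar_mass: float = Field(default=CELECOXIB_MOLAR_MASS, gt=0)
    glass_density: float = Field(gt=0)
    cp_glass: float = Field(gt=0)
    cp_liquid: float = Field(gt=0)
    tg_onset: Optional[float] = None

    @model_validator(mode="after")
    def _cp_ordering(self) -> "GlassSubstanceSpec":
        if self.cp_liquid <= self.cp_glass:
            raise ValueError(
                f"cp_liquid ({self.cp_liquid}) must exceed cp_glass ({self.cp_glass}): "
                "the supercooled liquid has the larger specific heat"
            )
        return self

    @property
    def glass_density_si(self) -> float:
        """Density in kg/m³."""
        return self.glass_density * 1e3

    @property
    def cp_glass_si(self) -> float:
        """Glass specific heat in J/(kg·K)."""
        return self.cp_glass * 1e3

    @property
    def cp_liquid_si(self) -> float:
        """Liquid specific heat in J/(kg·K)."""
        return self.cp_liquid * 1e3

    @property
    def tg_onset_K(self) -> Optional[float]:
        return None if self.tg_onset is None else self.tg_onset + 273.15


class MixtureSpec(BaseModel):
    """A drug-glass / silica binary mixture, declared by MS mass fraction."""

    model_config = ConfigDict(extra="forbid", frozen=True)

    substance: GlassSubstanceSpec
    silica: MesoporousSilicaSpec
    ms_mass_fraction: float = Field(ge=0.0, le=1.0)

    @property
    def drug_mass_fraction(self) -> float:
        return 1.0 - self.ms_mass_fraction


# Celecoxib constants: density 1.41 g/cm³ (He pycnometry on the glass),
# C_pg = 1.62 and C_pl = 2.07 J/(g·K), onset T_g ≈ 58 °C.
BUILTIN_SUBSTANCES: dict[str, GlassSubstanceSpec] = {
    "celecoxib": GlassSubstanceSpec(
        name="celecoxib",
        molar_mass=CELECOXIB_MOLAR_MASS,
        glass_density=1.41,
        cp_glass=1.62,
        cp_liquid=2.07,
        tg_onset=58.0,
    ),
}

# Sylysia 350 / 730 grades (vendor textural data).
BUILTIN_SILICAS: dict[str, MesoporousSilicaSpec] = {
    "SYL350": MesoporousSilicaSpec(
        name="SYL350", surface_area=300.0, pore_diameter=21.0,
        pore_volume=1.6, particle_diameter=4.0,
    ),
    "SYL730": MesoporousSilicaSpec(
        name="SYL730", surface_area=700.0, pore_diameter=2.5,
        pore_volume=0.44, particle_diameter=4.0,
    ),
}


_SILICA_KEYS = {"name", "surface_area", "pore_diameter", "pore_volume", "particle_diameter"}
_SUBSTANCE_KEYS = {"name", "molar_mass", "glass_density", "cp_glass", "cp_liquid", "tg_onset"}


def _build(cls, entry: dict, allowed: set[str], kind: str):
    if not isinstance(entry, dict):
        raise ConfigError(f"each {kind} entry must be a mapping, got {type(entry).__name__}")
    unknown = set(entry) - allowed
    if unknown:
        raise ConfigError(f"unknown {kind} key(s): {', '.join(sorted(unknown))}")
    if "name" not in entry:
        raise ConfigError(f"{kind} entry is missing required key 'name'")
    return cls(**entry)


def load_materials(config_text: str) -> tuple[list[MesoporousSilicaSpec], list[GlassSubstanceSpec]]:
    """Parse a YAML materials document into validated specs.

    The document is a mapping with optional top-level lists ``silicas``
    and ``substances``; every entry is validated and unknown keys are
    rejected with a :class:`ConfigError` naming the offending key.
    """
    try:
        doc = yaml.safe_load(config_text)
    except yaml.YAMLError as exc:  # pragma: no cover - passthrough
        raise ConfigError(f"config does not parse as YAML: {exc}") from exc
    if doc is None:
        doc = {}
    if not isinstance(doc, dict):
        raise ConfigError("top level of a materials config must be a mapping")
    unknown = set(doc) - {"silicas", "substances", "mixtures"}
    if unknown:
        raise ConfigError(f"unknown top-level key(s): {', '.join(sorted(unknown))}")
    silicas = [
        _build(MesoporousSilicaSpec, e, _SILICA_KEYS, "silica")
        for e in (doc.get("silicas") or [])
    ]
    substances = [
        _build(GlassSubstanceSpec, e, _SUBSTANCE_KEYS, "substance")
        for e in (doc.get("substances") or [])
    ]
    return silicas, substances


def load_materials_file(path) -> tuple[list[MesoporousSilicaSpec], list[GlassSubstanceSpec]]:
    with open(path, "r", encoding="utf-8") as fh:
        return load_materials(fh.read())


def dump_materials(silicas, substances) -> str:
    """Serialize specs back to the YAML config dialect (round-trippable)."""
    doc = {
        "silicas": [s.model_dump() for s in silicas],
        "substances": [s.model_dump() for s in substances],
    }
    return yaml.safe_dump(doc, sort_keys=False)
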