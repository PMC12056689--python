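"""Geometric loading model for a drug glass on mesoporous silica.

Answers three questions about a drug/silica mixture from textural data
alone, under a cubic-molecule idealization:

* how much wall area one drug molecule occupies when adsorbed
  (``molecular_footprint``: V^(2/3) with V = M / (ρ N_A));
* how many molecules one gram of silica can hold as a dense monolayer
  (``monolayer_capacity``: SA / footprint), and the silica mass fraction
  at which the monolayer sites exactly accommodate all drug
  (``ms_fraction_for_monolayer``);
* the silica mass fraction at which the pore volume exactly accommodates
  all drug as glass (``ms_fraction_for_pore_filling``: 1/(1 + V_p ρ)).

Fractions are dimensionless throughout; multiply by 100 only when
presenting.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional

from scipy.constants import Avogadro

from .materials import GlassSubstanceSpec, MesoporousSilicaSpec

__all__ = [
    "LoadingReport",
    "molecular_footprint",
    "monolayer_capacity",
    "monolayer_mass_ratio",
    "ms_fraction_for_monolayer",
    "ms_fraction_for_pore_filling",
    "monolayer_occupancy",
    "loading_report",
]


@dataclass(frozen=True)
class LoadingReport:
    """All geometric loading quantities for one silica/substance pair."""

    silica: str
    substance: str
    footprint_nm2: float                 # per-molecule adsorption area
    monolayer_capacity_per_g: float      # molecules per gram of silica
    monolayer_mass_ratio: float          # g drug per g silica at monolayer
    ms_fraction_monolayer: float         # silica mass fraction, (0, 1]
    ms_fraction_pore_filling: float      # silica mass fraction, (0, 1]
    occupancy_at: Mapping[float, float] = field(default_factory=dict)

    def as_dict(self) -> dict:
        d = {
            "silica": self.silica,
            "substance": self.substance,
            "footprint_nm2": self.footprint_nm2,
            "monolayer_capacity_per_g": self.monolayer_capacity_per_g,
            "monolayer_mass_ratio": self.monolayer_mass_ratio,
            "ms_fraction_monolayer": self.ms_fraction_monolayer,
            "ms_fraction_pore_filling": self.ms_fraction_pore_filling,
        }
        if self.occupancy_at:
            d["occupancy_at"] = dict(self.occupancy_at)
        return d


def molecular_footprint(substance: GlassSubstanceSpec) -> float:
    """Adsorption area per molecule, in nm², cubic-shape assumption.

    The molecular volume is taken from the glass density,
    V = M / (ρ N_A); a cube of that volume presents a face of area
    V^(2/3) to the surface.
    """
    # V in nm³: M [g/mol] / (ρ [g/cm³] · N_A) gives cm³; 1 cm³ = 1e21 nm³
    v_nm3 = substance.molar_mass / (substance.glass_density * Avogadro) * 1e21
    return v_nm3 ** (2.0 / 3.0)


def monolayer_capacity(
    silica: MesoporousSilicaSpec, substance: GlassSubstanceSpec
) -> float:
    """Molecules adsorbable as a dense monolayer per gram of silica."""
    # SA in nm² per gram: 1 m² = 1e18 nm²
    return silica.surface_area * 1e18 / molecular_footprint(substance)


def monolayer_mass_ratio(
    silica: MesoporousSilicaSpec, substance: GlassSubstanceSpec
) -> float:
    """Drug mass (g) held as a monolayer per gram of silica."""
    return monolayer_capacity(silica, substance) * substance.molar_mass / Avogadro


def ms_fraction_for_monolayer(
    silica: MesoporousSilicaSpec, substance: GlassSubstanceSpec
) -> float:
    """Silica mass fraction at which monolayer sites hold all the drug.

    With r = g drug per g silica at monolayer coverage, a mixture whose
    drug:silica ratio equals r has silica fraction f = 1/(1 + r).
    """
    return 1.0 / (1.0 + monolayer_mass_ratio(silica, substance))


def ms_fraction_for_pore_filling(
    silica: MesoporousSilicaSpec, substance: GlassSubstanceSpec
) -> float:
    """Silica mass fraction at which pore volume holds all drug as glass.

    One gram of silica offers V_p mL of pores, i.e. V_p·ρ grams of glass;
    the mixture with exactly that drug load has f = 1/(1 + V_p ρ).
    """
    return 1.0 / (1.0 + silica.pore_volume * substance.glass_density)


def monolayer_occupancy(
    silica: MesoporousSilicaSpec,
    substance: GlassSubstanceSpec,
    ms_fraction_full_rigid: float,
) -> float:
    """Monolayer-site occupancy at the measured full-rigid silica load.

    ``ms_fraction_full_rigid`` is the silica mass fraction at which the
    glass transition of the drug vanishes (all drug rigid, typically from
    the ΔC_p extrapolation).  The returned occupancy is the drug:silica
    mass ratio at that point divided by the monolayer mass ratio — 1 means
    the rigid drug exactly fills a monolayer, < 1 a sub-monolayer.

    This is an interpretive diagnostic: it assumes every rigid molecule
    sits in monolayer contact with the wall, which real partially-filled
    pores need not satisfy.
    """
    if not (0.0 < ms_fraction_full_rigid < 1.0):
        raise ValueError(
            f"ms_fraction_full_rigid must lie strictly inside (0, 1), "
            f"got {ms_fraction_full_rigid}"
        )
    ratio = (1.0 - ms_fraction_full_rigid) / ms_fraction_full_rigid
    return ratio / monolayer_mass_ratio(silica, substance)


def loading_report(
    silica: MesoporousSilicaSpec,
    substance: GlassSubstanceSpec,
    ms_fraction_full_rigid: Optional[float] = None,
) -> LoadingReport:
    """Assemble the full geometric loading report for one pair."""
    occupancy = {}
    if ms_fraction_full_rigid is not None:
        occupancy[ms_fraction_full_rigid] = monolayer_occupancy(
            silica, substance, ms_fraction_full_rigid
        )
    return LoadingReport(
        silica=silica.name,
        substance=substance.name,
        footprint_nm2=molecular_footprint(substance),
        monolayer_capacity_per_g=monolayer_capacity(silica, substance),
        monolayer_mass_ratio=monolayer_mass_ratio(silica, substance),
        ms_fraction_monolayer=ms_fraction_for_monolayer(silica, substance),
        ms_fraction_pore_filling=ms_fraction_for_pore_filling(silica, substance),
        occupancy_at=occupancy,
    )
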