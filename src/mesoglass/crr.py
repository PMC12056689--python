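"""Donth cooperatively-rearranging-region (CRR) size from calorimetry.

At the glass transition, temperature fluctuations of a cooperatively
rearranging subsystem relate its size to calorimetric observables.
Donth's fluctuation formula gives the characteristic length

    L = [ k_B T_g² Δ(1/c_p) / (ρ δT²) ]^(1/3)

with Δ(1/c_p) = 1/c_p(glass) − 1/c_p(liquid) > 0, T_g the onset glass
transition temperature, δT half the onset-to-end transition width, ρ the
density and k_B Boltzmann's constant.  All inputs are SI; the result is
returned in nm.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

from scipy.constants import Boltzmann

from .dsc import GlassTransitionResult
from .materials import GlassSubstanceSpec

__all__ = ["CRRInput", "crr_size", "crr_size_from_transition"]


@dataclass(frozen=True)
class CRRInput:
    """SI-unit inputs to the Donth relation.

    ``half_width`` is δT, half the onset-to-end glass transition width,
    the mean-square temperature fluctuation scale of one CRR.
    """

    tg_onset: float     # K
    half_width: float   # K
    density: float      # kg/m³
    cp_glass: float     # J/(kg·K)
    cp_liquid: float    # J/(kg·K)

    def __post_init__(self):
        if self.tg_onset <= 0 or self.half_width <= 0 or self.density <= 0:
            raise ValueError("tg_onset, half_width and density must be positive")
        if not (0 < self.cp_glass <= self.cp_liquid):
            raise ValueError("require 0 < cp_glass <= cp_liquid")


def crr_size(inp: CRRInput) -> float:
    """CRR characteristic length in nm via the Donth relation."""
    d_inv_cp = 1.0 / inp.cp_glass - 1.0 / inp.cp_liquid
    if d_inv_cp == 0.0:
        warnings.warn(
            "cp_glass equals cp_liquid: Donth length degenerates to 0",
            UserWarning,
            stacklevel=2,
        )
        return 0.0
    l_cubed = (
        Boltzmann * inp.tg_onset**2 * d_inv_cp / (inp.density * inp.half_width**2)
    )
    return l_cubed ** (1.0 / 3.0) * 1e9


def crr_size_from_transition(
    gt: GlassTransitionResult, substance: GlassSubstanceSpec
) -> float:
    """CRR size from a tangent-construction glass transition result.

    Uses the measured onset (converted to K) and half-width together with
    the substance's ambient glass density and specific heats.  The
    ambient density is used at T_g as well; the thermal-expansion
    correction is below the method's other uncertainties.
    """
    inp = CRRInput(
        tg_onset=gt.tg_onset + 273.15,
        half_width=gt.half_width,
        density=substance.glass_density_si,
        cp_glass=substance.cp_glass_si,
        cp_liquid=substance.cp_liquid_si,
    )
    return crr_size(inp)
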