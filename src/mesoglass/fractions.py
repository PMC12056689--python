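"""Rigid / intermediate / free decomposition of a confined drug glass.

A drug glass mixed with mesoporous silica splits into three populations:

* **rigid** — immobilized at the silica surface; shows no glass
  transition, so it is the part of the drug *missing* from ΔC_p;
* **free** — bulk-like; undergoes cold crystallization on heating, so it
  is read from the cold-crystallization enthalpy;
* **intermediate** — shows a glass transition but cannot crystallize;
  the remainder.

Both observables are measured per gram of mixture and referenced to the
pure-drug values per gram of drug, hence the division by the drug mass
fraction w = 1 − ms_mass_fraction.  Extrapolating the ΔC_p-vs-silica-load
line to zero gives the silica load at which the whole drug is rigid.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats

__all__ = [
    "MixtureObservation",
    "FractionProfile",
    "RigidExtrapolation",
    "rigid_fraction",
    "free_fraction",
    "decompose",
    "extrapolate_full_rigid_load",
]


@dataclass(frozen=True)
class MixtureObservation:
    """DSC observables for one mixture composition (per gram of mixture)."""

    ms_mass_fraction: float
    delta_cp_mixture: float      # J/(g·K)
    cc_enthalpy_mixture: float = 0.0   # J/g; 0 when no cold crystallization

    def __post_init__(self):
        if not (0.0 <= self.ms_mass_fraction < 1.0):
            raise ValueError("ms_mass_fraction must lie in [0, 1)")
        if self.delta_cp_mixture < 0 or self.cc_enthalpy_mixture < 0:
            raise ValueError("observables must be non-negative")

    @property
    def drug_mass_fraction(self) -> float:
        return 1.0 - self.ms_mass_fraction


@dataclass(frozen=True)
class FractionProfile:
    """Percent-of-drug-mass split into the three populations.

    ``rigid``/``free``/``intermediate`` are clipped to [0, 100] and
    renormalized only if the clipped sum exceeds 100; the raw (unclipped)
    values are retained for diagnostics.
    """

    rigid: float
    free: float
    intermediate: float
    raw_rigid: float
    raw_free: float
    raw_intermediate: float


@dataclass(frozen=True)
class RigidExtrapolation:
    """OLS line of ΔC_p versus silica load and its zero crossing."""

    ms_fraction_full_rigid: float
    slope: float
    intercept: float
    r_squared: float


def _check_refs(pure_value: float, w: float, what: str) -> None:
    if pure_value <= 0:
        raise ValueError(f"pure-drug reference {what} must be positive, got {pure_value}")
    if w <= 0:
        raise ValueError("mixture contains no drug (ms_mass_fraction = 1)")


def rigid_fraction(obs: MixtureObservation, pure_delta_cp: float) -> float:
    """Rigid percent of the drug mass from the missing ΔC_p.

    ΔC_p is proportional to the mobile drug; a mixture with drug fraction
    w would show w·ΔC_p(pure) if fully mobile, so
    rigid = 100·(1 − ΔC_p(mix)/(w·ΔC_p(pure))), clipped to [0, 100].
    """
    w = obs.drug_mass_fraction
    _check_refs(pure_delta_cp, w, "delta_cp")
    raw = 100.0 * (1.0 - obs.delta_cp_mixture / (w * pure_delta_cp))
    return float(np.clip(raw, 0.0, 100.0))


def free_fraction(obs: MixtureObservation, pure_cc_enthalpy: float) -> float:
    """Free (bulk-like) percent from the cold-crystallization enthalpy."""
    w = obs.drug_mass_fraction
    _check_refs(pure_cc_enthalpy, w, "cc_enthalpy")
    raw = 100.0 * obs.cc_enthalpy_mixture / (w * pure_cc_enthalpy)
    return float(np.clip(raw, 0.0, 100.0))


def decompose(
    obs: MixtureObservation, pure_delta_cp: float, pure_cc_enthalpy: float
) -> FractionProfile:
    """Full three-way split; intermediate is the remainder.

    Raw values satisfy rigid + free + intermediate = 100 exactly; the
    presented values are clipped to [0, 100] and rescaled only when the
    clipped rigid + free exceed 100 (a noise artifact).
    """
    w = obs.drug_mass_fraction
    _check_refs(pure_delta_cp, w, "delta_cp")
    _check_refs(pure_cc_enthalpy, w, "cc_enthalpy")
    raw_rigid = 100.0 * (1.0 - obs.delta_cp_mixture / (w * pure_delta_cp))
    raw_free = 100.0 * obs.cc_enthalpy_mixture / (w * pure_cc_enthalpy)
    raw_inter = 100.0 - raw_rigid - raw_free

    rigid = float(np.clip(raw_rigid, 0.0, 100.0))
    free = float(np.clip(raw_free, 0.0, 100.0))
    if rigid + free > 100.0:
        scale = 100.0 / (rigid + free)
        rigid *= scale
        free *= scale
    inter = 100.0 - rigid - free
    return FractionProfile(
        rigid=rigid, free=free, intermediate=inter,
        raw_rigid=float(raw_rigid), raw_free=float(raw_free),
        raw_intermediate=float(raw_inter),
    )


def extrapolate_full_rigid_load(
    series: Sequence[MixtureObservation],
) -> RigidExtrapolation:
    """Silica load at which the glass transition vanishes.

    Ordinary least squares of ΔC_p(mixture) against silica mass fraction;
    the root of the fitted line is the full-rigid load.  Requires at least
    three observations spanning at least 0.2 in silica fraction and a
    strictly negative slope (ΔC_p must fall as silica is added).
    """
    if len(series) < 3:
        raise ValueError(f"need >= 3 observations for extrapolation, got {len(series)}")
    x = np.array([o.ms_mass_fraction for o in series], dtype=float)
    y = np.array([o.delta_cp_mixture for o in series], dtype=float)
    if x.max() - x.min() < 0.2:
        raise ValueError(
            f"silica fractions span only {x.max() - x.min():.3f}; need >= 0.2 for a "
            "trustworthy extrapolation"
        )
    fit = stats.linregress(x, y)
    if fit.slope >= 0:
        raise ValueError(
            "delta_cp does not decrease with silica load; no full-rigid extrapolation"
        )
    root = -fit.intercept / fit.slope
    if not (0.0 < root <= 1.0):
        raise ValueError(
            f"extrapolated full-rigid load {root:.3f} falls outside (0, 1]"
        )
    return RigidExtrapolation(
        ms_fraction_full_rigid=float(root),
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        r_squared=float(fit.rvalue**2),
    )
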