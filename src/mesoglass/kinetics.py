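"""Isothermal crystallization kinetics (Avrami–Erofeev analysis).

An annealed drug glass crystallizes over hours; the conversion is tracked
either by the decay of the static permittivity (BDS, via the normalized
dispersion ε′_N) or by the shrinking glass-transition step (DSC, via
ΔC_p-derived crystallinity).  The conversion curve is fitted to the
Avrami–Erofeev law with an induction time,

    X(t) = plateau · (1 − exp(−k (t − d)^n))   for t > d, else 0,

where k is the rate constant, d the induction time and n the Avrami
exponent (growth dimensionality/nucleation signature).  In confined
systems conversion saturates below 100% (the rigid fraction never
crystallizes); the plateau is either fixed at 1 with the uncrystallized
remainder ignored — the default — or fitted freely.

Note on units: with this model form k carries units of s⁻ⁿ.  Kinetic
tables in the field often print k in s⁻¹ regardless of n; reports here
emit the fitted value (s⁻ⁿ) and ``rate_constant_per_s`` = k^(1/n) (s⁻¹)
side by side.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Optional

import numpy as np
from scipy import optimize, stats

__all__ = [
    "CrystallizationTrace",
    "AvramiFit",
    "epsilon_n",
    "avrami_conversion",
    "fit_avrami",
    "t_half",
    "t_half_empirical",
    "terminal_conversion",
]


@dataclass(frozen=True)
class CrystallizationTrace:
    """One isothermal annealing record: conversion (or ε′) versus time."""

    time: np.ndarray          # s, strictly increasing, from 0
    observable: np.ndarray    # conversion in [0,1] (kind-dependent)
    kind: Literal["bds", "dsc"]
    temperature: float        # K

    def __post_init__(self):
        t = np.asarray(self.time, dtype=float)
        x = np.asarray(self.observable, dtype=float)
        object.__setattr__(self, "time", t)
        object.__setattr__(self, "observable", x)
        if t.size < 8:
            raise ValueError(f"trace needs >= 8 points, got {t.size}")
        if t.shape != x.shape:
            raise ValueError("time and observable must be equally long")
        if np.any(np.diff(t) <= 0):
            raise ValueError("time must be strictly increasing")
        if t[0] < 0:
            raise ValueError("time must start at >= 0")
        if np.any(~np.isfinite(t)) or np.any(~np.isfinite(x)):
            raise ValueError("trace contains NaN/inf")


@dataclass(frozen=True)
class AvramiFit:
    """Fitted Avrami–Erofeev parameters.

    ``k`` is in s⁻ⁿ (consistent with the model form);
    ``rate_constant_per_s`` is the per-second convention k^(1/n).
    """

    k: float
    d: float
    n: float
    plateau: float
    residual: float

    def __post_init__(self):
        if self.k <= 0 or self.n <= 0 or self.d < 0:
            raise ValueError("require k > 0, n > 0, d >= 0")
        if not (0 < self.plateau <= 1):
            raise ValueError("plateau must lie in (0, 1]")

    @property
    def rate_constant_per_s(self) -> float:
        return self.k ** (1.0 / self.n)


def epsilon_n(eps0: float, eps_inf_t: float, eps_t) -> np.ndarray | float:
    """Normalized dielectric-dispersion conversion ε′_N.

    ε′_N = (ε′_0 − ε′_t)/(ε′_0 − ε′_∞): 0 at the start (ε′_t = ε′_0),
    1 once the dispersion has fully collapsed (ε′_t = ε′_∞); clipped to
    [0, 1] against noise overshoot.
    """
    if eps0 <= eps_inf_t:
        raise ValueError(
            f"initial permittivity ({eps0}) must exceed the long-time limit ({eps_inf_t})"
        )
    x = (eps0 - np.asarray(eps_t, dtype=float)) / (eps0 - eps_inf_t)
    out = np.clip(x, 0.0, 1.0)
    return float(out) if np.isscalar(eps_t) else out


def avrami_conversion(
    t: np.ndarray, k: float, d: float, n: float, plateau: float = 1.0
) -> np.ndarray:
    """Avrami–Erofeev conversion X(t); exactly 0 during the induction period."""
    t = np.asarray(t, dtype=float)
    x = np.zeros_like(t)
    grow = t > d
    x[grow] = plateau * (1.0 - np.exp(-k * (t[grow] - d) ** n))
    return x


def fit_avrami(
    trace: CrystallizationTrace,
    fix_n: Optional[float] = None,
    *,
    fix_d: Optional[float] = None,
    fit_plateau: bool = False,
) -> AvramiFit:
    """Nonlinear least-squares Avrami fit of a conversion trace.

    The trace must already be expressed as conversion (apply
    :func:`epsilon_n` or ΔC_p-derived crystallinity first).  Fitting is
    done over (log10 k, d, n[, plateau]) with d bounded below by 0,
    multi-started over a log-k grid; the classic double-log linearization
    serves only to seed k and n, never as the reported fit.  By default
    the plateau is fixed at 1 — the uncrystallized remainder is ignored —
    and ``fit_plateau=True`` frees it within (0, 1].

    ``fix_d`` pins the induction time when it is known from the protocol
    (e.g. seeded mixtures that crystallize immediately): the free-d fit
    leaves k strongly correlated with d and n, so fixing d sharpens the
    rate constant considerably.  ``fix_n`` likewise pins the exponent.
    """
    t = trace.time
    x = trace.observable
    x_max = x.max()
    if x_max <= 0 or x[-1] <= x[0] + 1e-12 and np.all(np.diff(x) <= 0):
        raise ValueError("no crystallization: conversion never increases")
    if x_max < 0.05:
        raise ValueError("no crystallization: conversion stays below 5%")

    # Double-log seed on the rising part (0.02 < X < 0.98 of its own max).
    rising = (x > 0.02 * x_max) & (x < 0.98 * x_max) & (t > 0)
    n0, log_k0 = 2.0, -np.log10(max(t[-1], 1.0)) * 2.0
    if np.count_nonzero(rising) >= 3:
        xr = np.clip(x[rising] / max(x_max, 1e-9), 1e-9, 1 - 1e-9)
        yy = np.log(-np.log(1.0 - xr))
        tt = np.log(t[rising])
        n0, lnk0 = np.polyfit(tt, yy, 1)
        n0 = float(np.clip(n0, 0.3, 6.0))
        log_k0 = lnk0 / np.log(10.0)

    d0 = float(t[np.argmax(x > 0.02 * x_max)]) if np.any(x > 0.02 * x_max) else 0.0

    free_n = fix_n is None
    free_d = fix_d is None

    def unpack(p):
        i = 0
        log_k = p[i]; i += 1
        d = p[i] if free_d else fix_d
        i += free_d
        n = p[i] if free_n else fix_n
        i += free_n
        plateau = p[i] if fit_plateau else 1.0
        return 10.0**log_k, d, n, plateau

    def resid(p):
        k, d, n, plateau = unpack(p)
        return avrami_conversion(t, k, d, n, plateau) - x

    lower = [-20.0]
    upper = [5.0]
    p0 = [float(np.clip(log_k0, -19, 4))]
    if free_d:
        lower.append(0.0); upper.append(float(t[-1])); p0.append(max(d0, 0.0))
    if free_n:
        lower.append(0.1); upper.append(8.0); p0.append(n0)
    if fit_plateau:
        lower.append(0.05); upper.append(1.0)
        p0.append(float(np.clip(x[-1], 0.06, 1.0)))

    best = None
    for dk in (0.0, -1.0, 1.0):
        start = list(p0)
        start[0] = float(np.clip(p0[0] + dk, -19.9, 4.9))
        sol = optimize.least_squares(
            resid, start, bounds=(lower, upper), xtol=1e-14, ftol=1e-14
        )
        if best is None or sol.cost < best.cost:
            best = sol
    k, d, n, plateau = unpack(best.x)
    rms = float(np.sqrt(np.mean(best.fun**2)))
    return AvramiFit(k=float(k), d=float(d), n=float(n), plateau=float(plateau), residual=rms)


def t_half(fit: AvramiFit) -> float:
    """Analytic time to 50% absolute conversion: d + (−ln(1 − 0.5/plateau)/k)^(1/n)."""
    if fit.plateau < 0.5:
        raise ValueError(
            f"conversion plateaus at {fit.plateau:.2f} < 0.5; t_1/2 is undefined"
        )
    return fit.d + (-np.log(1.0 - 0.5 / fit.plateau) / fit.k) ** (1.0 / fit.n)


def t_half_empirical(trace: CrystallizationTrace) -> float:
    """Model-free t_1/2: linear interpolation of the first 0.5 crossing."""
    t, x = trace.time, trace.observable
    above = np.nonzero(x >= 0.5)[0]
    if above.size == 0:
        raise ValueError("trace never reaches 50% conversion")
    i = int(above[0])
    if i == 0:
        return float(t[0])
    frac = (0.5 - x[i - 1]) / (x[i] - x[i - 1])
    return float(t[i - 1] + frac * (t[i] - t[i - 1]))


def terminal_conversion(
    trace: CrystallizationTrace,
    *,
    tail_fraction: float = 0.2,
    alpha: float = 0.05,
) -> tuple[float, bool]:
    """Mean of the settled tail and whether it has actually settled.

    The last ``tail_fraction`` of the points form the tail; it counts as
    settled when the OLS slope of conversion versus time over the tail is
    statistically indistinguishable from zero at level ``alpha``.  The
    tail mean is returned either way, with ``settled=False`` flagging a
    still-rising trace.
    """
    n_tail = max(3, int(np.ceil(tail_fraction * trace.time.size)))
    t = trace.time[-n_tail:]
    x = trace.observable[-n_tail:]
    mean = float(np.mean(x))
    if np.allclose(x, x[0]):
        return mean, True
    fit = stats.linregress(t, x)
    settled = bool(fit.pvalue > alpha)
    return mean, settled
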