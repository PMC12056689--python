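"""Feature extraction from tabular DSC heating traces.

A heating trace is represented as a :class:`Thermogram` of temperature
versus apparent specific heat (or heat flow, convertible via the heating
rate).  Three extractions are provided:

* ``detect_glass_transition`` — tangent construction of onset/end and the
  heat-capacity step ΔC_p across the transition;
* ``integrate_peak`` — enthalpy of an exo-/endothermic event above a
  linear baseline drawn between the window endpoints;
* ``crystallinity_from_dcp`` — conversion of a ΔC_p series into
  crystallinity, using ΔC_p as a proxy for the remaining amorphous phase.

Onset is the intersection of the pre-transition baseline tangent with the
maximum-slope tangent; end is symmetric with the post-transition baseline.
ΔC_p is the vertical separation of the two extrapolated baselines at the
transition midpoint.  Neither the baseline construction nor the tangent
choice is standardized across instruments; these are the conventions used
throughout this package.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Optional, Tuple

import numpy as np
from scipy.signal import savgol_filter

__all__ = [
    "Thermogram",
    "GlassTransitionResult",
    "PeakIntegral",
    "NoTransitionError",
    "detect_glass_transition",
    "integrate_peak",
    "crystallinity_from_dcp",
]


class NoTransitionError(ValueError):
    """No heat-capacity step above threshold inside the search window."""


@dataclass(frozen=True)
class Thermogram:
    """One DSC heating segment.

    ``signal_kind`` declares the y-axis: ``"cp"`` for apparent specific
    heat in J/(g·K), ``"heat_flow"`` for W/g (converted to a C_p basis by
    the heating rate on demand).  Temperatures are °C, strictly
    increasing, per gram of mixture.
    """

    temperature: np.ndarray
    signal: np.ndarray
    heating_rate: float  # K/min
    signal_kind: Literal["cp", "heat_flow"] = "cp"

    def __post_init__(self):
        t = np.asarray(self.temperature, dtype=float)
        s = np.asarray(self.signal, dtype=float)
        object.__setattr__(self, "temperature", t)
        object.__setattr__(self, "signal", s)
        if t.ndim != 1 or t.shape != s.shape:
            raise ValueError("temperature and signal must be 1-D and equally long")
        if t.size < 50:
            raise ValueError(f"thermogram needs >= 50 samples, got {t.size}")
        if np.any(np.diff(t) <= 0):
            idx = int(np.argmax(np.diff(t) <= 0))
            raise ValueError(f"temperature must be strictly increasing (violated at index {idx + 1})")
        if np.any(~np.isfinite(t)) or np.any(~np.isfinite(s)):
            raise ValueError("thermogram contains NaN/inf samples")
        if self.heating_rate <= 0:
            raise ValueError("heating_rate must be positive")

    def as_cp(self) -> np.ndarray:
        """Signal on an apparent-C_p basis, J/(g·K)."""
        if self.signal_kind == "cp":
            return self.signal
        # W/g divided by K/s gives J/(g·K); exothermic-up sign conventions
        # are the caller's responsibility.
        return self.signal / (self.heating_rate / 60.0)


@dataclass(frozen=True)
class GlassTransitionResult:
    """Tangent-construction glass transition parameters (°C, J/(g·K))."""

    tg_onset: float
    tg_end: float
    tg_mid: float
    delta_cp: float
    width: float
    half_width: float

    def __post_init__(self):
        if self.tg_end <= self.tg_onset:
            raise ValueError("tg_end must exceed tg_onset")


@dataclass(frozen=True)
class PeakIntegral:
    t_onset: float
    t_peak: float
    t_end: float
    enthalpy: float  # J/g, positive magnitude
    direction: Literal["exothermic", "endothermic"]


def _window_slice(t: np.ndarray, window: Tuple[float, float]) -> slice:
    lo, hi = window
    if lo >= hi:
        raise ValueError(f"window must be an increasing interval, got {window}")
    if lo < t[0] or hi > t[-1]:
        raise ValueError(
            f"window {window} extends outside the trace range ({t[0]:.2f}, {t[-1]:.2f})"
        )
    i0 = int(np.searchsorted(t, lo, side="left"))
    i1 = int(np.searchsorted(t, hi, side="right"))
    return slice(i0, i1)


def _smooth(y: np.ndarray, window_pts: int) -> np.ndarray:
    if window_pts < 5 or y.size <= window_pts:
        return y
    if window_pts % 2 == 0:
        window_pts += 1
    return savgol_filter(y, window_pts, polyorder=3)


def detect_glass_transition(
    thermogram: Thermogram,
    search_window: Tuple[float, float],
    *,
    smooth_window: int = 11,
    delta_cp_threshold: float = 0.02,
) -> GlassTransitionResult:
    """Locate a glass transition and quantify its step by tangents.

    Parameters
    ----------
    search_window
        (°C, °C) interval guaranteed to contain the whole transition,
        with some flat-ish baseline on each side.
    smooth_window
        Points of the Savitzky–Golay filter applied before
        differentiation; tangents on raw noisy traces are ill-posed.
    delta_cp_threshold
        Minimum step height in J/(g·K); below it the window is declared
        transition-free and :class:`NoTransitionError` raised.
    """
    t_all = thermogram.temperature
    cp_all = thermogram.as_cp()
    sl = _window_slice(t_all, search_window)
    t = t_all[sl]
    cp = cp_all[sl]
    if t.size < 20:
        raise ValueError("search window contains too few samples (< 20)")

    cps = _smooth(cp, smooth_window)
    dcp = np.gradient(cps, t)

    i_star = int(np.argmax(dcp))
    slope_max = dcp[i_star]
    t_star = t[i_star]

    # Transition extent: contiguous region around the max-slope point where
    # the derivative stays above 10% of its peak; baselines are fitted
    # outside it with a guard margin.
    above = dcp > 0.10 * slope_max
    lo = i_star
    while lo > 0 and above[lo - 1]:
        lo -= 1
    hi = i_star
    while hi < t.size - 1 and above[hi + 1]:
        hi += 1
    margin = max(2, (hi - lo) // 4)
    pre = slice(0, max(lo - margin, 4))
    post = slice(min(hi + margin, t.size - 4), t.size)
    if t[pre].size < 4 or t[post].size < 4:
        raise ValueError(
            "search window leaves no baseline on one side of the transition; widen it"
        )

    b_pre = np.polyfit(t[pre], cp[pre], 1)
    b_post = np.polyfit(t[post], cp[post], 1)

    # Tangent through the inflection with the maximum slope.
    tangent = np.array([slope_max, cps[i_star] - slope_max * t_star])

    def _intersect(l1, l2):
        if np.isclose(l1[0], l2[0]):
            raise NoTransitionError("tangent parallel to baseline; no step found")
        return (l2[1] - l1[1]) / (l1[0] - l2[0])

    tg_onset = _intersect(tangent, b_pre)
    tg_end = _intersect(tangent, b_post)
    if not (t[0] <= tg_onset < tg_end <= t[-1]):
        raise NoTransitionError("tangent construction degenerate inside window")
    tg_mid = 0.5 * (tg_onset + tg_end)
    delta_cp = float(np.polyval(b_post, tg_mid) - np.polyval(b_pre, tg_mid))
    if delta_cp < delta_cp_threshold:
        raise NoTransitionError(
            f"step height {delta_cp:.4f} J/(g·K) below threshold {delta_cp_threshold}"
        )
    width = tg_end - tg_onset
    return GlassTransitionResult(
        tg_onset=float(tg_onset),
        tg_end=float(tg_end),
        tg_mid=float(tg_mid),
        delta_cp=delta_cp,
        width=float(width),
        half_width=float(width) / 2.0,
    )


def integrate_peak(
    thermogram: Thermogram,
    window: Tuple[float, float],
    direction: Literal["exothermic", "endothermic"] = "exothermic",
) -> PeakIntegral:
    """Integrate one thermal event above a linear endpoint baseline.

    The baseline is the straight line joining the signal at the two window
    endpoints; the enthalpy is |∫ (signal − baseline) dT| expressed in
    J/g (heat-flow traces are divided by the heating rate).  The peak
    temperature is the extremum of the baseline-subtracted signal in the
    window.
    """
    t_all = thermogram.temperature
    cp_all = thermogram.as_cp()
    sl = _window_slice(t_all, window)
    t = t_all[sl]
    y = cp_all[sl]
    if t.size < 5:
        raise ValueError("peak window contains too few samples (< 5)")
    base = y[0] + (y[-1] - y[0]) * (t - t[0]) / (t[-1] - t[0])
    excess = y - base
    area = float(np.trapezoid(excess, t))  # J/g since cp basis is J/(g·K)
    if direction == "endothermic":
        i_pk = int(np.argmax(excess))
    else:
        # Exotherms are negative-going on a C_p (endo-up) basis.
        i_pk = int(np.argmin(excess)) if area < 0 else int(np.argmax(excess))
    return PeakIntegral(
        t_onset=float(t[0]),
        t_peak=float(t[i_pk]),
        t_end=float(t[-1]),
        enthalpy=abs(area),
        direction=direction,
    )


def crystallinity_from_dcp(dcp_t: float, dcp_0: float) -> float:
    """Crystallinity X from the residual glass-transition step.

    ΔC_p is proportional to the remaining amorphous (mobile) phase, so
    X = 1 − ΔC_p(t)/ΔC_p(0), clipped to [0, 1].
    """
    if dcp_0 <= 0:
        raise ValueError(f"reference step dcp_0 must be positive, got {dcp_0}")
    if dcp_t < 0:
        raise ValueError(f"dcp_t must be non-negative, got {dcp_t}")
    return float(np.clip(1.0 - dcp_t / dcp_0, 0.0, 1.0))
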