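"""Synthetic instrument-data generators with known ground truth.

Every input class the analysis consumes can be generated here with its
generating parameters ("truth") returned alongside, so each stage — and
the whole pipeline — is testable without any instrument data:

* HN-shaped dielectric loss spectra (1–2 processes + dc conductivity),
* VFT-distributed relaxation-time series τ_α(T),
* DSC heating traces (sigmoidal C_p step + Gaussian exo/endo peaks on a
  sloped baseline),
* Avrami conversion traces and their ε′(t) counterparts,
* ΔC_p / cold-crystallization observable series for mixture ladders.

Noise is multiplicative by default for spectra (instrument loss noise
scales with signal) and additive for conversion traces; both are set per
recipe.  The same :class:`GeneratorRecipe` always produces byte-identical
output.

``DEFAULTS`` collects the fixture constants used across tests and
examples; they mirror a celecoxib-like regime (onset T_g ≈ 58 °C,
ΔC_p ≈ 0.45 J/(g·K), KWW β ≈ 0.55–0.69, slow isothermal kinetics with
k ≈ 1.6×10⁻⁷ s⁻ⁿ, n ≈ 1.8, induction ≈ 900 s).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Literal, Optional, Sequence, Tuple

import numpy as np

from .bds import DielectricSpectrum, HNProcess, hn_model
from .dsc import Thermogram
from .fractions import MixtureObservation
from .kinetics import CrystallizationTrace, avrami_conversion

__all__ = [
    "GeneratorRecipe",
    "DEFAULTS",
    "gen_hn_spectrum",
    "gen_vft_series",
    "gen_thermogram",
    "gen_avrami_trace",
    "gen_mixture_series",
]

#: Fixture constants for a celecoxib-like glass/silica system.
DEFAULTS: dict = {
    "tg_onset_C": 58.0,           # onset glass transition of the drug glass
    "delta_cp": 0.45,             # J/(g·K), pure-glass transition step
    "tg_width_K": 4.0,            # tangent onset-to-end width
    "cc_enthalpy": 60.0,          # J/g, pure-glass cold-crystallization
    "kww_beta_bulk": 0.69,        # stretching exponent, bulk-like glass
    "avrami": {"k": 1.59e-7, "d": 907.0, "n": 1.8},   # s^-n, s, -
    "vft": {"tau0": 1e-14, "D": 8.0, "T0": 270.0},    # s, -, K
    "hn": {"delta_eps": 5.0, "tau_hn": 1e-3, "a": 0.8, "b": 0.5},
}


@dataclass(frozen=True)
class GeneratorRecipe:
    """Reproducibility contract for one synthetic data set."""

    seed: int
    noise_sigma: float = 0.0
    noise_model: Literal["multiplicative", "additive"] = "multiplicative"

    def rng(self) -> np.random.Generator:
        return np.random.default_rng(self.seed)

    def apply_noise(self, rng: np.random.Generator, y: np.ndarray) -> np.ndarray:
        if self.noise_sigma == 0.0:
            return y
        eps = rng.normal(0.0, self.noise_sigma, size=y.shape)
        if self.noise_model == "multiplicative":
            return y * (1.0 + eps)
        return y + eps


def _default_freq_grid(decades: Tuple[float, float] = (-2.0, 7.0), per_decade: int = 8) -> np.ndarray:
    lo, hi = decades
    n = int(round((hi - lo) * per_decade)) + 1
    return np.logspace(lo, hi, n)


def gen_hn_spectrum(
    recipe: GeneratorRecipe,
    processes: Sequence[HNProcess],
    eps_inf: float = 3.0,
    sigma_dc: float = 0.0,
    temperature: float = 347.15,
    frequency: Optional[np.ndarray] = None,
) -> Tuple[DielectricSpectrum, dict]:
    """Noisy HN loss spectrum plus its generating truth.

    Default grid: 8 points/decade over 10⁻²–10⁷ Hz.  Noise is applied to
    ε″ only; ε′ stays noiseless (it is used as a cross-check channel).
    """
    f = _default_freq_grid() if frequency is None else np.asarray(frequency, float)
    eps = hn_model(processes, eps_inf, sigma_dc, f)
    rng = recipe.rng()
    loss = recipe.apply_noise(rng, -eps.imag)
    spectrum = DielectricSpectrum(
        frequency=f, eps_real=eps.real, eps_imag=loss, temperature=temperature
    )
    truth = {
        "processes": [
            {"delta_eps": p.delta_eps, "tau_hn": p.tau_hn, "a": p.a, "b": p.b}
            for p in processes
        ],
        "eps_inf": eps_inf,
        "sigma_dc": sigma_dc,
        "temperature": temperature,
        "recipe": recipe,
    }
    return spectrum, truth


def gen_vft_series(
    recipe: GeneratorRecipe,
    tau0: float,
    D: float,
    T0: float,
    temperatures: Sequence[float],
) -> Tuple[list, dict]:
    """(T, τ) pairs from the VFT law with log-normal noise on τ."""
    T = np.asarray(temperatures, dtype=float)
    if np.any(T <= T0):
        raise ValueError("all temperatures must exceed T0")
    tau = tau0 * np.exp(D * T0 / (T - T0))
    rng = recipe.rng()
    if recipe.noise_sigma > 0:
        # noise_sigma is the std-dev on log10 tau regardless of noise_model:
        # relaxation times are intrinsically log-scale observables.
        tau = 10.0 ** (np.log10(tau) + rng.normal(0, recipe.noise_sigma, T.shape))
    series = list(zip(T.tolist(), tau.tolist()))
    truth = {"tau0": tau0, "D": D, "T0": T0, "recipe": recipe}
    return series, truth


@dataclass(frozen=True)
class PeakSpec:
    """One Gaussian thermal event for the thermogram generator."""

    center: float    # °C
    sigma: float     # K
    enthalpy: float  # J/g, positive magnitude
    direction: Literal["exothermic", "endothermic"] = "exothermic"


def gen_thermogram(
    recipe: GeneratorRecipe,
    tg_onset: float = DEFAULTS["tg_onset_C"],
    delta_cp: float = DEFAULTS["delta_cp"],
    width: float = DEFAULTS["tg_width_K"],
    peaks: Sequence[PeakSpec] = (),
    baseline: Tuple[float, float] = (1.6, 0.0),   # (intercept J/(g·K), slope per K)
    t_range: Tuple[float, float] = (20.0, 180.0),
    n_points: int = 1600,
    heating_rate: float = 10.0,
) -> Tuple[Thermogram, dict]:
    """DSC heating trace: logistic C_p step + Gaussian peaks + linear baseline.

    The step is a logistic sigmoid whose tangent construction has
    onset-to-end width ``width`` (logistic scale = width/4), so the truth
    against which `detect_glass_transition` is scored is
    onset = ``tg_onset``, end = onset + width, ΔC_p = ``delta_cp``.
    Peak areas are exact analytic Gaussian integrals (on the C_p basis an
    exotherm dips below baseline).  Additive noise in signal units.
    """
    if width <= 0 or delta_cp <= 0:
        raise ValueError("width and delta_cp must be positive")
    t = np.linspace(t_range[0], t_range[1], n_points)
    scale = width / 4.0
    mid = tg_onset + width / 2.0
    cp = baseline[0] + baseline[1] * t + delta_cp / (1.0 + np.exp(-(t - mid) / scale))
    overlap_warn = False
    for pk in peaks:
        if pk.sigma <= 0 or pk.enthalpy < 0:
            raise ValueError("peak sigma must be positive, enthalpy non-negative")
        if abs(pk.center - mid) < 3.0 * pk.sigma + width:
            overlap_warn = True
        sign = -1.0 if pk.direction == "exothermic" else 1.0
        # Endotherm-up C_p basis: area under (signal - baseline) equals
        # +enthalpy for endotherms, -enthalpy for exotherms.
        amp = pk.enthalpy / (pk.sigma * np.sqrt(2.0 * np.pi))
        cp = cp + sign * amp * np.exp(-0.5 * ((t - pk.center) / pk.sigma) ** 2)
    rng = recipe.rng()
    if recipe.noise_sigma > 0:
        cp = cp + rng.normal(0.0, recipe.noise_sigma, cp.shape)
    thermogram = Thermogram(temperature=t, signal=cp, heating_rate=heating_rate, signal_kind="cp")
    truth = {
        "tg_onset": tg_onset,
        "tg_end": tg_onset + width,
        "tg_mid": mid,
        "delta_cp": delta_cp,
        "width": width,
        "peaks": list(peaks),
        "baseline": baseline,
        "overlapping_events": overlap_warn,
        "recipe": recipe,
    }
    return thermogram, truth


def gen_avrami_trace(
    recipe: GeneratorRecipe,
    k: float = DEFAULTS["avrami"]["k"],
    d: float = DEFAULTS["avrami"]["d"],
    n: float = DEFAULTS["avrami"]["n"],
    plateau: float = 1.0,
    *,
    kind: Literal["dsc", "bds"] = "dsc",
    eps0: float = 8.0,
    eps_inf: float = 3.0,
    temperature: float = 368.15,
    t_max: float = 36000.0,
    dt: float = 600.0,
) -> Tuple[CrystallizationTrace, dict]:
    """Avrami conversion trace, as crystallinity (dsc) or raw ε′ (bds).

    For ``kind="bds"`` the observable is ε′(t) = ε′_0 − X(t)(ε′_0 − ε′_∞),
    so applying `epsilon_n` recovers the conversion curve exactly in the
    noiseless case.  Additive noise on the stored observable.
    """
    if not (0 < plateau <= 1):
        raise ValueError("plateau must lie in (0, 1]")
    t = np.arange(0.0, t_max + dt / 2, dt)
    x = avrami_conversion(t, k, d, n, plateau)
    if kind == "bds":
        obs = eps0 - x * (eps0 - eps_inf)
    else:
        obs = x
    rng = recipe.rng()
    if recipe.noise_sigma > 0:
        eps_noise = rng.normal(0.0, recipe.noise_sigma, obs.shape)
        obs = obs * (1.0 + eps_noise) if recipe.noise_model == "multiplicative" else obs + eps_noise
    trace = CrystallizationTrace(time=t, observable=obs, kind=kind, temperature=temperature)
    truth = {
        "k": k, "d": d, "n": n, "plateau": plateau,
        "eps0": eps0, "eps_inf": eps_inf, "kind": kind, "recipe": recipe,
    }
    return trace, truth


def linear_dcp_fraction_model(
    full_rigid_root: float = 0.839, free_percent: float = 0.0
) -> Callable[[float], Tuple[float, float]]:
    """(rigid%, free%) model whose mixture ΔC_p falls on a straight line.

    The mixture step is w·ΔC_p(pure)·(1 − rigid/100) with w = 1 − f; for
    it to be linear in the silica fraction f with root ``full_rigid_root``
    the rigid percent must be 100·(1 − (1 − f/root)/(1 − f)).
    """
    if not (0 < full_rigid_root <= 1):
        raise ValueError("full_rigid_root must lie in (0, 1]")

    def model(f: float) -> Tuple[float, float]:
        if f >= full_rigid_root:
            return 100.0, 0.0
        rigid = 100.0 * (1.0 - (1.0 - f / full_rigid_root) / (1.0 - f))
        return max(rigid, 0.0), free_percent

    return model


def gen_mixture_series(
    recipe: GeneratorRecipe,
    pure_delta_cp: float = DEFAULTS["delta_cp"],
    pure_cc_enthalpy: float = DEFAULTS["cc_enthalpy"],
    fraction_model: Optional[Callable[[float], Tuple[float, float]]] = None,
    ms_fractions: Sequence[float] = (0.17, 0.20, 0.25, 0.33, 0.50, 0.67),
) -> Tuple[list, dict]:
    """Mixture-ladder observables from a (rigid%, free%) fraction model.

    ``fraction_model`` maps silica mass fraction → (rigid, free) percents
    of drug mass; the observables are generated by inverting the fraction
    formulas, so `decompose` recovers the planted triple exactly in the
    noiseless case.  The default is :func:`linear_dcp_fraction_model` with
    a full-rigid root at 83.9% silica and no free fraction, so the ΔC_p
    ladder is an exact straight line through that root.
    """
    if fraction_model is None:
        fraction_model = linear_dcp_fraction_model()
    rng = recipe.rng()
    obs, truths = [], []
    for fms in ms_fractions:
        rigid, free = fraction_model(fms)
        if not (0 <= rigid <= 100 and 0 <= free <= 100):
            raise ValueError(f"fraction_model returned out-of-range values at {fms}")
        w = 1.0 - fms
        dcp = w * pure_delta_cp * (1.0 - rigid / 100.0)
        dh = w * pure_cc_enthalpy * free / 100.0
        if recipe.noise_sigma > 0:
            if recipe.noise_model == "multiplicative":
                dcp *= 1.0 + rng.normal(0, recipe.noise_sigma)
                dh *= 1.0 + rng.normal(0, recipe.noise_sigma)
            else:
                dcp += rng.normal(0, recipe.noise_sigma)
                dh += rng.normal(0, recipe.noise_sigma)
        obs.append(
            MixtureObservation(
                ms_mass_fraction=fms,
                delta_cp_mixture=max(dcp, 0.0),
                cc_enthalpy_mixture=max(dh, 0.0),
            )
        )
        truths.append({"ms_mass_fraction": fms, "rigid": rigid, "free": free,
                       "intermediate": 100.0 - rigid - free})
    truth = {
        "pure_delta_cp": pure_delta_cp,
        "pure_cc_enthalpy": pure_cc_enthalpy,
        "per_mixture": truths,
        "recipe": recipe,
    }
    return obs, truth
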