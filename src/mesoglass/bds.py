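"""Broadband dielectric spectroscopy: HN, VFT and KWW analysis.

The α relaxation of a supercooled drug glass appears as an asymmetric
loss peak in ε″(f).  Each isothermal sweep is fitted to a superposition
of Havriliak–Negami (HN) processes plus a dc-conductivity term,

    ε*(ω) = ε_∞ + Σ_j Δε_j / (1 + (i ω τ_HN,j)^a_j)^b_j − i σ_dc/(ε_0 ω),

the model relaxation time is mapped to the loss-peak α relaxation time

    τ_α = τ_HN [sin(aπ/(2+2b))]^(−1/a) [sin(abπ/(2+2b))]^(1/a),

its temperature dependence is fitted by Vogel–Fulcher–Tammann,
τ(T) = τ_0 exp(D T_0/(T−T_0)), and the loss-peak *shape* is summarized
by the stretching exponent β of the Kohlrausch–Williams–Watts decay
Φ(t) = exp(−(t/τ)^β), whose one-sided Fourier transform is matched to
the normalized loss peak.

Fitting conventions: loss-only objective on log10 ε″ over the measured
(log-spaced) frequencies, multi-start with jittered τ initializations;
two-process fits order the processes slow-to-fast to break the labelling
symmetry.  ε′ serves as a cross-check (the Δε of a process must match
the ε′ dispersion step), or can be fitted jointly via ``fit_real=True``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence, Tuple

import numpy as np
from lmfit import Parameters, minimize as lmfit_minimize
from scipy import integrate, optimize
from scipy.constants import epsilon_0

__all__ = [
    "DielectricSpectrum",
    "HNProcess",
    "HNFit",
    "VFTFit",
    "KWWFit",
    "NormalizedLoss",
    "FitFailure",
    "hn_model",
    "hn_loss",
    "fit_hn",
    "tau_alpha",
    "vft_tau",
    "fit_vft",
    "kww_loss",
    "fit_kww_beta",
    "normalize_loss",
]


class FitFailure(RuntimeError):
    """All fit starts failed to converge; carries diagnostics."""


# ---------------------------------------------------------------- containers

@dataclass(frozen=True)
class DielectricSpectrum:
    """One temperature's frequency sweep of complex permittivity."""

    frequency: np.ndarray   # Hz, strictly increasing
    eps_real: np.ndarray
    eps_imag: np.ndarray    # dielectric loss, >= 0
    temperature: float      # K

    def __post_init__(self):
        f = np.asarray(self.frequency, dtype=float)
        er = np.asarray(self.eps_real, dtype=float)
        ei = np.asarray(self.eps_imag, dtype=float)
        object.__setattr__(self, "frequency", f)
        object.__setattr__(self, "eps_real", er)
        object.__setattr__(self, "eps_imag", ei)
        if f.size < 20:
            raise ValueError(f"spectrum needs >= 20 frequency points, got {f.size}")
        if f.shape != er.shape or f.shape != ei.shape:
            raise ValueError("frequency, eps_real, eps_imag must be equally long")
        if np.any(np.diff(f) <= 0):
            raise ValueError("frequencies must be strictly increasing")
        if np.any(~np.isfinite(f)) or np.any(~np.isfinite(er)) or np.any(~np.isfinite(ei)):
            raise ValueError("spectrum contains NaN/inf")
        if np.any(f <= 0):
            raise ValueError("frequencies must be positive")


@dataclass(frozen=True)
class HNProcess:
    """One Havriliak–Negami relaxation process.

    ``a`` and ``b`` are the symmetric- and asymmetric-broadening shape
    exponents, both in (0, 1]; a = b = 1 is the Debye limit.
    """

    delta_eps: float
    tau_hn: float   # s
    a: float
    b: float

    def __post_init__(self):
        if self.delta_eps <= 0 or self.tau_hn <= 0:
            raise ValueError("delta_eps and tau_hn must be positive")
        if not (0 < self.a <= 1 and 0 < self.b <= 1):
            raise ValueError("shape exponents a, b must lie in (0, 1]")


@dataclass(frozen=True)
class HNFit:
    processes: Tuple[HNProcess, ...]
    eps_inf: float
    sigma_dc: float        # S/m
    residual: float        # relative RMS of loss (linear scale)
    covariance: Optional[dict] = None

    def __post_init__(self):
        if self.eps_inf < 1:
            raise ValueError("eps_inf must be >= 1")
        if self.sigma_dc < 0:
            raise ValueError("sigma_dc must be >= 0")


@dataclass(frozen=True)
class VFTFit:
    tau0: float     # s
    D: float
    T0: float       # K
    residual: float  # RMS on log10 tau

    def __post_init__(self):
        if self.tau0 <= 0 or self.D <= 0 or self.T0 <= 0:
            raise ValueError("tau0, D, T0 must be positive")


@dataclass(frozen=True)
class KWWFit:
    beta: float
    tau_kww: float
    residual: float

    def __post_init__(self):
        if not (0 < self.beta <= 1):
            raise ValueError("beta must lie in (0, 1]")
        if self.tau_kww <= 0:
            raise ValueError("tau_kww must be positive")


@dataclass(frozen=True)
class NormalizedLoss:
    """Loss spectrum scaled to unit peak (ε″/ε″_max versus f)."""

    frequency: np.ndarray
    loss: np.ndarray
    peak_frequency: float
    boundary_peak: bool = False


# ------------------------------------------------------------- forward model

def hn_model(
    processes: Sequence[HNProcess],
    eps_inf: float,
    sigma_dc: float,
    frequency: np.ndarray,
) -> np.ndarray:
    """Complex permittivity of an HN superposition with dc conductivity.

    Returns ε* = ε′ − i ε″ at each frequency (loss is the *negative*
    imaginary part, so ``-eps.imag`` is ≥ 0 for physical parameters).
    """
    f = np.asarray(frequency, dtype=float)
    if np.any(f <= 0):
        raise ValueError("frequencies must be positive (conductivity term diverges at 0)")
    w = 2.0 * np.pi * f
    eps = np.full(f.shape, complex(eps_inf))
    for p in processes:
        eps = eps + p.delta_eps / (1.0 + (1j * w * p.tau_hn) ** p.a) ** p.b
    if sigma_dc:
        eps = eps - 1j * sigma_dc / (epsilon_0 * w)
    return eps


def hn_loss(
    processes: Sequence[HNProcess],
    sigma_dc: float,
    frequency: np.ndarray,
) -> np.ndarray:
    """Dielectric loss ε″(f) of the HN superposition (ε_∞ drops out)."""
    return -hn_model(processes, 1.0, sigma_dc, frequency).imag


def tau_alpha(process: HNProcess) -> float:
    """α relaxation time: reciprocal angular frequency of the HN loss peak.

    For the HN shape the loss maximum sits at
    ω_max τ_HN = [sin(aπ/(2+2b)) / sin(abπ/(2+2b))]^(1/a), hence
    τ_α = 1/ω_max; in the Debye limit (a = b = 1) τ_α = τ_HN.
    """
    a, b = process.a, process.b
    s1 = np.sin(np.pi * a / (2.0 + 2.0 * b))
    s2 = np.sin(np.pi * a * b / (2.0 + 2.0 * b))
    return process.tau_hn * s1 ** (-1.0 / a) * s2 ** (1.0 / a)


# ---------------------------------------------------------------- HN fitting

def _loss_peak_index(loss: np.ndarray) -> int:
    return int(np.argmax(loss))


def _estimate_sigma_dc(f: np.ndarray, loss: np.ndarray) -> float:
    """Rough σ_dc from the low-frequency flank if it shows slope ≈ −1."""
    n = max(4, f.size // 8)
    lo_f, lo_l = np.log10(f[:n]), np.log10(np.maximum(loss[:n], 1e-300))
    slope, intercept = np.polyfit(lo_f, lo_l, 1)
    if slope < -0.8:
        # loss ≈ sigma/(2π ε0 f)  =>  sigma = loss·2π ε0 f at the lowest point
        return float(loss[0] * 2.0 * np.pi * epsilon_0 * f[0])
    return 0.0


def _params_to_processes(params: Parameters, n: int) -> Tuple[HNProcess, ...]:
    procs = []
    log_tau_prev = None
    for j in range(n):
        log_tau = params[f"log_tau{j}"].value
        if j > 0:
            log_tau = log_tau_prev - params[f"log_tau_gap{j}"].value
        procs.append(
            HNProcess(
                delta_eps=10.0 ** params[f"log_de{j}"].value,
                tau_hn=10.0 ** log_tau,
                a=params[f"a{j}"].value,
                b=params[f"b{j}"].value,
            )
        )
        log_tau_prev = log_tau
    return tuple(procs)


def fit_hn(
    spectrum: DielectricSpectrum,
    n_processes: int = 1,
    init: Optional[Sequence[HNProcess]] = None,
    *,
    sigma_dc_init: Optional[float] = None,
    fit_real: bool = False,
    n_starts: int = 5,
    seed: int = 0,
) -> HNFit:
    """Fit 1–2 HN processes (+ σ_dc) to a loss spectrum.

    The objective is least squares on log10 ε″ over the measured
    frequencies (log-spaced grids and decades of dynamic range make the
    linear scale useless); with ``fit_real=True`` the ε′ residual is
    appended.  Each fit is restarted from ``n_starts`` τ-jittered
    initializations (±0.5 decade) and the best solution kept.  For two
    processes the slow process is listed first, enforced through a
    non-negative log-τ gap parameter.
    """
    if n_processes not in (1, 2):
        raise ValueError("n_processes must be 1 or 2")
    f = spectrum.frequency
    loss = spectrum.eps_imag
    if np.any(loss <= 0):
        raise ValueError("loss must be strictly positive for log-scale fitting")
    rng = np.random.default_rng(seed)

    sigma0 = _estimate_sigma_dc(f, loss) if sigma_dc_init is None else sigma_dc_init
    i_pk = _loss_peak_index(loss)
    tau_pk = 1.0 / (2.0 * np.pi * f[i_pk])
    de_pk = 2.0 * loss[i_pk]

    if init is not None:
        init_procs = list(init)
        if len(init_procs) != n_processes:
            raise ValueError("init must supply one HNProcess per fitted process")
    elif n_processes == 1:
        init_procs = [HNProcess(de_pk, tau_pk, 0.8, 0.6)]
    else:
        # Slow process at the observed peak, fast one three decades up.
        init_procs = [
            HNProcess(de_pk, tau_pk, 0.8, 0.6),
            HNProcess(de_pk / 3.0, tau_pk / 1e3, 0.8, 0.6),
        ]

    eps_inf_est = float(np.mean(spectrum.eps_real[-max(3, f.size // 10):]))
    eps_inf_est = max(eps_inf_est, 1.0)
    log_loss = np.log10(loss)

    def residual(params):
        procs = _params_to_processes(params, n_processes)
        sigma = 10.0 ** params["log_sigma"].value if params["fit_sigma"].value else 0.0
        model = hn_model(procs, params["eps_inf"].value, sigma, f)
        r = np.log10(np.maximum(-model.imag, 1e-300)) - log_loss
        if fit_real:
            r = np.concatenate([r, (model.real - spectrum.eps_real) / eps_inf_est])
        return r

    best = None
    errors = []
    for start in range(n_starts):
        params = Parameters()
        params.add("fit_sigma", value=1 if sigma0 > 0 else 0, vary=False)
        params.add("eps_inf", value=eps_inf_est, min=1.0, vary=fit_real)
        params.add(
            "log_sigma",
            value=np.log10(sigma0) if sigma0 > 0 else -20.0,
            min=-20.0, max=2.0, vary=sigma0 > 0,
        )
        for j, p in enumerate(init_procs):
            jitter = 0.0 if start == 0 else rng.uniform(-0.5, 0.5)
            params.add(f"log_de{j}", value=np.log10(p.delta_eps), min=-4, max=6)
            if j == 0:
                params.add(f"log_tau{j}", value=np.log10(p.tau_hn) + jitter, min=-14, max=8)
            else:
                gap0 = np.log10(init_procs[0].tau_hn / p.tau_hn)
                params.add(f"log_tau{j}", value=0.0, vary=False)
                params.add(f"log_tau_gap{j}", value=max(gap0 + jitter, 0.3), min=0.0, max=12.0)
            params.add(f"a{j}", value=p.a, min=0.05, max=1.0)
            params.add(f"b{j}", value=p.b, min=0.05, max=1.0)
        try:
            out = lmfit_minimize(residual, params, method="leastsq")
        except Exception as exc:  # noqa: BLE001 - collected as diagnostics
            errors.append(f"start {start}: {exc}")
            continue
        if not out.success:
            errors.append(f"start {start}: {out.message}")
            continue
        if best is None or out.chisqr < best.chisqr:
            best = out
    if best is None:
        raise FitFailure(
            f"HN fit failed from all {n_starts} starts: " + "; ".join(errors)
        )

    procs = _params_to_processes(best.params, n_processes)
    sigma = 10.0 ** best.params["log_sigma"].value if sigma0 > 0 else 0.0
    model_loss = hn_loss(procs, sigma, f)
    rel_rms = float(np.sqrt(np.mean(((model_loss - loss) / loss) ** 2)))
    cov = None
    if best.errorbars:
        cov = {name: best.params[name].stderr for name in best.var_names}
    return HNFit(
        processes=procs,
        eps_inf=float(best.params["eps_inf"].value),
        sigma_dc=float(sigma),
        residual=rel_rms,
        covariance=cov,
    )


# --------------------------------------------------------------------- VFT

def vft_tau(T: np.ndarray, tau0: float, D: float, T0: float) -> np.ndarray:
    """Vogel–Fulcher–Tammann relaxation time τ(T) = τ_0 exp(D T_0/(T−T_0))."""
    T = np.asarray(T, dtype=float)
    if np.any(T <= T0):
        raise ValueError("all temperatures must exceed T0")
    return tau0 * np.exp(D * T0 / (T - T0))


def fit_vft(tau_by_temperature: Sequence[Tuple[float, float]]) -> VFTFit:
    """Fit the VFT law to (temperature K, τ s) pairs.

    Least squares on log10 τ.  Initialization scans candidate T0 values;
    for each, log10 τ is linear in 1/(T−T0), so τ_0 and D·T_0 come from a
    closed-form regression and the best scan point seeds a nonlinear
    polish.  Needs at least three points (three parameters); an exactly
    determined 3-point system is interpolated to machine accuracy.
    """
    pts = [(float(T), float(tau)) for T, tau in tau_by_temperature]
    if len(pts) < 3:
        raise ValueError(f"need >= 3 (T, tau) points for a VFT fit, got {len(pts)}")
    T = np.array([p[0] for p in pts])
    y = np.log10([p[1] for p in pts])
    if np.any(T <= 0):
        raise ValueError("temperatures must be positive kelvin")

    ln10 = np.log(10.0)
    t_floor = 0.01

    def scan_residual(T0):
        x = 1.0 / (T - T0)
        slope, intercept = np.polyfit(x, y, 1)
        return float(np.sum((np.polyval([slope, intercept], x) - y) ** 2)), slope, intercept

    best_T0, best_sse, best_lin = t_floor, np.inf, None
    for T0 in np.linspace(t_floor, T.min() - 0.5, 400):
        sse, slope, intercept = scan_residual(T0)
        if slope > 0 and sse < best_sse:
            best_T0, best_sse, best_lin = T0, sse, (slope, intercept)
    if best_lin is None:
        raise ValueError("tau does not increase toward low temperature; VFT inapplicable")

    slope, intercept = best_lin
    lo = np.array([-30.0, 1e-6, t_floor])
    hi = np.array([5.0, 1e7, T.min() - 1e-6])
    p0 = np.clip(
        [intercept, slope * ln10 / best_T0, best_T0],  # log10 tau0, D, T0
        lo + 1e-12, hi - 1e-12,
    )

    def resid(p):
        log_tau0, D, T0 = p
        if T0 >= T.min() or T0 < t_floor or D <= 0:
            return np.full_like(y, 1e6)
        return log_tau0 + D * T0 / (ln10 * (T - T0)) - y

    sol = optimize.least_squares(resid, p0, bounds=(lo, hi), xtol=1e-14, ftol=1e-14)
    log_tau0, D, T0 = sol.x
    rms = float(np.sqrt(np.mean(sol.fun**2)))
    return VFTFit(tau0=float(10.0**log_tau0), D=float(D), T0=float(T0), residual=rms)


# --------------------------------------------------------------------- KWW

def _kww_sin_transform(u_grid_w: float, beta: float) -> float:
    """∫_0^∞ β u^(β−1) exp(−u^β) sin(w u) du  (w = ω τ, dimensionless).

    Integrating by parts turns this into w·∫_0^∞ exp(−u^β) cos(w u) du,
    whose integrand is smooth at the origin (the raw form has an
    integrable u^(β−1) singularity that spoils oscillatory quadrature);
    the Fourier-weight QAWF rule then converges to near machine accuracy.
    """
    if u_grid_w == 0.0:
        return 0.0
    w = u_grid_w
    decay = lambda u: np.exp(-(u**beta))  # noqa: E731
    # support of the envelope: exp(-u^beta) < 6e-16 beyond u = 35^(1/beta)
    support = min(35.0 ** (1.0 / beta), 1e7)
    n_cycles = w * support / (2.0 * np.pi)
    if n_cycles <= 20.0:
        # few oscillations inside the envelope: ordinary adaptive
        # quadrature on the finite support is accurate, whereas QAWF's
        # cycle machinery breaks down when the cycle dwarfs the decay
        val, _ = integrate.quad(
            lambda u: decay(u) * np.cos(w * u), 0.0, support,
            limit=500, epsabs=1e-13, epsrel=1e-11,
        )
    else:
        # keep the origin (infinite-derivative point of exp(-u^beta) for
        # beta < 1) out of QAWF's first cycle
        a = min(1.0, 2.0 * np.pi / w)
        i1, _ = integrate.quad(
            lambda u: decay(u) * np.cos(w * u), 0.0, a,
            limit=200, epsabs=1e-14, epsrel=1e-12,
        )
        with warnings.catch_warnings():
            # QAWF flags slowly-decaying envelopes (small beta, small w)
            # as "bad behavior" although the extrapolated result matches
            # high-precision reference quadrature to ~1e-15
            warnings.simplefilter("ignore", integrate.IntegrationWarning)
            i2, _ = integrate.quad(
                decay, a, np.inf, weight="cos", wvar=w, limit=400, epsabs=1e-13,
            )
        val = i1 + i2
    return w * val


def _kww_loss_unnormalized(w: np.ndarray, beta: float) -> np.ndarray:
    """Loss shape ε″(ωτ)/Δε of the KWW decay, by Fourier quadrature."""
    if beta == 1.0:
        return w / (1.0 + w**2)
    return np.array([_kww_sin_transform(wi, beta) for wi in np.atleast_1d(w)])


def _kww_peak(beta: float) -> Tuple[float, float]:
    """(ωτ at peak, peak value) of the KWW loss shape."""
    if beta == 1.0:
        return 1.0, 0.5
    res = optimize.minimize_scalar(
        lambda lw: -_kww_sin_transform(np.exp(lw), beta),
        bounds=(np.log(1e-3), np.log(1e3)),
        method="bounded",
        options={"xatol": 1e-8},
    )
    return float(np.exp(res.x)), float(-res.fun)


def kww_loss(beta: float, tau_kww: float, frequency: np.ndarray) -> np.ndarray:
    """Frequency-domain KWW loss, normalized to unit peak.

    The loss is the one-sided sine transform of −dΦ/dt with
    Φ(t) = exp(−(t/τ)^β), evaluated by adaptive Fourier quadrature and
    divided by the peak value of the continuous curve (so the returned
    values are ≤ 1, reaching 1 at the loss maximum).
    """
    if not (0 < beta <= 1):
        raise ValueError("beta must lie in (0, 1]")
    if tau_kww <= 0:
        raise ValueError("tau_kww must be positive")
    f = np.asarray(frequency, dtype=float)
    w = 2.0 * np.pi * f * tau_kww
    _, peak_val = _kww_peak(beta)
    return _kww_loss_unnormalized(w, beta) / peak_val


def fit_kww_beta(
    normalized: NormalizedLoss,
    *,
    beta_bounds: Tuple[float, float] = (0.1, 1.0),
) -> KWWFit:
    """Fit the KWW stretching exponent to a normalized loss peak.

    Minimizes the squared residual between the data and the unit-peak KWW
    loss shape over (β, τ) on the measured log-frequency grid.  The input
    must be single-peaked with its maximum inside the grid.
    """
    f = np.asarray(normalized.frequency, dtype=float)
    y = np.asarray(normalized.loss, dtype=float)
    if normalized.boundary_peak:
        raise ValueError("loss peak sits at the grid boundary; cannot fit a shape")
    i_pk = int(np.argmax(y))
    if i_pk == 0 or i_pk == y.size - 1:
        raise ValueError("loss peak sits at the grid boundary; cannot fit a shape")
    # Single-peak check: no second local maximum above 30% prominence.
    interior = y[1:-1]
    local_max = (interior > y[:-2]) & (interior > y[2:]) & (interior > 0.3)
    if np.count_nonzero(local_max) > 1:
        raise ValueError("loss spectrum is not single-peaked")

    f_pk = f[i_pk]

    def objective(p):
        beta, log_tau = p
        beta = float(np.clip(beta, *beta_bounds))
        model = kww_loss(beta, 10.0**log_tau, f)
        return model - y

    best = None
    for beta0 in (0.4, 0.6, 0.8):
        wpk, _ = _kww_peak(beta0)
        log_tau0 = np.log10(wpk / (2.0 * np.pi * f_pk))
        sol = optimize.least_squares(
            objective, [beta0, log_tau0],
            bounds=([beta_bounds[0], log_tau0 - 4], [beta_bounds[1], log_tau0 + 4]),
            xtol=1e-12, ftol=1e-12,
        )
        if best is None or sol.cost < best.cost:
            best = sol
    beta, log_tau = best.x
    rms = float(np.sqrt(np.mean(best.fun**2)))
    return KWWFit(beta=float(beta), tau_kww=float(10.0**log_tau), residual=rms)


def normalize_loss(
    spectrum: DielectricSpectrum,
    hn_fit: Optional[HNFit] = None,
) -> NormalizedLoss:
    """Scale a loss spectrum to unit peak (ε″/ε″_max).

    When an :class:`HNFit` is supplied its conductivity term is
    subtracted first, so a dc-dominated low-frequency tail does not
    masquerade as the relaxation peak.  A peak located at the first or
    last grid point sets ``boundary_peak`` instead of raising.
    """
    loss = spectrum.eps_imag.astype(float).copy()
    if hn_fit is not None and hn_fit.sigma_dc > 0:
        loss = loss - hn_fit.sigma_dc / (
            epsilon_0 * 2.0 * np.pi * spectrum.frequency
        )
    if np.all(loss <= 0):
        raise ValueError("loss is non-positive everywhere after conductivity removal")
    i_pk = int(np.argmax(loss))
    boundary = i_pk in (0, loss.size - 1)
    if boundary:
        warnings.warn(
            "loss peak sits at the grid boundary; normalization unreliable",
            UserWarning,
            stacklevel=2,
        )
    return NormalizedLoss(
        frequency=spectrum.frequency.copy(),
        loss=loss / loss[i_pk],
        peak_frequency=float(spectrum.frequency[i_pk]),
        boundary_peak=boundary,
    )
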