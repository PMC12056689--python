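"""Havriliak–Negami forward model, τ_α mapping and spectrum fitting.

The forward-model oracle is mpmath complex arithmetic at 30 digits; the
τ_α oracle is a dense numerical scan for the loss maximum.  Fit-recovery
tests score against generator truth at fixed seeds.
"""

import mpmath as mp
import numpy as np
import pytest
from scipy.constants import epsilon_0

from mesoglass.bds import (
    DielectricSpectrum,
    HNProcess,
    fit_hn,
    hn_loss,
    hn_model,
    normalize_loss,
    tau_alpha,
)
from mesoglass.synthetic import GeneratorRecipe, gen_hn_spectrum


def _mp_hn_loss(delta_eps, tau, a, b, f):
    """Arbitrary-precision evaluation of the HN loss at one frequency."""
    with mp.workdps(30):
        w = 2 * mp.pi * mp.mpf(float(f))
        val = mp.mpf(float(delta_eps)) / (1 + (1j * w * mp.mpf(float(tau))) ** mp.mpf(float(a))) ** mp.mpf(float(b))
        return float(-mp.im(val))


class TestForwardModel:
    def test_debye_half_height_identity(self):
        p = HNProcess(delta_eps=4.0, tau_hn=1e-3, a=1.0, b=1.0)
        f_at_wtau_1 = 1.0 / (2 * np.pi * p.tau_hn)
        loss = hn_loss([p], 0.0, np.array([f_at_wtau_1]))
        assert loss[0] == pytest.approx(p.delta_eps / 2.0, rel=1e-12)

    def test_conductivity_only_spectrum_has_slope_minus_one(self):
        f = np.logspace(-2, 7, 50)
        loss = hn_loss([], 1e-10, f)
        slope = np.polyfit(np.log10(f), np.log10(loss), 1)[0]
        assert slope == pytest.approx(-1.0, abs=1e-12)
        assert loss[0] == pytest.approx(1e-10 / (epsilon_0 * 2 * np.pi * f[0]), rel=1e-12)

    @pytest.mark.parametrize("f", [1e-2, 1.0, 1e2, 1e5])
    def test_matches_arbitrary_precision_oracle(self, f):
        p = HNProcess(delta_eps=5.0, tau_hn=1e-3, a=0.8, b=0.5)
        ours = hn_loss([p], 0.0, np.array([f]))[0]
        oracle = _mp_hn_loss(5.0, 1e-3, 0.8, 0.5, f)
        assert abs(ours - oracle) < 1e-10

    def test_zero_frequency_with_conductivity_rejected(self):
        with pytest.raises(ValueError):
            hn_model([], 3.0, 1e-10, np.array([0.0, 1.0]))

    def test_loss_non_negative_for_physical_parameters(self, rng):
        f = np.logspace(-2, 7, 40)
        for _ in range(20):
            p = HNProcess(
                delta_eps=float(rng.uniform(0.5, 20)),
                tau_hn=float(10 ** rng.uniform(-8, 0)),
                a=float(rng.uniform(0.2, 1.0)),
                b=float(rng.uniform(0.2, 1.0)),
            )
            assert np.all(hn_loss([p], 0.0, f) >= 0)


class TestTauAlpha:
    def test_debye_limit_equals_tau_hn(self):
        p = HNProcess(1.0, 2.5e-4, 1.0, 1.0)
        assert tau_alpha(p) == pytest.approx(p.tau_hn, rel=1e-14)

    @pytest.mark.parametrize("a,b,tau", [(0.8, 0.5, 1e-3), (0.6, 0.9, 1.0)])
    def test_equals_numerical_loss_peak_reciprocal(self, a, b, tau):
        p = HNProcess(5.0, tau, a, b)
        f = np.logspace(np.log10(1 / tau) - 6, np.log10(1 / tau) + 6, 400001)
        loss = hn_loss([p], 0.0, f)
        f_peak = f[np.argmax(loss)]
        assert tau_alpha(p) == pytest.approx(1.0 / (2 * np.pi * f_peak), rel=0.005)

    def test_property_over_random_shape_draws(self, rng):
        for _ in range(100):
            a = float(rng.uniform(0.2, 1.0))
            b = float(rng.uniform(0.2, 1.0))
            p = HNProcess(1.0, 1e-3, a, b)
            f = np.logspace(-4, 6, 100001)
            f_peak = f[np.argmax(hn_loss([p], 0.0, f))]
            assert tau_alpha(p) == pytest.approx(1 / (2 * np.pi * f_peak), rel=0.01)


class TestFitSingleProcess:
    TRUTH = HNProcess(delta_eps=5.0, tau_hn=1e-3, a=0.8, b=0.5)

    def test_noiseless_self_consistency(self):
        spec, _ = gen_hn_spectrum(GeneratorRecipe(seed=1), [self.TRUTH])
        fit = fit_hn(spec, 1, seed=1)
        p = fit.processes[0]
        assert p.delta_eps == pytest.approx(self.TRUTH.delta_eps, rel=1e-3)
        assert p.tau_hn == pytest.approx(self.TRUTH.tau_hn, rel=1e-3)
        assert p.a == pytest.approx(self.TRUTH.a, abs=1e-3)
        assert p.b == pytest.approx(self.TRUTH.b, abs=1e-3)

    def test_recovery_under_noise_with_conductivity(self):
        spec, _ = gen_hn_spectrum(
            GeneratorRecipe(seed=2, noise_sigma=0.02), [self.TRUTH], sigma_dc=1e-11
        )
        fit = fit_hn(spec, 1, seed=3)
        p = fit.processes[0]
        assert p.delta_eps == pytest.approx(self.TRUTH.delta_eps, rel=0.05)
        assert p.tau_hn == pytest.approx(self.TRUTH.tau_hn, rel=0.05)
        assert p.a == pytest.approx(self.TRUTH.a, abs=0.05)
        assert p.b == pytest.approx(self.TRUTH.b, abs=0.05)
        assert fit.sigma_dc == pytest.approx(1e-11, rel=0.2)

    def test_graceful_degradation_at_double_noise(self):
        spec, _ = gen_hn_spectrum(
            GeneratorRecipe(seed=4, noise_sigma=0.04), [self.TRUTH]
        )
        fit = fit_hn(spec, 1, seed=5)
        p = fit.processes[0]
        assert p.delta_eps == pytest.approx(self.TRUTH.delta_eps, rel=0.10)
        assert p.tau_hn == pytest.approx(self.TRUTH.tau_hn, rel=0.10)

    def test_kramers_kronig_sanity_delta_eps_matches_real_step(self):
        spec, _ = gen_hn_spectrum(GeneratorRecipe(seed=6), [self.TRUTH], eps_inf=3.0)
        fit = fit_hn(spec, 1, seed=6)
        real_step = spec.eps_real[0] - spec.eps_real[-1]
        assert fit.processes[0].delta_eps == pytest.approx(real_step, rel=0.02)


class TestFitTwoProcess:
    def test_deconvolution_at_three_decade_tau_ratio(self):
        slow = HNProcess(delta_eps=6.0, tau_hn=1e-2, a=0.8, b=0.6)
        fast = HNProcess(delta_eps=2.0, tau_hn=1e-5, a=0.8, b=0.6)
        spec, _ = gen_hn_spectrum(
            GeneratorRecipe(seed=7, noise_sigma=0.02), [slow, fast]
        )
        fit = fit_hn(spec, 2, seed=8)
        assert fit.processes[0].tau_hn > fit.processes[1].tau_hn  # ordering
        assert fit.processes[0].tau_hn == pytest.approx(slow.tau_hn, rel=0.10)
        assert fit.processes[1].tau_hn == pytest.approx(fast.tau_hn, rel=0.10)


class TestNormalizeLoss:
    def test_peak_is_exactly_one_and_idempotent(self):
        spec, _ = gen_hn_spectrum(GeneratorRecipe(seed=9), [TestFitSingleProcess.TRUTH])
        norm = normalize_loss(spec)
        assert norm.loss.max() == pytest.approx(1.0)
        renorm = normalize_loss(
            DielectricSpectrum(norm.frequency, spec.eps_real, norm.loss, spec.temperature)
        )
        assert np.allclose(renorm.loss, norm.loss)

    def test_conductivity_tail_removed_before_peak_location(self):
        p = HNProcess(delta_eps=5.0, tau_hn=1e-3, a=0.8, b=0.5)
        spec, _ = gen_hn_spectrum(GeneratorRecipe(seed=10), [p], sigma_dc=3e-10)
        fit = fit_hn(spec, 1, seed=10)
        norm = normalize_loss(spec, fit)
        true_peak = 1.0 / (2 * np.pi * tau_alpha(p))
        # within one grid step (8 points/decade)
        assert abs(np.log10(norm.peak_frequency) - np.log10(true_peak)) < 1.0 / 8 + 1e-9

    def test_boundary_peak_flagged(self):
        f = np.logspace(2, 7, 30)
        loss = 1.0 / f  # monotone: "peak" at the low edge
        with pytest.warns(UserWarning, match="boundary"):
            norm = normalize_loss(DielectricSpectrum(f, np.full(30, 3.0), loss, 300.0))
        assert norm.boundary_peak
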