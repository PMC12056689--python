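"""Rigid / intermediate / free decomposition and the full-rigid extrapolation."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

from mesoglass.fractions import (
    MixtureObservation,
    decompose,
    extrapolate_full_rigid_load,
    free_fraction,
    rigid_fraction,
)
from mesoglass.synthetic import GeneratorRecipe, gen_mixture_series, linear_dcp_fraction_model

PURE_DCP = 0.45   # J/(g·K) per gram of drug glass
PURE_DH = 60.0    # J/g cold-crystallization, per gram of drug glass


class TestRigidFraction:
    def test_fully_mobile_glass_has_zero_rigid(self):
        obs = MixtureObservation(0.33, 0.67 * PURE_DCP)
        assert rigid_fraction(obs, PURE_DCP) == pytest.approx(0.0, abs=1e-12)

    def test_vanished_step_means_fully_rigid(self):
        obs = MixtureObservation(0.33, 0.0)
        assert rigid_fraction(obs, PURE_DCP) == pytest.approx(100.0)

    def test_consistency_with_reported_mixture_value(self):
        # inverted fixture: w = 0.67, mixture step 0.2558 J/(g·K) -> 15.2%
        obs = MixtureObservation(0.33, 0.2558)
        assert rigid_fraction(obs, PURE_DCP) == pytest.approx(15.2, abs=0.1)


class TestFreeFraction:
    def test_bulk_like_mixture_is_fully_free(self):
        obs = MixtureObservation(0.25, 0.3, cc_enthalpy_mixture=0.75 * PURE_DH)
        assert free_fraction(obs, PURE_DH) == pytest.approx(100.0)

    def test_no_cold_crystallization_means_zero_free(self):
        obs = MixtureObservation(0.25, 0.3, cc_enthalpy_mixture=0.0)
        assert free_fraction(obs, PURE_DH) == pytest.approx(0.0)

    def test_consistency_with_reported_mixture_value(self):
        # inverted fixture: w = 0.75, mixture enthalpy 38.1 J/g -> 84.7%
        obs = MixtureObservation(0.25, 0.3, cc_enthalpy_mixture=38.1)
        assert free_fraction(obs, PURE_DH) == pytest.approx(84.7, abs=0.1)


class TestDecompose:
    @pytest.mark.parametrize(
        "dcp,dh,expected",
        [
            (0.75 * PURE_DCP, 0.75 * PURE_DH, (0.0, 100.0, 0.0)),   # all free
            (0.0, 0.0, (100.0, 0.0, 0.0)),                          # all rigid
        ],
    )
    def test_pure_population_corners(self, dcp, dh, expected):
        prof = decompose(MixtureObservation(0.25, dcp, dh), PURE_DCP, PURE_DH)
        assert (prof.rigid, prof.free, prof.intermediate) == pytest.approx(expected, abs=1e-9)

    def test_intermediate_is_the_complement(self):
        obs = MixtureObservation(0.33, 0.2558, 0.0)
        prof = decompose(obs, PURE_DCP, PURE_DH)
        assert prof.rigid == pytest.approx(15.2, abs=0.1)
        assert prof.intermediate == pytest.approx(84.8, abs=0.1)

    @given(
        w=st.floats(min_value=0.2, max_value=0.95),
        mobile=st.floats(min_value=0.0, max_value=1.0),
        free=st.floats(min_value=0.0, max_value=1.0),
    )
    def test_raw_triple_always_sums_to_100(self, w, mobile, free):
        obs = MixtureObservation(1 - w, w * PURE_DCP * mobile, w * PURE_DH * free)
        prof = decompose(obs, PURE_DCP, PURE_DH)
        assert prof.raw_rigid + prof.raw_free + prof.raw_intermediate == pytest.approx(100.0)
        assert prof.rigid + prof.free + prof.intermediate == pytest.approx(100.0)

    def test_scale_invariance_of_enthalpic_observables(self):
        obs1 = MixtureObservation(0.33, 0.2, 10.0)
        obs2 = MixtureObservation(0.33, 0.2 * 7, 10.0 * 7)
        p1 = decompose(obs1, PURE_DCP, PURE_DH)
        p2 = decompose(obs2, PURE_DCP * 7, PURE_DH * 7)
        assert (p1.rigid, p1.free) == pytest.approx((p2.rigid, p2.free))

    def test_drug_free_mixture_rejected(self):
        with pytest.raises(ValueError):
            MixtureObservation(1.0, 0.0)


class TestFullRigidExtrapolation:
    def test_collinear_points_give_exact_root(self):
        obs = [
            MixtureObservation(0.0, 0.45),
            MixtureObservation(0.45, 0.225),
            MixtureObservation(0.9, 1e-15),
        ]
        fit = extrapolate_full_rigid_load(obs)
        assert fit.ms_fraction_full_rigid == pytest.approx(0.90, abs=1e-9)
        assert fit.r_squared == pytest.approx(1.0)

    def test_planted_root_recovered_under_noise(self):
        # single noisy ladders scatter the root by ~0.015, so score the
        # median over ten seeded replicates against the planted value
        errs = []
        for seed in range(10):
            obs, _ = gen_mixture_series(
                GeneratorRecipe(seed=seed, noise_sigma=0.01, noise_model="additive"),
                fraction_model=linear_dcp_fraction_model(0.839),
            )
            fit = extrapolate_full_rigid_load(obs)
            errs.append(abs(fit.ms_fraction_full_rigid - 0.839))
        assert float(np.median(errs)) < 0.02

    def test_constant_series_has_no_extrapolation(self):
        obs = [MixtureObservation(f, 0.3) for f in (0.1, 0.3, 0.5)]
        with pytest.raises(ValueError, match="decrease"):
            extrapolate_full_rigid_load(obs)

    def test_narrow_span_rejected(self):
        obs = [MixtureObservation(f, 0.4 - f / 10) for f in (0.30, 0.35, 0.40)]
        with pytest.raises(ValueError, match="span"):
            extrapolate_full_rigid_load(obs)


class TestPipelineProperty:
    def test_generator_to_decomposition_round_trip_is_exact_noiselessly(self):
        obs, truth = gen_mixture_series(GeneratorRecipe(seed=5))
        for o, t in zip(obs, truth["per_mixture"]):
            prof = decompose(o, truth["pure_delta_cp"], truth["pure_cc_enthalpy"])
            assert prof.rigid == pytest.approx(t["rigid"], abs=1e-9)
            assert prof.free == pytest.approx(t["free"], abs=1e-9)

    def test_thermogram_level_round_trip(self):
        # build full thermograms for two mixtures, extract the observables
        # with the DSC feature code, then decompose
        from mesoglass.dsc import detect_glass_transition, integrate_peak
        from mesoglass.synthetic import PeakSpec, gen_thermogram

        cases = [(0.25, 10.0, 80.0), (0.33, 30.0, 0.0)]  # (f_ms, rigid%, free%)
        for f_ms, rigid, free in cases:
            w = 1.0 - f_ms
            dcp = w * PURE_DCP * (1.0 - rigid / 100.0)
            dh = w * PURE_DH * free / 100.0
            peaks = [PeakSpec(center=120.0, sigma=3.0, enthalpy=dh)] if dh else []
            tg, _ = gen_thermogram(
                GeneratorRecipe(seed=8, noise_sigma=0.002, noise_model="additive"),
                tg_onset=56.0, delta_cp=dcp, width=4.0, peaks=peaks,
            )
            gt = detect_glass_transition(tg, (40.0, 80.0))
            dh_meas = integrate_peak(tg, (100.0, 140.0)).enthalpy if dh else 0.0
            prof = decompose(
                MixtureObservation(f_ms, gt.delta_cp, dh_meas), PURE_DCP, PURE_DH
            )
            assert abs(prof.rigid - rigid) < 3.0
            assert abs(prof.free - free) < 3.0

    def test_noisy_recovery_within_three_points(self):
        model = linear_dcp_fraction_model(0.85, free_percent=20.0)
        obs, truth = gen_mixture_series(
            GeneratorRecipe(seed=6, noise_sigma=0.003, noise_model="additive"),
            fraction_model=model,
        )
        for o, t in zip(obs, truth["per_mixture"]):
            prof = decompose(o, truth["pure_delta_cp"], truth["pure_cc_enthalpy"])
            assert abs(prof.rigid - t["rigid"]) < 3.0
            assert abs(prof.free - t["free"]) < 3.0
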