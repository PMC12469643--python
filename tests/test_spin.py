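"""Spectral densities and the four relaxation-rate expressions.

Frozen expected values were computed by independent scalar evaluation of
the rate formulas (plain-python arithmetic on the physical constants,
outside the package) before the implementation was written.
"""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from relaxsel.spin import (
    GAMMA_H,
    GAMMA_N,
    InteractionConstants,
    ModelFreeParams,
    MultiExpSpectrum,
    all_rates,
    eval_J_extended,
    eval_J_multiexp,
    eval_J_simple,
    rate_NOE,
    rate_R1,
    rate_R2,
    rate_eta_xy,
)
from conftest import quadrature_J

TAU_C = 14.7e-9


def J_simple(s2, tau_c):
    return lambda w: eval_J_simple(s2, tau_c, w)


class TestSpectralDensities:
    def test_zero_frequency_is_s2_tau_c(self):
        assert eval_J_simple(1.0, TAU_C, 0.0) == pytest.approx(TAU_C)
        assert eval_J_simple(0.85, 5e-9, 0.0) == pytest.approx(0.85 * 5e-9)

    def test_fully_disordered_limit_vanishes(self):
        assert eval_J_simple(0.0, TAU_C, 1e8) == 0.0

    def test_frozen_scalar_value(self, constants):
        # hand evaluation: S²=0.85, τc=14.7 ns at ωN(600.13 MHz)
        assert eval_J_simple(0.85, TAU_C, constants.omega_N) == pytest.approx(
            3.834106347168691e-10, rel=1e-12)

    def test_negative_tau_c_rejected(self):
        with pytest.raises(ValueError):
            eval_J_simple(0.5, -1e-9, 0.0)

    def test_extended_reduces_to_simple_when_slow_motion_absent(self):
        p = ModelFreeParams(s2_fast=0.9, s2_slow=1.0, tau_e=3e-9, tau_c=TAU_C)
        for w in (0.0, 1e8, 4e9):
            assert eval_J_extended(p, w) == pytest.approx(
                eval_J_simple(0.9, TAU_C, w), rel=1e-12)

    def test_extended_frozen_value_at_zero_frequency(self):
        # term-by-term hand computation: S²f=0.9, S²s=0.5, τe=1 ns, τc=14.7 ns
        p = ModelFreeParams(s2_fast=0.9, s2_slow=0.5, tau_e=1e-9, tau_c=TAU_C)
        assert eval_J_extended(p, 0.0) == pytest.approx(
            7.036337579617835e-09, rel=1e-12)

    def test_multiexp_rigid_limit(self):
        spec = MultiExpSpectrum(a0=1.0, terms=(), tau_c=10e-9)
        assert eval_J_multiexp(spec, 0.0) == pytest.approx(1e-8)
        for w in (0.0, 3.8e8, 3.8e9):
            assert eval_J_multiexp(spec, w) == pytest.approx(
                eval_J_simple(1.0, 10e-9, w), rel=1e-12)

    def test_multiexp_fast_term_dies(self):
        # τj → 0 kills the second Lorentzian, leaving the a0-weighted rigid value
        spec = MultiExpSpectrum(a0=0.7, terms=((0.3, 1e-15),), tau_c=10e-9)
        assert eval_J_multiexp(spec, 0.0) == pytest.approx(
            0.7 * 10e-9, rel=1e-5)

    def test_multiexp_matches_cosine_transform(self):
        spec = MultiExpSpectrum(
            a0=0.6, terms=((0.25, 0.3e-9), (0.15, 2e-9)), tau_c=TAU_C)
        for w in (0.0, 3.82e8, 3.77e9):
            num = quadrature_J(spec.time_domain, w, t_max=40 * TAU_C)
            assert eval_J_multiexp(spec, w) == pytest.approx(num, rel=1e-2)

    @given(
        s2=st.floats(0.0, 1.0),
        tau_c=st.floats(1e-10, 1e-7),
        omega=st.floats(0.0, 1e10),
    )
    @settings(deadline=None, max_examples=50)
    def test_J_nonnegative_even_and_decreasing(self, s2, tau_c, omega):
        val = eval_J_simple(s2, tau_c, omega)
        assert val >= 0.0
        assert val == eval_J_simple(s2, tau_c, -omega)
        assert val <= eval_J_simple(s2, tau_c, 0.0) + 1e-30

    def test_amplitudes_must_sum_to_one(self):
        with pytest.raises(ValueError, match="sum to 1"):
            MultiExpSpectrum(a0=0.5, terms=((0.1, 1e-9),), tau_c=1e-8)

    def test_tau_prime_below_tau_c(self):
        spec = MultiExpSpectrum(a0=0.5, terms=((0.5, 50e-9),), tau_c=TAU_C)
        assert all(tp < TAU_C for tp in spec.tau_primes())


class TestRateExpressions:
    def test_zero_J_gives_zero_rates(self, constants):
        zero = lambda w: 0.0  # noqa: E731
        assert rate_R1(zero, constants) == 0.0
        assert rate_R2(zero, constants) == 0.0
        assert rate_eta_xy(zero, constants) == 0.0

    @pytest.mark.parametrize("rate_fn, expected", [
        (rate_R1, 0.8065045310921211),
        (rate_R2, 17.652519612970544),
        (rate_eta_xy, 13.50829343558825),
    ])
    def test_frozen_rate_values(self, constants, rate_fn, expected):
        # independent scalar evaluation at S²=0.85, τc=14.7 ns, 600.13 MHz
        assert rate_fn(J_simple(0.85, TAU_C), constants) == pytest.approx(
            expected, rel=1e-10)

    def test_frozen_noe_value(self, constants):
        J = J_simple(0.85, TAU_C)
        noe = rate_NOE(J, constants, rate_R1(J, constants))
        assert noe == pytest.approx(0.9058077710863405, rel=1e-10)

    def test_slow_tumbling_orders_r2_above_r1(self, constants):
        J = J_simple(0.85, TAU_C)
        assert rate_R2(J, constants) > rate_R1(J, constants)

    def test_extreme_narrowing_noe_limit(self, dipolar_only):
        J = J_simple(1.0, 1e-12)
        noe = rate_NOE(J, dipolar_only, rate_R1(J, dipolar_only))
        assert noe == pytest.approx(1.0 + GAMMA_H / (2 * GAMMA_N), abs=1e-3)

    def test_doubling_csa_scales_csa_term_four_fold(self, constants):
        doubled = InteractionConstants(delta_sigma_ppm=-332.0)
        no_csa = InteractionConstants(delta_sigma_ppm=0.0)
        J = J_simple(0.85, TAU_C)
        csa_term = rate_R1(J, constants) - rate_R1(J, no_csa)
        csa_doubled = rate_R1(J, doubled) - rate_R1(J, no_csa)
        assert csa_doubled == pytest.approx(4.0 * csa_term, rel=1e-10)

    def test_rigid_eta_plateau_near_14(self, constants):
        # rigid residues at τc = 14.7 ns sit on the ~14 s⁻¹ η_xy plateau
        for s2 in (0.85, 0.87, 0.9):
            eta = rate_eta_xy(J_simple(s2, TAU_C), constants)
            assert 12.5 < eta < 15.0

    def test_eta_literal_low_frequency_variant_is_tiny(self, constants):
        # J(ωH−ωN) in place of J(0) collapses the rigid plateau
        eta = rate_eta_xy(J_simple(1.0, TAU_C), constants, j_zero=False)
        assert eta < 1.0

    def test_rates_linear_in_J_noe_invariant(self, constants):
        base = J_simple(0.8, TAU_C)
        scaled = lambda w: 2.5 * base(w)  # noqa: E731
        for fn in (rate_R1, rate_R2, rate_eta_xy):
            assert fn(scaled, constants) == pytest.approx(
                2.5 * fn(base, constants), rel=1e-12)
        noe_a = rate_NOE(base, constants, rate_R1(base, constants))
        noe_b = rate_NOE(scaled, constants, rate_R1(scaled, constants))
        assert noe_a == pytest.approx(noe_b, rel=1e-12)

    def test_eta_and_r2_share_j0_dominated_profile(self, constants):
        # both grow with S² at fixed τc (J(0) dominance)
        etas, r2s = [], []
        for s2 in np.linspace(0.2, 1.0, 9):
            J = J_simple(s2, TAU_C)
            etas.append(rate_eta_xy(J, constants))
            r2s.append(rate_R2(J, constants))
        assert np.all(np.diff(etas) > 0) and np.all(np.diff(r2s) > 0)

    def test_rates_accept_model_objects(self, constants):
        p = ModelFreeParams(s2_fast=0.85, s2_slow=1.0, tau_c=TAU_C)
        assert rate_R1(p, constants) == pytest.approx(
            rate_R1(J_simple(0.85, TAU_C), constants), rel=1e-12)

    def test_noe_requires_positive_r1(self, constants):
        with pytest.raises(ValueError):
            rate_NOE(J_simple(0.5, TAU_C), constants, 0.0)

    def test_all_rates_from_multiexp_match_quadrature(self, constants):
        # rate-level agreement between the analytic Lorentzian J and the
        # cosine-transform of the time-domain correlation function
        spec = MultiExpSpectrum(
            a0=0.75, terms=((0.2, 0.5e-9), (0.05, 3e-9)), tau_c=TAU_C)
        Jnum = lambda w: quadrature_J(spec.time_domain, w, 40 * TAU_C)  # noqa: E731
        got = all_rates(spec, constants)
        want = all_rates(Jnum, constants)
        for key in ("r1", "r2", "eta_xy", "noe"):
            assert got[key] == pytest.approx(want[key], rel=1e-2)


class TestInteractionConstants:
    def test_larmor_frequency_ratio(self, constants):
        assert constants.omega_N / constants.omega_H == pytest.approx(
            abs(GAMMA_N) / GAMMA_H, rel=1e-12)

    def test_invalid_inputs_rejected(self):
        with pytest.raises(ValueError):
            InteractionConstants(proton_freq_mhz=-600.0)
        with pytest.raises(ValueError):
            InteractionConstants(r_nh_angstrom=0.0)

    def test_dipolar_constant_magnitude(self, constants):
        # d = (μ0/4π)ħγHγN/r³ ≈ 7.15e4 rad/s at rNH = 1.023 Å
        assert constants.d_dipolar == pytest.approx(71481.7, rel=1e-4)
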