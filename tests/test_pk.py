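"""Closed-form two-compartment kinetics against independent oracles."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from doripk import (
    DoseRegimen,
    TwoCompartmentParams,
    conc_infusion,
    cumulative_auc,
    derive_micro_constants,
    model_auc_inf,
    steady_state_conc,
    steady_state_interval_profile,
    terminal_half_life,
)

from _oracles import eigen_exponents, ode_conc

TYP = dict(CL=14.2, Vc=8.17, Q=8.54, Vp=6.95)


class TestMicroConstants:
    def test_exponents_match_eigensolver(self, typical_params):
        m = derive_micro_constants(typical_params)
        alpha, beta = eigen_exponents(**TYP)
        assert m.alpha == pytest.approx(alpha, rel=1e-12)
        assert m.beta == pytest.approx(beta, rel=1e-12)
        # frozen values from the eigensolver oracle
        assert m.alpha == pytest.approx(3.38033, rel=1e-4)
        assert m.beta == pytest.approx(0.63180, rel=1e-4)

    def test_identities_over_random_parameters(self, random_param_sets):
        for p in random_param_sets:
            m = derive_micro_constants(p)
            assert m.A + m.B == pytest.approx(1.0 / p.Vc, rel=1e-9)
            assert m.A / m.alpha + m.B / m.beta == pytest.approx(1.0 / p.CL, rel=1e-9)
            assert m.k10 * m.k21 == pytest.approx(m.alpha * m.beta, rel=1e-12)
            assert m.alpha > m.beta > 0

    def test_small_q_limit(self):
        p = TwoCompartmentParams(CL=14.2, Vc=8.17, Q=1e-9, Vp=6.95)
        m = derive_micro_constants(p)
        k10, k21 = p.CL / p.Vc, p.Q / p.Vp
        assert m.beta == pytest.approx(k10 * k21 / (k10 + k21), rel=1e-6)
        assert m.A + m.B == pytest.approx(1.0 / p.Vc, rel=1e-9)

    def test_invalid_parameters_rejected(self):
        with pytest.raises(ValueError):
            TwoCompartmentParams(CL=-1, Vc=8, Q=8, Vp=7)
        with pytest.raises(ValueError):
            TwoCompartmentParams(CL=0, Vc=8, Q=8, Vp=7)


class TestInfusionConcentration:
    def test_zero_at_time_zero(self, typical_params):
        reg = DoseRegimen.from_grams(1.0, 1.0)
        assert conc_infusion(typical_params, reg, 0.0) == 0.0

    def test_end_of_infusion_values_match_ode(self, typical_params):
        """Typical-value spot checks frozen from the adaptive ODE oracle."""
        reg1 = DoseRegimen.from_grams(1.0, 1.0)
        c1 = conc_infusion(typical_params, reg1, 1.0)
        (o1,) = ode_conc(**TYP, dose=1000, t_inf=1.0, times=[1.0])
        assert c1 == pytest.approx(o1, rel=1e-8)
        assert c1 == pytest.approx(47.09, abs=0.05)

        reg4 = DoseRegimen.from_grams(1.0, 4.0)
        c4 = conc_infusion(typical_params, reg4, 4.0)
        (o4,) = ode_conc(**TYP, dose=1000, t_inf=4.0, times=[4.0])
        assert c4 == pytest.approx(o4, rel=1e-8)
        assert c4 == pytest.approx(16.77, abs=0.05)

    def test_closed_form_vs_ode_random_cases(self):
        """Max relative error <= 1e-6 on a 0-12 h grid, 100 random cases."""
        rng = np.random.default_rng(42)
        times = np.linspace(0.05, 12.0, 60)
        for _ in range(100):
            p = TwoCompartmentParams(
                CL=float(rng.uniform(5, 30)),
                Vc=float(rng.uniform(4, 20)),
                Q=float(rng.uniform(2, 20)),
                Vp=float(rng.uniform(3, 20)),
            )
            t_inf = float(rng.choice([0.5, 1.0, 2.0, 4.0]))
            dose = float(rng.choice([250, 500, 1000]))
            reg = DoseRegimen(dose, t_inf, tau=12.0)
            closed = np.asarray(conc_infusion(p, reg, times))
            ode = ode_conc(p.CL, p.Vc, p.Q, p.Vp, dose, t_inf, times)
            scale = np.maximum(np.abs(ode), 1e-9 * ode.max())
            assert np.max(np.abs(closed - ode) / scale) <= 1e-6

    def test_negative_time_rejected(self, typical_params):
        with pytest.raises(ValueError):
            conc_infusion(typical_params, DoseRegimen.from_grams(0.5, 1.0), -0.1)

    def test_superposition_linearity(self, typical_params):
        reg3 = DoseRegimen.from_grams(0.5, 1.0, tau=8.0, n_doses=3)
        reg1 = DoseRegimen.from_grams(0.5, 1.0, tau=8.0, n_doses=1)
        t = np.linspace(0, 24, 97)
        multi = np.asarray(conc_infusion(typical_params, reg3, t))
        manual = sum(
            np.asarray(conc_infusion(typical_params, reg1, np.maximum(t - 8 * k, 0)))
            * (t >= 8 * k)
            for k in range(3)
        )
        np.testing.assert_allclose(multi, manual, rtol=1e-12, atol=1e-12)

    @settings(deadline=None, derandomize=True, max_examples=50)
    @given(
        cl=st.floats(2, 40), vc=st.floats(3, 25), q=st.floats(1, 25),
        vp=st.floats(3, 25), t=st.floats(0, 48),
    )
    def test_concentration_non_negative(self, cl, vc, q, vp, t):
        p = TwoCompartmentParams(cl, vc, q, vp)
        assert conc_infusion(p, DoseRegimen.from_grams(0.5, 1.0, tau=48.0), t) >= 0.0


class TestSteadyState:
    def test_matches_ten_dose_superposition(self, typical_params):
        reg_ss = DoseRegimen.from_grams(0.5, 1.0, tau=8.0, n_doses=None)
        prof = steady_state_interval_profile(typical_params, reg_ss, dt=0.05)
        reg10 = DoseRegimen.from_grams(0.5, 1.0, tau=8.0, n_doses=10)
        super10 = np.asarray(conc_infusion(typical_params, reg10, prof.times + 9 * 8.0))
        np.testing.assert_allclose(prof.conc, super10, rtol=1e-6)

    def test_long_interval_limit_is_single_dose(self, typical_params):
        t_half = terminal_half_life(typical_params)
        tau = 1000.0 * t_half
        reg = DoseRegimen.from_grams(0.5, 1.0, tau=tau, n_doses=None)
        t = np.linspace(0, 12, 50)
        ss = np.asarray(steady_state_conc(typical_params, reg, t))
        single = np.asarray(
            conc_infusion(typical_params, DoseRegimen.from_grams(0.5, 1.0, tau=tau), t)
        )
        np.testing.assert_allclose(ss, single, rtol=1e-9, atol=1e-12)

    def test_slow_term_accumulation_factor(self, typical_params):
        m = derive_micro_constants(typical_params)
        acc = 1.0 / (1.0 - math.exp(-m.beta * 8.0))
        assert m.beta * 8.0 == pytest.approx(5.05, abs=0.01)
        assert acc == pytest.approx(1.0065, abs=0.001)

    def test_grid_contains_end_of_infusion(self, typical_params):
        reg = DoseRegimen.from_grams(1.0, 4.0, tau=8.0, n_doses=None)
        prof = steady_state_interval_profile(typical_params, reg, dt=0.3)
        assert np.any(np.isclose(prof.times, 4.0, atol=1e-12))
        assert prof.times[0] == 0.0 and prof.times[-1] < 8.0


class TestSummaryQuantities:
    def test_terminal_half_life_typicals(self, typical_params):
        # model-implied value; the observed NCA mean in the 0.5 g group is 1.10 h
        assert terminal_half_life(typical_params) == pytest.approx(1.10, abs=0.03)

    def test_half_life_one_compartment_limit(self):
        """As Q -> 0 the peripheral compartment decouples: the observable
        disposition phase approaches ln2*Vc/CL and the formal terminal
        phase carries a vanishing coefficient."""
        p = TwoCompartmentParams(CL=14.2, Vc=8.17, Q=1e-9, Vp=6.95)
        m = derive_micro_constants(p)
        assert math.log(2) / m.alpha == pytest.approx(
            math.log(2) * 8.17 / 14.2, rel=1e-6
        )
        assert m.B * p.Vc < 1e-8  # terminal phase is unobservable

    def test_half_life_increases_with_volume(self, typical_params):
        bigger = TwoCompartmentParams(CL=14.2, Vc=2 * 8.17, Q=8.54, Vp=2 * 6.95)
        assert terminal_half_life(bigger) > terminal_half_life(typical_params)

    def test_auc_is_dose_over_cl(self, typical_params):
        assert model_auc_inf(typical_params, 1000.0) == pytest.approx(1000 / 14.2)

    def test_cumulative_auc_converges_to_dose_over_cl(self, typical_params):
        reg = DoseRegimen.from_grams(1.0, 1.0, tau=24.0)
        full = cumulative_auc(typical_params, reg, math.inf)
        assert full == pytest.approx(1000.0 / 14.2, rel=1e-9)
        # quadrature cross-check of the analytic partial AUC
        t = np.linspace(0, 24, 20001)
        c = np.asarray(conc_infusion(typical_params, reg, t))
        assert cumulative_auc(typical_params, reg, 24.0) == pytest.approx(
            np.trapezoid(c, t), rel=1e-5
        )
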