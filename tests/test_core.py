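"""Unit and property tests for the model quantities and the RHS."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import ionsim as isim
from ionsim.parameters import pack
from ionsim._kernel import rhs as kernel_rhs


class TestGating:
    def test_removable_singularities(self):
        am, *_ = isim.gating_rates(-30.0)
        assert am == pytest.approx(1.0, abs=1e-9)
        _, _, an, *_ = isim.gating_rates(-34.0)
        assert an == pytest.approx(0.1, abs=1e-10)

    def test_beta_m_at_minus_55(self):
        _, bm, *_ = isim.gating_rates(-55.0)
        assert bm == pytest.approx(4.0)

    @given(st.floats(-120, 60))
    @settings(max_examples=200, deadline=None)
    def test_rates_nonnegative_and_continuous(self, v):
        rates = isim.gating_rates(v)
        assert all(np.all(r >= 0) for r in rates)
        near = isim.gating_rates(v + 1e-7)
        for a, b in zip(rates, near):
            assert abs(a - b) < 1e-3

    def test_m_infinity_limits_and_value(self):
        assert isim.m_infinity(200.0) > 0.999
        assert isim.m_infinity(-200.0) < 1e-6
        # closed form at V = -30 using the alpha_m limit
        expect = 1.0 / (1.0 + 4.0 * math.exp(-25.0 / 18.0))
        assert isim.m_infinity(-30.0) == pytest.approx(expect, rel=1e-9)
        assert isim.m_infinity(-30.0 + 1e-6) == pytest.approx(expect, rel=1e-5)
        assert isim.m_infinity(-30.0 - 1e-6) == pytest.approx(expect, rel=1e-5)


class TestNernst:
    def test_values(self):
        vk, vna, _ = isim.nernst_potentials(4.0, 140.0, 144.0, 18.0,
                                            132.0, 8.0)
        assert vk == pytest.approx(26.64 * math.log(4 / 140), rel=1e-12)
        assert vk == pytest.approx(-94.71, abs=0.01)
        assert vna == pytest.approx(26.64 * math.log(8.0), rel=1e-12)
        assert vna == pytest.approx(55.40, abs=0.01)

    def test_zero_at_equal_concentrations(self):
        vk, _, _ = isim.nernst_potentials(10.0, 10.0, 144.0, 18.0,
                                          132.0, 8.0)
        assert vk == 0.0

    def test_domain_error_names_ion(self):
        with pytest.raises(isim.DomainError, match="K_o"):
            isim.nernst_potentials(-1.0, 140.0, 144.0, 18.0, 132.0, 8.0)


class TestOxygenGate:
    def test_midpoint_and_tails(self):
        assert isim.oxygen_gate(16.0) == pytest.approx(0.5)
        assert isim.oxygen_gate(0.0) == pytest.approx(1 / (1 + math.e**4),
                                                      rel=1e-9)
        assert isim.oxygen_gate(30.0) == pytest.approx(
            1 / (1 + math.exp(-3.5)), rel=1e-9)

    def test_monotone(self):
        o2 = np.linspace(0, 60, 200)
        assert np.all(np.diff(isim.oxygen_gate(o2)) > 0)


class TestPumpGliaDiffusionKcc:
    def test_pump_bounded_and_monotone(self, params):
        nai = np.linspace(5, 60, 40)
        ko = np.linspace(0.5, 50, 40)
        j = isim.pump_rate(nai[:, None], ko[None, :], 1.0, params)
        assert np.all(j > 0) and np.all(j < params.rho)
        assert np.all(np.diff(j, axis=0) > 0)   # increasing in Na_i
        assert np.all(np.diff(j, axis=1) > 0)   # increasing in K_o
        assert isim.pump_rate(18.0, 8.0, 0.0, params) == 0.0
        assert isim.pump_rate(1e4, 1e4, 1.0, params) == pytest.approx(
            params.rho, rel=1e-3)

    def test_glia_midpoint_and_bounds(self):
        assert isim.glial_uptake(18.0, 1.0, 5.0) == pytest.approx(2.5)
        assert isim.glial_uptake(4.0, 0.0, 5.0) == 0.0
        assert isim.glial_uptake(4.0, 1.0, 5.0) == pytest.approx(
            5.0 / (1 + math.exp(5.6)), rel=1e-9)
        ko = np.linspace(1, 60, 100)
        g = isim.glial_uptake(ko, 1.0, 5.0)
        assert np.all(np.diff(g) > 0) and np.all(g < 5.0)

    def test_reservoir_diffusion_sign_and_gate(self):
        assert isim.reservoir_diffusion(4.0, 0.7, 1.25, 4.0) == 0.0
        assert isim.reservoir_diffusion(8.0, 0.5, 1.25, 4.0) == \
            pytest.approx(0.5 * 1.25 * 4.0)
        assert isim.reservoir_diffusion(8.0, 0.5, 1.25, 4.0, gated=False) \
            == pytest.approx(1.25 * 4.0)
        assert isim.reservoir_diffusion(2.0, 1.0, 1.25, 4.0) < 0

    def test_fick_formula_with_printed_constants(self):
        assert isim.eps_from_fick(250e-6, 20e-4) == pytest.approx(125.0)
        assert isim.eps_from_fick(2.5e-6, 20e-4) == pytest.approx(1.25)

    def test_kcc_equilibrium_value_and_antisymmetry(self):
        assert isim.kcc_flux(140.0, 4.0, 4.0, 140.0, 0.5) == \
            pytest.approx(0.0, abs=1e-12)
        val = isim.kcc_flux(140.0, 8.0, 4.0, 132.0, 0.5)
        assert val == pytest.approx(0.5 * math.log(1120 / 528), rel=1e-12)
        assert val == pytest.approx(0.3760, abs=1e-4)
        swapped = isim.kcc_flux(4.0, 132.0, 140.0, 8.0, 0.5)
        assert swapped == pytest.approx(-val, rel=1e-12)


class TestConservedConcentrations:
    def test_resting_anchor(self, params):
        ki, nao, clo = isim.conserved_concentrations(18.0, 4.0, 7.0, params)
        assert ki == 140.0 and nao == 144.0
        assert clo == pytest.approx(132.0)   # charge balance at rest

    def test_linearity_in_beta(self, params):
        _, nao, _ = isim.conserved_concentrations(20.0, 4.0, 2.0, params)
        assert nao == pytest.approx(140.0)

    def test_total_sodium_invariant(self, params):
        # Na_i*Vol_i + Na_o*Vol_o is independent of Na_i at fixed geometry
        geo = isim.geometry_from_radius(4.7)
        totals = []
        for nai in (14.0, 18.0, 25.0, 30.0):
            _, nao, _ = isim.conserved_concentrations(nai, 8.0, geo.beta,
                                                      params)
            totals.append(nai * geo.Vol_i + nao * geo.Vol_o)
        assert np.ptp(totals) < 1e-12 * abs(totals[0])

    def test_validity_error(self, params):
        with pytest.raises(isim.StateValidityError):
            isim.conserved_concentrations(60.0, 4.0, 30.0, params)


class TestMembraneCurrents:
    @given(st.floats(-90, 30), st.floats(0.01, 0.99), st.floats(0.01, 0.99))
    @settings(max_examples=100, deadline=None)
    def test_each_current_vanishes_at_its_reversal(self, v, n, h):
        i_na, i_k, i_kl, i_nal, i_cll = isim.membrane_currents(
            v, n, h, v, v, v, 100.0, 40.0, 0.05, 0.02, 0.05)
        assert i_na == 0 and i_k == 0 and i_kl == 0
        assert i_nal == 0 and i_cll == 0

    def test_printed_sign_convention(self):
        # gK*n^4 = 40*0.0625 at 10 mV above V_K gives -25 uA/cm^2
        _, i_k, *_ = isim.membrane_currents(
            -70.0, 0.5, 0.5, -80.0, 55.0, -75.0, 100.0, 40.0, 0.05, 0.02,
            0.05)
        assert i_k == pytest.approx(-40.0 * 0.0625 * 10.0)


class TestVolume:
    def test_osmotic_target_fixed_point_and_ceiling(self):
        assert isim.osmotic_target_volume(300.0, 300.0, 2.0) == \
            pytest.approx(2.0)
        assert isim.osmotic_target_volume(300.0, -1e4, 1.0) == \
            pytest.approx(1.1029, rel=1e-6)
        factor = isim.osmotic_target_volume(280.0, 300.0, 1.0)
        assert factor == pytest.approx(1.1029 - 0.1029 * math.e, rel=1e-9)

    @given(st.floats(-100, 100))
    @settings(max_examples=100, deadline=None)
    def test_monotone_decreasing_in_osmotic_gradient(self, d):
        lo = isim.osmotic_target_volume(300.0, 300.0 + d, 1.0)
        hi = isim.osmotic_target_volume(300.0, 300.0 + d + 1.0, 1.0)
        assert hi < lo

    def test_volume_relaxation_converges_to_target(self, params, flags):
        # frozen concentrations: dVol/dt is linear with fixed point Vol_hat
        geo = isim.geometry_from_radius(4.81)
        fl = flags.replace(dynamic_volume=True)
        st0 = isim.nominal_state(geo, params)
        concs = isim.derived_quantities(st0, params, fl, geo)
        target = isim.osmotic_target_volume(
            concs["pi_i"], concs["pi_o"], geo.Vol_i)
        # integrate dVol/dt with everything else frozen
        vol = geo.Vol_i
        dt_s = 1.0
        for _ in range(1000):
            vol += dt_s * (target - vol) / params.tau_v
        assert vol == pytest.approx(target, rel=1e-8)

    def test_scale_conductances_preserve_total(self, params):
        g = isim.scale_conductances(2.0e-6, 2.9e-6, params)
        bars = (params.gNa_bar, params.gK_bar, params.gKL_bar,
                params.gNaL_bar, params.gClL_bar)
        for gi, bi in zip(g, bars):
            assert gi * 2.0e-6 == pytest.approx(bi * 2.9e-6, rel=1e-14)

    def test_area_ratio_example(self, params):
        a1 = 4 * math.pi * (4.82e-4) ** 2
        a2 = 4 * math.pi * (4.84e-4) ** 2
        gna, *_ = isim.scale_conductances(a2, a1, params)
        assert gna == pytest.approx(100.0 * (4.82 / 4.84) ** 2, rel=1e-12)


class TestGeometry:
    def test_beta_from_radius(self):
        geo = isim.geometry_from_radius(4.0, 5.0)
        assert geo.beta == pytest.approx(64.0 / 61.0, rel=1e-12)
        assert geo.A == pytest.approx(4 * math.pi * (4e-4) ** 2, rel=1e-12)

    def test_volume_doubling_scales_radius(self):
        g1 = isim.geometry_from_radius(3.0)
        g2 = isim.geometry_from_volume(2 * g1.Vol_i)
        assert g2.r_in == pytest.approx(3.0 * 2 ** (1 / 3), rel=1e-12)

    def test_invalid_radius(self):
        with pytest.raises(isim.GeometryError):
            isim.geometry_from_radius(6.0, 5.0)
        with pytest.raises(isim.GeometryError):
            isim.geometry_from_volume(1.0)   # larger than the shell


class TestFullRhs:
    def test_zero_at_fixed_point(self, rest_state, params, flags):
        geo, st0 = rest_state
        dy = isim.full_rhs(st0, params, flags, geo)
        assert np.max(np.abs(dy)) < 1e-9

    def test_o2_equation_balance(self, params, flags):
        # with the pump silent (F_O2 -> 0 at O2=0 keeps J_pump ~ 0) and
        # O2 at the perfusate level, d[O2]/dt vanishes as the diffusion
        # term has zero gradient
        geo = isim.geometry_from_radius(4.0)
        st0 = isim.FullState(V=-65.0, n=0.05, h=0.97, K_o=4.0, Na_i=18.0,
                             Cl_i=8.0, O2=params.O2_inf, Vol=geo.Vol_i)
        p0 = params.replace(rho=1e-300)
        dy = isim.full_rhs(st0, p0, flags, geo)
        assert dy[6] == pytest.approx(0.0, abs=1e-12)

    def test_kernel_matches_reference(self, params, geo_mid):
        rng = np.random.default_rng(42)
        variants = [
            isim.VariantFlags(),
            isim.VariantFlags(concentration_mode="rate_equations"),
            isim.VariantFlags(chloride_mode="fixed"),
            isim.VariantFlags(dynamic_volume=True),
            isim.VariantFlags(dynamic_volume=True, dilution_flux=True),
            isim.VariantFlags(o2_gate_diffusion=False),
        ]
        for fl in variants:
            for _ in range(5):
                vol = geo_mid.Vol_i * (1.0 if not fl.dynamic_volume
                                       else rng.uniform(0.95, 1.05))
                y = np.array([
                    rng.uniform(-80, 0), rng.uniform(0.02, 0.9),
                    rng.uniform(0.1, 0.99), rng.uniform(3, 20),
                    rng.uniform(14, 26), rng.uniform(5, 15),
                    rng.uniform(5, 30), vol,
                    rng.uniform(120, 145), rng.uniform(120, 160),
                    rng.uniform(110, 150)])
                st0 = isim.FullState.from_vector(
                    y, fl.concentration_mode == "rate_equations")
                ref = isim.full_rhs(st0, params, fl, geo_mid)
                pv = pack(params, fl, geo_mid.r_tot_cm, geo_mid.Vol_i,
                          geo_mid.A_ss)
                dy = np.zeros(11)
                kernel_rhs(y, pv, 0.0, dy)
                np.testing.assert_allclose(dy, ref, rtol=1e-12, atol=1e-14)

    def test_rate_equation_rest_agrees_with_conservation(self, params):
        """The rate-equation closure and the conservation closure agree
        at the resting fixed point within 1 % per concentration."""
        geo = isim.geometry_from_radius(4.5)
        cons = isim.equilibrate(params, isim.VariantFlags(), geo)
        rate = isim.equilibrate(
            params, isim.VariantFlags(concentration_mode="rate_equations"),
            geo)
        d_cons = isim.derived_quantities(cons, params, isim.VariantFlags(),
                                         geo)
        for name, a, b in [
                ("K_o", cons.K_o, rate.K_o),
                ("Na_i", cons.Na_i, rate.Na_i),
                ("Cl_i", cons.Cl_i, rate.Cl_i),
                ("K_i", d_cons["K_i"], rate.K_i),
                ("Na_o", d_cons["Na_o"], rate.Na_o),
                ("Cl_o", d_cons["Cl_o"], rate.Cl_o)]:
            assert b == pytest.approx(a, rel=0.01), name
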