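"""Unit and property tests of the vector-field building blocks."""
import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import hcosim as H
from hcosim import model_core as mc
from hcosim import _kernels


class TestGatingSteadyState:
    def test_midpoint_is_half(self):
        assert mc.gating_steady_state(-4.1, -43.0, -43.0) == pytest.approx(0.5)

    def test_saturation(self):
        assert mc.gating_steady_state(-4.1, -43.0, 100.0) == pytest.approx(1.0, abs=1e-10)

    def test_analytic_inversion(self):
        # f(5, -57, -57 + 5 ln 9) = 1/(1+9) exactly
        vm = -57.0 + 5.0 * np.log(9.0)
        assert mc.gating_steady_state(5.0, -57.0, vm) == pytest.approx(0.1, rel=1e-12)

    def test_zero_slope_rejected(self):
        with pytest.raises(ValueError):
            mc.gating_steady_state(0.0, -43.0, -50.0)

    @given(st.floats(-100, 50), st.floats(-100, 50))
    @settings(max_examples=50, deadline=None)
    def test_negative_slope_is_monotone_increasing(self, v1, v2):
        lo, hi = sorted([v1, v2])
        assert (mc.gating_steady_state(-7.8, -15.0, lo)
                <= mc.gating_steady_state(-7.8, -15.0, hi))


class TestHCurrentKinetics:
    def test_mh_inf_quarter_at_anchor(self, params):
        # exponents vanish at the anchor voltage regardless of the slopes
        vh = params.kinetics.vh_mh
        assert mc.mh_steady_state(vh, params) == pytest.approx(0.25, rel=1e-12)

    def test_mh_inf_saturates_when_hyperpolarized(self, params):
        assert mc.mh_steady_state(-200.0, params) == pytest.approx(1.0, abs=1e-9)

    def test_mh_inf_strictly_decreasing(self, params):
        # away from the saturated tails, where float rounding flattens it
        v = np.linspace(-75, 20, 400)
        m = mc.mh_steady_state(v, params)
        assert np.all(np.diff(m) < 0)

    def test_tau_h_bounds(self, params):
        v = np.linspace(-120, 40, 400)
        tau = mc.mh_time_constant(v, params)
        k = params.kinetics
        assert np.all(tau >= k.tauh_base - 1e-12)
        assert np.all(tau <= k.tauh_base + k.tauh_amp + 1e-12)

    def test_tau_h_scale_is_multiplicative(self, params):
        v = np.linspace(-100, 20, 50)
        t1 = mc.mh_time_constant(v, params, tau_h_scale=1.0)
        t50 = mc.mh_time_constant(v, params, tau_h_scale=50.0)
        np.testing.assert_allclose(t50, 50.0 * t1, rtol=1e-14)


class TestTimeConstants:
    def test_fixed_constants(self, params):
        taus = mc.gating_time_constants(-60.0, params)
        assert taus["tau_mNaP"] == 0.001
        assert taus["tau_hNaP"] == 0.1
        assert taus["tau_hKA"] == 0.02
        assert taus["tau_hCaS"] == 0.34
        assert taus["tau_mSyn"] == 0.05

    def test_hnaf_tau_at_well_center(self, params):
        # both exponentials are 1 at the centre voltage
        k = params.kinetics
        taus = mc.gating_time_constants(k.tau_hNaF_c, params)
        assert taus["tau_hNaF"] == pytest.approx(k.tau_hNaF_A / 2.0, rel=1e-12)

    def test_positivity_and_boundedness(self, params):
        rng = np.random.default_rng(7)
        v = rng.uniform(-120, 60, 10_000)
        taus = mc.gating_time_constants(v, params)
        for name in ("tau_hNaF", "tau_mKDR", "tau_mCaS"):
            assert np.all(taus[name] > 0)
            assert np.all(np.isfinite(taus[name]))


class TestReversalsAndLeak:
    def test_equal_concentrations_zero_potential(self, params):
        assert mc.reversal_potentials(params, 120.0)["ENa"] == pytest.approx(0.0)

    def test_tenfold_gradient(self, params):
        expected = 26.45 * np.log(10.0)
        assert mc.reversal_potentials(params, 12.0)["ENa"] == pytest.approx(expected)

    def test_ek_canonical(self, params):
        assert params.EK == pytest.approx(26.45 * np.log(9.0 / 130.0), rel=1e-12)

    def test_nonpositive_nai_rejected(self, params):
        with pytest.raises(ValueError):
            mc.reversal_potentials(params, 0.0)

    def test_canonical_split_values(self, params):
        gLNa, gLK = params.leak_conductances()
        assert gLNa == pytest.approx(0.2166, abs=2e-4)
        assert gLK == pytest.approx(1.6634, abs=2e-4)

    @given(st.floats(0.1, 10.0), st.floats(-65.0, -40.0))
    @settings(max_examples=50, deadline=None)
    def test_split_sums_to_total(self, gL, ELRef):
        s = mc.leak_split(gL, ELRef, 65.0, -70.63)
        assert s["gLNa"] + s["gLK"] == pytest.approx(gL, rel=1e-12)

    def test_split_zero_na_component_at_ek(self):
        s = mc.leak_split(1.88, -70.63, 65.0, -70.63)
        assert s["gLNa"] == pytest.approx(0.0, abs=1e-15)

    def test_degenerate_reversal_rejected(self):
        with pytest.raises(ValueError):
            mc.leak_split(1.88, -55.0, -70.63, -70.63)


class TestPump:
    def test_half_activation_value(self, params):
        expected = 40.26 * 0.5 / (1.0 + np.exp(-3.0))
        assert mc.pump_current(25.0, params) == pytest.approx(expected, rel=1e-12)

    def test_low_sodium_limit(self, params):
        # residual pump current at vanishing internal Na+
        expected = 40.26 / (1 + np.exp(25.0 / 3.0)) / (1 + np.exp(-3.0))
        assert mc.pump_current(1e-9, params) == pytest.approx(expected, rel=1e-6)

    @given(st.floats(0.5, 100.0), st.floats(0.5, 100.0))
    @settings(max_examples=100, deadline=None)
    def test_bounded_and_monotone(self, n1, n2):
        p = H.canonical_parameters()
        lo, hi = sorted([n1, n2])
        a, b = mc.pump_current(lo, p), mc.pump_current(hi, p)
        assert 0 < a < p.IPumpMax and 0 < b < p.IPumpMax
        assert a <= b


class TestMembraneCurrents:
    def test_zero_driving_force_kills_k_currents(self, params):
        s = H.steady_state_cell(params.EK, params, nai=15.0)
        cur = mc.membrane_currents(s, 0.3, params)
        for name in ("IKDR", "IKA", "IhK", "ILK"):
            assert getattr(cur, name) == pytest.approx(0.0, abs=1e-12)

    def test_closed_h_channels(self, params):
        s = H.steady_state_cell(-50.0, params, nai=15.0, mh=0.0)
        cur = mc.membrane_currents(s, 0.0, params)
        assert cur.IhNa == 0.0 and cur.IhK == 0.0

    def test_h_current_split_ratio(self, params):
        s = H.steady_state_cell(-48.0, params, nai=15.0, mh=0.7)
        cur = mc.membrane_currents(s, 0.0, params)
        rev = mc.reversal_potentials(params, s.Nai)
        expected = 0.75 * (s.Vm - rev["ENa"]) / (s.Vm - rev["EK"])
        assert cur.IhNa / cur.IhK == pytest.approx(expected, rel=1e-12)

    def test_pump_always_outward_synapse_sign(self, params):
        s = H.steady_state_cell(-50.0, params, nai=20.0)
        cur = mc.membrane_currents(s, 0.5, params)
        assert cur.IPump > 0
        assert cur.ISyn > 0  # Vm above ESyn with open synapse


class TestStateDerivatives:
    def test_symmetric_state_symmetric_derivatives(self, params, sym_state):
        d = mc.state_derivatives(sym_state, params)
        np.testing.assert_allclose(d[:11], d[11:], rtol=1e-12)

    def test_gating_fixed_points(self, params):
        s = H.steady_state_cell(-55.0, params, nai=18.0)
        d = mc.single_cell_derivatives(s, params)
        # every gating derivative vanishes at its steady state (not Vm, Nai)
        np.testing.assert_allclose(d[1:10], 0.0, atol=1e-10)

    def test_decoupling_equivalence(self, params):
        p0 = H.decouple(params)
        cell = H.steady_state_cell(-52.0, p0, nai=17.0)
        single = mc.single_cell_derivatives(cell, p0)
        other = H.steady_state_cell(-60.0, p0, nai=17.0)
        two = mc.state_derivatives(H.HCOState(cell, other), p0)
        np.testing.assert_allclose(two[:11], single, rtol=1e-12)

    def test_swap_equivariance(self, params):
        a = H.steady_state_cell(-50.0, params, nai=16.0)
        b = H.steady_state_cell(-62.0, params, nai=19.0)
        d_ab = mc.state_derivatives(H.HCOState(a, b), params)
        d_ba = mc.state_derivatives(H.HCOState(b, a), params)
        np.testing.assert_allclose(d_ab[:11], d_ba[11:], rtol=1e-12)
        np.testing.assert_allclose(d_ab[11:], d_ba[:11], rtol=1e-12)

    def test_compiled_kernel_matches_reference(self, params):
        """The fused numba RHS agrees with the plain-NumPy reference to
        near machine precision across assorted states."""
        rng = np.random.default_rng(3)
        pvec = params.to_vector()
        for _ in range(20):
            vm1, vm2 = rng.uniform(-80, 20, 2)
            a = H.steady_state_cell(vm1, params, nai=rng.uniform(5, 40))
            b = H.steady_state_cell(vm2, params, nai=rng.uniform(5, 40))
            y = H.HCOState(a, b).to_array()
            d_ref = mc.state_derivatives(H.HCOState(a, b), params)
            d_kern = np.empty(22)
            _kernels.rhs(y, d_kern, pvec, 2)
            np.testing.assert_allclose(d_kern, d_ref, rtol=1e-10, atol=1e-10)

    def test_sodium_balance_matches_current_breakdown(self, params):
        """d[Na]i/dt recomputed from the current decomposition matches the
        fused vector field."""
        s = H.steady_state_cell(-48.0, params, nai=22.0)
        cur = mc.membrane_currents(s, 0.2, params)
        expected = params.M * (params.Nae - s.Nai) \
            - params.alpha_pA * cur.sodium_influx()
        d = mc._cell_derivatives(s, 0.2, params)
        assert d[10] == pytest.approx(expected, rel=1e-12)
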