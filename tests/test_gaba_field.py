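"""Tonic-conductance field dynamics, transporter reversal, concentration."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from gabawave.gaba_field import (
    GatIonSet,
    TonicParams,
    TonicState,
    af_scaling,
    closed_form_gtonic,
    gaba_concentration_trace,
    gat_reversal,
    mean_firing_rate,
    sliding_rate,
    steady_state_gtonic,
    tonic_current,
    update_gtonic,
)


class TestFieldDynamics:
    def test_basal_fixed_point(self):
        # f_m = f_b = 0: the field stays exactly at G_basal
        p = TonicParams(f_b=0.0)
        s = TonicState(g_tonic=p.g_basal)
        for _ in range(100):
            s = update_gtonic(s, 0.0, p, n_i=100, step=1.0)
        assert s.g_tonic == pytest.approx(p.g_basal, rel=1e-12)

    def test_steady_state_formula(self):
        # constant f_m: G_ss = G_basal + N A_f (f_m + f_b) / G_pump
        p = TonicParams(af=1e-4, g_pump=0.01, f_b=0.1)
        f_m = 25.0
        s = TonicState(g_tonic=p.g_basal)
        for _ in range(5000):
            s = update_gtonic(s, f_m, p, n_i=100, step=1.0)
        assert s.g_tonic == pytest.approx(steady_state_gtonic(f_m, p, 100), rel=1e-6)

    def test_never_drops_below_basal(self):
        p = TonicParams()
        s = TonicState(g_tonic=p.g_basal)
        g_min = s.g_tonic
        for k in range(500):
            s = update_gtonic(s, 50.0 if k < 100 else 0.0, p, n_i=100, step=1.0)
            g_min = min(g_min, s.g_tonic)
        assert g_min >= p.g_basal - 1e-12

    def test_monotone_in_fm_and_gpump(self):
        p = TonicParams(af=1e-4, g_pump=0.01)
        g1 = steady_state_gtonic(10.0, p, 100)
        g2 = steady_state_gtonic(20.0, p, 100)
        g3 = steady_state_gtonic(10.0, p.with_(g_pump=0.02), 100)
        assert g2 > g1 > g3

    def test_r_factor_unity_matches_unscaled(self):
        p1 = TonicParams(af=1e-4, g_pump=0.01, r_factor=1.0)
        s1 = TonicState(g_tonic=p1.g_basal)
        s2 = TonicState(g_tonic=p1.g_basal)
        for _ in range(200):
            s1 = update_gtonic(s1, 12.0, p1, n_i=50, step=0.5)
            s2 = update_gtonic(s2, 12.0, p1.with_(r_factor=1.0), n_i=50, step=0.5)
        assert s1.g_tonic == s2.g_tonic

    def test_r_scales_kinetics_not_steady_state(self):
        p = TonicParams(af=1e-4, g_pump=0.01)
        assert steady_state_gtonic(10.0, p, 100) == pytest.approx(
            steady_state_gtonic(10.0, p.with_(r_factor=3.0), 100)
        )

    def test_bad_step_rejected(self):
        with pytest.raises(ValueError):
            update_gtonic(TonicState(0.1), 1.0, TonicParams(), 10, step=-1.0)


class TestClosedForm:
    def test_initial_value_is_basal(self):
        p = TonicParams()
        assert closed_form_gtonic(0.0, 10.0, p, 100, t_p=0.05) == pytest.approx(p.g_basal)

    def test_long_time_limit(self):
        p = TonicParams(af=1e-4)
        limit = p.af * 10.0 * 100 / 0.05
        assert closed_form_gtonic(1e6, 10.0, p, 100, t_p=0.05) == pytest.approx(limit)

    def test_one_time_constant_point(self):
        # G(1/t_p) = limit + (G_basal - limit)/e
        p = TonicParams(af=1e-4)
        t_p = 0.05
        limit = p.af * 10.0 * 100 / t_p
        expected = limit + (p.g_basal - limit) / math.e
        assert closed_form_gtonic(1.0 / t_p, 10.0, p, 100, t_p) == pytest.approx(expected)

    def test_af_scaling_helper(self):
        val = af_scaling(3.0, g_init=0.1, t_p=0.05, f_m=10.0, n_i=100)
        assert val == pytest.approx(3.0 * 0.1 * 0.05 / (10.0 * 100))
        with pytest.raises(ValueError):
            af_scaling(5.0, 0.1, 0.05, 10.0, 100)

    def test_numerical_matches_closed_form_to_1e6(self):
        # same convention: pump on absolute G, no basal production, f_b = 0
        p = TonicParams(af=1e-4, g_pump=0.05, g_basal=0.1, f_b=0.0)
        pc = p.with_(g_basal=0.0)
        f_m, n_i = 10.0, 100
        s = TonicState(g_tonic=p.g_basal)
        t = 0.0
        for _ in range(50_000):
            s = update_gtonic(s, f_m, pc, n_i, step=0.02)
            t += 0.02
        ref = closed_form_gtonic(t, f_m, p, n_i, t_p=0.05)
        assert abs(s.g_tonic - ref) / ref < 1e-6


class TestRates:
    def test_no_spikes_zero_rate(self):
        assert mean_firing_rate(0, window=1000.0, n_i=100) == 0.0

    def test_direct_count(self):
        # 100 cells x 10 spikes in 1 s -> 10 Hz
        trains = [np.linspace(0, 999, 10) for _ in range(100)]
        assert mean_firing_rate(trains, window=1000.0, n_i=100) == pytest.approx(10.0)

    def test_empty_network_rejected(self):
        with pytest.raises(ValueError):
            mean_firing_rate(0, window=100.0, n_i=0)

    def test_sliding_rate_tracks_generator(self, rng):
        # inhomogeneous Poisson with rate step 5 -> 20 Hz at t = 5 s
        n_i, dur = 50, 10_000.0
        spikes = []
        for _ in range(n_i):
            t = 0.0
            while t < dur:
                lam = 5.0 if t < 5000.0 else 20.0
                t += rng.exponential(1000.0 / lam)
                if t < dur:
                    spikes.append(t)
        t_grid, f = sliding_rate(np.array(spikes), dur, window=1000.0, n_i=n_i, step=100.0)
        early = f[(t_grid > 2000) & (t_grid < 5000)].mean()
        late = f[t_grid > 7000].mean()
        assert early == pytest.approx(5.0, abs=2 * math.sqrt(5.0 / (n_i * 1.0)))
        assert late == pytest.approx(20.0, abs=2 * math.sqrt(20.0 / (n_i * 1.0)))


class TestTonicCurrent:
    def test_zero_at_reversal(self):
        assert tonic_current(0.3, -56.0, -56.0) == 0.0

    def test_sign_flips_across_reversal(self):
        assert tonic_current(0.3, -56.0, -70.0) > 0
        assert tonic_current(0.3, -56.0, -40.0) < 0

    def test_interneuron_doubling(self):
        i_pyr = tonic_current(0.3, -56.0, -65.0, cell_class="pyramidal")
        i_int = tonic_current(0.3, -56.0, -65.0, cell_class="interneuron")
        assert i_int == pytest.approx(2.0 * i_pyr)


class TestGatReversal:
    def test_unit_ratios_give_zero(self):
        ions = GatIonSet(na_out=10, na_in=10, gaba_out=1, gaba_in=1, cl_out=10, cl_in=10)
        assert gat_reversal(ions) == pytest.approx(0.0, abs=1e-12)

    def test_chloride_step_shift(self):
        # 115 -> 125 mM Cl_out at 306 K: shift = -(RT/F) ln(125/115) ~ -2.2 mV
        base = GatIonSet(temperature=306.0)
        up = GatIonSet(cl_out=125.0, temperature=306.0)
        shift = gat_reversal(up) - gat_reversal(base)
        rt_f = 8.31446261815324 * 306.0 / 96485.33212 * 1000.0
        assert shift == pytest.approx(-rt_f * math.log(125.0 / 115.0), rel=1e-12)
        assert shift == pytest.approx(-2.2, abs=0.1)

    def test_sodium_doubling(self):
        base = GatIonSet(temperature=306.0)
        up = GatIonSet(na_out=290.0, temperature=306.0)
        shift = gat_reversal(up) - gat_reversal(base)
        assert shift == pytest.approx(36.6, abs=0.2)

    def test_nonpositive_concentration_rejected(self):
        with pytest.raises(ValueError):
            GatIonSet(na_out=0.0)


class TestConcentrationTrace:
    def test_no_spikes_relaxes_to_basal(self):
        t, c = gaba_concentration_trace(np.empty(0), 2000.0, basal=0.3)
        assert np.allclose(c, 0.3)

    def test_single_ap_impulse_response(self):
        t, c = gaba_concentration_trace(np.array([100.0]), 2000.0, step=1.0,
                                        release_per_ap=0.5, decay_rate=0.004, basal=0.3)
        i0 = 100
        assert c[i0] == pytest.approx(0.8, abs=1e-9)
        # decay with time constant 1/0.004 = 250 ms
        assert c[i0 + 250] - 0.3 == pytest.approx(0.5 / math.e, rel=0.01)

    def test_burst_superposition(self):
        spikes = np.array([100.0, 150.0, 300.0])
        t, c_all = gaba_concentration_trace(spikes, 2000.0, basal=0.0)
        parts = [gaba_concentration_trace(np.array([s]), 2000.0, basal=0.0)[1]
                 for s in spikes]
        np.testing.assert_allclose(c_all, np.sum(parts, axis=0), atol=1e-9)
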