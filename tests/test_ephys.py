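"""Field-potential, clamp, single-channel and fluorescence analyses."""

import math

import numpy as np
import pandas as pd
import pytest

from gabawave.ephys import (
    Trace,
    band_power_around_peak,
    channel_analysis,
    classify_wave_like,
    detect_iie,
    event_probability,
    fluorescence_events,
    hill_fit,
    hill_inverse,
)
from gabawave.observables import InsufficientDataError
from gabawave.synthetic import (
    SENSOR_FIT,
    GeneratorSpec,
    gen_fluorescence,
    gen_lfp,
    gen_patch_channel,
)


class TestDetectIie:
    def test_flat_trace_no_events(self):
        # zero variance everywhere -> no events, no crash
        tr = Trace(np.zeros(10_000), rate=1000.0)
        assert len(detect_iie(tr)) == 0

    def test_round_trip_at_snr8(self):
        spec = GeneratorSpec(duration=60.0, rate=10_000.0, noise_sd=1.0, seed=0)
        trace, truth = gen_lfp(spec, event_rate=0.2, amplitude=8.0)
        events = detect_iie(trace)
        for t0 in truth["onset"]:
            err = np.abs(np.asarray(events["onset"]) - t0).min()
            assert err < 0.010  # onset error < 10 ms

    def test_offset_invariance(self):
        spec = GeneratorSpec(duration=30.0, rate=10_000.0, noise_sd=1.0, seed=1)
        trace, _ = gen_lfp(spec, event_rate=0.2, amplitude=8.0)
        shifted = Trace(trace.samples + 42.0, trace.rate)
        pd.testing.assert_frame_equal(detect_iie(trace), detect_iie(shifted))

    def test_sensitivity_monotone_in_snr(self):
        spec = GeneratorSpec(duration=40.0, rate=10_000.0, noise_sd=1.0, seed=2)
        found = []
        for amp in (3.0, 6.0, 12.0):
            trace, truth = gen_lfp(spec, event_rate=0.2, amplitude=amp)
            ev = detect_iie(trace)
            hits = sum(
                np.abs(np.asarray(ev["onset"]) - t0).min() < 0.05
                for t0 in truth["onset"]
                if len(ev)
            )
            found.append(hits)
        assert found[0] <= found[1] <= found[2]
        _, truth = gen_lfp(spec, event_rate=0.2, amplitude=12.0)
        assert found[2] == len(truth)  # all events at high SNR

    def test_short_trace_rejected(self):
        with pytest.raises(InsufficientDataError):
            detect_iie(Trace(np.zeros(1000), rate=1000.0))

    def test_low_rate_rejected(self):
        with pytest.raises(ValueError):
            detect_iie(Trace(np.zeros(1000), rate=500.0))


class TestEventProbability:
    def test_all_hit(self):
        stim = np.array([1.0, 2.0, 3.0])
        ev = pd.DataFrame({"onset": stim + 0.05})
        assert event_probability(ev, stim, kind="pulse") == 1.0

    def test_no_events(self):
        assert event_probability(pd.DataFrame({"onset": []}), np.array([1.0])) == 0.0

    def test_partial_fraction(self):
        # 20 stimuli, in-window events after the first 16 -> 0.8
        stim = np.arange(20, dtype=float)
        ev = pd.DataFrame({"onset": stim[:16] + 0.05})
        assert event_probability(ev, stim, kind="pulse") == pytest.approx(0.8)

    def test_ramp_window(self):
        # ramp window: [start + 0.5 s, start + duration + 0.1 s]
        stim = np.array([10.0])
        inside = pd.DataFrame({"onset": [10.8]})
        before = pd.DataFrame({"onset": [10.3]})
        assert event_probability(inside, stim, kind="ramp") == 1.0
        assert event_probability(before, stim, kind="ramp") == 0.0

    def test_overlap_warns(self):
        stim = np.array([0.0, 0.05])
        with pytest.warns(UserWarning):
            event_probability(pd.DataFrame({"onset": [0.01]}), stim, kind="pulse")


class TestClassifyWaveLike:
    def test_white_noise_mostly_negative(self):
        hits = 0
        for seed in range(100):
            x = np.random.default_rng(seed).standard_normal(int(120 * 500))
            if classify_wave_like(Trace(x, 500.0)).has_rhythm:
                hits += 1
        assert hits <= 5  # >= 95% correctly classified as non-wave

    def test_slow_sinusoid_detected(self):
        rng = np.random.default_rng(0)
        fs = 500.0
        t = np.arange(int(200 * fs)) / fs
        x = np.sin(2 * np.pi * 0.25 * t) + rng.standard_normal(t.size) / 3.0
        res = classify_wave_like(Trace(x, fs))
        assert res.has_rhythm
        assert res.dominant_freq == pytest.approx(0.25, abs=0.02)

    def test_fast_sinusoid_rejected(self):
        # 5 Hz lies outside the 0.01-2 Hz band after the 2-Hz low-pass
        fs = 500.0
        t = np.arange(int(120 * fs)) / fs
        x = np.sin(2 * np.pi * 5.0 * t)
        assert not classify_wave_like(Trace(x, fs)).has_rhythm


class TestChannelAnalysis:
    def test_flat_baseline(self):
        tr = Trace(np.zeros(50_000), rate=10_000.0)
        out = channel_analysis(tr, v_hold=-70.0, v_rev=0.0)
        assert out["opening_frequency"] == 0.0
        assert out["charge_transfer_rate"] == 0.0

    def test_single_opening_conductance(self):
        # one 5-pA opening across 70 mV -> G ~ 71.4 pS
        fs = 10_000.0
        x = np.zeros(int(fs))
        x[5000:5050] = -5.0  # 5-ms inward opening
        out = channel_analysis(Trace(x, fs), v_hold=-70.0, v_rev=0.0)
        assert len(out["events"]) == 1
        assert out["unitary_conductance"] * 1000 == pytest.approx(71.4, abs=1.0)

    def test_two_state_rate_recovery(self):
        spec = GeneratorSpec(duration=60.0, rate=10_000.0, noise_sd=0.3, seed=4)
        trace, truth = gen_patch_channel(spec, gaba_waveform=1.26)
        out = channel_analysis(trace, v_hold=-70.0, v_rev=0.0)
        n_true = len(truth)
        n_det = out["opening_frequency"] * spec.duration
        assert abs(n_det - n_true) < 2 * math.sqrt(n_true) + 0.05 * n_true

    def test_equal_potentials_rejected(self):
        with pytest.raises(ValueError):
            channel_analysis(Trace(np.zeros(100), 1000.0), v_hold=0.0, v_rev=0.0)


class TestHill:
    def test_half_max_inverts_to_kd(self):
        assert hill_inverse(SENSOR_FIT.e_max / 2.0, SENSOR_FIT) == pytest.approx(
            SENSOR_FIT.k_d
        )

    def test_sensor_peak_inversion(self):
        # dF/F0 = 0.074 with E = 0.175, K_d = 1.26, n = 2 -> ~1.08 uM
        c = hill_inverse(0.074, SENSOR_FIT)
        assert c == pytest.approx(1.08, abs=0.01)

    def test_noiseless_round_trip(self):
        conc = np.logspace(-1.5, 1.5, 12)
        resp = SENSOR_FIT(conc)
        fit = hill_fit(conc, resp)
        assert fit.e_max == pytest.approx(SENSOR_FIT.e_max, rel=1e-4)
        assert fit.k_d == pytest.approx(SENSOR_FIT.k_d, rel=1e-4)
        assert fit.n == pytest.approx(SENSOR_FIT.n, rel=1e-4)

    def test_inverse_domain_error(self):
        with pytest.raises(ValueError):
            hill_inverse(0.2, SENSOR_FIT)  # above e_max

    def test_too_few_concentrations(self):
        with pytest.raises(ValueError):
            hill_fit([1.0, 1.0], [0.1, 0.1])

    def test_fit_inverse_round_trip_identity(self):
        conc = np.logspace(-1, 1, 8)
        fit = hill_fit(conc, SENSOR_FIT(conc))
        for c in (0.3, 1.0, 3.0):
            assert hill_inverse(fit(c), fit) == pytest.approx(c, rel=1e-3)


class TestFluorescenceEvents:
    @staticmethod
    def _world(lead_s=0.085, n_events=15, seed=1):
        rate, dur = 1000.0, 60.0
        ev_times = np.arange(5.0, 5.0 + 3.0 * n_events, 3.0)
        t = np.arange(int(dur * rate)) / rate
        conc = np.zeros(t.size)
        for te in ev_times:
            tt = t - (te - lead_s)
            m = tt > 0
            amp = 1.0785  # peak [GABA] that maps to dF/F0 = 0.074
            conc[m] += amp * (tt[m] / 0.02) * np.exp(1 - tt[m] / 0.02) * (tt[m] < 0.02) \
                + amp * np.exp(-(tt[m] - 0.02) / 0.3) * (tt[m] >= 0.02)
        fl, _ = gen_fluorescence(
            GeneratorSpec(duration=dur, rate=rate, noise_sd=0.004, seed=seed), conc
        )
        field = pd.DataFrame(
            {
                "onset": ev_times,
                "peak_time": ev_times,
                "amplitude": 10.0,
                "width": 0.08,
                "label": "iie",
            }
        )
        return fl, field, ev_times

    def test_recovered_lead_in_band(self):
        # transient starts 85 ms before each field event -> mean lead 80-90 ms
        fl, field, _ = self._world()
        table, lags = fluorescence_events(fl, field)
        assert len(table) >= 12
        assert -0.090 <= np.mean(lags) <= -0.080

    def test_noise_only_no_events(self):
        rate, dur = 1000.0, 30.0
        fl, _ = gen_fluorescence(
            GeneratorSpec(duration=dur, rate=rate, noise_sd=0.01, seed=2), 0.0
        )
        field = pd.DataFrame(
            {"onset": [10.0], "peak_time": [10.0], "amplitude": 10.0,
             "width": 0.08, "label": "iie"}
        )
        table, lags = fluorescence_events(fl, field)
        assert len(table) == 0

    def test_chained_concentration_estimate(self):
        # a 0.074-dF/F0 transient implies ~1.1 uM via the sensor model
        fl, field, _ = self._world()
        table, _ = fluorescence_events(fl, field)
        peak = float(np.median(table["amplitude"]))
        conc = hill_inverse(min(peak, 0.174), SENSOR_FIT)
        assert conc == pytest.approx(hill_inverse(0.074, SENSOR_FIT), rel=0.25)


class TestBandPower:
    def test_ramping_high_band_before_peaks(self, rng):
        # high-frequency events ramp up before each slow peak
        fs = 500.0
        t = np.arange(int(60 * fs)) / fs
        slow = np.sin(2 * np.pi * 0.2 * t - np.pi / 2)
        envelope = np.clip(np.sin(2 * np.pi * 0.2 * t), 0, None)  # peaks before slow peaks
        high = envelope * np.sin(2 * np.pi * 12.0 * t)
        x = slow + high + 0.05 * rng.standard_normal(t.size)
        out = band_power_around_peak(Trace(x, fs))
        assert out["power_before"].size >= 5
        frac = np.mean(out["power_before"] > out["power_after"])
        assert frac > 0.5

    def test_stationary_high_band_ratio_near_one(self, rng):
        fs = 500.0
        t = np.arange(int(120 * fs)) / fs
        x = np.sin(2 * np.pi * 0.2 * t) + 0.3 * rng.standard_normal(t.size)
        out = band_power_around_peak(Trace(x, fs))
        ratio = out["power_before"].mean() / out["power_after"].mean()
        assert 0.7 < ratio < 1.4

    def test_zero_high_band(self):
        fs = 500.0
        t = np.arange(int(60 * fs)) / fs
        x = np.sin(2 * np.pi * 0.2 * t)
        out = band_power_around_peak(Trace(x, fs))
        assert np.all(out["power_before"] < 1e-4)
        assert np.all(out["power_after"] < 1e-4)
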