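"""Ring connectivity, biexponential synapses, Poisson drive, release."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from gabawave.network_core import (
    NetworkConfig,
    SynapseParams,
    biexp_conductance,
    biexp_peak_time,
    build_connectivity,
    circular_distance,
    poisson_drive,
    ring_positions,
    stochastic_release,
)


class TestConnectivity:
    def test_zero_distance_gives_max_weight(self):
        # adjacent-population probe: weight at distance 0 equals 1 (x class G)
        cfg = NetworkConfig(n_interneurons=10, g_ii=0.1)
        conn = build_connectivity(cfg)
        # nearest neighbours on a 10-cell ring with sigma_ii = 5 (index units)
        w01 = conn.weight[0, 1]
        assert 0 < w01 <= 1.0
        assert conn.weight[0, 0] == 0.0  # no self-connection

    def test_weight_nonincreasing_with_distance(self):
        cfg = NetworkConfig(n_interneurons=40, g_ii=0.1)
        conn = build_connectivity(cfg)
        w = conn.weight[0, 1:21]  # increasing distance up to the half-ring
        assert np.all(np.diff(w) <= 1e-12)

    def test_circular_symmetry(self):
        # rotating indices leaves weight statistics invariant (no edge effects)
        cfg = NetworkConfig(n_interneurons=30, g_ii=0.1)
        conn = build_connectivity(cfg)
        row_sums = conn.weight.sum(axis=1)
        assert np.allclose(row_sums, row_sums[0])

    def test_delays_bounded_by_half_circumference(self):
        cfg = NetworkConfig(n_interneurons=25, g_ii=0.1, propagation_speed=100.0,
                            max_delay=1e9)
        conn = build_connectivity(cfg)
        bound = math.pi * cfg.radius_i / cfg.propagation_speed
        assert np.all(conn.delay >= 0)
        assert conn.delay.max() <= bound + 1e-9

    def test_delay_cap_applies(self):
        cfg = NetworkConfig(n_interneurons=25, g_ii=0.1, propagation_speed=0.1)
        conn = build_connectivity(cfg)
        assert conn.delay.max() <= cfg.max_delay

    def test_sampled_mode_mean_outdegree_matches_density(self):
        # Monte-Carlo: existence probability equals the Gaussian density
        cfg = NetworkConfig(
            n_interneurons=100, g_ii=0.1, connection_mode="sampled", sigma_units="um"
        )
        degrees = []
        for seed in range(30):
            conn = build_connectivity(cfg.with_(seed=seed))
            degrees.append((conn.weight > 0).sum(axis=0).mean())
        # expected out-degree = sum of Gaussian(um arc distance) over partners
        pos = ring_positions(100, 250.0)
        d = circular_distance(pos, pos, 250.0)
        p = np.exp(-0.5 * (d / 5.0) ** 2)
        np.fill_diagonal(p, 0.0)
        expected = p.sum(axis=0).mean()
        assert abs(np.mean(degrees) - expected) < 0.25 * expected + 0.2

    def test_sigma_zero_rejected(self):
        with pytest.raises(ValueError):
            NetworkConfig(sigma={"EE": 10.0, "EI": 12.5, "IE": 8.0, "II": 0.0})

    def test_edge_list_round_trip(self):
        cfg = NetworkConfig(n_interneurons=12, g_ii=0.1)
        conn = build_connectivity(cfg)
        df = conn.to_edge_list()
        assert set(df.columns) == {"source", "target", "conn_class", "weight", "delay_ms"}
        assert (df["weight"] > 0).all()
        assert len(df) == (conn.weight > 0).sum()


class TestBiexp:
    def test_zero_at_origin_and_decay(self):
        p = SynapseParams(tau_rise=0.5, tau_decay=3.0, peak_conductance=0.2)
        assert biexp_conductance(0.0, p) == pytest.approx(0.0, abs=1e-12)
        assert biexp_conductance(10 * p.tau_decay, p) < 1e-3 * p.peak_conductance

    def test_peak_time_and_value(self):
        # t* = (tr td/(td-tr)) ln(td/tr): 0.5/3 ms -> 1.075 ms, value = peak
        p = SynapseParams(tau_rise=0.5, tau_decay=3.0, peak_conductance=0.2)
        t_star = biexp_peak_time(0.5, 3.0)
        assert t_star == pytest.approx(1.0751, abs=1e-3)
        assert biexp_conductance(t_star, p) == pytest.approx(0.2, rel=1e-9)

    def test_degenerate_taus_rejected(self):
        with pytest.raises(ValueError):
            SynapseParams(tau_rise=3.0, tau_decay=3.0)

    @given(
        tr=st.floats(0.1, 2.0),
        ratio=st.floats(1.5, 20.0),
        t=st.floats(0.0, 50.0),
    )
    @settings(max_examples=100, deadline=None, derandomize=True)
    def test_conductance_bounded_by_peak(self, tr, ratio, t):
        p = SynapseParams(tau_rise=tr, tau_decay=tr * ratio, peak_conductance=1.0)
        g = biexp_conductance(t, p)
        assert -1e-9 <= g <= 1.0 + 1e-9


class TestPoissonDrive:
    def test_zero_rate_empty(self, rng):
        events, g = poisson_drive(0.0, 0.02, 3.0, 1000.0, rng)
        assert events.size == 0
        assert np.all(g == 0.0)

    def test_event_count_poisson(self, rng):
        events, _ = poisson_drive(100.0, 0.02, 3.0, 10_000.0, rng)
        # 3 SD band around mean 1000
        assert abs(events.size - 1000) < 3 * math.sqrt(1000)

    def test_campbell_mean_conductance(self, rng):
        # time-average g = rate x amplitude x tau (Campbell's theorem), 5%
        rate, amp, tau = 50.0, 0.1, 3.0
        _, g = poisson_drive(rate, amp, tau, 100_000.0, rng, dt=0.1)
        expected = rate * 1e-3 * amp * tau
        assert g.mean() == pytest.approx(expected, rel=0.05)

    def test_negative_rate_rejected(self, rng):
        with pytest.raises(ValueError):
            poisson_drive(-1.0, 0.02, 3.0, 100.0, rng)


class TestStochasticRelease:
    def test_extremes(self, rng):
        assert np.all(stochastic_release(1.0, rng, n=100))
        assert not np.any(stochastic_release(0.0, rng, n=100))

    def test_half_probability_fraction(self, rng):
        out = stochastic_release(0.5, rng, n=10_000)
        assert 0.47 <= out.mean() <= 0.53

    def test_out_of_range_rejected(self, rng):
        with pytest.raises(ValueError):
            stochastic_release(1.5, rng)
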