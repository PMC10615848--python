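"""Co-simulation engine: determinism, rest sanity, scaling, protocols."""

import numpy as np
import pytest

from gabawave.gaba_field import TonicParams, steady_state_gtonic
from gabawave.network_core import NetworkConfig
from gabawave.recipes import fig3b_config, fig3c_config
from gabawave.simulator import (
    DriveParams,
    SimulationConfig,
    run_forced_gtonic,
    run_network,
    run_twinned,
    twinned_config,
)


def tiny_config(**kw):
    base = dict(
        network=NetworkConfig(n_interneurons=20, g_ii=0.1),
        duration=1000.0,
        seed=3,
    )
    base.update(kw)
    return SimulationConfig(**base)


class TestRunNetwork:
    def test_same_seed_identical_rasters(self):
        r1 = run_network(tiny_config())
        r2 = run_network(tiny_config())
        assert r1.raster.n_spikes == r2.raster.n_spikes
        for a, b in zip(r1.raster.spike_times, r2.raster.spike_times):
            np.testing.assert_array_equal(a, b)
        np.testing.assert_array_equal(r1.g_tonic, r2.g_tonic)

    def test_different_seeds_differ(self):
        r1 = run_network(tiny_config(seed=1))
        r2 = run_network(tiny_config(seed=2))
        assert r1.raster.pooled().size != r2.raster.pooled().size or not np.array_equal(
            r1.raster.pooled(), r2.raster.pooled()
        )

    def test_rest_without_drive_or_field(self):
        # all synapses and drives off, zero tonic: unshifted cells stay at
        # rest (the default interneuron is deliberately pacemaking, its
        # kinetics shift standing in for the epileptogenic depolarization)
        from gabawave.cell_models import CellParams

        cfg = tiny_config(
            network=NetworkConfig(n_interneurons=10, g_ii=0.0),
            drive_i=DriveParams(g_s=0.0, f_s=0.0),
            gtonic_mode="constant",
            gtonic_value=0.0,
            interneuron=CellParams(kinetics_shift=0.0),
        )
        res = run_network(cfg)
        assert res.raster.n_spikes == 0

    def test_spike_times_within_duration(self, small_net_result):
        pooled = small_net_result.raster.pooled()
        assert pooled.size > 0
        assert pooled.min() >= 0.0
        assert pooled.max() <= small_net_result.config.duration

    def test_series_share_time_base(self, small_net_result):
        r = small_net_result
        assert r.t_ms.size == r.g_tonic.size == r.f_m.size == r.gaba_e.size
        np.testing.assert_allclose(r.gaba_e * r.config.tonic.alpha, r.g_tonic)

    def test_scaling_rule_preserves_steady_state(self):
        # halving N with N x A_f constant preserves the field fixed point
        p1 = TonicParams(af=2e-6)
        p2 = TonicParams(af=4e-6)
        assert steady_state_gtonic(10.0, p1, 100) == pytest.approx(
            steady_state_gtonic(10.0, p2, 50)
        )

    def test_constant_mode_holds_value(self):
        res = run_network(tiny_config(gtonic_mode="constant", gtonic_value=0.3))
        assert np.allclose(res.g_tonic, 0.3)

    def test_dynamic_mode_starts_at_basal(self):
        res = run_network(tiny_config())
        assert res.g_tonic[0] == pytest.approx(res.config.tonic.g_basal)
        assert np.all(res.g_tonic >= res.config.tonic.g_basal - 1e-12)

    def test_invalid_config_rejected(self):
        with pytest.raises(ValueError):
            tiny_config(duration=-1.0)
        with pytest.raises(ValueError):
            tiny_config(gtonic_mode="nonsense")


class TestTwinned:
    def test_joint_raster_labels(self):
        res = run_twinned(twinned_config(
            n_interneurons=20, n_pyramidal=20, duration=2000.0, seed=1))
        assert res.raster.n_cells == 40
        assert res.raster.cell_labels.sum() == 20
        assert res.lfp is not None
        assert res.pyr_currents.shape[1] == 20

    def test_decoupled_populations_independent(self):
        # zero internetwork conductances + fixed G_tonic: the two
        # populations' rate fluctuations are uncorrelated
        from gabawave.observables import population_rate

        base = twinned_config(n_interneurons=25, n_pyramidal=25,
                              duration=8000.0, seed=5)
        net0 = base.network.with_(g_ei=0.0, g_ie=0.0)
        cfg = base.with_(network=net0, gtonic_mode="constant", gtonic_value=0.3)
        res = run_network(cfg)
        inh = res.raster.subset(res.raster.cell_labels)
        pyr = res.raster.subset(~res.raster.cell_labels)
        _, ri = population_rate(inh, 100.0)
        _, re_ = population_rate(pyr, 100.0)
        if ri.std() > 0 and re_.std() > 0:
            r = np.corrcoef(ri, re_)[0, 1]
            assert abs(r) < 0.25

    def test_requires_both_populations(self):
        with pytest.raises(ValueError):
            run_twinned(twinned_config(n_interneurons=10, n_pyramidal=0,
                                       duration=100.0))


class TestForcedGtonic:
    def test_zero_amplitude_reduces_to_constant(self):
        cfg = tiny_config()
        forced = run_forced_gtonic(cfg, freq_hz=1.0, amplitude=0.0, offset=0.3)
        const = run_network(cfg.with_(gtonic_mode="constant", gtonic_value=0.3))
        np.testing.assert_array_equal(forced.raster.pooled(), const.raster.pooled())

    def test_waveform_followed_exactly(self):
        cfg = tiny_config(duration=2000.0)
        res = run_forced_gtonic(cfg, freq_hz=1.0, amplitude=0.1, offset=0.3)
        # record at stride r holds the waveform of the last executed step,
        # whose prescribed time is (r * stride - 1) * dt
        stride_ms = res.t_ms[1] - res.t_ms[0]
        t_s = (res.t_ms[1:] - cfg.dt) * 1e-3
        expected = 0.3 + 0.1 * np.sin(2 * np.pi * 1.0 * t_s)
        np.testing.assert_allclose(res.g_tonic[1:], expected, atol=1e-6)

    def test_negative_amplitude_rejected(self):
        with pytest.raises(ValueError):
            run_forced_gtonic(tiny_config(), amplitude=-0.1)


def test_fig_configs_build():
    assert fig3b_config().gtonic_mode == "constant"
    assert fig3c_config().gtonic_mode == "dynamic"
    cfg = fig3c_config(n=50)
    # N x A_f preserved across scaling
    assert cfg.tonic.af * 50 == pytest.approx(fig3c_config(n=100).tonic.af * 100)
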