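"""Numba-compiled inner loop of the network co-simulation.

All state lives in flat float64/int64 arrays; the loop advances membrane
potentials (forward Euler at fixed dt), biexponential synapses (pair of
leaky integrators per receptor channel), dt-quantized conduction delays
(ring buffer), stochastic release, Poisson external drive (pre-generated
event lists), and the tonic-conductance field (exponential update, exact
for piecewise-constant f_m).

Everything stochastic inside the loop draws from numpy's legacy global RNG
seeded once at entry, so a run is bit-reproducible given its seed.
"""

from __future__ import annotations

import numpy as np
from numba import njit

#: tonic-conductance modes
MODE_DYNAMIC = 0
MODE_PRESCRIBED = 1


@njit(cache=True)
def run_engine(
    seed,
    n_steps,
    dt,
    # --- per-cell parameters (n,) ---
    cm,
    gl,
    el,
    gna,
    ena,
    gk,
    ek,
    phi,
    iapp,
    kshift,
    is_inh,  # uint8
    tonic_scale,  # interneurons 2.0, pyramidal 1.0
    v0,
    h0,
    n0,
    # --- synapses ---
    weight,  # (n, n) effective peak conductance, post x pre, mS/cm^2
    delay_steps,  # (n, n) int64
    release_p,  # (n, n)
    tau_r,
    tau_d,
    bnorm,  # 1 / (e^(-t*/td) - e^(-t*/tr))
    v_gaba,
    e_exc,
    # --- external Poisson drive, events sorted by step ---
    drv_step,  # (m,) int64
    drv_cell,  # (m,) int64
    drv_amp,  # (m,)
    drv_tau,
    # --- tonic field ---
    tonic_mode,
    g_prescribed,  # (n_steps,) used when tonic_mode == MODE_PRESCRIBED
    af,
    gpump,
    gbasal,
    fb,
    r_factor,
    n_i_count,
    fm_window_steps,
    field_delay_steps,
    # --- spike detection / recording ---
    spike_thresh,
    refrac_steps,
    record_stride,
    record_currents,  # uint8: record per-pyramidal synaptic+tonic current
    spike_capacity,
):
    np.random.seed(seed)
    n = cm.shape[0]

    v = v0.copy()
    h = h0.copy()
    ng = n0.copy()

    # synapse states: difference-of-exponentials as two leaky integrators
    xr_inh = np.zeros(n)
    xd_inh = np.zeros(n)
    xr_exc = np.zeros(n)
    xd_exc = np.zeros(n)
    g_drv = np.zeros(n)
    dec_r = np.exp(-dt / tau_r)
    dec_d = np.exp(-dt / tau_d)
    dec_drv = np.exp(-dt / drv_tau)

    # delayed-delivery ring buffers
    max_d = 0
    for i in range(n):
        for j in range(n):
            if weight[i, j] > 0.0 and delay_steps[i, j] > max_d:
                max_d = delay_steps[i, j]
    buf_len = max_d + 1
    buf_inh = np.zeros((buf_len, n))
    buf_exc = np.zeros((buf_len, n))

    # spike bookkeeping
    spike_step = np.empty(spike_capacity, dtype=np.int64)
    spike_cell = np.empty(spike_capacity, dtype=np.int64)
    n_spikes = 0
    lockout = np.full(n, -1, dtype=np.int64)
    above = v >= spike_thresh

    # cumulative interneuron spike counts: cum[q] = spikes in steps < q
    cum = np.zeros(n_steps + 2, dtype=np.int64)

    g_tonic = gbasal if tonic_mode == MODE_DYNAMIC else g_prescribed[0]
    k_pump = r_factor * gpump
    pump_decay = np.exp(-k_pump * dt)

    n_rec = n_steps // record_stride + 1
    g_rec = np.zeros(n_rec)
    fm_rec = np.zeros(n_rec)
    n_pyr = 0
    for i in range(n):
        if is_inh[i] == 0:
            n_pyr += 1
    if record_currents == 1 and n_pyr > 0:
        cur_rec = np.zeros((n_rec, n_pyr))
    else:
        cur_rec = np.zeros((1, 1))
    g_rec[0] = g_tonic

    drv_ptr = 0
    m_drv = drv_step.shape[0]
    overflow = False

    for s in range(n_steps):
        # delayed synaptic increments due this step
        row = s % buf_len
        for i in range(n):
            wi = buf_inh[row, i]
            if wi > 0.0:
                xr_inh[i] += bnorm * wi
                xd_inh[i] += bnorm * wi
                buf_inh[row, i] = 0.0
            we = buf_exc[row, i]
            if we > 0.0:
                xr_exc[i] += bnorm * we
                xd_exc[i] += bnorm * we
                buf_exc[row, i] = 0.0

        # external drive events due this step
        while drv_ptr < m_drv and drv_step[drv_ptr] == s:
            g_drv[drv_cell[drv_ptr]] += drv_amp[drv_ptr]
            drv_ptr += 1

        # tonic field
        if tonic_mode == MODE_PRESCRIBED:
            g_tonic = g_prescribed[s]
        else:
            # trailing window ending field_delay_steps in the past
            hi = s - field_delay_steps
            if hi < 0:
                hi = 0
            lo = hi - fm_window_steps
            if lo < 0:
                lo = 0
            win_ms = (hi - lo) * dt
            if win_ms <= 0.0:
                fm_hz = 0.0
            else:
                fm_hz = (cum[hi] - cum[lo]) / (win_ms * 1e-3) / n_i_count
            drive = n_i_count * r_factor * af * (fm_hz + fb)
            if k_pump == 0.0:
                g_tonic = g_tonic + dt * drive
            else:
                g_ss = gbasal + drive / k_pump
                g_tonic = g_ss + (g_tonic - g_ss) * pump_decay

        # membrane update
        step_count_inh = 0
        for i in range(n):
            vi = v[i]
            # Wang-Buzsaki rate functions (instantaneous m), voltage-shifted
            vk = vi - kshift[i]
            x = -(vk + 35.0)
            if abs(x) < 1e-5:
                am = 0.1 * 10.0
            else:
                am = 0.1 * x / (np.exp(x / 10.0) - 1.0)
            bm = 4.0 * np.exp(-(vk + 60.0) / 18.0)
            m_inf = am / (am + bm)
            ah = 0.07 * np.exp(-(vk + 58.0) / 20.0)
            bh = 1.0 / (np.exp(-0.1 * (vk + 28.0)) + 1.0)
            x = -(vk + 34.0)
            if abs(x) < 1e-5:
                an = 0.01 * 10.0
            else:
                an = 0.01 * x / (np.exp(x / 10.0) - 1.0)
            bn = 0.125 * np.exp(-(vk + 44.0) / 80.0)

            g_inh = xd_inh[i] - xr_inh[i]
            g_exc = xd_exc[i] - xr_exc[i]
            i_syn = g_inh * (v_gaba - vi) + (g_exc + g_drv[i]) * (e_exc - vi)
            i_ton = tonic_scale[i] * g_tonic * (v_gaba - vi)
            dv = (
                -gl[i] * (vi - el[i])
                - gna[i] * m_inf**3 * h[i] * (vi - ena[i])
                - gk[i] * ng[i] ** 4 * (vi - ek[i])
                + iapp[i]
                + i_syn
                + i_ton
            ) / cm[i]
            v_new = vi + dt * dv
            h[i] = h[i] + dt * phi[i] * (ah * (1.0 - h[i]) - bh * h[i])
            if h[i] < 0.0:
                h[i] = 0.0
            elif h[i] > 1.0:
                h[i] = 1.0
            ng[i] = ng[i] + dt * phi[i] * (an * (1.0 - ng[i]) - bn * ng[i])
            if ng[i] < 0.0:
                ng[i] = 0.0
            elif ng[i] > 1.0:
                ng[i] = 1.0

            if abs(v_new) > 500.0:
                # signal blow-up via sentinel; caller raises
                return (
                    spike_step[:n_spikes],
                    spike_cell[:n_spikes],
                    g_rec,
                    fm_rec,
                    cur_rec,
                    -(s + 1),
                )

            # spike detection: upward crossing with refractory lockout
            if v_new >= spike_thresh and not above[i] and s >= lockout[i]:
                if n_spikes < spike_capacity:
                    spike_step[n_spikes] = s + 1
                    spike_cell[n_spikes] = i
                    n_spikes += 1
                else:
                    overflow = True
                lockout[i] = s + refrac_steps
                if is_inh[i] == 1:
                    step_count_inh += 1
                # propagate with per-synapse stochastic release
                for post in range(n):
                    w = weight[post, i]
                    if w > 0.0:
                        p = release_p[post, i]
                        if p >= 1.0 or np.random.random() < p:
                            slot = (s + delay_steps[post, i]) % buf_len
                            if is_inh[i] == 1:
                                buf_inh[slot, post] += w
                            else:
                                buf_exc[slot, post] += w
            above[i] = v_new >= spike_thresh
            v[i] = v_new

        cum[s + 1] = cum[s] + step_count_inh

        # decay synaptic states
        for i in range(n):
            xr_inh[i] *= dec_r
            xd_inh[i] *= dec_d
            xr_exc[i] *= dec_r
            xd_exc[i] *= dec_d
            g_drv[i] *= dec_drv

        # recording
        if (s + 1) % record_stride == 0:
            r = (s + 1) // record_stride
            g_rec[r] = g_tonic
            lo = s + 1 - fm_window_steps
            if lo < 0:
                lo = 0
            win_ms = (s + 1 - lo) * dt
            fm_rec[r] = (cum[s + 1] - cum[lo]) / (win_ms * 1e-3) / n_i_count
            if record_currents == 1 and n_pyr > 0:
                pidx = 0
                for i in range(n):
                    if is_inh[i] == 0:
                        g_inh = xd_inh[i] - xr_inh[i]
                        g_exc = xd_exc[i] - xr_exc[i]
                        cur_rec[r, pidx] = (
                            g_inh * (v_gaba - v[i])
                            + (g_exc + g_drv[i]) * (e_exc - v[i])
                            + tonic_scale[i] * g_tonic * (v_gaba - v[i])
                        )
                        pidx += 1

    status = n_spikes if not overflow else -(n_steps + 2)
    return (
        spike_step[:n_spikes],
        spike_cell[:n_spikes],
        g_rec,
        fm_rec,
        cur_rec,
        status,
    )
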