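"""Volume-transmitted GABA field: firing-rate-driven tonic conductance.

The extracellular GABA concentration [GABA]_e is treated as a well-mixed
scalar per population. Interneuronal firing releases GABA into the volume;
GAT-1 uptake removes it, giving a first-order relaxation. The tonic
GABA_A-receptor conductance G_tonic is taken proportional to [GABA]_e
(G_tonic = alpha * [GABA]_e), so the canonical dynamics is written directly
on the conductance::

    dG/dt = N_i * R * A_f * (f_m[t - dt] + f_b) - R * G_pump * (G - G_basal)

with G(0) = G_basal. Units: time in ms, conductances in mS/cm^2, population
rates f_m and f_b in Hz (spikes per cell per second). A_f is a free scaling
in these simulation units (the printed per-ms units are not mutually
consistent with the printed conductance scale); defaults follow the
figure-level parameter sets. With R = 1 the R-scaled form reduces exactly to
the unscaled equation.

A verbatim closed-form solution for constant f_m is provided separately
(:func:`closed_form_gtonic`); note it pumps *absolute* G rather than
(G - G_basal) and omits f_b, so it solves dG/dt = N_i*A_f*f_m - t_p*G.
Both conventions are kept as published; see docs/methods.md.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
import math

import numpy as np

__all__ = [
    "TonicParams",
    "TonicState",
    "GatIonSet",
    "update_gtonic",
    "steady_state_gtonic",
    "mean_firing_rate",
    "sliding_rate",
    "closed_form_gtonic",
    "af_scaling",
    "tonic_current",
    "gat_reversal",
    "gaba_concentration_trace",
]

# Gas constant (J/mol/K) over Faraday constant (C/mol), in mV per K.
_R_OVER_F_MV = 8.31446261815324 / 96485.33212 * 1000.0

#: Conversion from the published A_f figure-caption values (printed in
#: nS cm^-2 ms^-1, which is not mutually consistent with the mS cm^-2
#: conductance scale of the same figures) to simulation units
#: (mS cm^-2 ms^-1 per Hz of population rate). Calibrated once so that the
#: caption parameter sets put the release-uptake feedback in its working
#: regime; see docs/methods.md.
AF_UNIT_SCALE = 10.0


@dataclass(frozen=True)
class TonicParams:
    """Parameters of the tonic-conductance field dynamics.

    af
        Conductance increment scale per unit population rate
        (mS cm^-2 ms^-1 per Hz). Published figure-level values: 1.35e-7
        (interneuron network), 2e-7 (twinned network), 1e-8 (N = 1500
        uptake sweep), each multiplied by AF_UNIT_SCALE in simulation
        units; the default is the interneuron-network value.
    g_pump : ms^-1
        GABA uptake (GAT-1) rate constant.
    g_basal : mS/cm^2
        Resting tonic conductance (0.1); the field relaxes to it.
    f_b : Hz
        Basal network spiking rate added to f_m (0.1).
    delay_dt : ms
        Release-to-receptor delay; f_m is read this far in the past (< 1 ms).
    r_factor
        Combined release-uptake factor R, scaling both terms jointly.
    alpha
        Linear G_tonic <-> [GABA]_e map (mS/cm^2 per uM). Never printed;
        default 0.25 puts the simulated G_tonic range (~0.1-0.5 mS/cm^2)
        onto the observed ~0.4-2 uM [GABA]_e range.
    interneuron_scale
        Tonic-conductance range of interneurons relative to pyramidal
        cells (2).
    """

    af: float = 1.35e-6
    g_pump: float = 0.003
    g_basal: float = 0.1
    f_b: float = 0.1
    delay_dt: float = 0.5
    r_factor: float = 1.0
    alpha: float = 0.25
    interneuron_scale: float = 2.0

    def __post_init__(self) -> None:
        if self.g_pump < 0 or self.g_basal < 0 or self.delay_dt < 0:
            raise ValueError("g_pump, g_basal and delay_dt must be >= 0")
        if self.r_factor <= 0 or self.interneuron_scale <= 0 or self.alpha <= 0:
            raise ValueError("r_factor, alpha and interneuron_scale must be > 0")

    def with_(self, **kw) -> "TonicParams":
        return replace(self, **kw)


@dataclass
class TonicState:
    """Instantaneous field state: G_tonic (mS/cm^2) and its [GABA]_e proxy."""

    g_tonic: float
    t: float = 0.0
    alpha: float = 0.25

    @property
    def gaba_e(self) -> float:
        """Extracellular GABA concentration proxy, uM."""
        return self.g_tonic / self.alpha


def steady_state_gtonic(f_m: float, params: TonicParams, n_i: int) -> float:
    """Fixed point of the field equation for constant f_m (Hz)."""
    if params.g_pump == 0:
        raise ValueError("no steady state with zero uptake rate")
    return params.g_basal + n_i * params.af * (f_m + params.f_b) / params.g_pump


def update_gtonic(
    state: TonicState,
    f_m: float,
    params: TonicParams,
    n_i: int,
    step: float,
) -> TonicState:
    """Advance the field one step of ``step`` ms with (delayed) rate f_m (Hz).

    Uses the exponential update, exact when f_m is constant over the step:
    G(t+h) = G_ss + (G(t) - G_ss) * exp(-R*G_pump*h). The caller is
    responsible for supplying f_m evaluated at t - delay_dt.
    """
    if step <= 0:
        raise ValueError("step must be > 0")
    if f_m < 0:
        raise ValueError("f_m must be >= 0")
    r = params.r_factor
    k = r * params.g_pump
    drive = n_i * r * params.af * (f_m + params.f_b)
    if k == 0:
        g_new = state.g_tonic + step * drive
    else:
        g_ss = params.g_basal + drive / k
        g_new = g_ss + (state.g_tonic - g_ss) * math.exp(-k * step)
    return TonicState(g_tonic=g_new, t=state.t + step, alpha=params.alpha)


def mean_firing_rate(spike_counts_or_raster, window: float, n_i: int) -> float:
    """Population-mean firing rate f_m (Hz) over a window of ``window`` ms.

    Accepts either a total spike count, a sequence of per-cell spike-time
    arrays, or a :class:`~gabawave.observables.SpikeRaster`.
    """
    if window <= 0:
        raise ValueError("window must be > 0")
    if n_i <= 0:
        raise ValueError("empty network: n_i must be >= 1")
    obj = spike_counts_or_raster
    if hasattr(obj, "spike_times"):
        total = sum(len(s) for s in obj.spike_times)
    elif np.isscalar(obj):
        total = float(obj)
    else:
        total = sum(len(np.atleast_1d(s)) for s in obj)
    return total / (window * 1e-3) / n_i


def sliding_rate(
    spike_times: np.ndarray, duration: float, window: float, n_i: int, step: float
) -> tuple[np.ndarray, np.ndarray]:
    """Sliding-window f_m (Hz) over pooled spike times (ms).

    Returns (t, f_m) sampled every ``step`` ms; the window is trailing
    (covers [t - window, t)), truncated at t = 0.
    """
    t_grid = np.arange(0.0, duration + 0.5 * step, step)
    spikes = np.sort(np.asarray(spike_times, dtype=float))
    hi = np.searchsorted(spikes, t_grid, side="left")
    lo = np.searchsorted(spikes, t_grid - window, side="left")
    eff_window = np.minimum(t_grid, window)
    eff_window[eff_window == 0] = window
    f_m = (hi - lo) / (eff_window * 1e-3) / n_i
    return t_grid, f_m


def closed_form_gtonic(
    t: float | np.ndarray,
    f_m: float,
    params: TonicParams,
    n_i: int,
    t_p: float,
) -> float | np.ndarray:
    """Published closed-form G_tonic(t) for constant f_m.

    G(t) = exp(-t_p t) G_basal + (A_f f_m N_i / t_p) (1 - exp(-t_p t)),
    i.e. the solution of dG/dt = N_i A_f f_m - t_p G with G(0) = G_basal.
    ``t_p`` is the pump rate in ms^-1 (published range 0.02-0.1).
    """
    t = np.asarray(t, dtype=float)
    if np.any(t < 0):
        raise ValueError("t must be >= 0")
    if t_p <= 0:
        raise ValueError("t_p must be > 0")
    decay = np.exp(-t_p * t)
    out = decay * params.g_basal + (params.af * f_m * n_i / t_p) * (1.0 - decay)
    return float(out) if out.ndim == 0 else out


def af_scaling(k: float, g_init: float, t_p: float, f_m: float, n_i: int) -> float:
    """A_f = K G_init t_p / (f_m N_i), the published scaling helper (2 < K < 4)."""
    if not 2.0 < k < 4.0:
        raise ValueError("K must lie in (2, 4)")
    if f_m <= 0 or n_i <= 0:
        raise ValueError("f_m and n_i must be > 0")
    return k * g_init * t_p / (f_m * n_i)


def tonic_current(
    g_tonic: float,
    v_gaba: float,
    v_m: float,
    cell_class: str = "pyramidal",
    interneuron_scale: float = 2.0,
) -> float:
    """Non-specific tonic current I = G_eff (V_GABA - V_m), muA/cm^2.

    The effective conductance is doubled for interneurons (their tonic
    range is twice that of pyramidal cells).
    """
    scale = interneuron_scale if cell_class == "interneuron" else 1.0
    return scale * g_tonic * (v_gaba - v_m)


@dataclass(frozen=True)
class GatIonSet:
    """Ionic concentrations setting the GABA-transporter reversal potential.

    Sodium and chloride in mM, GABA in uM (only ratios enter), temperature
    in K. Defaults: physiological-range slice values at 33 C.
    """

    na_out: float = 145.0
    na_in: float = 10.0
    gaba_out: float = 0.3
    gaba_in: float = 2000.0
    cl_out: float = 115.0
    cl_in: float = 8.0
    temperature: float = 306.0

    def __post_init__(self) -> None:
        for name in ("na_out", "na_in", "gaba_out", "gaba_in", "cl_out", "cl_in"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if self.temperature <= 0:
            raise ValueError("temperature must be > 0 (kelvin)")


def gat_reversal(ions: GatIonSet) -> float:
    """GABA transport reversal potential V_GAT (mV).

    V_GAT = (RT/F) [2 ln([Na]o/[Na]i) + ln([GABA]o/[GABA]i) - ln([Cl]o/[Cl]i)]
    (GAT-1 stoichiometry: 2 Na+, 1 Cl-, 1 GABA per cycle).
    """
    rt_f = _R_OVER_F_MV * ions.temperature
    return rt_f * (
        2.0 * math.log(ions.na_out / ions.na_in)
        + math.log(ions.gaba_out / ions.gaba_in)
        - math.log(ions.cl_out / ions.cl_in)
    )


def gaba_concentration_trace(
    spike_times: np.ndarray,
    duration: float,
    step: float = 1.0,
    release_per_ap: float = 0.5,
    decay_rate: float = 0.004,
    basal: float = 0.3,
) -> tuple[np.ndarray, np.ndarray]:
    """Explicit [GABA]_e time course from pooled spike times (ms).

    Each action potential adds ``release_per_ap`` uM (0.5 uM/ms over the
    ~1 ms spike, into a ~20-um-radius volume around the releasing cell);
    uptake and diffusion relax the concentration to ``basal`` with rate
    constant ``decay_rate`` (ms^-1). Linear, so a burst is the superposition
    of single-AP responses. Returns (t, concentration) sampled every
    ``step`` ms.
    """
    if release_per_ap < 0 or decay_rate < 0:
        raise ValueError("rates must be >= 0")
    n = int(round(duration / step)) + 1
    t = np.arange(n) * step
    counts = np.zeros(n)
    spikes = np.asarray(spike_times, dtype=float)
    if spikes.size:
        idx = np.clip(np.round(spikes / step).astype(int), 0, n - 1)
        np.add.at(counts, idx, 1.0)
    conc = np.empty(n)
    conc[0] = basal + release_per_ap * counts[0]
    decay = math.exp(-decay_rate * step)
    for k in range(1, n):
        conc[k] = basal + (conc[k - 1] - basal) * decay + release_per_ap * counts[k]
    return t, conc
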