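"""Single-compartment Hodgkin-Huxley cell models.

Two cell classes are supported, both as pure parameterizations of the same
compartment scheme: fast-spiking (FS) basket-type interneurons with
Wang-Buzsaki channel kinetics (instantaneous Na activation m_inf(V),
phi-scaled h/n kinetics), and pyramidal cells, which reuse the scheme with a
distinct parameter set (slower gating, phi = 1).

Membrane equation (mu A/cm^2, mV, ms)::

    C dV/dt = -g_L (V - E_L) - g_Na m_inf(V)^3 h (V - E_Na)
              - g_K n^4 (V - E_K) + I_app + I_syn + I_tonic

Rate functions (Wang & Buzsaki FS interneuron lineage)::

    alpha_m = -0.1 (V + 35) / (exp(-0.1 (V + 35)) - 1)
    beta_m  = 4 exp(-(V + 60) / 18)
    alpha_h = 0.07 exp(-(V + 58) / 20)
    beta_h  = 1 / (exp(-0.1 (V + 28)) + 1)
    alpha_n = -0.01 (V + 34) / (exp(-0.1 (V + 34)) - 1)
    beta_n  = 0.125 exp(-(V + 44) / 80)

with dh/dt = phi (alpha_h (1-h) - beta_h h), likewise for n, and
m = m_inf = alpha_m / (alpha_m + beta_m) taken as instantaneous.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
import math

import numpy as np

__all__ = [
    "CellParams",
    "CellState",
    "INTERNEURON",
    "PYRAMIDAL",
    "cell_derivatives",
    "integrate_cell",
    "rate_functions",
    "steady_state_gating",
    "InvalidStateError",
    "IntegrationFailure",
]


class InvalidStateError(ValueError):
    """Raised when a cell state contains non-finite or out-of-range values."""


class IntegrationFailure(RuntimeError):
    """Raised when the membrane potential blows up during integration."""


@dataclass(frozen=True)
class CellParams:
    """Biophysical parameters of a single-compartment cell.

    Units: capacitance muF/cm^2, conductances mS/cm^2, reversals mV,
    applied current muA/cm^2. ``temperature_factor`` (phi) scales the h/n
    gating kinetics. ``kinetics_shift`` (mV) translates all channel rate
    functions along the voltage axis (negative = lower spike threshold);
    it parameterizes the "minor modifications" of the base fast-spiking
    cell that the source network model leaves unprinted.
    """

    membrane_capacitance: float = 1.0
    leak_conductance: float = 0.1
    leak_reversal: float = -65.0
    na_max_conductance: float = 35.0
    na_reversal: float = 55.0
    k_max_conductance: float = 9.0
    k_reversal: float = -90.0
    temperature_factor: float = 5.0
    applied_current: float = 0.0
    kinetics_shift: float = 0.0
    cell_class: str = "interneuron"

    def __post_init__(self) -> None:
        if self.membrane_capacitance <= 0:
            raise ValueError("membrane_capacitance must be > 0")
        for name in ("leak_conductance", "na_max_conductance", "k_max_conductance"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        for name in ("leak_reversal", "na_reversal", "k_reversal"):
            if not math.isfinite(getattr(self, name)):
                raise ValueError(f"{name} must be finite")
        if self.cell_class not in ("interneuron", "pyramidal"):
            raise ValueError("cell_class must be 'interneuron' or 'pyramidal'")

    def with_current(self, i_app: float) -> "CellParams":
        return replace(self, applied_current=i_app)


#: Default FS interneuron parameter set (Wang-Buzsaki kinetics, phi = 5,
#: rate functions shifted -3 mV: the unprinted "minor modification" that
#: places the spike threshold just below the GABA_A reversal potential, so
#: rising tonic conductance first drives and then blocks firing).
INTERNEURON = CellParams(kinetics_shift=-3.0)

#: Pyramidal-cell parameter set: same compartment scheme, slower gating
#: (phi = 1), lower leak, and a -2.9 mV kinetics shift that puts the spike
#: threshold a couple of noise standard deviations above the tonic-clamped
#: equilibrium potential, so pyramidal firing is phasic and gated by the
#: tonic-conductance wave. An interpretation: the source model prints no
#: pyramidal channel values.
PYRAMIDAL = CellParams(
    leak_conductance=0.05,
    leak_reversal=-67.0,
    temperature_factor=1.0,
    kinetics_shift=-2.9,
    cell_class="pyramidal",
)


@dataclass
class CellState:
    """Dynamic state: membrane potential (mV) and gating variables h, n."""

    v: float = -65.0
    gating_h: float = 0.78
    gating_n: float = 0.09

    def validate(self) -> None:
        if not (
            math.isfinite(self.v)
            and 0.0 <= self.gating_h <= 1.0
            and 0.0 <= self.gating_n <= 1.0
        ):
            raise InvalidStateError(
                f"invalid cell state: v={self.v}, h={self.gating_h}, n={self.gating_n}"
            )


def _vtrap(x: float, y: float) -> float:
    # x/(exp(x/y)-1) with the removable singularity at x=0 handled.
    if abs(x / y) < 1e-6:
        return y * (1.0 - x / (2.0 * y))
    return x / (math.expm1(x / y))


def rate_functions(v: float) -> dict[str, float]:
    """Voltage-dependent transition rates (ms^-1) at potential ``v`` (mV)."""
    alpha_m = 0.1 * _vtrap(-(v + 35.0), 10.0)
    beta_m = 4.0 * math.exp(-(v + 60.0) / 18.0)
    alpha_h = 0.07 * math.exp(-(v + 58.0) / 20.0)
    beta_h = 1.0 / (math.exp(-0.1 * (v + 28.0)) + 1.0)
    alpha_n = 0.01 * _vtrap(-(v + 34.0), 10.0)
    beta_n = 0.125 * math.exp(-(v + 44.0) / 80.0)
    return {
        "alpha_m": alpha_m,
        "beta_m": beta_m,
        "alpha_h": alpha_h,
        "beta_h": beta_h,
        "alpha_n": alpha_n,
        "beta_n": beta_n,
    }


def steady_state_gating(v: float) -> tuple[float, float, float]:
    """(m_inf, h_inf, n_inf) at clamped potential ``v``."""
    r = rate_functions(v)
    return (
        r["alpha_m"] / (r["alpha_m"] + r["beta_m"]),
        r["alpha_h"] / (r["alpha_h"] + r["beta_h"]),
        r["alpha_n"] / (r["alpha_n"] + r["beta_n"]),
    )


def cell_derivatives(
    state: CellState,
    params: CellParams,
    synaptic_current: float = 0.0,
    tonic_current: float = 0.0,
) -> tuple[float, float, float]:
    """Time derivatives (dV/dt, dh/dt, dn/dt) of a cell state.

    ``synaptic_current`` and ``tonic_current`` are inward-positive membrane
    currents in muA/cm^2, added to the applied current.
    """
    state.validate()
    if not (math.isfinite(synaptic_current) and math.isfinite(tonic_current)):
        raise InvalidStateError("input currents must be finite")
    v, h, n = state.v, state.gating_h, state.gating_n
    r = rate_functions(v - params.kinetics_shift)
    m_inf = r["alpha_m"] / (r["alpha_m"] + r["beta_m"])
    i_na = params.na_max_conductance * m_inf**3 * h * (v - params.na_reversal)
    i_k = params.k_max_conductance * n**4 * (v - params.k_reversal)
    i_leak = params.leak_conductance * (v - params.leak_reversal)
    dv = (
        -i_leak
        - i_na
        - i_k
        + params.applied_current
        + synaptic_current
        + tonic_current
    ) / params.membrane_capacitance
    phi = params.temperature_factor
    dh = phi * (r["alpha_h"] * (1.0 - h) - r["beta_h"] * h)
    dn = phi * (r["alpha_n"] * (1.0 - n) - r["beta_n"] * n)
    return dv, dh, dn


def integrate_cell(
    state: CellState,
    params: CellParams,
    inputs: np.ndarray | float = 0.0,
    dt: float = 0.02,
    duration: float = 0.0,
    spike_threshold: float = 0.0,
    refractory: float = 2.0,
):
    """Fixed-step integration of a single cell.

    Parameters
    ----------
    inputs : array or scalar
        Extra inward current (muA/cm^2), either constant or sampled every
        ``dt`` (length >= number of steps).
    dt, duration : ms
        Step size (default 0.02 ms) and total time.
    spike_threshold, refractory : mV, ms
        Spikes are recorded at upward crossings of ``spike_threshold`` with a
        refractory lockout.

    Returns
    -------
    (t, v, spike_times)
        ``t`` and ``v`` are arrays with ``n_steps + 1`` samples (including the
        initial condition); ``spike_times`` is an array in ms. Deterministic
        given identical inputs.
    """
    if dt <= 0:
        raise ValueError("dt must be > 0")
    if duration < 0:
        raise ValueError("duration must be >= 0")
    n_steps = int(round(duration / dt))
    if n_steps == 0:
        return np.empty(0), np.empty(0), np.empty(0)
    state.validate()
    if np.isscalar(inputs):
        cur = np.full(n_steps, float(inputs))
    else:
        cur = np.asarray(inputs, dtype=float)
        if cur.size < n_steps:
            raise ValueError("inputs shorter than the number of steps")
    v_trace = np.empty(n_steps + 1)
    v_trace[0] = state.v
    spikes: list[float] = []
    v, h, n = state.v, state.gating_h, state.gating_n
    lockout_until = -math.inf
    above = v >= spike_threshold
    def clamp(x):
        return min(1.0, max(0.0, x))

    for k in range(n_steps):
        # classical RK4 (input held constant over the step): spike-time
        # drift over 500 ms is far below the dt-halving tolerance
        i_in = cur[k]
        try:
            k1 = cell_derivatives(CellState(v, h, n), params, synaptic_current=i_in)
            k2 = cell_derivatives(
                CellState(v + 0.5 * dt * k1[0], clamp(h + 0.5 * dt * k1[1]),
                          clamp(n + 0.5 * dt * k1[2])),
                params, synaptic_current=i_in,
            )
            k3 = cell_derivatives(
                CellState(v + 0.5 * dt * k2[0], clamp(h + 0.5 * dt * k2[1]),
                          clamp(n + 0.5 * dt * k2[2])),
                params, synaptic_current=i_in,
            )
            k4 = cell_derivatives(
                CellState(v + dt * k3[0], clamp(h + dt * k3[1]), clamp(n + dt * k3[2])),
                params, synaptic_current=i_in,
            )
            v += dt / 6.0 * (k1[0] + 2 * k2[0] + 2 * k3[0] + k4[0])
            h = clamp(h + dt / 6.0 * (k1[1] + 2 * k2[1] + 2 * k3[1] + k4[1]))
            n = clamp(n + dt / 6.0 * (k1[2] + 2 * k2[2] + 2 * k3[2] + k4[2]))
        except OverflowError as exc:
            raise IntegrationFailure(
                f"membrane potential blew up at step {k + 1}"
            ) from exc
        t_now = (k + 1) * dt
        if abs(v) > 500.0:
            raise IntegrationFailure(
                f"membrane potential blew up (|V| > 500 mV) at step {k + 1}"
            )
        if v >= spike_threshold and not above and t_now >= lockout_until:
            spikes.append(t_now)
            lockout_until = t_now + refractory
        above = v >= spike_threshold
        v_trace[k + 1] = v
    state.v, state.gating_h, state.gating_n = v, h, n
    t = np.arange(n_steps + 1) * dt
    return t, v_trace, np.asarray(spikes)
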