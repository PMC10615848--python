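"""Ground-truth signal generators for every input the analysis stages
consume: field potentials with embedded interictal spikes, two-state
GABA_A-channel patch currents driven by a [GABA] waveform, Hill-sensor
fluorescence traces, calibration curves, and spike-train pairs with
controllable synchrony.

Defaults emulate the published experimental regimes: interictal events are
brief (< 200 ms) biphasic spikes recurring at ~0.14 Hz (acute-slice regime)
or every 2-4 s (organotypic regime); the fluorescence sensor follows the
Hill model E = 0.175, K_d = 1.26 uM, n = 2; each generator returns its
ground truth and is bit-reproducible given its seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
import math

import numpy as np
import pandas as pd

from .ephys import EVENT_COLUMNS, HillFit, Trace, hill_curve
from .observables import SpikeRaster

__all__ = [
    "SENSOR_FIT",
    "GeneratorSpec",
    "iie_waveform",
    "gen_lfp",
    "gen_patch_channel",
    "gen_fluorescence",
    "gen_calibration_curve",
    "gen_spike_pairs",
]

#: Published best-fit sensor model (fluorescence dF/F0 vs [GABA]_e, uM).
SENSOR_FIT = HillFit(e_max=0.175, k_d=1.26, n=2.0)


@dataclass(frozen=True)
class GeneratorSpec:
    """Shared generator settings; per-kind parameters are function kwargs."""

    duration: float = 100.0  # s
    rate: float = 10_000.0  # Hz
    noise_sd: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.duration <= 0:
            raise ValueError("duration must be > 0")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")


def iie_waveform(rate: float, width_s: float = 0.08) -> np.ndarray:
    """Stereotyped biphasic interictal spike (< 200 ms), unit peak amplitude.

    A sharp negative deflection followed by a slower positive rebound,
    built from two gamma-like lobes.
    """
    if width_s >= 0.2:
        raise ValueError("interictal events are < 200 ms wide")
    n = int(width_s * rate)
    t = np.arange(n) / rate
    t1, t2 = width_s / 10.0, width_s / 3.0
    sharp = (t / t1) * np.exp(1.0 - t / t1)
    slow = (t / t2) * np.exp(1.0 - t / t2)
    w = -sharp + 0.6 * slow
    return w / np.abs(w).max()


def gen_lfp(
    spec: GeneratorSpec,
    event_times: np.ndarray | None = None,
    event_rate: float = 0.14,
    amplitude: float = 10.0,
    width_s: float = 0.08,
    periodic: bool = True,
    pink_noise: bool = False,
) -> tuple[Trace, pd.DataFrame]:
    """Synthetic field potential: noise plus stereotyped interictal spikes.

    Events are placed at ``event_times`` (s) if given, else periodically or
    Poisson at ``event_rate`` (Hz; 0.14 Hz is the spontaneous acute-slice
    regime, 0.25-0.5 Hz the organotypic 2-4 s inter-spike interval).
    Returns (trace, truth EventTable); the truth onset is the start of each
    embedded waveform. SNR = amplitude / noise_sd.
    """
    rng = np.random.default_rng(spec.seed)
    n = int(spec.duration * spec.rate)
    if pink_noise:
        white = rng.standard_normal(n)
        f = np.fft.rfftfreq(n, 1.0 / spec.rate)
        shaping = np.where(f > 0, 1.0 / np.sqrt(np.maximum(f, 1e-12)), 0.0)
        x = np.fft.irfft(np.fft.rfft(white) * shaping, n)
        x *= spec.noise_sd / max(x.std(), 1e-30)
    else:
        x = spec.noise_sd * rng.standard_normal(n)
    if event_times is None:
        if event_rate > 0:
            if periodic:
                period = 1.0 / event_rate
                event_times = np.arange(period, spec.duration - width_s, period)
            else:
                n_ev = rng.poisson(event_rate * spec.duration)
                event_times = np.sort(rng.uniform(1.0, spec.duration - width_s, n_ev))
        else:
            event_times = np.empty(0)
    event_times = np.asarray(event_times, dtype=float)
    if event_times.size > 1 and np.any(np.diff(event_times) < width_s):
        import warnings

        warnings.warn("events overlap (spacing < waveform width)", stacklevel=2)
    w = iie_waveform(spec.rate, width_s) * amplitude
    rows = []
    for t_ev in event_times:
        i0 = int(t_ev * spec.rate)
        i1 = min(i0 + w.size, n)
        x[i0:i1] += w[: i1 - i0]
        rows.append(
            {
                "onset": t_ev,
                "peak_time": t_ev + float(np.argmax(np.abs(w))) / spec.rate,
                "amplitude": -amplitude,
                "width": width_s,
                "label": "iie_truth",
            }
        )
    truth = pd.DataFrame(rows, columns=EVENT_COLUMNS)
    return Trace(x, spec.rate, units="mV"), truth


def gen_patch_channel(
    spec: GeneratorSpec,
    gaba_waveform: np.ndarray | float = 0.0,
    unitary_current: float = 3.0,
    basal_rate: float = 1.0,
    max_rate: float = 80.0,
    mean_open_ms: float = 5.0,
    hill: HillFit = SENSOR_FIT,
) -> tuple[Trace, pd.DataFrame]:
    """Two-state (closed/open) channel current driven by a [GABA] waveform.

    The opening rate is basal_rate + max_rate * Hill([GABA]) / E_max (so the
    open probability follows the sigmoid concentration dependence of the
    sniffer patch); closures are exponential with ``mean_open_ms``. The
    trace is the open-state indicator times ``unitary_current`` (pA,
    negative = inward) plus Gaussian recording noise. Returns
    (trace, truth opening table).
    """
    rng = np.random.default_rng(spec.seed)
    n = int(spec.duration * spec.rate)
    conc = np.broadcast_to(np.asarray(gaba_waveform, dtype=float), (n,)) if np.ndim(gaba_waveform) else np.full(n, float(gaba_waveform))
    if np.any(conc < 0):
        raise ValueError("GABA concentrations must be >= 0")
    open_rate = basal_rate + max_rate * hill_curve(conc, 1.0, hill.k_d, hill.n)
    close_rate = 1000.0 / mean_open_ms
    dt = 1.0 / spec.rate
    state = np.zeros(n, dtype=bool)
    is_open = False
    u = rng.random(n)
    for k in range(n):
        r = close_rate if is_open else open_rate[k]
        if u[k] < r * dt:
            is_open = not is_open
        state[k] = is_open
    x = -unitary_current * state + spec.noise_sd * rng.standard_normal(n)
    idx = np.flatnonzero(state)
    rows = []
    if idx.size:
        splits = np.flatnonzero(np.diff(idx) > 1) + 1
        for g in np.split(idx, splits):
            rows.append(
                {
                    "onset": g[0] * dt,
                    "peak_time": g[0] * dt,
                    "amplitude": unitary_current,
                    "width": g.size * dt,
                    "label": "opening_truth",
                }
            )
    return Trace(x, spec.rate, units="pA"), pd.DataFrame(rows, columns=EVENT_COLUMNS)


def gen_fluorescence(
    spec: GeneratorSpec,
    gaba_waveform: np.ndarray | float,
    hill: HillFit = SENSOR_FIT,
) -> tuple[Trace, pd.DataFrame]:
    """Sensor fluorescence dF/F0 = Hill([GABA](t)) + Gaussian noise.

    ``gaba_waveform`` is the [GABA]_e time course in uM sampled at
    ``spec.rate``. Returns (trace, truth peak table) where truth peaks are
    the local maxima of the noiseless response.
    """
    rng = np.random.default_rng(spec.seed)
    n = int(spec.duration * spec.rate)
    conc = np.broadcast_to(np.asarray(gaba_waveform, dtype=float), (n,)).copy() if np.ndim(gaba_waveform) else np.full(n, float(gaba_waveform))
    if np.any(conc < 0):
        raise ValueError("GABA concentrations must be >= 0")
    clean = hill(conc)
    x = clean + spec.noise_sd * rng.standard_normal(n)
    from scipy.signal import find_peaks

    peaks, _ = find_peaks(clean, prominence=0.05 * max(clean.max(), 1e-12))
    rows = [
        {
            "onset": p / spec.rate,
            "peak_time": p / spec.rate,
            "amplitude": clean[p],
            "width": np.nan,
            "label": "dff_truth",
        }
        for p in peaks
    ]
    return Trace(x, spec.rate, units="dF/F0"), pd.DataFrame(rows, columns=EVENT_COLUMNS)


def gen_calibration_curve(
    spec: GeneratorSpec,
    concentrations: np.ndarray | None = None,
    hill: HillFit = SENSOR_FIT,
    noise_frac: float = 0.05,
) -> tuple[np.ndarray, np.ndarray]:
    """Concentration-response samples from the sensor Hill model.

    Responses get multiplicative Gaussian noise of fractional SD
    ``noise_frac`` (5% default). Default concentrations: 8 log-spaced
    points over 0.1-30 uM.
    """
    rng = np.random.default_rng(spec.seed)
    if concentrations is None:
        concentrations = np.logspace(math.log10(0.1), math.log10(30.0), 8)
    concentrations = np.asarray(concentrations, dtype=float)
    clean = hill(concentrations)
    responses = clean * (1.0 + noise_frac * rng.standard_normal(concentrations.size))
    return concentrations, responses


def gen_spike_pairs(
    n_trains: int = 2,
    rate: float = 10.0,
    shared_fraction: float = 0.5,
    jitter_ms: float = 1.0,
    duration_ms: float = 10_000.0,
    seed: int = 0,
) -> SpikeRaster:
    """Spike trains with controllable pairwise synchrony.

    A mother Poisson train of the given rate (Hz) is thinned independently
    into each child: a spike is copied (with Gaussian jitter of SD
    ``jitter_ms``) with probability ``shared_fraction``; independent Poisson
    events at rate (1 - shared_fraction) * rate keep each child's rate at
    ``rate``. shared_fraction 1 with zero jitter gives identical trains
    (k = 1); shared_fraction 0 gives independent trains.
    """
    if not 0.0 <= shared_fraction <= 1.0:
        raise ValueError("shared_fraction must be in [0, 1]")
    rng = np.random.default_rng(seed)
    dur_s = duration_ms * 1e-3
    n_mother = rng.poisson(rate * dur_s)
    mother = np.sort(rng.uniform(0.0, duration_ms, n_mother))
    trains = []
    for _ in range(n_trains):
        keep = rng.random(n_mother) < shared_fraction
        shared = mother[keep]
        if jitter_ms > 0 and shared.size:
            shared = shared + jitter_ms * rng.standard_normal(shared.size)
        n_own = rng.poisson((1.0 - shared_fraction) * rate * dur_s)
        own = rng.uniform(0.0, duration_ms, n_own)
        t = np.clip(np.concatenate([shared, own]), 0.0, duration_ms)
        trains.append(np.sort(t))
    return SpikeRaster(trains, duration_ms)
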