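"""Network observables: spike rasters, pairwise synchrony, population rate,
rhythm detection, simulated field potential, and parameter sweeps.

The synchronization coefficient k(tau) bins each spike train into binary
occupancy at bin width tau (by default tau = 0.1 / f_m, f_m the
network-average rate) and, for each pair,

    k_ij = sum_l X(l) Y(l) / sqrt(sum_l X(l) * sum_l Y(l))

averaged over all pairs. The square-root normalization (coherence measure of
the FS-interneuron model lineage) bounds k in [0, 1] with identical trains
scoring 1; the published formula's plain-product denominator is available
via ``normalization='printed'``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
import math
import warnings

import numpy as np
from scipy import signal

__all__ = [
    "SpikeRaster",
    "HeatmapResult",
    "sync_coefficient",
    "population_rate",
    "rhythm_detect",
    "RhythmResult",
    "simulated_lfp",
    "parameter_sweep",
    "burst_onsets",
    "spike_burst_onsets",
    "spectral_peak_test",
    "cycle_average",
    "phase_of_peak",
    "InsufficientDataError",
]


class InsufficientDataError(ValueError):
    """Raised when a series is too short for the requested analysis."""


@dataclass
class SpikeRaster:
    """Per-cell spike times (ms) for a simulated network."""

    spike_times: list  # list of 1-D float arrays, one per cell
    duration: float
    cell_labels: np.ndarray | None = None  # optional: True for interneurons

    def __post_init__(self) -> None:
        self.spike_times = [np.sort(np.asarray(s, dtype=float)) for s in self.spike_times]
        for s in self.spike_times:
            if s.size and (s[0] < 0 or s[-1] > self.duration):
                raise ValueError("spike times must lie within [0, duration]")

    @property
    def n_cells(self) -> int:
        return len(self.spike_times)

    @property
    def n_spikes(self) -> int:
        return sum(len(s) for s in self.spike_times)

    def mean_rate(self) -> float:
        """Network-average firing rate in Hz."""
        if self.duration == 0:
            return 0.0
        return self.n_spikes / self.n_cells / (self.duration * 1e-3)

    def pooled(self) -> np.ndarray:
        """All spike times pooled and sorted (ms)."""
        if not self.spike_times:
            return np.empty(0)
        return np.sort(np.concatenate(self.spike_times))

    def subset(self, mask: np.ndarray) -> "SpikeRaster":
        trains = [s for s, m in zip(self.spike_times, mask) if m]
        labels = self.cell_labels[mask] if self.cell_labels is not None else None
        return SpikeRaster(trains, self.duration, labels)


def _binarize(train: np.ndarray, tau: float, n_bins: int) -> np.ndarray:
    x = np.zeros(n_bins, dtype=np.float64)
    if train.size:
        idx = np.minimum((train / tau).astype(int), n_bins - 1)
        x[idx] = 1.0
    return x


def sync_coefficient(
    raster: SpikeRaster,
    tau: float | None = None,
    normalization: str = "sqrt",
) -> float:
    """Network synchronization coefficient k(tau) in [0, 1].

    ``tau`` is the bin width in ms; if None, tau = 0.1 / f_m with f_m the
    network-average rate. Pairs involving a silent cell contribute 0.
    """
    if raster.n_cells < 2:
        raise ValueError("sync_coefficient needs >= 2 cells")
    if normalization not in ("sqrt", "printed"):
        raise ValueError("normalization must be 'sqrt' or 'printed'")
    if tau is None:
        f_m = raster.mean_rate()
        if f_m == 0:
            return 0.0
        tau = 0.1 / f_m * 1000.0  # 0.1 / f_m seconds, in ms
    if tau <= 0:
        raise ValueError("tau must be > 0")
    n_bins = max(1, int(math.ceil(raster.duration / tau)))
    binned = [_binarize(s, tau, n_bins) for s in raster.spike_times]
    sums = np.array([b.sum() for b in binned])
    mat = np.vstack(binned)
    prod = mat @ mat.T  # pairwise sum X*Y
    ks = []
    for i, j in combinations(range(raster.n_cells), 2):
        if sums[i] == 0 or sums[j] == 0:
            ks.append(0.0)
        elif normalization == "sqrt":
            ks.append(prod[i, j] / math.sqrt(sums[i] * sums[j]))
        else:
            ks.append(prod[i, j] / (sums[i] * sums[j]))
    return float(np.mean(ks))


def population_rate(
    raster: SpikeRaster, bin_ms: float = 10.0
) -> tuple[np.ndarray, np.ndarray]:
    """Population rate (Hz per cell) in bins of ``bin_ms``.

    Returns (bin_centers_ms, rate_hz); rate = spikes / (N * bin).
    """
    if bin_ms <= 0:
        raise ValueError("bin must be > 0")
    n_bins = max(1, int(math.ceil(raster.duration / bin_ms)))
    edges = np.arange(n_bins + 1) * bin_ms
    pooled = raster.pooled()
    counts, _ = np.histogram(pooled, bins=edges)
    rate = counts / raster.n_cells / (bin_ms * 1e-3)
    centers = edges[:-1] + bin_ms / 2.0
    return centers, rate


@dataclass
class RhythmResult:
    has_rhythm: bool
    dominant_freq: float | None
    peak_power: float
    threshold: float


def spectral_peak_test(
    x: np.ndarray,
    fs: float,
    band: tuple[float, float] = (0.01, 2.0),
    alpha: float = 0.05,
    method: str = "chi2",
    n_surrogates: int = 200,
    rng: np.random.Generator | None = None,
    reference_variance: float | None = None,
    min_power_fraction: float = 1e-4,
    psd_gain: "callable | None" = None,
) -> RhythmResult:
    """Test for a significant spectral peak of ``x`` within ``band`` (Hz).

    The periodogram is compared against the 95% confidence bound of its
    noise floor. ``method='chi2'``: each periodogram ordinate of a noise
    series is floor * chi2_2 / 2 (exponential); the floor is estimated by
    median-smoothing the log spectrum, and the bound is Sidak-corrected for
    the number of in-band frequencies, keeping the family-wise false-alarm
    rate near ``alpha``. ``method='surrogate'``: the bound is the
    (1 - alpha) quantile of in-band maxima over phase-shuffled surrogates.

    ``reference_variance`` (if given, e.g. the variance of the unfiltered
    trace) guards against degenerate noise-free inputs: a peak must also
    carry at least ``min_power_fraction`` of it, so numerical leakage of a
    strong out-of-band component cannot be declared a slow wave.
    ``psd_gain(freqs)`` is the known power gain applied to the series by
    prior filtering (e.g. |H|^4 of a forward-backward filter); the spectrum
    is divided by it so the noise floor is flat again before testing.
    """
    x = np.asarray(x, dtype=float)
    duration_s = x.size / fs
    f_hi = min(band[1], fs / 2.0)
    if duration_s < 2.0 / f_hi:
        raise InsufficientDataError(
            f"series of {duration_s:.2f} s holds < 2 cycles at {f_hi} Hz"
        )
    f_lo = band[0]
    if duration_s < 2.0 / max(f_lo, 1e-12):
        f_lo = 2.0 / duration_s
        warnings.warn(
            f"series too short for {band[0]} Hz; using {f_lo:.3g} Hz as the "
            "lower band edge",
            stacklevel=2,
        )
    x = x - x.mean()
    freqs, pxx = signal.periodogram(x, fs=fs, detrend="linear")
    if psd_gain is not None:
        gain = np.maximum(np.asarray(psd_gain(freqs), dtype=float), 1e-12)
        pxx = pxx / gain
    in_band = (freqs >= f_lo) & (freqs <= f_hi) & (freqs > 0)
    if not np.any(in_band):
        return RhythmResult(False, None, 0.0, np.inf)
    n_band = int(in_band.sum())
    if method == "chi2":
        # noise floor: in-band median (robust to a narrow peak); for white
        # noise each periodogram ordinate is floor * chi2_2 / 2, whose
        # median is floor * ln 2
        floor = float(np.median(pxx[in_band])) / math.log(2.0)
        if floor <= 0:
            return RhythmResult(False, None, 0.0, np.inf)
        # Sidak per-bin level for family-wise alpha over the band; the
        # floor's own sampling error (median of ~n_band exponentials)
        # inflates the false-alarm rate, so widen by its 2-SE bound
        alpha_bin = 1.0 - (1.0 - alpha) ** (1.0 / n_band)
        threshold = floor * (1.0 + 2.0 / math.sqrt(n_band)) * -math.log(alpha_bin)
        i_best = int(np.argmax(pxx[in_band]))
        peak = float(pxx[in_band][i_best])
        has = bool(peak > threshold)
        if has and reference_variance is not None:
            df = freqs[1] - freqs[0]
            if peak * df < min_power_fraction * reference_variance:
                has = False
        fsel = freqs[in_band]
        return RhythmResult(
            has, float(fsel[i_best]) if has else None, peak, threshold
        )
    elif method == "surrogate":
        rng = np.random.default_rng(0) if rng is None else rng
        maxima = np.empty(n_surrogates)
        for k in range(n_surrogates):
            xs = rng.permutation(x)
            _, ps = signal.periodogram(xs, fs=fs, detrend="linear")
            maxima[k] = ps[in_band].max()
        threshold = float(np.quantile(maxima, 1.0 - alpha))
        i_best = int(np.argmax(pxx[in_band]))
        peak = float(pxx[in_band][i_best])
        has = peak > threshold
        fsel = freqs[in_band]
        return RhythmResult(has, float(fsel[i_best]) if has else None, peak, threshold)
    raise ValueError("method must be 'chi2' or 'surrogate'")


def rhythm_detect(
    rate: np.ndarray,
    fs: float,
    band: tuple[float, float] = (0.01, 2.0),
    alpha: float = 0.05,
    method: str = "chi2",
    **kwargs,
) -> RhythmResult:
    """Detect a sub-2-Hz rhythm in a population-rate series sampled at fs (Hz).

    Extra keyword arguments (e.g. ``reference_variance`` /
    ``min_power_fraction`` for a modulation-depth requirement) pass through
    to :func:`spectral_peak_test`.
    """
    return spectral_peak_test(rate, fs, band=band, alpha=alpha, method=method, **kwargs)


def simulated_lfp(
    currents: np.ndarray,
    distance: float = 250.0,
    tissue_conductance: float = 100.0,
) -> np.ndarray:
    """Point-source volume-conductor field potential.

    V(t) = sum_k I_k(t) / (4 pi sigma r), with every source at the stated
    distance. ``currents``: (n_samples, n_cells) membrane currents in
    muA/cm^2 (treated as point currents of muA per unit cell area);
    ``distance`` in um, ``tissue_conductance`` sigma in mS/cm. Output in mV
    per unit cell area (1 muA source at 250 um and sigma = 100 mS/cm gives
    1 / (4 pi * 100 mS/cm * 0.025 cm) ~ 0.032 mV).
    """
    if tissue_conductance <= 0:
        raise ValueError("tissue conductance must be > 0")
    if distance <= 0:
        raise ValueError("distance must be > 0")
    currents = np.atleast_2d(np.asarray(currents, dtype=float))
    r_cm = distance * 1e-4
    return currents.sum(axis=1) / (4.0 * math.pi * tissue_conductance * r_cm)


@dataclass
class HeatmapResult:
    """Grid of rhythm metrics from a two-parameter sweep."""

    axis1_name: str
    axis1_values: np.ndarray
    axis2_name: str
    axis2_values: np.ndarray
    has_rhythm: np.ndarray  # (n1, n2) fraction of seeds with a rhythm
    dominant_freq: np.ndarray  # (n1, n2) mean dominant frequency (NaN if none)
    seeds: tuple

    def to_frame(self):
        import pandas as pd

        rows = []
        for i, a in enumerate(self.axis1_values):
            for j, b in enumerate(self.axis2_values):
                rows.append(
                    {
                        self.axis1_name: a,
                        self.axis2_name: b,
                        "has_rhythm": self.has_rhythm[i, j],
                        "dominant_freq": self.dominant_freq[i, j],
                    }
                )
        return pd.DataFrame(rows)


def parameter_sweep(
    run_fn,
    axis1: tuple[str, np.ndarray],
    axis2: tuple[str, np.ndarray],
    seeds: tuple = (1,),
    rate_bin_ms: float = 50.0,
) -> HeatmapResult:
    """Two-parameter rhythm sweep.

    ``run_fn(overrides: dict, seed: int) -> SimulationResult`` runs one
    simulation; each grid cell applies {axis1_name: value1, axis2_name:
    value2} and runs ``rhythm_detect`` on the population rate. Cells are
    independent (embarrassingly parallel); execution order does not matter.
    """
    name1, vals1 = axis1
    name2, vals2 = axis2
    vals1 = np.asarray(vals1, dtype=float)
    vals2 = np.asarray(vals2, dtype=float)
    if vals1.size == 0 or vals2.size == 0:
        raise ValueError("axis grids must be non-empty")
    has = np.zeros((vals1.size, vals2.size))
    freq = np.full((vals1.size, vals2.size), np.nan)
    for i, a in enumerate(vals1):
        for j, b in enumerate(vals2):
            flags, fqs = [], []
            for seed in seeds:
                result = run_fn({name1: float(a), name2: float(b)}, int(seed))
                t, rate = population_rate(result.raster, rate_bin_ms)
                rr = rhythm_detect(rate, fs=1000.0 / rate_bin_ms)
                flags.append(rr.has_rhythm)
                if rr.has_rhythm:
                    fqs.append(rr.dominant_freq)
            has[i, j] = float(np.mean(flags))
            if fqs:
                freq[i, j] = float(np.mean(fqs))
    return HeatmapResult(name1, vals1, name2, vals2, has, freq, tuple(seeds))


def burst_onsets(
    t: np.ndarray,
    rate: np.ndarray,
    threshold_frac: float = 0.25,
    min_separation_ms: float = 300.0,
    smooth_bins: int = 5,
) -> np.ndarray:
    """Burst onset times (ms) from a population-rate series.

    The rate is boxcar-smoothed, thresholded at ``threshold_frac`` of its
    maximum (at least mean + 2 SD), and onsets are upward crossings separated
    by at least ``min_separation_ms``.
    """
    rate = np.asarray(rate, dtype=float)
    if smooth_bins > 1:
        kernel = np.ones(smooth_bins) / smooth_bins
        rate = np.convolve(rate, kernel, mode="same")
    thr = max(threshold_frac * rate.max(), rate.mean() + 2.0 * rate.std())
    above = rate >= thr
    crossings = np.flatnonzero(~above[:-1] & above[1:]) + 1
    onsets = []
    last = -math.inf
    for c in crossings:
        if t[c] - last >= min_separation_ms:
            onsets.append(t[c])
            last = t[c]
    return np.asarray(onsets)


def spike_burst_onsets(
    raster: SpikeRaster,
    max_gap_ms: float = 200.0,
    min_spikes: int = 10,
) -> np.ndarray:
    """Burst onset times (ms) by gap-clustering the pooled spike train.

    Pooled spikes separated by more than ``max_gap_ms`` start a new group;
    groups with at least ``min_spikes`` spikes count as population bursts.
    Robust for sparse, strongly phasic firing where a binned-rate threshold
    is unreliable.
    """
    pooled = raster.pooled()
    if pooled.size == 0:
        return np.empty(0)
    splits = np.flatnonzero(np.diff(pooled) > max_gap_ms) + 1
    onsets = [
        grp[0] for grp in np.split(pooled, splits) if grp.size >= min_spikes
    ]
    return np.asarray(onsets)


def cycle_average(
    t: np.ndarray, x: np.ndarray, freq_hz: float, n_bins: int = 36
) -> tuple[np.ndarray, np.ndarray]:
    """Average ``x`` by phase of a ``freq_hz`` cycle (t in ms, phase of
    sin(2 pi f t): 0 at the ascending zero, pi/2 at the crest).

    Returns (phase_bin_centers_rad, mean_x_per_bin).
    """
    phase = (2.0 * math.pi * freq_hz * (np.asarray(t) * 1e-3)) % (2.0 * math.pi)
    edges = np.linspace(0.0, 2.0 * math.pi, n_bins + 1)
    idx = np.clip(np.digitize(phase, edges) - 1, 0, n_bins - 1)
    means = np.full(n_bins, np.nan)
    for b in range(n_bins):
        sel = idx == b
        if np.any(sel):
            means[b] = float(np.mean(np.asarray(x)[sel]))
    centers = (edges[:-1] + edges[1:]) / 2.0
    return centers, means


def phase_of_peak(phase_centers: np.ndarray, means: np.ndarray) -> float:
    """Circular-mean phase (rad) of the peak of a cycle-averaged profile.

    Uses the profile (minus its minimum) as a circular weight so broad peaks
    are located robustly.
    """
    w = np.nan_to_num(means - np.nanmin(means))
    if w.sum() == 0:
        return float(phase_centers[int(np.nanargmax(means))])
    z = np.sum(w * np.exp(1j * phase_centers))
    return float(np.angle(z) % (2.0 * math.pi))
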