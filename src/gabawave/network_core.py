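"""Ring-network construction: Gaussian connectivity, biexponential synapses,
stochastic release and Poisson external drive.

Cells are spaced uniformly on a circle (no edge effects, every cell
equivalent); connection strength between two cells falls off as a Gaussian
of their circular arc distance, scaled by a per-class maximum W_max, and the
effective synaptic peak conductance is the class peak conductance times
W(i,j)/W_max. Conduction delays are arc distance over a finite propagation
speed.

Connection classes are named by (presynaptic, postsynaptic) population:
II (interneuron->interneuron, GABAergic), EE (pyramidal->pyramidal,
glutamatergic), EI (pyramidal->interneuron), IE (interneuron->pyramidal).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
import math

import numpy as np

__all__ = [
    "NetworkConfig",
    "ConnectivityMatrix",
    "SynapseParams",
    "build_connectivity",
    "ring_positions",
    "circular_distance",
    "biexp_conductance",
    "biexp_peak_time",
    "poisson_drive",
    "stochastic_release",
]

CLASS_CODES = {"none": 0, "II": 1, "EE": 2, "EI": 3, "IE": 4}


@dataclass(frozen=True)
class SynapseParams:
    """Biexponential synapse: g(t) = A (exp(-t/tau_decay) - exp(-t/tau_rise)),
    normalized so the maximum equals ``peak_conductance``.

    tau_rise is never printed in the source model (only the 3-ms decay);
    0.5 ms is the package default.
    """

    tau_rise: float = 0.5
    tau_decay: float = 3.0
    peak_conductance: float = 0.1
    reversal: float = -65.0
    release_probability: float = 1.0

    def __post_init__(self) -> None:
        if self.tau_rise <= 0 or self.tau_decay <= 0:
            raise ValueError("time constants must be > 0")
        if self.tau_rise >= self.tau_decay:
            raise ValueError(
                "tau_rise must be < tau_decay (degenerate alpha function not supported)"
            )
        if self.peak_conductance < 0:
            raise ValueError("peak_conductance must be >= 0")
        if not 0.0 <= self.release_probability <= 1.0:
            raise ValueError("release_probability must be in [0, 1]")


@dataclass(frozen=True)
class NetworkConfig:
    """Full parameterization of the two-population ring network.

    Peak conductances G_xy in mS/cm^2; W_max are the dimensionless strength
    coefficients (W_ee=2, W_ii=0.8, W_ei=0.9, W_ie=0.3); spatial sigmas in um
    (sigma_ee=10, sigma_ei=12.5, sigma_ie=8, sigma_ii=5); release
    probabilities P_EE = P_EI = 0.5, P_II = 1.0 (P_IE unprinted, default 1).

    ``sigma_units`` selects whether sigmas are read in cell-index units
    (default) or in um of circular arc distance. The published connectivity
    expression is written in cell indices and evaluates, for neighbors on a
    100-cell ring, to a Gaussian of index distance with width ~sigma cells;
    the um reading (sigma ~5-12 um against a ~16 um inter-cell spacing)
    makes the coupling nearly diagonal and functionally negligible. Both
    are supported; see docs/methods.md.
    """

    n_interneurons: int = 100
    n_pyramidal: int = 0
    radius_i: float = 250.0
    radius_e: float = 200.0
    g_ii: float = 0.1
    g_ee: float = 0.0
    g_ei: float = 0.0
    g_ie: float = 0.0
    w_max: dict = field(
        default_factory=lambda: {"EE": 2.0, "II": 0.8, "EI": 0.9, "IE": 0.3}
    )
    sigma: dict = field(
        default_factory=lambda: {"EE": 10.0, "EI": 12.5, "IE": 8.0, "II": 5.0}
    )
    release_p: dict = field(
        default_factory=lambda: {"EE": 0.5, "EI": 0.5, "II": 1.0, "IE": 1.0}
    )
    propagation_speed: float = 100.0
    max_delay: float = 10.0
    sigma_units: str = "cells"
    connection_mode: str = "dense"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_interneurons < 0 or self.n_pyramidal < 0:
            raise ValueError("cell counts must be >= 0")
        if self.n_interneurons + self.n_pyramidal < 1:
            raise ValueError("network must contain at least one cell")
        if any(s <= 0 for s in self.sigma.values()):
            raise ValueError("spatial sigmas must be > 0")
        if any(not 0.0 <= p <= 1.0 for p in self.release_p.values()):
            raise ValueError("release probabilities must be in [0, 1]")
        if self.propagation_speed <= 0:
            raise ValueError("propagation_speed must be > 0")
        if self.sigma_units not in ("um", "cells"):
            raise ValueError("sigma_units must be 'um' or 'cells'")
        if self.connection_mode not in ("dense", "sampled"):
            raise ValueError("connection_mode must be 'dense' or 'sampled'")

    @property
    def n_cells(self) -> int:
        return self.n_interneurons + self.n_pyramidal

    def with_(self, **kw) -> "NetworkConfig":
        return replace(self, **kw)


@dataclass
class ConnectivityMatrix:
    """Dense (post, pre) weight/delay/class matrices.

    ``weight`` is the dimensionless Gaussian scaling in [0, 1] (relative to
    the class maximum; multiply by the class peak conductance for the
    effective synaptic peak); ``delay`` in ms; ``conn_class`` holds
    CLASS_CODES. No self-connections.
    """

    weight: np.ndarray
    delay: np.ndarray
    conn_class: np.ndarray
    release_p: np.ndarray
    is_interneuron: np.ndarray

    @property
    def n_cells(self) -> int:
        return self.weight.shape[0]

    def to_edge_list(self):
        """Edge list as a pandas DataFrame (source, target, class, weight, delay_ms)."""
        import pandas as pd

        post, pre = np.nonzero(self.weight > 0)
        code_names = {v: k for k, v in CLASS_CODES.items()}
        return pd.DataFrame(
            {
                "source": pre,
                "target": post,
                "conn_class": [code_names[c] for c in self.conn_class[post, pre]],
                "weight": self.weight[post, pre],
                "delay_ms": self.delay[post, pre],
            }
        )


def ring_positions(n: int, radius: float) -> np.ndarray:
    """Arc-length positions (um) of n cells uniformly spaced on a ring."""
    circumference = 2.0 * math.pi * radius
    return np.arange(n) * circumference / n


def circular_distance(pos_a: np.ndarray, pos_b: np.ndarray, radius: float) -> np.ndarray:
    """Pairwise circular arc distance (um) on a ring of the given radius."""
    circumference = 2.0 * math.pi * radius
    d = np.abs(pos_a[:, None] - pos_b[None, :])
    return np.minimum(d, circumference - d)


def _class_of(pre_inh: np.ndarray, post_inh: np.ndarray) -> np.ndarray:
    """Class code matrix (post, pre) from interneuron flags."""
    pre = pre_inh[None, :]
    post = post_inh[:, None]
    out = np.where(
        pre & post,
        CLASS_CODES["II"],
        np.where(
            ~pre & ~post,
            CLASS_CODES["EE"],
            np.where(~pre & post, CLASS_CODES["EI"], CLASS_CODES["IE"]),
        ),
    )
    return out.astype(np.int8)


def build_connectivity(
    config: NetworkConfig, rng: np.random.Generator | None = None
) -> ConnectivityMatrix:
    """Construct the (post, pre) connectivity of the ring network.

    Interneurons occupy indices [0, N_i) on a ring of radius ``radius_i``;
    pyramidal cells occupy [N_i, N_i + N_e) on a concentric ring of radius
    ``radius_e`` (distances between populations use the interneuron-ring
    arc coordinate). Weight(i,j) = exp(-d_ij^2 / (2 sigma_class^2)), zero on
    the diagonal; in "sampled" mode each connection additionally exists with
    probability equal to the Gaussian density factor, weight W_max-relative
    1 when present. Delay = d_ij / speed, capped at ``max_delay``.
    """
    rng = np.random.default_rng(config.seed) if rng is None else rng
    n_i, n_e = config.n_interneurons, config.n_pyramidal
    n = n_i + n_e
    is_inh = np.zeros(n, dtype=bool)
    is_inh[:n_i] = True

    # Angular coordinate shared by the two concentric rings.
    theta = np.concatenate(
        [
            np.arange(n_i) * (2.0 * math.pi / max(n_i, 1)),
            np.arange(n_e) * (2.0 * math.pi / max(n_e, 1)),
        ]
    )
    radius_of = np.where(is_inh, config.radius_i, config.radius_e)
    dtheta = np.abs(theta[:, None] - theta[None, :])
    dtheta = np.minimum(dtheta, 2.0 * math.pi - dtheta)
    # Arc distance evaluated on the larger of the two cells' rings.
    pair_radius = np.maximum(radius_of[:, None], radius_of[None, :])
    dist_um = dtheta * pair_radius

    conn_class = _class_of(is_inh, is_inh)
    code_names = {v: k for k, v in CLASS_CODES.items()}
    sigma_mat = np.empty((n, n))
    relp_mat = np.empty((n, n))
    for code in np.unique(conn_class):
        name = code_names[int(code)]
        sigma_mat[conn_class == code] = config.sigma[name]
        relp_mat[conn_class == code] = config.release_p[name]

    if config.sigma_units == "um":
        dist_eff = dist_um
    else:  # sigma in cell-index units: distance in index steps around the ring
        idx = np.concatenate([np.arange(n_i), np.arange(n_e)]).astype(float)
        n_pop = np.where(is_inh, max(n_i, 1), max(n_e, 1)).astype(float)
        didx = np.abs(idx[:, None] - idx[None, :])
        didx = np.minimum(didx, np.maximum(n_pop[:, None], n_pop[None, :]) - didx)
        dist_eff = didx

    weight = np.exp(-0.5 * (dist_eff / sigma_mat) ** 2)
    if config.connection_mode == "sampled":
        exists = rng.random((n, n)) < weight
        weight = exists.astype(float)
    np.fill_diagonal(weight, 0.0)

    # Zero out classes whose peak conductance is zero (no such projection).
    g_of = {"II": config.g_ii, "EE": config.g_ee, "EI": config.g_ei, "IE": config.g_ie}
    for code in np.unique(conn_class):
        name = code_names[int(code)]
        if g_of[name] == 0.0:
            weight[conn_class == code] = 0.0

    delay = np.minimum(dist_um / config.propagation_speed, config.max_delay)
    np.fill_diagonal(delay, 0.0)
    conn_class = np.where(weight > 0, conn_class, CLASS_CODES["none"]).astype(np.int8)
    return ConnectivityMatrix(
        weight=weight,
        delay=delay,
        conn_class=conn_class,
        release_p=relp_mat,
        is_interneuron=is_inh,
    )


def biexp_peak_time(tau_rise: float, tau_decay: float) -> float:
    """Time of the biexponential maximum: (tr td / (td - tr)) ln(td / tr)."""
    return tau_rise * tau_decay / (tau_decay - tau_rise) * math.log(tau_decay / tau_rise)


def biexp_norm(tau_rise: float, tau_decay: float) -> float:
    """Amplitude A such that max_t A (e^(-t/td) - e^(-t/tr)) = 1."""
    t_star = biexp_peak_time(tau_rise, tau_decay)
    return 1.0 / (math.exp(-t_star / tau_decay) - math.exp(-t_star / tau_rise))


def biexp_conductance(t_since_event, params: SynapseParams):
    """Synaptic conductance (mS/cm^2) at time t (ms) after a release event.

    Zero at t = 0, peaks at ``biexp_peak_time`` with value
    ``peak_conductance``, decays to zero.
    """
    t = np.asarray(t_since_event, dtype=float)
    if np.any(t < 0):
        raise ValueError("t_since_event must be >= 0")
    a = params.peak_conductance * biexp_norm(params.tau_rise, params.tau_decay)
    out = a * (np.exp(-t / params.tau_decay) - np.exp(-t / params.tau_rise))
    return float(out) if out.ndim == 0 else out


def poisson_drive(
    rate: float,
    unit_conductance: float,
    tau_decay: float,
    duration: float,
    rng: np.random.Generator,
    dt: float = 0.02,
) -> tuple[np.ndarray, np.ndarray]:
    """Homogeneous Poisson conductance drive for one cell.

    Each event adds an instantaneous-rise, single-exponential transient of
    amplitude ``unit_conductance`` and decay ``tau_decay`` (ms). Returns
    (event_times_ms, conductance_trace) with the trace sampled every ``dt``;
    time-average conductance ~= rate * unit_conductance * tau (Campbell).
    """
    if rate < 0:
        raise ValueError("rate must be >= 0")
    if duration <= 0:
        raise ValueError("duration must be > 0")
    n_steps = int(round(duration / dt))
    n_events = rng.poisson(rate * duration * 1e-3)
    events = np.sort(rng.uniform(0.0, duration, size=n_events))
    g = np.zeros(n_steps)
    if n_events:
        decay = math.exp(-dt / tau_decay)
        idx = np.minimum((events / dt).astype(int), n_steps - 1)
        incr = np.zeros(n_steps)
        np.add.at(incr, idx, unit_conductance)
        acc = 0.0
        for k in range(n_steps):
            acc = acc * decay + incr[k]
            g[k] = acc
    return events, g


def stochastic_release(
    p: float, rng: np.random.Generator, n: int = 1
) -> bool | np.ndarray:
    """Bernoulli(p) release decision per presynaptic spike."""
    if not 0.0 <= p <= 1.0:
        raise ValueError("p must be in [0, 1]")
    out = rng.random(n) < p
    return bool(out[0]) if n == 1 else out
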