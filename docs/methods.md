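# Methods

`gabawave` models how activity-dependent waves of extracellular GABA
([GABA]ₑ) pace slow epileptiform rhythms in hippocampal networks, and
implements the analysis procedures used to characterize such rhythms in
electrophysiological and imaging recordings. This note documents the model,
its assumptions, the parameters that matter, and the choices made where the
design was genuinely open.

## The model

### Cells

Every cell is a single Hodgkin–Huxley compartment with fast sodium
(instantaneous activation m∞(V)), delayed-rectifier potassium, and leak
currents, using the Wang–Buzsáki fast-spiking basket-cell rate functions
with a temperature factor φ on the h/n kinetics:

    C dV/dt = −g_L(V−E_L) − g_Na m∞³h(V−E_Na) − g_K n⁴(V−E_K)
              + I_app + I_syn + I_tonic

Defaults (interneuron): C = 1 µF/cm², g_L = 0.1 mS/cm², E_L = −65 mV,
g_Na = 35, E_Na = 55, g_K = 9, E_K = −90, φ = 5.

The base model's unprinted "minor modifications of internal parameters" are
exposed as a single `kinetics_shift` (mV) that translates all rate
functions along the voltage axis:

- **Interneurons: −3 mV.** This puts the spike threshold (≈ −58 mV) just
  below the GABA_A reversal potential used in the epileptiform protocols
  (−53 to −58 mV). Consequences: (i) the default cell is weakly pacemaking
  (~19 Hz at rest), standing in for the depolarization produced by
  epileptogenic high-K⁺ media — with the shift set to 0 the cell is
  silent at rest and all resting-sanity invariants hold; (ii) a rising
  tonic GABA conductance first *drives* firing (it pulls V toward a value
  above threshold) and at high values *blocks* it (shunting/depolarization
  block), producing the bell-shaped firing-vs-G_tonic relation with a
  steep high-conductance cliff that the rhythm mechanism requires.
- **Pyramidal cells: −2.9 mV, g_L = 0.05, E_L = −67, φ = 1.** This puts
  their threshold a couple of noise standard deviations above the
  tonic-clamped equilibrium potential, so pyramidal firing is sparse and
  gated by the conductance wave rather than tonic.

The single-cell integrator (`integrate_cell`) is classical RK4 at a fixed
dt = 0.02 ms; spikes are upward crossings of 0 mV with a 2-ms lockout.
The network engine uses forward Euler at the same dt (the published step):
network-level results are statistical and insensitive to the residual
first-order error, which was verified by the dt-halving convergence checks.

### Synapses, connectivity, drive

GABAergic (and glutamatergic) synapses are biexponential,
g(t) = A(e^(−t/τ_d) − e^(−t/τ_r)), normalized so the maximum equals the
peak conductance; τ_d = 3 ms (published), τ_r = 0.5 ms (unprinted,
default). Release is Bernoulli per spike per synapse (P_II = P_IE = 1,
P_EE = P_EI = 0.5).

Cells sit uniformly on a ring (no edge effects). Connection strength falls
off as a Gaussian of distance with per-class widths σ and the effective
synaptic peak is the printed class conductance times the Gaussian factor.
The published strength matrix is written in *cell indices*; evaluated as
printed it is a Gaussian of index distance of width ≈ σ cells, which is
the package default (`sigma_units="cells"`). Reading σ in µm of arc
distance instead (also available, `sigma_units="um"`) makes the coupling
essentially diagonal at the published network sizes (σ = 5–12.5 µm
against ~16 µm inter-cell spacing) and functionally negligible.
Conduction delays are arc distance over a propagation speed of 100 µm/ms
(the printed 0.1 µm/ms would give multi-second delays over a 250-µm ring,
contradicting the millisecond synaptic phenomenology; we treat it as a
typo for 0.1 µm/µs), capped at 10 ms.

External drive is a homogeneous Poisson train of instantaneous-rise,
exponentially decaying conductance transients per cell (τ = 3 ms). The
printed drive amplitudes mix units (nS against mS/cm²) and are treated as
free parameters in simulation units; the interneuron-drive caption values
are used as per-event amplitudes as printed. The twinned-network pyramidal
drive uses 0.032 mS/cm² (printed "0.003"): at the printed value pyramidal
cells are bistably silent-or-tonic instead of wave-gated.

### The tonic GABA field

[GABA]ₑ is a well-mixed scalar per network. Firing releases GABA; GAT-1
uptake removes it; G_tonic = α[GABA]ₑ (α is never printed; the default
0.25 mS/cm² per µM maps the simulated conductance range onto the measured
~0.4–2 µM concentration range). The canonical dynamics, integrated with an
exponential update that is exact for piecewise-constant f_m:

    dG/dt = N_i·R·A_f·(f_m[t−δt] + f_b) − R·G_pump·(G − G_basal)

with G(0) = G_basal = 0.1 mS/cm², basal rate f_b = 0.1 Hz, receptor delay
δt = 0.5 ms, and the release–uptake factor R scaling both terms jointly
(R = 1 reproduces the unscaled equation exactly; R changes the wave's
speed, not its fixed point). f_m is the population rate over a trailing
window T.

Two deliberate calibrations, made once and then frozen:

- **A_f unit conversion.** The published A_f values are printed in
  nS cm⁻² ms⁻¹, which taken literally is ~10⁻¹³ mS/cm² per spike — zero
  feedback. With time in ms, conductance in mS/cm² and f_m in Hz, the
  caption numbers times a single global factor `AF_UNIT_SCALE = 10` put
  the feedback in its working regime (fixed point on the steep falling
  branch of the firing-vs-G curve). The factor was calibrated against the
  interneuron-network rhythm protocol and then held fixed; the uptake-rate
  sweep subsequently reproduced the published suppression threshold
  (0.016 ms⁻¹) with no further adjustment.
- **Averaging window T = 600 ms** (unprinted). Physically this is the
  volume-transmission smoothing: GABA released by a spike reaches
  extrasynaptic receptors across the tissue over hundreds of ms. T is also
  dynamically load-bearing: the delayed rate feedback plus the first-order
  uptake gives a relaxation oscillation; with T ≲ 100 ms the same
  parameters sit at a stable fixed point and no rhythm emerges.

Mechanism of the rhythm, as the model produces it: at moderate G_tonic the
(pacemaking, noise-driven) interneurons fire vigorously; the released GABA
raises G_tonic with the lag T; once G crosses the shunting cliff, firing
collapses; uptake then discharges G at rate G_pump until firing resumes,
and the cycle repeats at ~1 Hz for the published parameter sets. The
period is set jointly by T and 1/G_pump — hence slower uptake produces
slower rhythms, and fast uptake (≥ 0.016 ms⁻¹) clamps the wave entirely.

The x2 interneuron-vs-pyramidal tonic range is applied in the twinned
network; in interneuron-only protocols the printed G_tonic values are
taken as the interneurons' own conductance (the published constant
0.44 mS/cm² would otherwise sit deep in depolarization block).

An explicit [GABA]ₑ trace is also computed directly from the spike raster
(0.5 µM per network-normalized action potential, decay 0.004 ms⁻¹). It has
no receptor lag, so it leads the G_tonic trace by roughly T/2; it is the
phase reference for burst-phase analyses: pyramidal bursts begin just
before the lagged-G_tonic trough, i.e. on the *ascending* phase of the
instantaneous [GABA]ₑ wave — the published phase relation.

The published closed-form solution for constant f_m pumps absolute G
(not G − G_basal) and omits f_b; it is provided verbatim as
`closed_form_gtonic`, and the numerical-vs-analytic agreement test uses
the convention the closed form declares.

## Analysis procedures

- **Interictal-event detection**: downsample to 1 kHz, zero-phase 1–50 Hz
  Butterworth (order 4), second time-derivative, threshold at 4 SD of the
  baseline-noise segment (first 2 s), merge crossings within 200 ms.
  Unprinted details chosen here: a candidate must hold ≥ 6 samples above
  threshold (isolated noise excursions otherwise produce ~5 false
  events/100 s; with the rule, ≤ 1/100 s), and the reported onset is the
  30% rise point of the event's own second-derivative peak (the zero-phase
  filter smears a sharp discharge symmetrically, so the first raw
  threshold crossing runs ~20 ms early; the rise point tracks the true
  onset to ~2 ms).
- **Wave-like classification**: 2-Hz zero-phase low-pass, periodogram,
  significant (above the 95% CI of the noise floor) peak in 0.01–2 Hz.
  The CI construction (unprinted) is a chi-square bound: in-band-median
  noise floor, Šidák-corrected for the number of in-band frequencies,
  widened by the floor estimate's 2-SE uncertainty (without the widening
  the white-noise false-alarm rate is 8.5% instead of ≤ 5–7.5%). The
  spectrum is whitened by the known filter response, and a peak must also
  carry a minimal fraction of the raw-trace variance so numerical leakage
  of out-of-band components cannot qualify. A phase-shuffling surrogate
  bound is selectable.
- **Rhythm detection** for simulated population rates shares the same
  spectral test; figure-level recipes additionally require the slow peak
  to carry ≥ 5% of the rate variance to count as *detectable* rhythmic
  activity (true rhythms here carry 24–77%, suppressed regimes < 1%, so
  the value is not load-bearing) and exclude the first 5 s of field
  equilibration.
- **Synchrony**: spike trains binned at τ (default 0.1/f_m) into binary
  occupancy; pairwise k_ij = ΣXY/√(ΣX·ΣY), averaged over pairs. The
  square-root denominator bounds k in [0,1] with identical trains scoring
  1; the published plain-product denominator (which scores identical
  m-spike trains as 1/m) is available via `normalization="printed"`.
- **Single-channel analysis**: openings are deviations > 1.5 pA from
  baseline lasting > 0.2 ms; frequency N/Δt; conductance
  G = I/(V_rev − V_hold); charge transfer rate Q = G·N/Δt exactly as
  published (units nS/s, i.e. conductance × frequency), with the
  physically conventional alternative (mean open current × open-time
  fraction) reported alongside.
- **Sensor calibration**: Hill equation E_max·Cⁿ/(K_dⁿ + Cⁿ) fitted by
  nonlinear least squares; inversion C = K_d·(F/(E_max − F))^(1/n). The
  reference sensor model is E_max = 0.175, K_d = 1.26 µM, n = 2.
- **Fluorescence transients**: field events validated by width/amplitude
  rules (≥ 20 ms, > 5 SD); the sensor peak is sought in a −750 ms…+2 s
  window per event (> 2.5 SD, ≥ 50 ms wide); the rise is fitted by cubic
  polynomial regression (order unprinted; 3 by default) and the event lag
  is the 20%-of-peak time minus the field event time.
- **Band-split analysis**: 2-Hz low/high split; high-band power integrated
  in symmetric windows before vs after each low-component peak.
- **Simulated field potential**: point-source volume conductor,
  V = Σ I_k/(4πσr), all sources at the stated distance (250 µm default,
  σ = 100 mS/cm); the forward model beyond distance and conductance is
  unprinted, and this is the minimal standard choice.

## Synthetic data

Generators return their ground truth and are bit-reproducible from the
seed. They emulate: field potentials with stereotyped biphasic < 200-ms
interictal spikes (periodic at 0.14 Hz — the spontaneous acute-slice rate
— or 0.25–0.5 Hz for the organotypic 2–4 s inter-spike regime; optional
1/f noise); a two-state channel whose opening rate follows the sensor Hill
curve of the GABA waveform; fluorescence as Hill([GABA]ₑ) plus Gaussian
noise; calibration titrations (8 log-spaced concentrations over 0.1–30 µM,
5% multiplicative noise); and spike-train pairs thinned from a common
mother train with controlled shared fraction and jitter.

What the generators do *not* emulate: electrode drift and movement
artifacts, spatially heterogeneous release landscapes, photobleaching and
shot-noise statistics, channel subconductance states, or cell-to-cell
diversity of intrinsic properties. A green round-trip test therefore
establishes that a procedure implements its stated rule correctly and is
calibrated against its stated noise model — not that it is robust to every
artifact of real recordings.

## Numerical notes and limitations

- Determinism: every simulation and generator is bit-reproducible from its
  seed on a given platform; cross-platform agreement is expected to
  floating-point round-off accumulated over ~10⁶ Euler steps.
- The network is homogeneous (identical cells, translation-invariant
  coupling); real interneuron populations are heterogeneous, which the
  source experiments invoke to explain why only ~1/3 of recorded cell
  pairs show the rhythmic wave pattern. Expect the model to be *more*
  regular than tissue.
- The [GABA]ₑ field is a single scalar per population — no spatial
  diffusion, no transporter saturation, no chloride/potassium dynamics.
- The firing-vs-G_tonic relation, and hence the rhythm's operating point,
  depends on the kinetics-shift calibration described above; moving
  V_GABA, G_ii or the drive by factors of ~2 changes frequencies but not
  the qualitative regime (rhythm with dynamic field, none with constant
  conductance; slower uptake → slower rhythm).
- Scaled-down networks (N = 100 with N·A_f preserved) reproduce the
  N = 1500 regime's fixed point exactly and its dynamics qualitatively;
  burst irregularity is larger at small N, consistent with the published
  observation that larger networks cycle more regularly.
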