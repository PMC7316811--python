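# Methods

This note documents the models implemented in `ihcsync`, the defaults and
why they were chosen, the numerical schemes, and what the synthetic-data
generators do and do not emulate.

## Units and sign conventions

Voltages in mV, currents in nA (pA where stated), conductances in µS
(1 µS = 1/MΩ), capacitances in pF, time in ms with integration steps in µs
(MΩ·pF = µs, so the system is consistent).  Inward membrane current is
negative; an amplifier current is positive when it flows from the pipette
into the cell; the junctional current I_J = g_J (V₁ − V₂) is positive from
cell 1 into cell 2.  With this convention a positive command difference on
the stepped cell produces a *negative* current change at the held
amplifier; `SyntheticPairedRecording` stores the held-amplifier current as
measured, and `to_paired_iv()` flips its sign so the I_J–V_J relation of a
coupled pair has positive slope.

## Dual voltage-clamp circuit (`coupling_circuit`)

Two cells, each clamped through a series resistance R_S and carrying a
membrane leak (R_M, reversal E_M), joined by R_J.  Node balance for cell i:

    g_S (cmd_i − V_i) = g_M (V_i − E_M) + g_J (V_i − V_j)

E_M defaults to the holding potential so the circuit rests at holding with
zero current, as the recordings it reproduces do.  Steady states are the
2×2 linear solve; transients use the trapezoidal rule (unconditionally
stable; the default dt = 1 µs is far below the fastest time constant
C/(g_S+g_M+g_J) ≈ 50 µs of the reference parameters C = 10 pF,
R_S = 10 MΩ, R_M = 1 GΩ, R_J = 10 MΩ).

**R_J estimation.**  The raw ("apparent") estimate is 1/slope of the
through-origin least-squares fit of I_J on V_J.  It is biased upward
because the command difference divides over both series resistances and
the membrane shunt.  The compensated estimate inverts the full two-node
network: with p = (g_S1+g_M1)(g_S2+g_M2) and s = g_S1+g_M1+g_S2+g_M2 the
predicted slope is m(g_J) = g_S1 g_S2 g_J / (p + s·g_J), which solves in
closed form, g_J = m·p / (g_S1 g_S2 − m·s).  The compensated estimate is
exact for noiseless data from the declared topology and always ≤ the
apparent one.  A non-positive slope, a slope below a configurable noise
floor (default 1 nS), or a slope at/above the theoretical maximum
g_S1 g_S2/s classifies the pair as non-coupled (R_J = ∞).  The exact
compensation formula used in the original recordings is published
elsewhere; the network inversion here is this package's own, exact
equivalent for the declared circuit.

**Apparent capacitance.**  A small step is applied to cell 1 of an N-cell
chain (equal per-junction R_J; a linear chain because IHCs sit in a single
row).  The amplifier-current transient above its steady state is
integrated to the delivered capacitive charge Q, and the recording is read
out with the standard one-compartment model (unknown C_x, g_x behind known
R_S):

    g_x = g_S·I_ss / (g_S·ΔV_cmd − I_ss),
    C_m,app = Q (g_S + g_x) / (g_S·ΔV₁_ss).

This returns exactly C for one cell and exactly N·C in the fused
(R_J → 0) limit; intermediate coupling gives intermediate values,
decreasing in R_J — the behaviour that makes C_m rise with the number of
dye-coupled cells.  We model no pipette-capacitance artifacts or amplifier
compensation firmware; only this transparent charge-integral estimator.

**IV summaries.**  Evoked currents are averaged over a 3–8 ms post-step
window by convention; I_rest is the (interpolated) current at holding;
I_CaMax the most negative window-averaged current; G_m the
central-difference slope dI/dV at requested voltages (−60 and +20 mV in
typical use).

## Stochastic signal chain (`syncytium_sim`)

Per cell i of an N-cell chain (uncoupled means g_J = 0):

* stimulus: x(t) = A sin(2πft), identical for all cells; f = 500 Hz,
  100 ms duration, the first 10 ms discarded from analysis; dt = 10 µs.
* MET channels: n = 80 two-state Markov channels per cell with
  displacement-dependent equilibrium p∞(x) = 1/(1+exp(−(x−x_half)/s)) and
  relaxation time τ_MET = 50 µs; per-step switching probabilities
  p∞·dt/τ (open) and (1−p∞)·dt/τ (close), exact in the dt → 0 limit.
* membrane: C dV_i/dt = −g_L(V_i−E_L) + g₁N_open,i(t)(E_MET−V_i)
  − Σ_j g_J(V_i−V_j); backward-Euler integration.  When the chain is
  uncoupled the update runs through the identical scalar arithmetic as a
  single-cell simulation, so an R_J = ∞ run reproduces N independent
  single-cell runs bit-identically (a tested invariant).
* Ca²⁺ channels: p∞(V) = 1/(1+exp(−(V−V_h)/k)) with V_h = −25 mV
  (anchored to the ≈ −24 mV measured half-activation of presynaptic Ca²⁺
  signals), k = 8 mV, τ_act = 0.5 ms — consistent with the 0.5 ms lag
  compensated in the Ca-stage correlations (0.3 ms for voltage).  The
  ensemble open probability follows dp/dt = (p∞(V) − p)/τ_act (exact
  exponential update); single channels are two-state Markov chains with
  α = p∞/τ_act, β = (1−p∞)/τ_act.
* release and APs: one release event per maximal single-channel opening
  lasting ≥ 2 ms, timestamped when the 2 ms elapse (causality: release
  cannot be declared earlier).  A greedy 1 ms refractory pass turns events
  into SGN APs.  Because any two events of one channel are ≥ 2 ms apart by
  construction, the 1 ms dead time only matters for rules with
  min_open < refractory; the pruning is tested against the renewal-theory
  dead-time rate λ/(1+λt_ref) on Poisson input.
* Exact release intensity: the first-order intensity of the release
  process given a voltage trace is
  λ(t) = α(t−d)(1−p(t−d))·exp(−∫_{t−d}^t β ds), d = 2 ms — the
  "very many realizations" limit used by the analytic cochlear-nucleus
  layer and cross-checked against the Monte-Carlo pipeline.

Coupled and uncoupled conditions of one experiment share the identical
per-cell MET realizations (per-cell child seeds of one `SeedSequence`), so
downstream differences are attributable to coupling alone.

### Parameter calibration

The quantitative single-channel parameters of the transduction stage are
not fixed by the measurements the model rests on, so they were calibrated
once, jointly, to the reported operating behaviour, and frozen:

* **g₁ = 1.0 nS, n = 80** (population 80 nS).  The single-channel value is
  an *effective* lumped conductance: together with n it sets both the
  receptor-potential amplitude and the binomial transduction-noise level.
  Physically smaller channels in larger numbers would give the same mean
  drive with less noise and no measurable coupling effect; the calibrated
  noise level is what reproduces the reported correlation gap (below).
* **x_half = 0** (resting open probability 0.5, the maximally sensitive
  point of the transducer curve) and **g_L = 20 nS, E_L = −60 mV**, which
  put the resting potential near −20 mV, within a few k of the Ca²⁺-channel
  half-activation.  This working point yields spontaneous SGN rates of
  ~100 s⁻¹ (high-spontaneous-rate fibers) and well-resolved
  cochlear-nucleus firing probabilities.  Membrane time constant
  C/(g_L+g_MET) ≈ 0.17 ms.
* **stimulus amplitude A = 0.24** (in units of the transducer slope s),
  calibrated so the uncoupled Ca²⁺-open-probability-versus-stimulus
  correlation is ≈ 0.82; the coupled condition (25 MΩ) then lands at
  ≈ 0.89 with no further tuning.  The calibration was verified on three
  disjoint 20-seed sets before freezing; the coupled > uncoupled ordering
  holds in every matched block.

All of these are plain dataclass fields and can be overridden per run.

## Cochlear-nucleus coincidence detection (`cn_coincidence`)

A bushy cell pools K = 4 SGN inputs assigned round-robin to the syncytium's
cells and fires when ≥ M = 2 distinct inputs spike within w = 0.5 ms (the
textbook submillisecond coincidence regime of bushy cells; all
overridable).  On event trains the detector fires at the earliest time the
rule is met and re-arms after w.  Analytically, given the voltage traces
the SGN event processes are independent, so the probability that ≥ M of K
inputs have an event in the trailing window is a Poisson-binomial tail
computed from the per-input window probabilities 1 − exp(−∫λ); this is the
many-trial limit of the event-level pipeline and is cross-checked against
it.

**Improvement metric.**  The reported improvement is the
across-presentation *reliability* of the CN response: the mean pairwise
Pearson correlation between CN firing-probability traces evoked by
independent presentations (independent transduction noise, same stimulus).
Electrical coupling removes part of each cell's private transduction noise
from every receptor potential, which makes the CN response more
reproducible — by ≈ 2–3 % under the defaults, stable in sign across block
pairs, with a bootstrap-over-blocks CI.

We deliberately did *not* use the raw per-cycle coincidence probability:
measured with 16,000 paired trials its change is 0 ± 0.6 %.  The reason is
structural, not statistical: uncorrelated voltage noise inflates each
cell's mean event rate through the convexity of the rate–voltage relation
(a Jensen effect) by almost exactly as much as coupling's cross-input
correlation concentrates coincidences, so raw coincidence *counts* are
insensitive to coupling.  What coupling improves is the fidelity and
reproducibility of the CN response, not its quantity.  Per-cycle hit
probability and the vector strength of the CN output are still computed
and reported alongside (`metric="cycle_hit"` switches the improvement to
the count-based reading).

## Tonotopy (`tonotopy`)

Positions are measured from the apex; IHCs are assumed uniformly spaced in
a single row, so n cells cover 100·n/N % of the cochlear length.  Mouse
default: N = 700 IHCs over 5.13 mm, log-linear map of 4.7 octaves total —
under which 9 IHCs span 1.29 % of the length and 0.060 octaves.  Human
defaults: 35 mm, N = 3500, Greenwood map f(x) = A(10^{ax} − k) with
A = 165.4 Hz, a = 0.06 /mm, k = 0.88 (x from apex), evaluated mid-map for
"mid-cochlear" statements; an alternative uniform-octave mode spreads the
audible 20 Hz–20 kHz (≈ 9.97 octaves) evenly over the IHC row.  Both modes
give ≈ 3 cents per IHC (2.60 Greenwood at mid-cochlea, 3.42 uniform), and
the n-IHC "best possible resolution" multiplies the *rounded* integer
per-IHC cents (3 × 3 = 9 cents for the average 3-IHC mini-syncytium), the
integer-cent convention used in psychophysical comparisons;
`round_per_ihc=False` returns the exact span instead.  Spans in the
log-linear form are additive and position-independent; cents are always
1200 × octaves.

## Ca²⁺-imaging pipeline (`imaging_fv`)

Dye time-series are background-subtracted per frame and normalized to the
maximum of the patched (reference) cell, which therefore peaks at exactly
1; normalization is idempotent.  For hotspots: F₀ is the mean of 10 rest
frames, the depolarized image the mean of 6 depolarized frames; the 3×3
analysis square sits on the argmax pixel of the mean ΔF image (row-major
tie-break; clipped one pixel inside the border); ΔF per frame is the 3×3
mean minus the 3×3 mean of F₀; ΔF_max averages the 5 consecutive per-frame
ΔF values centred on the depolarized-sequence peak (shifted, never shrunk,
at the edges) — we read the "5 neighboring values" temporally, at the peak
of Ca²⁺ influx, not spatially.  A hotspot is synaptic if
ΔF_max > rest mean + 2·rest SD, where the rest statistics are those of the
per-frame ΔF values over the rest frames.  On null movies this criterion
passes < 5 % of the time; spots of amplitude ≥ 6 noise SD are always
detected (both tested over many seeds).

The FV relation is fitted in two stages with V_r fixed (taken from the
whole-cell current reversal, never fitted): (i) the slope factor f_v from
the least-squares line on samples with V ∈ [3, 23] mV, where the channels
are essentially fully activated and fluorescence declines with driving
force; (ii) nonlinear least squares over (F₀, f_v, V_h, k) with f_v
initialized from (i).  Fractional activation divides the FV fit by the
extrapolated driving-force line, activation(V) = (F−F₀)/(f_v(V_r−V)),
excluding |V − V_r| < 3k where the line crosses zero, and refits a
Boltzmann for (V_h, k).  On exact model input the composition is the exact
Boltzmann of the generating parameters (tested to 1e−6); with 2 % noise
the median errors over 100 seeds are < 1 % (F₀), < 1 mV (V_h), < 10 % (k).

Interleaved-ramp merging assumes the standard protocol: −87 to +63 mV in
150 ms (1 mV/ms), 100 Hz frames (10 mV per frame within one ramp), second
ramp shifted 5 ms so merged samples sit on a 5 mV grid.

## Synthetic data (`synthetic_data`)

All generators are pure functions of (parameters, seed) — same seed, same
bits.  Noise is additive i.i.d. Gaussian everywhere (Student-t optional),
the simplest model consistent with mean ± SEM reporting; the sample SD of
generated noise matches the requested SD within 5 % at 10⁵ draws (tested).
Hotspots are isotropic 2-D Gaussians (σ = 1 px default) — only the 3×3
averaging window matters downstream, not the true spot shape.  The movies
emulate neither dye diffusion between cells nor photobleaching; the
paired-recording generator emulates steady-state currents only (no
capacitive transients); imaging noise magnitudes are free parameters since
no reference values exist.  Consequently, passing recovery tests shows the
estimators are correct and well-conditioned under the declared noise
model — not that they are robust to drift, bleaching, or correlated noise
in real microscope data.

## Problem sizes and determinism

The default analysis runs 20 independent-noise blocks of a 3-cell,
100 ms simulation at dt = 10 µs (9,000 analysis samples), with 2,000
Monte-Carlo SGN trials for count-based diagnostics — sizes chosen so the
whole reproduction script completes in well under a minute while leaving
the reported quantities' sampling error far below the effects of interest.
Every random stream descends from explicit integer seeds via
`numpy.random.SeedSequence`; there is no hidden global RNG state.

## Known limitations

No basilar-membrane mechanics or outer-hair-cell amplification; no K⁺
channel inventory (a single leak stands in); no vesicle-pool dynamics or
EPSC model (release is a binary threshold on open duration); one SGN per
active zone, one Ca²⁺ channel chain per SGN; the bushy cell is a
point-process rule, not a conductance model.  The N-cell chain assumes
equal junctional resistances.  The tonotopic maps ignore spiral geometry
and per-row IHC width variation.
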