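"""Stochastic signal-chain simulation of coupled and uncoupled inner hair cells.

The model follows the sound-encoding chain of the cochlear inner hair cell
(IHC): a deterministic sinusoidal mechanical stimulus gates
mechanotransducer (MET) channels stochastically; the resulting current
drives the membrane voltage of each cell in an N-cell chain, optionally
coupled through junctional resistances R_J; the receptor potential controls
Ca2+-channel gating (both the ensemble mean open probability and
single-channel Markov realizations); long single-channel openings trigger
neurotransmitter release events, which, pruned by refractoriness, become
action potentials (APs) in the postsynaptic spiral ganglion neuron (SGN).

The coupled and uncoupled conditions of the same experiment share the
identical per-cell MET realizations, so that any difference downstream is
attributable to the junctional coupling alone.

Units: mV, nA, uS (conductances also quoted in nS where noted), pF, with
time bookkeeping in ms and an integration step in us.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

from .coupling_circuit import RJ_OPEN

__all__ = [
    "SinusoidStimulus",
    "METModel",
    "IHCCompartment",
    "CaChannelModel",
    "ReleaseRules",
    "SyncytiumConfig",
    "SimResult",
    "ProbabilityTrace",
    "CorrelationSummary",
    "make_stimulus",
    "met_open_prob",
    "simulate_met_gating",
    "integrate_membrane",
    "ca_open_prob_trace",
    "simulate_ca_channel",
    "release_events",
    "prune_refractory",
    "release_intensity",
    "simulate_syncytium",
    "simulate_conditions",
    "ap_probability",
    "lagged_pearson",
    "correlation_summary",
    "UndefinedCorrelationError",
]


class UndefinedCorrelationError(ValueError):
    """Pearson correlation is undefined (an input has zero variance)."""


# ---------------------------------------------------------------------------
# configuration types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SinusoidStimulus:
    """Sinusoidal hair-bundle displacement, identical for all cells.

    Amplitude is in the dimensionless displacement units of the MET
    activation curve (multiples of its slope parameter).
    """

    frequency_hz: float = 500.0
    amplitude: float = 0.24
    phase_rad: float = 0.0
    duration_ms: float = 100.0
    dt_us: float = 10.0
    onset_discard_ms: float = 10.0

    def __post_init__(self) -> None:
        if self.dt_us > 20.0:
            raise ValueError("dt_us must be <= 20 us to resolve 200 us windows")
        if not self.duration_ms > self.onset_discard_ms:
            raise ValueError("duration must exceed onset_discard")

    @property
    def n_samples(self) -> int:
        return int(round(self.duration_ms * 1e3 / self.dt_us))


@dataclass(frozen=True)
class METModel:
    """Mechanotransducer channel population of one IHC.

    Open probability follows a first-order Boltzmann of displacement,
    p_inf(x) = 1/(1+exp(-(x-x_half)/s)); each channel is a two-state Markov
    chain relaxing toward p_inf with time constant tau_met.  The default
    x_half = 0 puts the resting bundle at the midpoint of the transducer
    curve (resting open probability 0.5, maximal sensitivity).  The
    single-channel conductance is an effective lumped value: together with
    the channel count it sets both the receptor-potential amplitude and the
    transduction noise level (binomial gating fluctuations of an 80-channel
    population).
    """

    n_channels: int = 80
    x_half: float = 0.0  # resting p_inf = 0.5
    slope: float = 1.0
    tau_met_us: float = 50.0
    g_single_nS: float = 1.0
    e_met_mV: float = 0.0

    def __post_init__(self) -> None:
        if self.n_channels < 1 or self.slope <= 0 or self.tau_met_us <= 0:
            raise ValueError("invalid MET model parameters")


@dataclass(frozen=True)
class IHCCompartment:
    """Passive electrical compartment of one IHC."""

    cm_pF: float = 10.0
    g_leak_nS: float = 20.0
    e_leak_mV: float = -60.0
    v_init_mV: float | None = None  # default: leak/MET resting balance

    def __post_init__(self) -> None:
        if self.cm_pF <= 0 or self.g_leak_nS < 0:
            raise ValueError("invalid compartment parameters")


@dataclass(frozen=True)
class CaChannelModel:
    """Voltage-gated Ca2+ channel (Cav1.3-like) of one active zone.

    p_inf(V) = 1/(1+exp(-(V-vh)/k)); single channels are two-state Markov
    chains with rates alpha = p_inf/tau_act and beta = (1-p_inf)/tau_act.
    The default half-activation voltage matches the value measured from
    presynaptic Ca2+-imaging (about -24 mV).
    """

    vh_mV: float = -25.0
    k_mV: float = 8.0
    tau_act_us: float = 500.0
    n_channels: int = 1

    def __post_init__(self) -> None:
        if self.k_mV <= 0 or self.tau_act_us <= 0:
            raise ValueError("invalid Ca-channel parameters")


@dataclass(frozen=True)
class ReleaseRules:
    """Release and refractoriness rules: one release event per maximal
    single-channel opening of at least ``min_open_ms``; accepted APs are at
    least ``refractory_ms`` apart."""

    min_open_ms: float = 2.0
    refractory_ms: float = 1.0

    def __post_init__(self) -> None:
        if self.min_open_ms <= 0 or self.refractory_ms < 0:
            raise ValueError("invalid release rules")


@dataclass(frozen=True)
class SyncytiumConfig:
    """N-cell chain of IHC compartments with junctional resistance ``rj_mohm``
    between neighbours (``inf`` = uncoupled)."""

    n_cells: int = 3
    rj_mohm: float = 25.0
    stimulus: SinusoidStimulus = field(default_factory=SinusoidStimulus)
    met: METModel = field(default_factory=METModel)
    compartment: IHCCompartment = field(default_factory=IHCCompartment)
    ca: CaChannelModel = field(default_factory=CaChannelModel)
    release: ReleaseRules = field(default_factory=ReleaseRules)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_cells < 1:
            raise ValueError("n_cells must be >= 1")
        if not (self.rj_mohm > 0):
            raise ValueError("rj_mohm must be > 0 (use math.inf for uncoupled)")


@dataclass(frozen=True)
class ProbabilityTrace:
    """AP probability per analysis window for one SGN/cell."""

    window_edges_ms: np.ndarray
    p_ap: np.ndarray
    n_realizations: int

    def __post_init__(self) -> None:
        p = np.asarray(self.p_ap, float)
        if np.any((p < 0) | (p > 1)):
            raise ValueError("probabilities must lie in [0, 1]")


@dataclass(frozen=True)
class CorrelationSummary:
    """Average lag-compensated Pearson correlations per signal stage:
    between cell pairs (``pairwise``) and between each cell and the
    stimulus (``vs_stimulus``)."""

    pairwise: dict[str, float]
    vs_stimulus: dict[str, float]
    lags_ms: dict[str, float]


@dataclass(frozen=True)
class SimResult:
    """Deterministic-given-MET stages of one syncytium simulation."""

    config: SyncytiumConfig
    t_ms: np.ndarray
    stimulus: np.ndarray
    met_open: np.ndarray      # (n_cells, n_samples) open-channel counts
    voltage: np.ndarray       # (n_cells, n_samples) mV
    ca_open_prob: np.ndarray  # (n_cells, n_samples) ensemble open probability

    @property
    def analysis_mask(self) -> np.ndarray:
        return self.t_ms >= self.config.stimulus.onset_discard_ms


# ---------------------------------------------------------------------------
# stimulus and MET gating
# ---------------------------------------------------------------------------

def make_stimulus(s: SinusoidStimulus) -> tuple[np.ndarray, np.ndarray]:
    """Return (t_ms, x) with x(t) = A sin(2 pi f t + phase)."""
    t_ms = np.arange(s.n_samples) * (s.dt_us / 1e3)
    x = s.amplitude * np.sin(2.0 * np.pi * s.frequency_hz * t_ms / 1e3
                             + s.phase_rad)
    return t_ms, x


def met_open_prob(x: np.ndarray | float, m: METModel) -> np.ndarray | float:
    """Steady-state MET open probability for displacement ``x``."""
    return 1.0 / (1.0 + np.exp(-(np.asarray(x, float) - m.x_half) / m.slope))


def simulate_met_gating(
    x: np.ndarray,
    m: METModel,
    rng: np.random.Generator | int,
    dt_us: float = 10.0,
) -> np.ndarray:
    """Simulate the two-state Markov gating of ``m.n_channels`` MET channels
    driven by the displacement trace ``x``; returns the open-channel count
    per time step.

    Per channel and time step, the opening hazard is p_inf(x)/tau * dt and
    the closing hazard (1-p_inf(x))/tau * dt (exact in the dt -> 0 limit).
    The initial state is an equilibrium draw at x[0].
    """
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    p_inf = np.asarray(met_open_prob(x, m), float)
    a = p_inf * (dt_us / m.tau_met_us)        # opening prob per step
    b = (1.0 - p_inf) * (dt_us / m.tau_met_us)  # closing prob per step
    n = m.n_channels
    open_state = rng.random(n) < p_inf[0]
    counts = np.empty(p_inf.size, dtype=np.int32)
    counts[0] = int(open_state.sum())
    for k in range(1, p_inf.size):
        u = rng.random(n)
        open_state = np.where(open_state, u >= b[k], u < a[k])
        counts[k] = int(open_state.sum())
    return counts


# ---------------------------------------------------------------------------
# membrane integration
# ---------------------------------------------------------------------------

def integrate_membrane(
    met_counts: np.ndarray,
    cfg: SyncytiumConfig,
) -> np.ndarray:
    """Integrate the membrane voltage of every cell in the chain.

    Per cell i (conductances in uS):

        C dV_i/dt = -g_L (V_i - E_L) + g_MET N_i(t) (E_MET - V_i)
                    - sum_j (V_i - V_j)/R_J

    Backward-Euler integration (implicit, unconditionally stable).  When the
    chain is uncoupled (R_J = inf) the update is performed cell-by-cell with
    the identical scalar arithmetic used for a single-cell chain, so an
    uncoupled N-cell run reproduces N independent single-cell runs
    bit-identically.
    """
    met_counts = np.atleast_2d(np.asarray(met_counts, float))
    n_cells, n_samples = met_counts.shape
    if n_cells != cfg.n_cells:
        raise ValueError("met_counts rows must equal cfg.n_cells")
    comp, met = cfg.compartment, cfg.met
    dt = cfg.stimulus.dt_us
    cm = comp.cm_pF
    gl = comp.g_leak_nS * 1e-3          # uS
    g1 = met.g_single_nS * 1e-3         # uS
    gj = 0.0 if math.isinf(cfg.rj_mohm) else 1.0 / cfg.rj_mohm

    g_met = g1 * met_counts             # (n_cells, n_samples) uS
    drive = gl * comp.e_leak_mV + g_met * met.e_met_mV  # nA

    if comp.v_init_mV is not None:
        v0 = np.full(n_cells, float(comp.v_init_mV))
    else:
        # rest at the mean-MET conductance balance
        g0 = g1 * met.n_channels * float(np.asarray(
            met_open_prob(0.0, met)))
        v0 = np.full(n_cells, (gl * comp.e_leak_mV + g0 * met.e_met_mV)
                     / (gl + g0))

    v = np.empty((n_cells, n_samples))
    v[:, 0] = v0
    if gj == 0.0 or n_cells == 1:
        # decoupled scalar path (bit-identical to a 1-cell chain per cell)
        denom_all = cm / dt + gl + g_met
        vk = v0.copy()
        for k in range(1, n_samples):
            vk = ((cm / dt) * vk + drive[:, k]) / denom_all[:, k]
            v[:, k] = vk
    else:
        lap = np.zeros((n_cells, n_cells))
        for i in range(n_cells - 1):
            lap[i, i] += gj
            lap[i + 1, i + 1] += gj
            lap[i, i + 1] -= gj
            lap[i + 1, i] -= gj
        eye = np.eye(n_cells)
        vk = v0.copy()
        for k in range(1, n_samples):
            a = (cm / dt) * eye + np.diag(gl + g_met[:, k]) + lap
            rhs = (cm / dt) * vk + drive[:, k]
            vk = np.linalg.solve(a, rhs)
            v[:, k] = vk
    if not np.all(np.isfinite(v)):
        raise RuntimeError("membrane integration diverged")
    return v


def junctional_currents(v: np.ndarray, rj_mohm: float) -> np.ndarray:
    """Junctional current flowing from cell i into cell i+1 (nA), shape
    (n_cells-1, n_samples)."""
    gj = 0.0 if math.isinf(rj_mohm) else 1.0 / rj_mohm
    return gj * (v[:-1] - v[1:])


# ---------------------------------------------------------------------------
# Ca2+ channel gating
# ---------------------------------------------------------------------------

def ca_p_inf(v: np.ndarray | float, ca: CaChannelModel) -> np.ndarray | float:
    return 1.0 / (1.0 + np.exp(-(np.asarray(v, float) - ca.vh_mV) / ca.k_mV))


def ca_open_prob_trace(v: np.ndarray, ca: CaChannelModel,
                       dt_us: float = 10.0) -> np.ndarray:
    """Ensemble-average Ca2+ channel open probability along a voltage trace:
    first-order relaxation dp/dt = (p_inf(V) - p)/tau_act (exact exponential
    update per step)."""
    p_inf = np.asarray(ca_p_inf(v, ca), float)
    decay = math.exp(-dt_us / ca.tau_act_us)
    p = np.empty_like(p_inf)
    p[0] = p_inf[0]
    for k in range(1, p.size):
        p[k] = p_inf[k] + (p[k - 1] - p_inf[k]) * decay
    return p


def simulate_ca_channel(
    v: np.ndarray,
    ca: CaChannelModel,
    rng: np.random.Generator | int,
    dt_us: float = 10.0,
    n_realizations: int = 1,
) -> np.ndarray:
    """Two-state Markov realization(s) of a single Ca2+ channel along a
    voltage trace.  Returns a boolean array (n_realizations, n_samples);
    squeezed to 1-D when ``n_realizations == 1``.

    Rates: alpha(V) = p_inf(V)/tau_act (opening), beta(V) = (1-p_inf)/tau_act.
    """
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    p_inf = np.asarray(ca_p_inf(v, ca), float)
    a = p_inf * (dt_us / ca.tau_act_us)
    b = (1.0 - p_inf) * (dt_us / ca.tau_act_us)
    n = n_realizations
    state = rng.random(n) < p_inf[0]
    out = np.empty((n, p_inf.size), dtype=bool)
    out[:, 0] = state
    for k in range(1, p_inf.size):
        u = rng.random(n)
        state = np.where(state, u >= b[k], u < a[k])
        out[:, k] = state
    return out[0] if n_realizations == 1 else out


# ---------------------------------------------------------------------------
# release and refractoriness
# ---------------------------------------------------------------------------

def release_events(state: np.ndarray, rules: ReleaseRules,
                   dt_us: float = 10.0) -> np.ndarray:
    """Release event times (ms) from a binary channel-state trace: one event
    per maximal open interval lasting at least ``min_open_ms``, timestamped
    at the instant the interval reaches that duration."""
    state = np.asarray(state, bool)
    min_steps = int(round(rules.min_open_ms * 1e3 / dt_us))
    if min_steps < 1:
        raise ValueError("min_open_ms shorter than one time step")
    padded = np.concatenate(([False], state, [False])).astype(np.int8)
    d = np.diff(padded)
    starts = np.flatnonzero(d == 1)
    ends = np.flatnonzero(d == -1)  # exclusive
    long_enough = (ends - starts) >= min_steps
    event_idx = starts[long_enough] + min_steps - 1
    return event_idx * (dt_us / 1e3)


def prune_refractory(events_ms: np.ndarray, rules: ReleaseRules) -> np.ndarray:
    """Greedy forward pass turning release events into an AP train: accept an
    event iff it is at least ``refractory_ms`` after the last accepted one."""
    events = np.asarray(events_ms, float)
    if events.size == 0:
        return events
    if np.any(np.diff(events) < 0):
        raise ValueError("events must be sorted ascending")
    out = [events[0]]
    for t in events[1:]:
        if t - out[-1] >= rules.refractory_ms:
            out.append(t)
    return np.asarray(out)


def release_intensity(v: np.ndarray, ca: CaChannelModel, rules: ReleaseRules,
                      dt_us: float = 10.0) -> np.ndarray:
    """Exact first-order intensity (events/ms) of the release point process
    along a voltage trace.

    A release event at time t requires the channel to open at t - d (with
    d = ``min_open_ms``) from the closed state and stay open throughout
    [t-d, t].  With alpha(V) = p_inf/tau and beta(V) = (1-p_inf)/tau and the
    deterministic occupancy p(t) from :func:`ca_open_prob_trace`:

        lambda(t) = alpha(t-d) (1 - p(t-d)) exp(-int_{t-d}^{t} beta ds)

    This is the "very many realizations" limit of the stochastic
    single-channel pipeline and is cross-checked against it in the tests.
    The intensity is zero for t < d (no complete opening can have occurred).
    """
    p_inf = np.asarray(ca_p_inf(v, ca), float)
    p = ca_open_prob_trace(v, ca, dt_us)
    dt_ms = dt_us / 1e3
    alpha = p_inf / ca.tau_act_us * 1e3   # per ms
    beta = (1.0 - p_inf) / ca.tau_act_us * 1e3
    m = int(round(rules.min_open_ms * 1e3 / dt_us))
    if m < 1:
        raise ValueError("min_open_ms shorter than one time step")
    cum_beta = np.concatenate([[0.0], np.cumsum(beta) * dt_ms])
    lam = np.zeros_like(p_inf)
    ks = np.arange(m, p_inf.size)
    lam[ks] = (alpha[ks - m] * (1.0 - p[ks - m])
               * np.exp(-(cum_beta[ks] - cum_beta[ks - m])))
    return lam


# ---------------------------------------------------------------------------
# simulation drivers
# ---------------------------------------------------------------------------

def _met_rngs(seed: int, n_cells: int) -> list[np.random.Generator]:
    ss = np.random.SeedSequence(seed)
    return [np.random.default_rng(c) for c in ss.spawn(n_cells)]


def simulate_syncytium(cfg: SyncytiumConfig,
                       met_counts: np.ndarray | None = None) -> SimResult:
    """Run the deterministic-given-MET part of the chain: stimulus -> MET
    gating -> membrane voltage -> ensemble Ca2+ open probability.

    ``met_counts`` may be passed to reuse pre-simulated MET realizations
    (e.g. to compare coupled and uncoupled conditions on identical input).
    """
    t_ms, x = make_stimulus(cfg.stimulus)
    dt = cfg.stimulus.dt_us
    if met_counts is None:
        rngs = _met_rngs(cfg.seed, cfg.n_cells)
        met_counts = np.stack(
            [simulate_met_gating(x, cfg.met, r, dt) for r in rngs])
    v = integrate_membrane(met_counts, cfg)
    p_ca = np.stack([ca_open_prob_trace(v[i], cfg.ca, dt)
                     for i in range(cfg.n_cells)])
    return SimResult(config=cfg, t_ms=t_ms, stimulus=x,
                     met_open=np.asarray(met_counts), voltage=v,
                     ca_open_prob=p_ca)


def simulate_conditions(cfg: SyncytiumConfig) -> tuple[SimResult, SimResult]:
    """Simulate the coupled (cfg.rj_mohm) and uncoupled (R_J = inf)
    conditions with identical per-cell MET realizations.  Returns
    (coupled, uncoupled)."""
    t_ms, x = make_stimulus(cfg.stimulus)
    rngs = _met_rngs(cfg.seed, cfg.n_cells)
    met_counts = np.stack(
        [simulate_met_gating(x, cfg.met, r, cfg.stimulus.dt_us) for r in rngs])
    coupled = simulate_syncytium(cfg, met_counts)
    uncoupled = simulate_syncytium(replace(cfg, rj_mohm=RJ_OPEN), met_counts)
    return coupled, uncoupled


def _ca_release_events_vec(
    v: np.ndarray,
    ca: CaChannelModel,
    rules: ReleaseRules,
    rng: np.random.Generator,
    n_realizations: int,
    dt_us: float,
) -> list[np.ndarray]:
    """Release-event times (ms) for many independent single-channel
    realizations along one voltage trace, computed with a vectorized
    run-length scan (memory O(n_realizations))."""
    p_inf = np.asarray(ca_p_inf(v, ca), float)
    a = p_inf * (dt_us / ca.tau_act_us)
    b = (1.0 - p_inf) * (dt_us / ca.tau_act_us)
    min_steps = int(round(rules.min_open_ms * 1e3 / dt_us))
    n = n_realizations
    state = rng.random(n) < p_inf[0]
    run = state.astype(np.int32)
    events: list[list[float]] = [[] for _ in range(n)]
    hit0 = np.flatnonzero(run >= min_steps)  # only if min_steps == 1
    for idx in hit0:
        events[idx].append(0.0)
    for k in range(1, p_inf.size):
        u = rng.random(n)
        state = np.where(state, u >= b[k], u < a[k])
        run = np.where(state, run + 1, 0)
        hits = np.flatnonzero(run == min_steps)
        if hits.size:
            t = k * dt_us / 1e3
            for idx in hits:
                events[idx].append(t)
    return [np.asarray(e) for e in events]


def ap_probability(
    result: SimResult,
    n_realizations: int = 1000,
    window_us: float = 200.0,
    seed: int | None = None,
) -> list[ProbabilityTrace]:
    """AP probability per analysis window for the SGN of each cell.

    Repeats the Ca-channel -> release -> refractoriness chain on the shared
    voltage traces with independent channel seeds; p_ap(w) is the fraction
    of realizations with at least one AP in window w.  Windows tile the
    post-onset analysis interval.
    """
    cfg = result.config
    if n_realizations < 100:
        raise ValueError("n_realizations must be >= 100")
    dt = cfg.stimulus.dt_us
    if window_us % dt != 0:
        raise ValueError("window must be a multiple of dt")
    t0 = cfg.stimulus.onset_discard_ms
    t1 = cfg.stimulus.duration_ms
    edges = np.arange(t0, t1 + 1e-9, window_us / 1e3)
    # distinct spawn key so channel noise never reuses the MET streams
    master = np.random.SeedSequence(
        [cfg.seed if seed is None else seed, 0xCA])
    out = []
    for i, child in enumerate(master.spawn(cfg.n_cells)):
        rng = np.random.default_rng(child)
        evs = _ca_release_events_vec(result.voltage[i], cfg.ca, cfg.release,
                                     rng, n_realizations, dt)
        hit = np.zeros((edges.size - 1, n_realizations), dtype=bool)
        for r, e in enumerate(evs):
            aps = prune_refractory(e, cfg.release)
            aps = aps[(aps >= t0) & (aps < t1)]
            if aps.size:
                w = np.minimum(((aps - t0) * 1e3 / window_us).astype(int),
                               edges.size - 2)
                hit[w, r] = True
        out.append(ProbabilityTrace(window_edges_ms=edges,
                                    p_ap=hit.mean(axis=1),
                                    n_realizations=n_realizations))
    return out


# ---------------------------------------------------------------------------
# correlation summaries
# ---------------------------------------------------------------------------

def lagged_pearson(x: np.ndarray, y: np.ndarray, lag_ms: float,
                   dt_us: float, discard_ms: float = 0.0) -> float:
    """Pearson correlation of x(t) and y(t + lag) over their overlap, with
    the first ``discard_ms`` of the overlap excluded (onset transient)."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    k = int(round(lag_ms * 1e3 / dt_us))
    d = int(round(discard_ms * 1e3 / dt_us))
    if k >= 0:
        xs, ys = x[: x.size - k or None], y[k:]
    else:
        xs, ys = x[-k:], y[: y.size + k or None]
    xs, ys = xs[d:], ys[d:]
    if xs.size < 100:
        raise ValueError("overlap after shift/discard is < 100 samples")
    if np.std(xs) == 0 or np.std(ys) == 0:
        raise UndefinedCorrelationError("zero variance input")
    return float(np.corrcoef(xs, ys)[0, 1])


DEFAULT_LAGS_MS = {"voltage": 0.3, "ca_open_prob": 0.5}


def correlation_summary(
    result: SimResult,
    lags_ms: dict[str, float] | None = None,
) -> CorrelationSummary:
    """Average lag-compensated Pearson correlations per stage.

    ``pairwise`` averages over all unordered cell pairs at zero lag;
    ``vs_stimulus`` averages, over cells, the correlation between the
    stimulus and each cell's trace with the stage's lag compensated
    (default 0.3 ms for voltage, 0.5 ms for the Ca2+ channels).
    """
    cfg = result.config
    if cfg.n_cells < 2:
        raise ValueError("pairwise correlations need >= 2 cells")
    lags = dict(DEFAULT_LAGS_MS)
    if lags_ms:
        lags.update(lags_ms)
    dt = cfg.stimulus.dt_us
    discard = cfg.stimulus.onset_discard_ms
    stages = {"voltage": result.voltage, "ca_open_prob": result.ca_open_prob}
    pairwise: dict[str, float] = {}
    vs_stim: dict[str, float] = {}
    for name, traces in stages.items():
        rs = [lagged_pearson(traces[i], traces[j], 0.0, dt, discard)
              for i in range(cfg.n_cells) for j in range(i + 1, cfg.n_cells)]
        pairwise[name] = float(np.mean(rs))
        rs = [lagged_pearson(result.stimulus, traces[i], lags[name], dt,
                             discard)
              for i in range(cfg.n_cells)]
        vs_stim[name] = float(np.mean(rs))
    return CorrelationSummary(pairwise=pairwise, vs_stimulus=vs_stim,
                              lags_ms=lags)
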