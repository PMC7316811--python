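"""Equivalent-circuit model of voltage-clamped, electrically coupled inner hair cells.

Two IHCs joined by a junctional resistance ``RJ`` and each clamped through a
pipette series resistance form a two-node linear conductance network.  This
module solves that network in steady state, integrates its step transients,
estimates ``RJ`` from paired-recording I_J-V_J data with series/input
resistance compensation, and computes the apparent-capacitance and
slope-conductance readouts expected for an N-cell chain of coupled IHCs.

Unit convention (consistent throughout the package):

=============  ======
voltage        mV
current        nA
conductance    uS   (1/MOhm)
capacitance    pF
time           us   (MOhm * pF = us)
=============  ======

Sign convention: inward membrane current is negative; an amplifier current is
positive when it flows from the pipette into the cell.  The junctional
current ``I_J`` is positive when it flows from cell 1 into cell 2.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "ClampCircuit",
    "PairedIV",
    "EphysSummary",
    "SteadyState",
    "RJEstimate",
    "DegenerateCircuitError",
    "EstimationError",
    "solve_clamp_steady_state",
    "simulate_step_transient",
    "estimate_rj",
    "apparent_capacitance",
    "iv_summary",
    "slope_conductance",
    "window_average",
]

#: Sentinel junctional resistance meaning "not coupled" (open junction).
RJ_OPEN = math.inf


class DegenerateCircuitError(ValueError):
    """The conductance network is singular (no unique node voltages)."""


class EstimationError(RuntimeError):
    """An estimator could not produce a valid result."""


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ClampCircuit:
    """Lumped two-cell dual voltage-clamp circuit.

    Parameters
    ----------
    c1, c2 : float
        Cell capacitances (pF).
    rj : float
        Junctional resistance (MOhm).  ``math.inf`` means uncoupled.
    rm1, rm2 : float
        Cell membrane resistances (GOhm).
    rs1, rs2 : float
        Pipette series resistances (MOhm).
    vh : float
        Holding potential of both amplifiers (mV).
    em : float
        Membrane leak reversal potential (mV).  Defaults to ``vh`` so the
        circuit rests at holding with zero current, as in the recordings the
        model reproduces.
    """

    c1: float = 10.0
    c2: float = 10.0
    rj: float = 10.0
    rm1: float = 1.0
    rm2: float = 1.0
    rs1: float = 10.0
    rs2: float = 10.0
    vh: float = -70.0
    em: float | None = None

    def __post_init__(self) -> None:
        for name in ("c1", "c2", "rj", "rm1", "rm2", "rs1", "rs2"):
            v = getattr(self, name)
            if not (v > 0):  # catches NaN too
                raise ValueError(f"{name} must be > 0, got {v!r}")
        for name in ("vh",):
            if not math.isfinite(getattr(self, name)):
                raise ValueError(f"{name} must be finite")
        if self.em is None:
            object.__setattr__(self, "em", self.vh)
        elif not math.isfinite(self.em):
            raise ValueError("em must be finite")

    # conductances in uS
    @property
    def gj(self) -> float:
        return 0.0 if math.isinf(self.rj) else 1.0 / self.rj

    @property
    def gm1(self) -> float:
        return 1e-3 / self.rm1

    @property
    def gm2(self) -> float:
        return 1e-3 / self.rm2

    @property
    def gs1(self) -> float:
        return 1.0 / self.rs1

    @property
    def gs2(self) -> float:
        return 1.0 / self.rs2


@dataclass(frozen=True)
class PairedIV:
    """Junctional current-voltage relation from a paired recording.

    ``vj`` holds the junctional command-voltage differences (mV) and ``ij``
    the junctional currents (nA) in the convention I_J = g_J * V_J, i.e. a
    coupled pair yields a positive slope.  The current measured at the held
    amplifier is ``-ij`` (the junction dumps charge into the held cell and
    the amplifier removes it).
    """

    vj: np.ndarray
    ij: np.ndarray
    direction: tuple[str, ...] | None = None

    def __post_init__(self) -> None:
        vj = np.asarray(self.vj, dtype=float)
        ij = np.asarray(self.ij, dtype=float)
        if vj.shape != ij.shape or vj.ndim != 1:
            raise ValueError("vj and ij must be 1-D arrays of equal length")
        object.__setattr__(self, "vj", vj)
        object.__setattr__(self, "ij", ij)


@dataclass(frozen=True)
class EphysSummary:
    """Whole-cell readouts: maximal Ca2+ current, resting current,
    apparent capacitance and slope conductance(s)."""

    icamax_pA: float | None = None
    irest_pA: float | None = None
    cm_app_pF: float | None = None
    gm_nS: dict[float, float] = field(default_factory=dict)


@dataclass(frozen=True)
class SteadyState:
    v1: float
    v2: float
    i1: float
    i2: float
    ij: float


@dataclass(frozen=True)
class RJEstimate:
    rj_hat: float          # MOhm; inf => classified non-coupled
    rj_apparent: float     # MOhm; 1 / raw I_J-V_J slope
    slope_nS: float        # raw least-squares slope of I_J vs V_J, in nS
    coupled: bool


# ---------------------------------------------------------------------------
# steady state and transient
# ---------------------------------------------------------------------------

def solve_clamp_steady_state(
    circuit: ClampCircuit, command1: float, command2: float
) -> SteadyState:
    """Solve the two-node network for amplifier commands ``command1/2`` (mV).

    Node balance for cell i (conductances in uS, currents in nA):

        g_Si (cmd_i - V_i) = g_Mi (V_i - E_M) + g_J (V_i - V_j)

    Returns the node voltages, amplifier currents I_i = g_Si (cmd_i - V_i)
    and the junctional current I_J = g_J (V_1 - V_2).
    """
    gs1, gs2 = circuit.gs1, circuit.gs2
    gm1, gm2 = circuit.gm1, circuit.gm2
    gj, em = circuit.gj, circuit.em

    a = np.array(
        [[gs1 + gm1 + gj, -gj],
         [-gj, gs2 + gm2 + gj]]
    )
    b = np.array([gs1 * command1 + gm1 * em, gs2 * command2 + gm2 * em])
    if abs(np.linalg.det(a)) < 1e-300:
        raise DegenerateCircuitError("all conductances vanish; network singular")
    v1, v2 = np.linalg.solve(a, b)
    return SteadyState(
        v1=v1,
        v2=v2,
        i1=gs1 * (command1 - v1),
        i2=gs2 * (command2 - v2),
        ij=gj * (v1 - v2),
    )


def _chain_matrices(
    n: int, c: float, gj: float, gm: float, gs: float
) -> tuple[np.ndarray, np.ndarray]:
    """Conductance matrix G (uS) and capacitance vector (pF) for an N-cell
    chain with the clamp attached to cell 1 only."""
    g = np.zeros((n, n))
    for i in range(n):
        g[i, i] += gm
        if i + 1 < n:
            g[i, i] += gj
            g[i + 1, i + 1] += gj
            g[i, i + 1] -= gj
            g[i + 1, i] -= gj
    g[0, 0] += gs
    caps = np.full(n, c)
    return g, caps


def simulate_step_transient(
    circuit: ClampCircuit,
    step_mV: float,
    t_on_ms: float = 1.0,
    dt_us: float = 1.0,
    duration_ms: float = 10.0,
    stepped_cell: int = 1,
) -> dict[str, np.ndarray]:
    """Integrate the dual-clamp transient for a command step on one cell.

    The stepped amplifier jumps from ``vh`` to ``vh + step_mV`` at
    ``t_on_ms``; the other amplifier stays at ``vh``.  Integration uses the
    trapezoidal (Crank-Nicolson) rule, unconditionally stable for this stiff
    linear system.  Returns a dict with keys ``t_ms, v1, v2, i1, i2, ij``.
    """
    if stepped_cell not in (1, 2):
        raise ValueError("stepped_cell must be 1 or 2")
    n_steps = int(round(duration_ms * 1e3 / dt_us))
    t_us = np.arange(n_steps + 1) * dt_us
    cmd1 = np.full(n_steps + 1, circuit.vh)
    cmd2 = np.full(n_steps + 1, circuit.vh)
    on = t_us >= t_on_ms * 1e3
    (cmd1 if stepped_cell == 1 else cmd2)[on] += step_mV

    gs = np.array([circuit.gs1, circuit.gs2])
    gm = np.array([circuit.gm1, circuit.gm2])
    gj = circuit.gj
    caps = np.array([circuit.c1, circuit.c2])

    g = np.array(
        [[gs[0] + gm[0] + gj, -gj],
         [-gj, gs[1] + gm[1] + gj]]
    )
    m = np.diag(caps)
    a_minus = m / dt_us - g / 2.0
    a_plus = m / dt_us + g / 2.0
    a_plus_inv = np.linalg.inv(a_plus)

    v = np.empty((n_steps + 1, 2))
    # start at rest: both commands at vh, membrane at em-balanced steady state
    ss0 = solve_clamp_steady_state(circuit, circuit.vh, circuit.vh)
    v[0] = (ss0.v1, ss0.v2)
    src = np.stack([gs[0] * cmd1 + gm[0] * circuit.em,
                    gs[1] * cmd2 + gm[1] * circuit.em], axis=1)
    for k in range(n_steps):
        rhs = a_minus @ v[k] + 0.5 * (src[k] + src[k + 1])
        v[k + 1] = a_plus_inv @ rhs
    if not np.all(np.isfinite(v)):
        raise EstimationError("transient integration diverged; reduce dt_us")

    i1 = gs[0] * (cmd1 - v[:, 0])
    i2 = gs[1] * (cmd2 - v[:, 1])
    ij = gj * (v[:, 0] - v[:, 1])
    return {"t_ms": t_us / 1e3, "v1": v[:, 0], "v2": v[:, 1],
            "i1": i1, "i2": i2, "ij": ij}


# ---------------------------------------------------------------------------
# junctional-resistance estimation
# ---------------------------------------------------------------------------

def predicted_ij_slope(rj: float, rs1: float, rs2: float,
                       rm1: float, rm2: float) -> float:
    """Slope of the true junctional current I_J versus the command difference
    V_J for the two-node network (uS).

    With p = (g_S1+g_M1)(g_S2+g_M2) and s = g_S1+g_M1+g_S2+g_M2:

        dI_J/dV_J = g_S1 g_S2 g_J / (p + s g_J)
    """
    gs1, gs2 = 1.0 / rs1, 1.0 / rs2
    gm1, gm2 = 1e-3 / rm1, 1e-3 / rm2
    gj = 0.0 if math.isinf(rj) else 1.0 / rj
    p = (gs1 + gm1) * (gs2 + gm2)
    s = gs1 + gm1 + gs2 + gm2
    return gs1 * gs2 * gj / (p + s * gj)


def estimate_rj(
    data: PairedIV,
    rs1: float = 10.0,
    rs2: float = 10.0,
    rm1: float = 1.0,
    rm2: float = 1.0,
    noise_floor_nS: float = 1.0,
) -> RJEstimate:
    """Estimate the junctional resistance from an I_J-V_J relation.

    ``rj_apparent`` is the naive estimate 1/slope of the through-origin
    least-squares fit of I_J on V_J.  ``rj_hat`` compensates for the series
    and membrane (cell input) resistances by inverting the full two-node
    network: the observed slope m satisfies m = g1 g2 gJ / (p + s gJ)
    (see :func:`predicted_ij_slope`), which solves in closed form for

        g_J = m p / (g_S1 g_S2 - m s).

    A non-positive slope, a slope below ``noise_floor_nS``, or a slope at or
    above the theoretical maximum g_S1 g_S2 / s (which no finite R_J can
    produce) classifies the pair as non-coupled (``rj_hat = inf``).
    ``rj_hat <= rj_apparent`` always: compensation removes the bias of the
    series/shunt pathway.
    """
    vj, ij = data.vj, data.ij
    if np.unique(vj).size < 2:
        raise ValueError("need >= 2 distinct V_J values")
    denom = float(np.dot(vj, vj))
    slope = float(np.dot(vj, ij)) / denom  # uS, fit through the origin

    gs1, gs2 = 1.0 / rs1, 1.0 / rs2
    gm1, gm2 = 1e-3 / rm1, 1e-3 / rm2
    p = (gs1 + gm1) * (gs2 + gm2)
    s = gs1 + gm1 + gs2 + gm2
    slope_max = gs1 * gs2 / s

    if slope <= 0 or slope * 1e3 < noise_floor_nS:
        return RJEstimate(rj_hat=math.inf, rj_apparent=math.inf,
                          slope_nS=slope * 1e3, coupled=False)
    rj_apparent = 1.0 / slope
    if slope >= slope_max:
        # slope exceeds what a zero junctional resistance would give:
        # treat as perfectly fused (R_J -> 0), not estimable from this fit
        raise EstimationError(
            f"fitted slope {slope:.4g} uS >= network maximum {slope_max:.4g} uS"
        )
    gj = slope * p / (gs1 * gs2 - slope * s)
    return RJEstimate(rj_hat=1.0 / gj, rj_apparent=rj_apparent,
                      slope_nS=slope * 1e3, coupled=True)


# ---------------------------------------------------------------------------
# apparent capacitance of an N-cell chain
# ---------------------------------------------------------------------------

def apparent_capacitance(
    n_cells: int,
    c_pF: float = 10.0,
    rj: float = 25.0,
    rs: float = 10.0,
    rm: float = 1.0,
    dt_us: float = 0.5,
    step_mV: float = 5.0,
    duration_ms: float = 25.0,
) -> float:
    """Apparent membrane capacitance seen by a single clamp on cell 1 of an
    R_J-chained N-cell syncytium (pF).

    A small command step ``step_mV`` is applied through the series
    resistance; the transient of the amplifier current above its steady-state
    level is integrated (trapezoidal rule) to the delivered capacitive charge
    Q.  Interpreting the recording with the standard one-compartment model
    (unknown C_x and leak g_x behind a known R_S) gives

        g_x     = g_S I_ss / (g_S dV_cmd - I_ss)
        C_m,app = Q (g_S + g_x) / (g_S dV1_ss)

    which returns exactly C for a single cell and exactly N*C in the fused
    (R_J -> 0) limit; intermediate R_J yields C < C_m,app < N*C.
    """
    if n_cells < 1:
        raise ValueError("n_cells must be >= 1")
    gs, gm = 1.0 / rs, 1e-3 / rm
    gj = 0.0 if math.isinf(rj) else 1.0 / rj
    g, caps = _chain_matrices(n_cells, c_pF, gj, gm, gs)

    # work in deviations from rest (em = command baseline), so v0 = 0
    b = np.zeros(n_cells)
    b[0] = gs * step_mV
    v_inf = np.linalg.solve(g, b)

    n_steps = int(round(duration_ms * 1e3 / dt_us))
    m = np.diag(caps)
    a_minus = m / dt_us - g / 2.0
    a_plus_inv = np.linalg.inv(m / dt_us + g / 2.0)
    v = np.zeros(n_cells)
    i_ss = gs * (step_mV - v_inf[0])
    q = 0.0  # nA*us = fC
    i_prev = gs * step_mV - i_ss
    for _ in range(n_steps):
        v = a_plus_inv @ (a_minus @ v + b)
        i_now = gs * (step_mV - v[0]) - i_ss
        q += 0.5 * (i_prev + i_now) * dt_us
        i_prev = i_now
    if i_prev > 1e-3 * gs * step_mV:
        raise EstimationError("transient did not decay; increase duration_ms")

    dv1_ss = v_inf[0]
    i_ss_total = gs * (step_mV - dv1_ss)
    gx = gs * i_ss_total / (gs * step_mV - i_ss_total)
    cm_app = q * (gs + gx) / (gs * dv1_ss)  # fC / mV = pF
    if cm_app <= 0:
        raise EstimationError("non-positive capacitance estimate")
    return float(cm_app)


# ---------------------------------------------------------------------------
# IV summaries
# ---------------------------------------------------------------------------

def window_average(t_ms: np.ndarray, i_pA: np.ndarray,
                   window_ms: tuple[float, float] = (3.0, 8.0)) -> float:
    """Average a current trace over a time window after depolarization onset
    (the convention used to score evoked Ca2+ currents)."""
    t_ms = np.asarray(t_ms, float)
    i_pA = np.asarray(i_pA, float)
    mask = (t_ms >= window_ms[0]) & (t_ms <= window_ms[1])
    if not mask.any():
        raise ValueError("window contains no samples")
    return float(i_pA[mask].mean())


def iv_summary(v_mV: np.ndarray, i_pA: np.ndarray, v_hold: float) -> EphysSummary:
    """Score an IV relation: resting current at the holding potential and the
    maximal (most negative) window-averaged inward current.

    ``i_pA`` are already window-averaged currents per step potential (use
    :func:`window_average` to reduce traces first).
    """
    v = np.asarray(v_mV, float)
    i = np.asarray(i_pA, float)
    if v.size == 0 or v.shape != i.shape:
        raise ValueError("empty or mismatched IV input")
    order = np.argsort(v)
    v, i = v[order], i[order]
    if not (v[0] <= v_hold <= v[-1]):
        raise ValueError("holding potential outside sampled IV range")
    irest = float(np.interp(v_hold, v, i))
    icamax = float(i.min())
    return EphysSummary(icamax_pA=icamax, irest_pA=irest)


def slope_conductance(v_mV: np.ndarray, i_pA: np.ndarray,
                      at_voltages: list[float] | np.ndarray) -> dict[float, float]:
    """Central-difference membrane slope conductance G_m = dI/dV (nS) at the
    requested voltages.  Requires each voltage to be interior to the sampled
    range."""
    v = np.asarray(v_mV, float)
    i = np.asarray(i_pA, float)
    order = np.argsort(v)
    v, i = v[order], i[order]
    if v.size < 3:
        raise ValueError("need >= 3 IV samples for a central difference")
    grad = np.gradient(i, v)  # pA/mV = nS
    out: dict[float, float] = {}
    for v0 in np.atleast_1d(at_voltages):
        v0 = float(v0)
        if not (v[0] < v0 < v[-1]):
            raise ValueError(f"voltage {v0} mV outside sampled interior range")
        out[v0] = float(np.interp(v0, v, grad))
    return out
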