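"""Synthetic inputs with known ground truth for the analysis modules.

Since no raw recordings are distributed, every input the estimators consume
is generated here from the same forward models the estimators invert:
paired-recording I_J-V_J data from the two-cell clamp circuit, fluorescence-
voltage traces from the FV relation, and small image stacks with Gaussian
fluorescence hotspots for the dF/F pipeline.  All generators are pure
functions of (parameters, seed): the same seed regenerates bit-identical
data.  Noise is additive i.i.d. Gaussian throughout (Student-t noise is
available as an option for heavier tails).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .coupling_circuit import ClampCircuit, solve_clamp_steady_state
from .imaging_fv import FVModel, fv_curve

__all__ = [
    "SyntheticPairedRecording",
    "SyntheticFVTrace",
    "SyntheticHotspotMovie",
    "HotspotSpec",
    "gen_paired_recording",
    "gen_fv_trace",
    "gen_hotspot_movie",
]


def _noise(rng: np.random.Generator, sd: float, size,
           dist: str = "gaussian", df: float = 3.0) -> np.ndarray:
    if sd < 0:
        raise ValueError("noise_sd must be >= 0")
    if dist == "gaussian":
        return rng.normal(0.0, sd, size)
    if dist == "student_t":
        raw = rng.standard_t(df, size)
        return sd * raw / math.sqrt(df / (df - 2.0))
    raise ValueError(f"unknown noise distribution {dist!r}")


# ---------------------------------------------------------------------------
# paired voltage-clamp recordings
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SyntheticPairedRecording:
    """Junctional-current measurements at the held (non-stepped) amplifier.

    ``ij_measured`` is the baseline-subtracted current at the held
    amplifier in nA: a positive command difference on the stepped cell
    produces a *negative* held-amplifier current (the clamp removes the
    charge the junction injects).
    """

    vj_steps: np.ndarray      # mV, command difference (stepped - held)
    ij_measured: np.ndarray   # nA, held-amplifier current change
    truth: ClampCircuit
    noise_sd_pA: float
    seed: int

    def __post_init__(self) -> None:
        if len(self.vj_steps) != len(self.ij_measured):
            raise ValueError("vj_steps and ij_measured lengths differ")

    def to_paired_iv(self):
        """Convert to a :class:`~ihcsync.coupling_circuit.PairedIV` in the
        junctional convention I_J = g_J V_J (sign-flipped held current)."""
        from .coupling_circuit import PairedIV
        return PairedIV(vj=self.vj_steps, ij=-self.ij_measured)

    def to_csv(self, path) -> None:
        pd.DataFrame({"vj_mV": self.vj_steps,
                      "ij_nA": self.ij_measured}).to_csv(path, index=False)


def gen_paired_recording(
    circuit: ClampCircuit,
    vj_steps,
    noise_sd_pA: float = 0.0,
    seed: int = 0,
    noise_dist: str = "gaussian",
) -> SyntheticPairedRecording:
    """Forward-simulate a paired recording: cell 1 is stepped by each value
    of ``vj_steps`` from holding while cell 2 stays held; the steady-state
    current change at the held amplifier plus Gaussian noise is recorded."""
    vj = np.asarray(vj_steps, float)
    if vj.size == 0:
        raise ValueError("vj_steps must be nonempty")
    if not np.all(np.isfinite(vj)):
        raise ValueError("non-finite step value")
    base = solve_clamp_steady_state(circuit, circuit.vh, circuit.vh).i2
    ij = np.array([
        solve_clamp_steady_state(circuit, circuit.vh + dv, circuit.vh).i2
        - base
        for dv in vj
    ])
    rng = np.random.default_rng(seed)
    ij = ij + _noise(rng, noise_sd_pA * 1e-3, ij.shape, noise_dist)
    return SyntheticPairedRecording(vj_steps=vj, ij_measured=ij,
                                    truth=circuit, noise_sd_pA=noise_sd_pA,
                                    seed=seed)


# ---------------------------------------------------------------------------
# fluorescence-voltage traces
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SyntheticFVTrace:
    voltages: np.ndarray      # mV, strictly increasing
    fluorescence: np.ndarray  # a.u.
    truth: FVModel
    noise_sd: float
    seed: int

    def to_csv(self, path) -> None:
        pd.DataFrame({"voltage_mV": self.voltages,
                      "F_au": self.fluorescence}).to_csv(path, index=False)


def gen_fv_trace(
    truth: FVModel,
    voltages,
    noise_sd: float = 0.0,
    seed: int = 0,
    noise_dist: str = "gaussian",
) -> SyntheticFVTrace:
    """Evaluate the FV relation at ``voltages`` (strictly increasing ramp
    samples) and add i.i.d. noise."""
    v = np.asarray(voltages, float)
    if v.size and np.any(np.diff(v) <= 0):
        raise ValueError("voltages must be strictly increasing")
    f = np.asarray(fv_curve(v, truth), float)
    rng = np.random.default_rng(seed)
    f = f + _noise(rng, noise_sd, f.shape, noise_dist)
    return SyntheticFVTrace(voltages=v, fluorescence=f, truth=truth,
                            noise_sd=noise_sd, seed=seed)


# ---------------------------------------------------------------------------
# hotspot movies
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class HotspotSpec:
    """One fluorescence hotspot: isotropic 2-D Gaussian profile added to the
    depolarized frames."""

    row: int
    col: int
    amplitude: float
    sigma_px: float = 1.0


@dataclass(frozen=True)
class SyntheticHotspotMovie:
    frames: np.ndarray                   # (time, rows, cols), >= 0
    spot_centers: tuple[tuple[int, int], ...]
    spot_amplitudes: tuple[float, ...]
    baseline: float
    noise_sd: float
    rest_frames: np.ndarray              # frame indices at rest
    depol_frames: np.ndarray             # frame indices during depolarization
    seed: int


def gen_hotspot_movie(
    n_rest: int = 10,
    n_depol: int = 6,
    shape: tuple[int, int] = (16, 16),
    spots: list[HotspotSpec] | None = None,
    baseline: float = 100.0,
    noise_sd: float = 1.0,
    seed: int = 0,
) -> SyntheticHotspotMovie:
    """Simulate a hotspot image stack: ``n_rest`` rest frames (baseline +
    noise) followed by ``n_depol`` depolarized frames with each spot's
    Gaussian profile added.  Intensities are clipped at zero."""
    if n_rest < 10 or n_depol < 6:
        raise ValueError("need >= 10 rest and >= 6 depolarized frames")
    spots = spots or []
    nrow, ncol = shape
    for s in spots:
        if not (0 <= s.row < nrow and 0 <= s.col < ncol):
            raise ValueError(f"spot center {(s.row, s.col)} outside frame")
    rows = np.arange(nrow)[:, None]
    cols = np.arange(ncol)[None, :]
    spot_img = np.zeros(shape)
    for s in spots:
        spot_img += s.amplitude * np.exp(
            -((rows - s.row) ** 2 + (cols - s.col) ** 2)
            / (2.0 * s.sigma_px ** 2))
    n_frames = n_rest + n_depol
    rng = np.random.default_rng(seed)
    frames = baseline + _noise(rng, noise_sd, (n_frames, nrow, ncol))
    frames[n_rest:] += spot_img
    frames = np.clip(frames, 0.0, None)
    return SyntheticHotspotMovie(
        frames=frames,
        spot_centers=tuple((s.row, s.col) for s in spots),
        spot_amplitudes=tuple(s.amplitude for s in spots),
        baseline=baseline,
        noise_sd=noise_sd,
        rest_frames=np.arange(n_rest),
        depol_frames=np.arange(n_rest, n_frames),
        seed=seed,
    )
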