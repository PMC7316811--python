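"""Presynaptic Ca2+-imaging analysis: dye normalization, dF/F hotspots,
interleaved-ramp merging, fluorescence-voltage (FV) fitting and fractional
activation.

The FV relation of a presynaptic Ca2+ hotspot under a voltage ramp is
modelled as the product of a Boltzmann activation and the linear Ca2+
driving force:

    F(V) = F0 + fv (Vr - V) / (1 + exp((Vh - V)/k))

with F0 the fluorescence at rest, fv the slope factor of the driving-force
line, Vr the Ca2+ reversal potential (measured from the whole-cell current,
never fitted), Vh the half-activation voltage and k the voltage sensitivity.
Dividing the fit by the extrapolated fv line yields the fractional
activation curve, which is refit with a Boltzmann to report (Vh, k).

Pixel coordinates are 0-based (row, col); frame indices are 0-based.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.optimize import curve_fit

__all__ = [
    "FVModel",
    "RampProtocol",
    "HotspotMeasurement",
    "FitError",
    "fv_curve",
    "normalize_dye_timeseries",
    "compute_dF",
    "hotspot_filter",
    "merge_interleaved_ramps",
    "fit_fv",
    "fractional_activation",
    "boltzmann",
]


class FitError(RuntimeError):
    """A nonlinear fit did not converge or was ill-posed."""


# ---------------------------------------------------------------------------
# model
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class FVModel:
    """Parameter set of the fluorescence-voltage relation."""

    f0: float        # a.u., fluorescence at rest
    fv: float        # a.u./mV, driving-force slope factor
    vr: float        # mV, Ca2+ reversal potential (input, not fitted)
    vh: float        # mV, half-activation voltage
    k: float         # mV, voltage sensitivity

    def __post_init__(self) -> None:
        if self.k == 0 or not math.isfinite(self.k):
            raise ValueError("k must be nonzero and finite")
        if not math.isfinite(self.fv):
            raise ValueError("fv must be finite")


def boltzmann(v: np.ndarray | float, vh: float, k: float) -> np.ndarray | float:
    return 1.0 / (1.0 + np.exp((vh - np.asarray(v, float)) / k))


def fv_curve(v: np.ndarray | float, model: FVModel) -> np.ndarray | float:
    """Evaluate F(V) = F0 + fv (Vr - V) * boltzmann(V; Vh, k)."""
    v = np.asarray(v, float)
    return model.f0 + model.fv * (model.vr - v) * boltzmann(v, model.vh,
                                                            model.k)


@dataclass(frozen=True)
class RampProtocol:
    """Voltage-ramp stimulus, applied twice with a time shift so the two
    acquisitions interleave on the voltage axis."""

    start_mV: float = -87.0
    stop_mV: float = 63.0
    duration_ms: float = 150.0
    shift_ms: float = 5.0
    frame_rate_hz: float = 100.0

    @property
    def rate_mV_per_ms(self) -> float:
        return (self.stop_mV - self.start_mV) / self.duration_ms

    @property
    def frame_period_ms(self) -> float:
        return 1e3 / self.frame_rate_hz

    @property
    def n_frames(self) -> int:
        return int(self.duration_ms / self.frame_period_ms)

    def frame_voltages(self, shifted: bool = False) -> np.ndarray:
        """Command voltage at each acquired frame of one ramp."""
        offset = self.shift_ms if shifted else 0.0
        t = offset + np.arange(self.n_frames) * self.frame_period_ms
        return self.start_mV + self.rate_mV_per_ms * t


@dataclass(frozen=True)
class HotspotMeasurement:
    center: tuple[int, int]       # (row, col), 0-based
    dF: np.ndarray                # per-frame dF (a.u.), all frames
    dF_max: float                 # a.u.
    rest_mean: float              # mean of dF over rest frames
    rest_sd: float                # SD of dF over rest frames
    passes_criterion: bool


# ---------------------------------------------------------------------------
# dye time-series normalization
# ---------------------------------------------------------------------------

def normalize_dye_timeseries(
    stack: np.ndarray,
    background_mask: np.ndarray,
    reference_mask: np.ndarray,
    cell_masks: list[np.ndarray] | None = None,
) -> np.ndarray:
    """Background-subtract and normalize per-cell dye intensity traces.

    Each frame's mean background (extracellular) intensity is subtracted,
    and traces are divided by the maximum background-subtracted intensity of
    the reference (patched) cell, which therefore peaks at exactly 1.
    Returns an array (n_cells, n_frames); ``cell_masks`` defaults to the
    reference cell alone.  Normalizing an already-normalized stack is the
    identity.
    """
    stack = np.asarray(stack, float)
    if stack.ndim != 3:
        raise ValueError("stack must be (time, rows, cols)")
    if cell_masks is None:
        cell_masks = [reference_mask]
    bg = stack[:, background_mask].mean(axis=1)
    ref = stack[:, reference_mask].mean(axis=1) - bg
    scale = ref.max()
    if scale <= 0:
        raise ValueError("zero dynamic range: reference never exceeds "
                         "background")
    out = np.stack([(stack[:, m].mean(axis=1) - bg) / scale
                    for m in cell_masks])
    return out


# ---------------------------------------------------------------------------
# dF/F hotspot pipeline
# ---------------------------------------------------------------------------

def _box3_mean(img: np.ndarray, center: tuple[int, int]) -> float:
    r, c = center
    return float(img[r - 1: r + 2, c - 1: c + 2].mean())


def compute_dF(
    frames: np.ndarray,
    rest_frames: np.ndarray,
    depol_frames: np.ndarray,
    center: tuple[int, int] | None = None,
    n_rest_avg: int = 10,
    n_depol_avg: int = 6,
    n_peak_avg: int = 5,
) -> HotspotMeasurement:
    """Score one fluorescence hotspot in an image stack.

    * F0 image: average of ``n_rest_avg`` rest frames.
    * Depolarized image: average of ``n_depol_avg`` depolarized frames;
      their difference is the mean dF image.
    * The 3x3 analysis square is centred on the pixel of greatest mean
      increase (ties resolved first-in-row-major) unless ``center`` is
      given; the centre is clipped to keep the square inside the frame.
    * dF per frame is the 3x3 average minus the 3x3 average of F0.
    * dF_max is the mean of ``n_peak_avg`` consecutive per-frame dF values
      centred on the peak frame of the depolarized sequence (the Ca2+-influx
      peak); the window is shifted, never shrunk, at the sequence edges.
    * Rest statistics are the mean and SD of dF over the rest frames, used
      by :func:`hotspot_filter`.
    """
    frames = np.asarray(frames, float)
    rest_frames = np.asarray(rest_frames, int)
    depol_frames = np.asarray(depol_frames, int)
    if rest_frames.size < n_rest_avg or depol_frames.size < n_depol_avg:
        raise ValueError(
            f"protocol needs >= {n_rest_avg} rest and >= {n_depol_avg} "
            "depolarized frames")
    f0_img = frames[rest_frames[:n_rest_avg]].mean(axis=0)
    depol_img = frames[depol_frames[:n_depol_avg]].mean(axis=0)
    d_img = depol_img - f0_img

    nrow, ncol = d_img.shape
    if center is None:
        flat = int(np.argmax(d_img))
        r, c = divmod(flat, ncol)
        r = min(max(r, 1), nrow - 2)
        c = min(max(c, 1), ncol - 2)
        center = (r, c)
    else:
        r, c = center
        if not (1 <= r <= nrow - 2 and 1 <= c <= ncol - 2):
            raise ValueError("center must be >= 1 pixel from the border")

    f0_box = _box3_mean(f0_img, center)
    dF = np.array([_box3_mean(frames[k], center) - f0_box
                   for k in range(frames.shape[0])])

    depol_dF = dF[depol_frames]
    peak = int(np.argmax(depol_dF))
    half = n_peak_avg // 2
    lo = min(max(peak - half, 0), max(depol_dF.size - n_peak_avg, 0))
    dF_max = float(depol_dF[lo: lo + n_peak_avg].mean())

    rest_dF = dF[rest_frames]
    rest_mean = float(rest_dF.mean())
    rest_sd = float(rest_dF.std(ddof=1))
    return HotspotMeasurement(
        center=center, dF=dF, dF_max=dF_max, rest_mean=rest_mean,
        rest_sd=rest_sd,
        passes_criterion=dF_max > rest_mean + 2.0 * rest_sd,
    )


def hotspot_filter(m: HotspotMeasurement) -> bool:
    """Synaptic Ca2+-signal criterion: the maximal fluorescence increment
    must exceed the resting level by more than 2 standard deviations."""
    return m.dF_max > m.rest_mean + 2.0 * m.rest_sd


# ---------------------------------------------------------------------------
# interleaved-ramp merging
# ---------------------------------------------------------------------------

def merge_interleaved_ramps(
    trace1: np.ndarray,
    trace2: np.ndarray,
    protocol: RampProtocol = RampProtocol(),
) -> tuple[np.ndarray, np.ndarray]:
    """Merge two fluorescence acquisitions of the same ramp, the second
    time-shifted so its frame voltages interleave the first (e.g. 10 mV
    frame spacing per ramp, 5 mV after merging).  Returns voltage-sorted
    (voltages, fluorescence)."""
    t1 = np.asarray(trace1, float)
    t2 = np.asarray(trace2, float)
    v1 = protocol.frame_voltages(shifted=False)
    v2 = protocol.frame_voltages(shifted=True)
    if t1.size != v1.size or t2.size != v2.size:
        raise ValueError(
            f"trace lengths ({t1.size}, {t2.size}) do not match the "
            f"protocol frame count {v1.size}")
    spacing = protocol.rate_mV_per_ms * protocol.frame_period_ms
    shift = protocol.rate_mV_per_ms * protocol.shift_ms
    if not math.isclose(shift * 2.0, spacing, rel_tol=1e-9):
        raise ValueError("shift does not interleave the frame grid")
    v = np.concatenate([v1, v2])
    f = np.concatenate([t1, t2])
    order = np.argsort(v, kind="stable")
    return v[order], f[order]


# ---------------------------------------------------------------------------
# FV fitting and fractional activation
# ---------------------------------------------------------------------------

def fit_fv(
    voltages: np.ndarray,
    fluorescence: np.ndarray,
    vr: float,
    fv_range_mV: tuple[float, float] = (3.0, 23.0),
    initial_guess: dict[str, float] | None = None,
) -> tuple[FVModel, dict[str, float]]:
    """Two-stage fit of the FV relation with the reversal potential fixed.

    Stage 1 estimates the slope factor fv from a least-squares line on the
    samples with V in ``fv_range_mV`` (where the channels are essentially
    fully activated and F declines with the driving force).  Stage 2 refines
    (F0, fv, Vh, k) by nonlinear least squares with Vr held fixed, fv
    initialized from stage 1 and (F0, Vh, k) from simple heuristics unless
    given in ``initial_guess``.  Returns the model and diagnostics
    (residual norm, fv of stage 1).
    """
    v = np.asarray(voltages, float)
    f = np.asarray(fluorescence, float)
    if v.shape != f.shape or v.ndim != 1:
        raise ValueError("voltages and fluorescence must be equal-length 1-D")
    lo, hi = fv_range_mV
    line_mask = (v >= lo) & (v <= hi)
    if line_mask.sum() < 2:
        raise ValueError("insufficient samples in the fv fitting range")
    if v.min() >= lo:
        raise ValueError("samples must also cover the sub-threshold range")
    slope, _ = np.polyfit(v[line_mask], f[line_mask], 1)
    fv0 = -slope  # F ~ F0 + fv (Vr - V) at full activation

    guess = {"f0": float(np.median(f[v <= v.min() + 10.0])),
             "vh": -25.0, "k": 8.0, "fv": fv0}
    if initial_guess:
        guess.update(initial_guess)

    def model(vv, f0, fv, vh, k):
        return f0 + fv * (vr - vv) / (1.0 + np.exp((vh - vv) / k))

    try:
        popt, _ = curve_fit(
            model, v, f,
            p0=[guess["f0"], guess["fv"], guess["vh"], guess["k"]],
            bounds=([-np.inf, -np.inf, -150.0, 1e-3],
                    [np.inf, np.inf, 100.0, 100.0]),
            maxfev=20000,
        )
    except RuntimeError as exc:
        raise FitError(f"FV fit did not converge: {exc}") from exc
    f0_hat, fv_hat, vh_hat, k_hat = popt
    fit = FVModel(f0=float(f0_hat), fv=float(fv_hat), vr=float(vr),
                  vh=float(vh_hat), k=float(k_hat))
    resid = f - fv_curve(v, fit)
    diag = {"residual_norm": float(np.linalg.norm(resid)),
            "fv_stage1": float(fv0)}
    return fit, diag


def fractional_activation(
    fit: FVModel,
    voltages: np.ndarray,
    fluorescence: np.ndarray | None = None,
    vr_exclusion_k: float = 3.0,
) -> tuple[np.ndarray, np.ndarray, float, float]:
    """Fractional activation curve and its Boltzmann parameters.

    The FV data (or the fit itself if ``fluorescence`` is None) is divided
    by the extrapolated driving-force line:

        activation(V) = (F(V) - F0) / (fv (Vr - V))

    Voltages within ``vr_exclusion_k * k`` of Vr are excluded (the line
    crosses zero there and the ratio blows up).  Returns
    (voltages_kept, activation, Vh, k) with (Vh, k) from a Boltzmann fit.
    """
    v = np.asarray(voltages, float)
    f = fv_curve(v, fit) if fluorescence is None \
        else np.asarray(fluorescence, float)
    keep = np.abs(v - fit.vr) >= vr_exclusion_k * abs(fit.k)
    v_k, f_k = v[keep], f[keep]
    if v_k.size < 4:
        raise ValueError("too few samples outside the Vr exclusion window")
    act = (f_k - fit.f0) / (fit.fv * (fit.vr - v_k))
    try:
        popt, _ = curve_fit(boltzmann, v_k, act, p0=[fit.vh, abs(fit.k)],
                            bounds=([-150.0, 1e-3], [100.0, 100.0]),
                            maxfev=20000)
    except RuntimeError as exc:
        raise FitError(f"Boltzmann fit did not converge: {exc}") from exc
    vh_hat, k_hat = popt
    return v_k, act, float(vh_hat), float(k_hat)
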