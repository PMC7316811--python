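"""Tonotopic span arithmetic for pools of inner hair cells.

The cochlea maps sound frequency to position (tonotopy).  Given a species
place-frequency map and the total IHC count, these helpers express the span
of an n-IHC pool (e.g. an electrically coupled mini-syncytium) as a fraction
of cochlear length, in octaves, and in cents (1 octave = 1200 cents), to
compare against psychophysical and physiological frequency-resolution
estimates.

Two map forms are supported:

* ``log_linear`` - frequency is exponential in place, i.e. a fixed number of
  octaves per unit length (``total_octaves`` over the whole cochlea);
* ``greenwood`` - the Greenwood function f(x) = A (10^(a x) - k) with x the
  distance from the apex in mm.

Positions are measured from the apex.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

__all__ = [
    "PlaceFrequencyMap",
    "SpanResult",
    "mouse_map",
    "human_map",
    "length_fraction",
    "octave_span",
    "cents_per_ihc",
    "syncytium_resolution_cents",
    "place_to_freq",
    "freq_to_place",
    "span_result",
]


@dataclass(frozen=True)
class PlaceFrequencyMap:
    """Species tonotopic map.

    For ``form="log_linear"`` supply ``total_octaves`` (and optionally
    ``f_apex_hz``); for ``form="greenwood"`` supply the constants ``A``
    (Hz), ``a`` (1/mm) and ``k`` (dimensionless).
    """

    species: str
    total_length_mm: float
    n_ihc_total: int
    form: str = "log_linear"
    total_octaves: float | None = None
    f_apex_hz: float | None = None
    greenwood_A: float | None = None
    greenwood_a: float | None = None
    greenwood_k: float | None = None

    def __post_init__(self) -> None:
        if self.total_length_mm <= 0 or self.n_ihc_total < 1:
            raise ValueError("invalid map geometry")
        if self.form == "log_linear":
            if self.total_octaves is None or self.total_octaves <= 0:
                raise ValueError("log_linear map needs total_octaves > 0")
        elif self.form == "greenwood":
            if None in (self.greenwood_A, self.greenwood_a, self.greenwood_k):
                raise ValueError("greenwood map needs A, a, k")
        else:
            raise ValueError(f"unknown map form {self.form!r}")

    @property
    def mid_position_mm(self) -> float:
        return self.total_length_mm / 2.0


def mouse_map() -> PlaceFrequencyMap:
    """Mouse defaults: 700 IHCs in a single row over ~5.1 mm, log-linear map
    spanning 4.7 octaves."""
    return PlaceFrequencyMap(
        species="mouse", total_length_mm=5.13, n_ihc_total=700,
        form="log_linear", total_octaves=4.7, f_apex_hz=4000.0,
    )


def human_map(mode: str = "greenwood") -> PlaceFrequencyMap:
    """Human defaults: 35 mm, 3500 IHCs.

    ``mode="greenwood"`` uses the Greenwood constants A = 165.4 Hz,
    a = 0.06 /mm, k = 0.88; ``mode="uniform_octave"`` spreads the audible
    range (20 Hz - 20 kHz, ~9.97 octaves) uniformly over the IHC row.
    """
    if mode == "greenwood":
        return PlaceFrequencyMap(
            species="human", total_length_mm=35.0, n_ihc_total=3500,
            form="greenwood", greenwood_A=165.4, greenwood_a=0.06,
            greenwood_k=0.88,
        )
    if mode == "uniform_octave":
        return PlaceFrequencyMap(
            species="human", total_length_mm=35.0, n_ihc_total=3500,
            form="log_linear", total_octaves=math.log2(20000.0 / 20.0),
            f_apex_hz=20.0,
        )
    raise ValueError("mode must be 'greenwood' or 'uniform_octave'")


def place_to_freq(x_mm: float, fmap: PlaceFrequencyMap) -> float:
    """Frequency (Hz) at distance ``x_mm`` from the apex."""
    if not (0.0 <= x_mm <= fmap.total_length_mm):
        raise ValueError("position outside the cochlea")
    if fmap.form == "greenwood":
        return fmap.greenwood_A * (10.0 ** (fmap.greenwood_a * x_mm)
                                   - fmap.greenwood_k)
    f_apex = fmap.f_apex_hz if fmap.f_apex_hz is not None else 1.0
    return f_apex * 2.0 ** (fmap.total_octaves * x_mm / fmap.total_length_mm)


def freq_to_place(f_hz: float, fmap: PlaceFrequencyMap) -> float:
    """Distance from the apex (mm) at which ``f_hz`` is encoded; inverse of
    :func:`place_to_freq` to within 1e-9 relative."""
    lo = place_to_freq(0.0, fmap)
    hi = place_to_freq(fmap.total_length_mm, fmap)
    if not (min(lo, hi) <= f_hz <= max(lo, hi)):
        raise ValueError("frequency outside the map range")
    if fmap.form == "greenwood":
        return math.log10(f_hz / fmap.greenwood_A + fmap.greenwood_k) \
            / fmap.greenwood_a
    f_apex = fmap.f_apex_hz if fmap.f_apex_hz is not None else 1.0
    return math.log2(f_hz / f_apex) * fmap.total_length_mm / fmap.total_octaves


def length_fraction(n_ihc: int, fmap: PlaceFrequencyMap) -> float:
    """Percentage of cochlear length covered by ``n_ihc`` adjacent IHCs under
    uniform single-row spacing: 100 * n / n_total."""
    if not (1 <= n_ihc <= fmap.n_ihc_total):
        raise ValueError("n_ihc out of range")
    return 100.0 * n_ihc / fmap.n_ihc_total


def octave_span(fraction_pct: float, fmap: PlaceFrequencyMap,
                position_mm: float | None = None) -> float:
    """Octave span of a stretch covering ``fraction_pct`` of the cochlea.

    Log-linear maps are position-independent (fraction/100 * total span and
    spans are additive); Greenwood maps evaluate
    log2 f(x + dx) / f(x) at ``position_mm`` (default: mid-cochlea).
    """
    if not (0.0 < fraction_pct <= 100.0):
        raise ValueError("fraction must be in (0, 100]")
    if fmap.form == "log_linear":
        return fraction_pct / 100.0 * fmap.total_octaves
    x0 = fmap.mid_position_mm if position_mm is None else position_mm
    dx = fraction_pct / 100.0 * fmap.total_length_mm
    if not (0.0 <= x0 <= fmap.total_length_mm - dx):
        raise ValueError("position outside map for this span")
    return math.log2(place_to_freq(x0 + dx, fmap) / place_to_freq(x0, fmap))


def cents_per_ihc(fmap: PlaceFrequencyMap,
                  position_mm: float | None = None) -> float:
    """Tonotopic span of a single IHC in cents (1200 * octaves), evaluated
    mid-cochlea by default."""
    return 1200.0 * octave_span(length_fraction(1, fmap), fmap, position_mm)


def syncytium_resolution_cents(
    n_ihc: int,
    fmap: PlaceFrequencyMap,
    position_mm: float | None = None,
    round_per_ihc: bool = True,
) -> float:
    """Best possible frequency resolution (cents) if the cochlea were tiled
    by n-IHC mini-syncytia.

    With ``round_per_ihc`` (default) the single-IHC span is rounded to the
    nearest integer cent before multiplying, matching the integer-cent
    convention of psychophysical comparisons; otherwise the exact n-IHC
    octave span is converted.
    """
    if round_per_ihc:
        return n_ihc * round(cents_per_ihc(fmap, position_mm))
    return 1200.0 * octave_span(length_fraction(n_ihc, fmap), fmap,
                                position_mm)


@dataclass(frozen=True)
class SpanResult:
    n_ihc: int
    length_fraction_pct: float
    octaves: float
    cents: float


def span_result(n_ihc: int, fmap: PlaceFrequencyMap,
                position_mm: float | None = None) -> SpanResult:
    """Bundle the span of an n-IHC pool in all three units."""
    frac = length_fraction(n_ihc, fmap)
    octv = octave_span(frac, fmap, position_mm)
    return SpanResult(n_ihc=n_ihc, length_fraction_pct=frac, octaves=octv,
                      cents=1200.0 * octv)
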