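"""Two-wave analysis of side-by-side diffusion-cell traces.

The receiving-cell concentration of methylene blue rises in two waves: the
first is free dye crossing the membrane; after a plateau (while the gelatin
holds dye back) a second, slower, nearly linear wave appears as dye bound to
the gelatin is released.  The effective diffusion coefficient of a wave is
computed from the quasi-steady relation

    D_eff = (dn/dt) * l / delta_c

with dn/dt the least-squares slope of the receiving-cell concentration over
the wave segment, l the membrane thickness, and delta_c the source-receiving
concentration difference at the segment midpoint.  The trace stores
concentration, so dn/dt is a concentration rate and the cell volume/area
factors are absorbed into the supplied trace (the reported coefficient is on
the same conventional scale the trace was calibrated to).  Dividing by the
layer count recalculates the coefficient for a single layer.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

__all__ = [
    "DiffusionTrace", "WaveSegmentation", "DeffEstimate", "TwoWaveReport",
    "EquilibriumError", "DirectionError", "NoRisingSegmentError",
    "detect_waves", "estimate_deff", "two_wave_report",
    "DEFAULT_SLOPE_TOL",
]

DEFAULT_SLOPE_TOL = 0.15
_SMOOTH_WINDOW = 3


class EquilibriumError(ValueError):
    """Source-receiving concentration difference is not positive."""


class DirectionError(ValueError):
    """Segment slope is not positive (concentration not rising)."""


class NoRisingSegmentError(ValueError):
    """Trace contains no rising segment to analyze."""


@dataclass(frozen=True)
class DiffusionTrace:
    """Receiving-cell concentration vs time for one membrane.

    times in s (strictly increasing, starting at >= 0); concentrations in
    g dm^-3, bounded by the initial source concentration ``source_c0``;
    ``thickness`` is the whole-membrane thickness l in m.
    """

    times: np.ndarray
    concentrations: np.ndarray
    source_c0: float
    thickness: float
    n_layers: int

    def __post_init__(self):
        t = np.asarray(self.times, dtype=float)
        c = np.asarray(self.concentrations, dtype=float)
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "concentrations", c)
        if t.ndim != 1 or t.shape != c.shape:
            raise ValueError("times and concentrations must be equal-length 1-D")
        if t.size and t[0] < 0:
            raise ValueError("times must start at >= 0")
        if np.any(np.diff(t) <= 0):
            raise ValueError("times must be strictly increasing")
        if np.any(c < 0) or np.any(c > self.source_c0 + 1e-12):
            raise ValueError("concentrations must lie in [0, source_c0]")
        if self.source_c0 <= 0 or self.thickness <= 0 or self.n_layers < 1:
            raise ValueError("source_c0 and thickness must be positive, "
                             "n_layers >= 1")

    def __len__(self) -> int:
        return self.times.size


@dataclass(frozen=True)
class WaveSegmentation:
    """Index ranges [start, stop) of the two waves and the plateau.

    ``wave2`` is None when no second rise was detected.
    """

    wave1: tuple
    plateau: tuple | None
    wave2: tuple | None
    n_points: int

    def __post_init__(self):
        ranges = [r for r in (self.wave1, self.plateau, self.wave2)
                  if r is not None]
        prev_stop = 0
        for start, stop in ranges:
            if not (0 <= start < stop <= self.n_points):
                raise ValueError(f"segment ({start}, {stop}) out of bounds")
            if start < prev_stop:
                raise ValueError("segments must be ordered and non-overlapping")
            prev_stop = stop


@dataclass(frozen=True)
class DeffEstimate:
    """Effective diffusion coefficient for one wave segment."""

    deff: float                 # conventional m^2 s^-1 scale (see module docs)
    deff_per_layer: float
    dndt: float                 # concentration rate used (g dm^-3 s^-1)
    delta_c: float              # source - receiving at segment midpoint
    wave: str                   # 'first' or 'second'

    def __post_init__(self):
        if self.deff <= 0:
            raise ValueError("deff must be positive")


@dataclass(frozen=True)
class TwoWaveReport:
    first: DeffEstimate
    second: DeffEstimate
    segmentation: WaveSegmentation


def _smoothed_slopes(trace: DiffusionTrace) -> np.ndarray:
    s = np.gradient(trace.concentrations, trace.times)
    if len(trace) >= _SMOOTH_WINDOW:
        kernel = np.ones(_SMOOTH_WINDOW) / _SMOOTH_WINDOW
        pad = _SMOOTH_WINDOW // 2
        padded = np.pad(s, pad, mode="edge")
        s = np.convolve(padded, kernel, mode="valid")
    return s


def _first_sustained_below(s: np.ndarray, threshold: float, start: int,
                           run: int = 2) -> int | None:
    """First index >= start opening a run of ``run`` sub-threshold slopes."""
    below = s[start:] < threshold
    for i in range(below.size - run + 1):
        if below[i:i + run].all():
            return start + i
    return None


def _stick_fit(t: np.ndarray, c: np.ndarray, kind: str):
    """Best continuous two-segment fit over a breakpoint grid.

    ``kind='flat_rise'`` fits a constant followed by a line (plateau into a
    second wave); ``kind='rise_flat'`` fits a line flattening out (end of
    the first wave, or a saturating tail).  Returns (sse, breakpoint index,
    [level, slope]).
    """
    n = t.size
    best = None
    for j in range(2, n - 2):
        if kind == "flat_rise":
            ramp = np.clip(t - t[j], 0.0, None)
        else:
            ramp = np.clip(t - t[j], None, 0.0)
        design = np.column_stack([np.ones(n), ramp])
        coef, *_ = np.linalg.lstsq(design, c, rcond=None)
        resid = c - design @ coef
        sse = float(resid @ resid)
        if best is None or sse < best[0]:
            best = (sse, j, coef)
    return best


def _broken_stick_rise(t: np.ndarray, c: np.ndarray) -> int | None:
    """Locate the onset of a second rise after the plateau, if any.

    The second wave is typically an order of magnitude slower than the
    first, so its onset is found by a least-squares flat-then-rise
    breakpoint fit over the whole tail rather than by thresholding single
    noisy slope estimates.  The rise is accepted only if its slope is
    significant (> 3 standard errors), it accumulates at least 5 residual
    standard deviations by the end of the trace, and the flat-then-rise
    model beats the rise-then-flat alternative — a monotone saturating
    tail, whose slope only decreases, fits the latter better and is
    rejected.
    """
    flat_rise = _stick_fit(t, c, "flat_rise")
    rise_flat = _stick_fit(t, c, "rise_flat")
    if flat_rise is None or rise_flat is None:
        return None
    sse, j, coef = flat_rise
    s2 = float(coef[1])
    sigma = math.sqrt(sse / max(t.size - 3, 1))
    ramp = np.clip(t - t[j], 0.0, None)
    ramp_var = float(((ramp - ramp.mean()) ** 2).sum())
    se_s2 = sigma / math.sqrt(ramp_var) if ramp_var > 0 else math.inf
    rise = s2 * (t[-1] - t[j])
    ok = (s2 > 0 and s2 > 3.0 * se_s2 and rise > 5.0 * sigma
          and sse < rise_flat[0])
    return j if ok else None


def detect_waves(trace: DiffusionTrace,
                 slope_tol: float = DEFAULT_SLOPE_TOL) -> WaveSegmentation:
    """Segment a trace into first wave, plateau, and optional second wave.

    The first wave is the initial rising run; it ends where the smoothed
    local slope falls (for two consecutive samples) below ``slope_tol``
    times the median first-wave slope.  The boundary between the plateau
    and the much slower second wave is then located by a least-squares
    flat-then-rise breakpoint fit over the post-wave-1 samples, which uses
    the whole tail rather than single noisy slope estimates — the second
    wave's slope is typically an order of magnitude below the first wave's
    and is invisible to the wave-1 threshold.  A trace that never rises
    raises :class:`NoRisingSegmentError`; a trace that never flattens, or
    flattens without a significant second rise, yields ``wave2 = None``.
    """
    if len(trace) < 8:
        raise ValueError("wave detection needs at least 8 time points")
    s = _smoothed_slopes(trace)
    smax = float(s.max())
    if smax <= 0:
        raise NoRisingSegmentError("trace has no rising segment")

    ref0 = slope_tol * smax
    rising = np.nonzero(s > ref0)[0]
    if rising.size == 0:
        raise NoRisingSegmentError("trace has no rising segment")
    i0 = int(rising[0])

    e1 = _first_sustained_below(s, ref0, i0 + 1)
    if e1 is None:
        return WaveSegmentation(wave1=(i0, len(trace)), plateau=None,
                                wave2=None, n_points=len(trace))
    # Refine against the median first-wave slope, then sharpen the boundary
    # with a local rise-then-flat breakpoint fit around the crossing.
    ref = slope_tol * float(np.median(s[i0:e1]))
    e1 = _first_sustained_below(s, ref, i0 + 1) or e1
    lo, hi = max(i0 + 2, e1 - 6), min(len(trace), e1 + 8)
    if hi - lo >= 5:
        local = _stick_fit(trace.times[lo:hi], trace.concentrations[lo:hi],
                           "rise_flat")
        if local is not None:
            e1 = lo + local[1]

    if len(trace) - e1 < 5:
        return WaveSegmentation(wave1=(i0, e1), plateau=(e1, len(trace)),
                                wave2=None, n_points=len(trace))
    j_rel = _broken_stick_rise(trace.times[e1:], trace.concentrations[e1:])
    if j_rel is None:
        return WaveSegmentation(wave1=(i0, e1), plateau=(e1, len(trace)),
                                wave2=None, n_points=len(trace))
    q0 = e1 + j_rel
    return WaveSegmentation(wave1=(i0, e1), plateau=(e1, q0),
                            wave2=(q0, len(trace)), n_points=len(trace))


def estimate_deff(trace: DiffusionTrace, segment: tuple,
                  wave: str = "first") -> DeffEstimate:
    """Apply the quasi-steady relation to one [start, stop) segment.

    dn/dt is the least-squares slope of concentration on time over the
    segment; delta_c is source_c0 minus the receiving concentration at the
    segment's midpoint time, linearly interpolated between samples
    (midpoint rather than segment start minimizes the secant bias of
    evaluating a changing difference over a window).
    """
    start, stop = segment
    if stop - start < 3:
        raise ValueError("segment must contain at least 3 points")
    t = trace.times[start:stop]
    c = trace.concentrations[start:stop]
    slope = float(np.polyfit(t, c, 1)[0])
    if slope <= 0:
        raise DirectionError(f"segment slope {slope:g} is not positive")
    t_mid = 0.5 * (t[0] + t[-1])
    delta_c = float(trace.source_c0 - np.interp(t_mid, t, c))
    if delta_c <= 0:
        raise EquilibriumError("receiving cell has reached the source "
                               "concentration; delta_c <= 0")
    deff = slope * trace.thickness / delta_c
    return DeffEstimate(deff=deff, deff_per_layer=deff / trace.n_layers,
                        dndt=slope, delta_c=delta_c, wave=wave)


def two_wave_report(trace: DiffusionTrace,
                    slope_tol: float = DEFAULT_SLOPE_TOL) -> TwoWaveReport:
    """Detect both waves and estimate a coefficient for each."""
    seg = detect_waves(trace, slope_tol=slope_tol)
    if seg.wave2 is None:
        raise ValueError("no second diffusion wave detected in trace")
    first = estimate_deff(trace, seg.wave1, wave="first")
    second = estimate_deff(trace, seg.wave2, wave="second")
    return TwoWaveReport(first=first, second=second, segmentation=seg)
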