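"""MRM chromatographic peak detection, integration and quality checks.

A scheduled-MRM chromatogram is a short time/intensity series per
transition.  Quantification rests on four primitives implemented here:

* apex detection inside a retention-time window,
* trapezoidal integration above a linear baseline,
* signal-to-noise against a signal-free region, and
* the quantifier/qualifier area ratio used downstream for identity
  confirmation.

The acquisition-geometry check (points across a peak versus the MS duty
cycle) lives here too, since it decides whether integration is
reproducible at all.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

__all__ = [
    "ChromatogramTrace",
    "Peak",
    "detect_peak",
    "integrate_area",
    "signal_to_noise",
    "quantifier_qualifier_ratio",
    "points_across_peak",
]


@dataclass
class ChromatogramTrace:
    """Per-transition time/intensity series.

    ``times`` are in minutes and strictly increasing; ``intensities`` are
    non-negative counts.  ``sampling_interval_sec`` is the nominal duty
    cycle and must agree with the median time spacing within 1%.
    """

    compound: str
    transition_role: str
    times: np.ndarray
    intensities: np.ndarray
    sampling_interval_sec: float

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.intensities = np.asarray(self.intensities, dtype=float)
        if self.times.shape != self.intensities.shape:
            raise ValueError("times and intensities must have equal length")
        if self.times.size >= 2:
            dt = np.diff(self.times)
            if np.any(dt <= 0):
                raise ValueError("times must be strictly increasing")
            med = float(np.median(dt)) * 60.0
            if not math.isclose(med, self.sampling_interval_sec, rel_tol=0.01):
                raise ValueError(
                    f"sampling_interval_sec {self.sampling_interval_sec} "
                    f"inconsistent with median spacing {med:.4f} s"
                )
        if np.any(self.intensities < 0):
            raise ValueError("intensities must be non-negative")

    def __len__(self) -> int:
        return int(self.times.size)


@dataclass
class Peak:
    """An integrated chromatographic peak."""

    apex_rt_min: float
    area: float
    height: float
    baseline_level: float
    signal_to_noise: float
    n_points: int
    width_sec_at_base: float
    left_min: float = float("nan")
    right_min: float = float("nan")

    def __post_init__(self) -> None:
        if self.area < 0:
            raise ValueError("area must be non-negative")
        if self.n_points < 3:
            raise ValueError("a reported peak needs >= 3 points")


class TraceDataError(ValueError):
    """Trace too short or otherwise unusable for peak detection."""


def points_across_peak(width_sec: float, duty_cycle_sec: float) -> int:
    """Number of acquisition points across a peak of the given base width.

    ``floor(width / duty_cycle)``; with a 12 s narrowest peak and a
    0.73 s duty cycle this yields 16 points, satisfying the usual
    >= 15 points-per-peak requirement for reproducible integration.
    """
    if width_sec <= 0 or duty_cycle_sec <= 0:
        raise ValueError("width and duty cycle must be positive")
    return int(math.floor(width_sec / duty_cycle_sec))


def integrate_area(
    trace: ChromatogramTrace,
    bounds: tuple[float, float],
    baseline: str = "linear_endpoints",
) -> float:
    """Trapezoidal peak area above a linear baseline between the bounds.

    The baseline is the straight line joining the trace intensities at
    the two bound times; the returned area (intensity x seconds) is
    clipped at zero.
    """
    lo, hi = bounds
    if hi < lo:
        raise ValueError(f"inverted bounds {bounds}")
    if baseline != "linear_endpoints":
        raise ValueError(f"unknown baseline mode {baseline!r}")
    t, y = trace.times, trace.intensities
    if lo < t[0] or hi > t[-1]:
        raise ValueError("bounds outside trace time range")
    if hi == lo:
        return 0.0
    mask = (t >= lo) & (t <= hi)
    tt, yy = t[mask], y[mask]
    # ensure the exact bound points participate (linear interpolation)
    if tt.size == 0 or tt[0] > lo:
        tt = np.insert(tt, 0, lo)
        yy = np.insert(yy, 0, np.interp(lo, t, y))
    if tt[-1] < hi:
        tt = np.append(tt, hi)
        yy = np.append(yy, np.interp(hi, t, y))
    base = np.interp(tt, [tt[0], tt[-1]], [yy[0], yy[-1]])
    area_min = float(np.trapezoid(yy - base, tt))
    return max(area_min * 60.0, 0.0)


def _estimate_noise(
    trace: ChromatogramTrace, noise_region: tuple[float, float]
) -> tuple[float, float]:
    """(baseline level, noise sd) from a signal-free region."""
    lo, hi = noise_region
    mask = (trace.times >= lo) & (trace.times <= hi)
    seg = trace.intensities[mask]
    if seg.size == 0:
        raise ValueError("empty noise region")
    return float(np.mean(seg)), float(np.std(seg, ddof=1)) if seg.size > 1 else 0.0


def detect_peak(
    trace: ChromatogramTrace,
    expected_rt_min: float,
    rt_window_min: float = 0.1,
    noise_region: tuple[float, float] | None = None,
    max_half_width_sec: float = 12.0,
) -> Peak | None:
    """Find and integrate the peak nearest ``expected_rt_min``.

    The apex is the local maximum inside ``expected +/- rt_window_min``
    exceeding ``baseline + 3*noise_sd``; among several candidates the one
    closest to the expected retention time wins (ties go to the taller).
    Peak bounds extend from the apex to the first crossing of
    ``baseline + noise_sd``, capped at ``max_half_width_sec`` either side
    (roughly a 4-sigma half-window for the default 12 s base width).
    Returns ``None`` when no qualifying apex exists.

    ``noise_region`` defaults to the 0.5 min immediately before the
    retention-time window (falling back to the trace start when the
    window starts early).
    """
    if rt_window_min <= 0:
        raise ValueError("rt_window_min must be positive")
    if len(trace) < 5:
        raise TraceDataError("trace shorter than 5 points")
    t, y = trace.times, trace.intensities
    if noise_region is None:
        hi = max(expected_rt_min - rt_window_min, t[0])
        lo = max(hi - 0.5, t[0])
        noise_region = (lo, hi)
    try:
        baseline, noise_sd = _estimate_noise(trace, noise_region)
    except ValueError:
        baseline, noise_sd = float(np.min(y)), 0.0

    lo_w, hi_w = expected_rt_min - rt_window_min, expected_rt_min + rt_window_min
    idx = np.flatnonzero((t >= lo_w) & (t <= hi_w))
    if idx.size == 0:
        return None
    # local maxima within the window (window edges count)
    cands = []
    for i in idx:
        left = y[i - 1] if i > 0 else -np.inf
        right = y[i + 1] if i < y.size - 1 else -np.inf
        if y[i] >= left and y[i] >= right and y[i] > baseline + 3.0 * noise_sd:
            cands.append(i)
    if not cands:
        return None
    apex = min(cands, key=lambda i: (abs(t[i] - expected_rt_min), -y[i]))

    thresh = baseline + noise_sd
    half_min = max_half_width_sec / 60.0
    li = apex
    while li > 0 and y[li - 1] > thresh and t[apex] - t[li - 1] <= half_min:
        li -= 1
    ri = apex
    while ri < y.size - 1 and y[ri + 1] > thresh and t[ri + 1] - t[apex] <= half_min:
        ri += 1
    if ri - li + 1 < 3:
        return None

    bounds = (float(t[li]), float(t[ri]))
    area = integrate_area(trace, bounds)
    height = float(y[apex] - baseline)
    sn = math.inf if noise_sd == 0 else height / noise_sd
    return Peak(
        apex_rt_min=float(t[apex]),
        area=area,
        height=height,
        baseline_level=baseline,
        signal_to_noise=sn,
        n_points=int(ri - li + 1),
        width_sec_at_base=(bounds[1] - bounds[0]) * 60.0,
        left_min=bounds[0],
        right_min=bounds[1],
    )


def signal_to_noise(
    trace: ChromatogramTrace, peak: Peak, noise_region: tuple[float, float]
) -> float:
    """Peak height over the intensity sd of a signal-free region.

    A zero noise sd (noise-free synthetic data) yields ``inf``, which
    passes any threshold.
    """
    lo, hi = noise_region
    if hi <= lo:
        raise ValueError("empty noise region")
    mask = (trace.times >= lo) & (trace.times <= hi)
    if not np.isnan(peak.left_min) and not (hi <= peak.left_min or lo >= peak.right_min):
        raise ValueError("noise region overlaps the peak bounds")
    seg = trace.intensities[mask]
    if seg.size < 10:
        raise ValueError("noise region must contain >= 10 points")
    sd = float(np.std(seg, ddof=1))
    signal = peak.height
    if sd == 0.0:
        return math.inf
    return signal / sd


def quantifier_qualifier_ratio(peak_q: Peak | None, peak_c: Peak | None) -> float:
    """Quantifier/qualifier area ratio (MRM_qc) for identity confirmation.

    An absent or zero-area qualifier leaves the ratio undefined
    (``nan``), which downstream identity confirmation treats as a
    failure, never as a pass.
    """
    if peak_q is None or peak_c is None:
        return math.nan
    if peak_c.area == 0.0:
        return math.nan
    if peak_q.area < 0 or peak_c.area < 0:
        raise ValueError("areas must be non-negative")
    return peak_q.area / peak_c.area
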