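"""Beat detection and windowed heart-rate / pulse-rate-variability metrics.

Conventions pinned here (they matter for reproducibility):

* Window HR is ``60000 / mean(IBI)`` over the intervals whose *second* beat
  falls inside the window — robust to partial beats at window edges.
* pNN50 counts successive-interval differences *strictly* greater than
  50 ms, as a percentage of all successive differences.
* An interval belongs to a window by the time of its second beat.
* Windows with too few usable intervals yield NaN, never zero.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from scipy import signal as sps

from .preprocess import HR_WINDOW, PRV_WINDOW, FilterParams, WindowParams, bandpass, window_count
from .records import IBISeries, ParameterError, PPGRecord, WindowedMetricSeries

__all__ = [
    "BeatDetectorParams",
    "HealthyRange",
    "detect_beats",
    "refine_peak_positions",
    "ibi_from_beats",
    "extract_ibi",
    "hr_windowed",
    "pnn50",
    "prv_windowed",
]


@dataclass
class BeatDetectorParams:
    """Adaptive-prominence peak picking with a refractory period.

    ``min_ibi_ms`` caps detectable rate at 60000/min_ibi_ms bpm (default
    330 ms ~ 180 bpm).  The prominence threshold adapts to the local signal
    range over a ``rolling_window_s`` neighbourhood, which keeps detection
    stable through amplitude drift and artifact bursts.
    """

    min_ibi_ms: float = 330.0
    prominence_fraction: float = 0.3
    rolling_window_s: float = 2.0

    def __post_init__(self) -> None:
        if self.min_ibi_ms < 250:
            raise ParameterError("min_ibi_ms must be >= 250 ms")
        if not 0 < self.prominence_fraction < 1:
            raise ParameterError("prominence_fraction must lie in (0, 1)")


@dataclass
class HealthyRange:
    """Plausibility bounds used to discard implausible derived values."""

    hr: tuple[float, float] = (40.0, 200.0)
    pnn50: tuple[float, float] = (0.0, 100.0)
    ibi: tuple[float, float] = (250.0, 2000.0)

    def __post_init__(self) -> None:
        for lo, hi in (self.hr, self.pnn50, self.ibi):
            if not lo < hi:
                raise ParameterError("range lower bound must be below upper")


def detect_beats(rec: PPGRecord, params: BeatDetectorParams | None = None) -> np.ndarray:
    """Systolic peak indices in a band-passed record.

    Local maxima are kept when their prominence exceeds
    ``prominence_fraction`` of the local peak-to-peak signal range, then
    thinned greedily by descending height (earliest index wins ties) under
    the ``min_ibi_ms`` refractory constraint.  Deterministic; a flat or
    empty record yields an empty array.
    """
    params = params or BeatDetectorParams()
    x = rec.samples
    if len(x) < 3 or np.ptp(x) == 0:
        return np.array([], dtype=int)
    cand, _ = sps.find_peaks(x)
    if len(cand) == 0:
        return np.array([], dtype=int)
    prom = sps.peak_prominences(x, cand)[0]
    w = max(3, int(round(params.rolling_window_s * rec.fs)))
    local_range = ndimage.maximum_filter1d(x, w) - ndimage.minimum_filter1d(x, w)
    keep = prom >= params.prominence_fraction * local_range[cand]
    cand, heights = cand[keep], x[cand[keep]]
    if len(cand) == 0:
        return np.array([], dtype=int)
    min_dist = params.min_ibi_ms * rec.fs / 1000.0
    order = np.lexsort((cand, -heights))  # tallest first, earliest wins ties
    taken: list[int] = []
    for i in order:
        p = cand[i]
        if all(abs(p - q) >= min_dist for q in taken):
            taken.append(int(p))
    return np.array(sorted(taken), dtype=int)


def refine_peak_positions(rec: PPGRecord, peaks: np.ndarray) -> np.ndarray:
    """Sub-sample peak positions by parabolic interpolation.

    Returns float sample positions; interior peaks are shifted by up to half
    a sample toward the true continuous maximum, which matters for interval
    precision at moderate sampling rates.
    """
    x = rec.samples
    pos = np.asarray(peaks, dtype=float)
    for j, p in enumerate(peaks):
        if 0 < p < len(x) - 1:
            denom = x[p - 1] - 2 * x[p] + x[p + 1]
            if denom < 0:
                delta = 0.5 * (x[p - 1] - x[p + 1]) / denom
                pos[j] = p + np.clip(delta, -0.5, 0.5)
    return pos


def ibi_from_beats(
    beats: np.ndarray,
    fs: float,
    healthy: HealthyRange | None = None,
) -> IBISeries:
    """Successive beat-position differences in ms, range-validated.

    ``beats`` are sample positions (integers or refined floats).  Intervals
    outside the plausible IBI range are discarded and counted in
    ``n_discarded``; surviving intervals keep the time of their second beat
    so windowed statistics remain anchored.
    """
    healthy = healthy or HealthyRange()
    beats = np.asarray(beats, dtype=float)
    if len(beats) < 2:
        return IBISeries(np.array([]), np.array([]))
    times_s = beats / fs
    intervals = np.diff(times_s) * 1000.0
    ok = (intervals >= healthy.ibi[0]) & (intervals <= healthy.ibi[1])
    return IBISeries(
        intervals_ms=intervals[ok],
        end_times_s=times_s[1:][ok],
        n_discarded=int(np.sum(~ok)),
    )


def extract_ibi(
    rec: PPGRecord,
    filter_params: FilterParams | None = None,
    detector: BeatDetectorParams | None = None,
    healthy: HealthyRange | None = None,
) -> IBISeries:
    """Full record-to-intervals pipeline: band-pass, detect, refine, validate."""
    filtered = bandpass(rec, filter_params)
    peaks = detect_beats(filtered, detector)
    refined = refine_peak_positions(filtered, peaks)
    return ibi_from_beats(refined, rec.fs, healthy)


def _window_values(
    ibi: IBISeries,
    params: WindowParams,
    total_s: float | None,
    fn,
    min_intervals: int,
) -> WindowedMetricSeries:
    total = total_s if total_s is not None else ibi.duration
    n = window_count(total, params)
    starts = np.arange(n) * params.step_s
    values = np.full(n, np.nan)
    for k, start in enumerate(starts):
        sel = (ibi.end_times_s >= start) & (ibi.end_times_s < start + params.window_s)
        iv = ibi.intervals_ms[sel]
        if len(iv) >= min_intervals:
            values[k] = fn(iv)
    return WindowedMetricSeries(
        values=values, start_times_s=starts,
        window_s=params.window_s, step_s=params.step_s,
    )


def hr_windowed(
    ibi: IBISeries,
    params: WindowParams = HR_WINDOW,
    total_s: float | None = None,
) -> WindowedMetricSeries:
    """Heart rate (bpm) on a sliding-window grid; NaN below 2 intervals."""
    out = _window_values(ibi, params, total_s, lambda iv: 60000.0 / np.mean(iv), 2)
    out.metric = "hr"
    return out


def pnn50(intervals_ms) -> float:
    """Percent of successive interval differences exceeding 50 ms.

    Accepts an :class:`IBISeries` or a plain interval array.  NaN (not zero)
    when fewer than two successive differences exist.
    """
    if isinstance(intervals_ms, IBISeries):
        intervals_ms = intervals_ms.intervals_ms
    intervals_ms = np.asarray(intervals_ms, dtype=float)
    if len(intervals_ms) < 3:
        return float("nan")
    d = np.abs(np.diff(intervals_ms))
    return 100.0 * float(np.sum(d > 50.0)) / len(d)


def prv_windowed(
    ibi: IBISeries,
    params: WindowParams = PRV_WINDOW,
    total_s: float | None = None,
) -> WindowedMetricSeries:
    """pNN50 (%) per sliding window; NaN below 3 intervals in a window."""
    out = _window_values(ibi, params, total_s, pnn50, 3)
    out.metric = "pnn50"
    return out
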