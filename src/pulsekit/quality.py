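"""Classical spectral signal-quality index, quality gating and channel selection.

The relative power signal quality index (pSQI) scores a raw PPG segment by
the fraction of its spectral power lying in the pulse band (0.7-4.0 Hz, the
same band the analysis filter passes) relative to the total band (0-10 Hz).
A clean pulse concentrates its fundamental and first harmonics in-band, so
values near 100% indicate a usable segment; broadband motion noise drags the
index down.  Quality gating drops analysis windows whose *reference-device*
pSQI falls below a threshold — from both devices at once, on the assumption
that motion corrupts both recordings of the same session equally.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import signal as sps

from .preprocess import WindowParams, window_count
from .records import ParameterError, PPGRecord, QualityVector, WindowedMetricSeries

__all__ = [
    "PSQIParams",
    "AlignmentError",
    "psqi",
    "psqi_windowed",
    "quality_gate",
    "select_best_channel",
]


class AlignmentError(ValueError):
    """Two windowed series do not share a window grid."""


@dataclass
class PSQIParams:
    pulse_band: tuple[float, float] = (0.7, 4.0)
    total_band: tuple[float, float] = (0.0, 10.0)

    def __post_init__(self) -> None:
        if not (self.total_band[0] <= self.pulse_band[0]
                and self.pulse_band[1] <= self.total_band[1]):
            raise ParameterError("pulse_band must lie inside total_band")


def psqi(segment: np.ndarray | PPGRecord, fs: float | None = None,
         params: PSQIParams | None = None) -> float:
    """Relative pulse-band power of a raw segment, in percent.

    The spectrum is a mean-removed periodogram, so the ratio equals a direct
    FFT band-power summation and a DC offset never counts as signal.
    A constant segment has no power at all and scores 0% (with a warning);
    segments shorter than 10 s give coarse frequency resolution and also
    warn.
    """
    params = params or PSQIParams()
    if isinstance(segment, PPGRecord):
        fs = segment.fs
        x = segment.samples
    else:
        if fs is None:
            raise ParameterError("fs required when passing a bare array")
        x = np.asarray(segment, dtype=float)
    if params.total_band[1] >= fs / 2:
        raise ParameterError("total_band upper edge must be below fs/2")
    if len(x) / fs < 10.0:
        warnings.warn("pSQI on a segment shorter than 10 s is coarse", stacklevel=2)
    if len(x) < 2 or np.ptp(x) == 0:
        warnings.warn("constant segment has zero power; pSQI defined as 0%", stacklevel=2)
        return 0.0
    f, pxx = sps.periodogram(x, fs=fs, window="boxcar", detrend="constant")
    total = (f >= params.total_band[0]) & (f <= params.total_band[1])
    pulse = (f >= params.pulse_band[0]) & (f <= params.pulse_band[1])
    denom = float(np.sum(pxx[total]))
    if denom == 0.0:
        warnings.warn("no power in total band; pSQI defined as 0%", stacklevel=2)
        return 0.0
    return 100.0 * float(np.sum(pxx[pulse])) / denom


def psqi_windowed(
    rec: PPGRecord,
    window: WindowParams,
    params: PSQIParams | None = None,
    total_s: float | None = None,
) -> WindowedMetricSeries:
    """pSQI per sliding window of a raw record, on the metric window grid."""
    total = total_s if total_s is not None else rec.duration
    n = window_count(total, window)
    starts = np.arange(n) * window.step_s
    values = np.full(n, np.nan)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for k, start in enumerate(starts):
            lo = int(round(start * rec.fs))
            hi = int(round((start + window.window_s) * rec.fs))
            values[k] = psqi(rec.samples[lo:hi], rec.fs, params)
    return WindowedMetricSeries(
        values=values, start_times_s=starts,
        window_s=window.window_s, step_s=window.step_s, metric="psqi",
    )


def _check_grid(a: WindowedMetricSeries, b: WindowedMetricSeries) -> None:
    if a.window_s != b.window_s or a.step_s != b.step_s:
        raise AlignmentError(
            f"window grids differ: {a.window_s}/{a.step_s} vs {b.window_s}/{b.step_s}"
        )
    if len(a) != len(b) or not np.allclose(a.start_times_s, b.start_times_s):
        raise AlignmentError("window start times differ")


def quality_gate(
    test: WindowedMetricSeries,
    ref: WindowedMetricSeries,
    ref_psqi: WindowedMetricSeries,
    threshold: float = 40.0,
) -> tuple[WindowedMetricSeries, WindowedMetricSeries, np.ndarray]:
    """Paired discard of windows with poor reference signal quality.

    Windows whose reference pSQI is below ``threshold`` percent become NaN
    in *both* returned series, so a window is never dropped from one device
    without dropping its pair.  Returns the gated copies and the keep mask.
    """
    _check_grid(test, ref)
    _check_grid(test, ref_psqi)
    keep = ref_psqi.values >= threshold
    tv, rv = test.values.copy(), ref.values.copy()
    tv[~keep] = np.nan
    rv[~keep] = np.nan
    gated_test = WindowedMetricSeries(tv, test.start_times_s.copy(),
                                      test.window_s, test.step_s, test.metric)
    gated_ref = WindowedMetricSeries(rv, ref.start_times_s.copy(),
                                     ref.window_s, ref.step_s, ref.metric)
    return gated_test, gated_ref, keep


def select_best_channel(
    channels: list[tuple[PPGRecord, WindowedMetricSeries | QualityVector]],
    window: WindowParams,
    total_s: float | None = None,
) -> np.ndarray:
    """Per-window index of the channel with the highest mean quality.

    Quality may be a windowed pSQI series (already on the target grid) or a
    0.5 s quality vector (averaged within each window).  Ties go to the
    first channel in the given order.
    """
    if not channels:
        raise ParameterError("need at least one channel")
    total = total_s if total_s is not None else channels[0][0].duration
    n = window_count(total, window)
    starts = np.arange(n) * window.step_s
    scores = np.zeros((len(channels), n))
    for i, (_rec, q) in enumerate(channels):
        if isinstance(q, QualityVector):
            times = q.segment_times()
            for k, start in enumerate(starts):
                sel = (times >= start) & (times < start + window.window_s) & q.labeled
                scores[i, k] = float(np.mean(q.scores[sel])) if np.any(sel) else np.nan
        else:
            if len(q) != n:
                raise AlignmentError("windowed quality series not on the target grid")
            scores[i] = q.values
    # argmax over channels; NaN scores lose to any number; ties -> lowest index
    filled = np.where(np.isnan(scores), -np.inf, scores)
    return np.argmax(filled, axis=0)
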