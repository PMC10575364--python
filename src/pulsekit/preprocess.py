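"""Filtering, windowing and resampling front end.

The pulse band-pass is a third-order Butterworth with the 0.7-4.0 Hz band
that brackets plausible pulse rates (42-240 bpm).  It is applied
forward-backward (``sosfiltfilt``) so beat peak times are not shifted by
filter group delay; the effective magnitude response is therefore the square
of the designed third-order response, which only sharpens the stopband.

Windowing follows a half-open convention: window ``k`` covers
``[k*step, k*step + window)`` seconds, and only complete windows are
emitted — a recording shorter than one window yields nothing.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterator

import numpy as np
from scipy import signal as sps

from .records import ParameterError, PPGRecord

__all__ = ["FilterParams", "WindowParams", "bandpass", "window_iter", "window_count", "resample"]


class ConfigurationError(ValueError):
    """Processing parameters incompatible with the data they were applied to."""


@dataclass
class FilterParams:
    low_cut: float = 0.7
    high_cut: float = 4.0
    order: int = 3
    zero_phase: bool = True

    def __post_init__(self) -> None:
        if not 0 < self.low_cut < self.high_cut:
            raise ParameterError("need 0 < low_cut < high_cut")
        if self.order < 1:
            raise ParameterError("order must be >= 1")


@dataclass
class WindowParams:
    window_s: float
    step_s: float

    def __post_init__(self) -> None:
        if self.window_s <= 0:
            raise ParameterError("window_s must be positive")
        if not 0 < self.step_s <= self.window_s:
            raise ParameterError("need 0 < step_s <= window_s")


#: 30 s / 10 s sliding windows for heart rate
HR_WINDOW = WindowParams(window_s=30.0, step_s=10.0)
#: 120 s / 10 s sliding windows for pulse-rate variability
PRV_WINDOW = WindowParams(window_s=120.0, step_s=10.0)


def bandpass(rec: PPGRecord, params: FilterParams | None = None) -> PPGRecord:
    """Band-pass a record, preserving length, rate and peak timing."""
    params = params or FilterParams()
    if rec.fs <= 2 * params.high_cut:
        raise ConfigurationError(
            f"fs={rec.fs} Hz too low for high_cut={params.high_cut} Hz"
        )
    sos = sps.butter(
        params.order, [params.low_cut, params.high_cut], btype="bandpass",
        fs=rec.fs, output="sos",
    )
    if params.zero_phase:
        y = sps.sosfiltfilt(sos, rec.samples)
    else:
        y = sps.sosfilt(sos, rec.samples)
    return PPGRecord(samples=y, fs=rec.fs, channel=rec.channel, quality=rec.quality)


def window_count(total_s: float, params: WindowParams) -> int:
    """Number of complete windows in ``total_s`` seconds."""
    if total_s < params.window_s:
        return 0
    # tiny epsilon guards float representation of durations like 180.0
    return int(np.floor((total_s - params.window_s) / params.step_s + 1e-9)) + 1


def window_iter(total_s: float, params: WindowParams) -> Iterator[tuple[float, float]]:
    """Yield ``(start_s, end_s)`` for each complete window, in order."""
    for k in range(window_count(total_s, params)):
        start = k * params.step_s
        yield start, start + params.window_s


def resample(rec: PPGRecord, target_fs: float) -> PPGRecord:
    """Band-limited resampling to ``target_fs``, duration preserved within
    one sample."""
    if target_fs < 25:
        raise ParameterError("target_fs must be at least 25 Hz")
    if target_fs == rec.fs:
        return rec.copy()
    n_out = int(round(len(rec.samples) * target_fs / rec.fs))
    y = sps.resample_poly(
        rec.samples,
        up=int(round(target_fs * 1000)),
        down=int(round(rec.fs * 1000)),
    )
    # resample_poly output length is ceil(n*up/down); trim/pad to rounded length
    if len(y) > n_out:
        y = y[:n_out]
    elif len(y) < n_out:
        y = np.pad(y, (0, n_out - len(y)), mode="edge")
    return PPGRecord(samples=y, fs=target_fs, channel=rec.channel, quality=rec.quality)
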