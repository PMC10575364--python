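"""Core in-memory containers shared across the toolkit.

All signal containers carry their own sampling rate so downstream code never
has to thread ``fs`` separately.  Times are seconds from record start unless a
field name says otherwise; inter-beat intervals are milliseconds, the unit in
which pulse-rate-variability statistics are conventionally defined.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np

__all__ = [
    "PPGRecord",
    "IBISeries",
    "QualityVector",
    "WindowedMetricSeries",
    "ParameterError",
]


class ParameterError(ValueError):
    """An operation received arguments outside its documented domain."""


@dataclass
class PPGRecord:
    """A uniformly sampled photoplethysmogram.

    Parameters
    ----------
    samples : ndarray
        1-D float array of signal values (arbitrary units or ADC counts).
    fs : float
        Sampling rate in Hz.
    channel : str
        Channel name, e.g. ``"finger"`` or ``"ear"``.
    quality : QualityVector, optional
        Per-0.5 s quality annotation aligned to the record start.
    """

    samples: np.ndarray
    fs: float
    channel: str = "ppg"
    quality: Optional["QualityVector"] = None

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim != 1:
            raise ParameterError("PPGRecord samples must be 1-D")
        if self.fs <= 0:
            raise ParameterError(f"sampling rate must be positive, got {self.fs}")

    @property
    def duration(self) -> float:
        """Record length in seconds."""
        return len(self.samples) / self.fs

    @property
    def times(self) -> np.ndarray:
        """Sample times in seconds (0-based)."""
        return np.arange(len(self.samples)) / self.fs

    def copy(self) -> "PPGRecord":
        return replace(self, samples=self.samples.copy())

    def __len__(self) -> int:
        return len(self.samples)


@dataclass
class IBISeries:
    """Ordered inter-beat intervals with the beat times that delimit them.

    ``intervals_ms[i]`` is the gap between ``beat_times_s[i]`` and
    ``beat_times_s[i+1]``... except when out-of-range intervals have been
    discarded, in which case ``end_times_s`` keeps each interval anchored to
    the time of its *second* beat so windowed statistics stay well defined.
    """

    intervals_ms: np.ndarray
    end_times_s: np.ndarray
    n_discarded: int = 0

    def __post_init__(self) -> None:
        self.intervals_ms = np.asarray(self.intervals_ms, dtype=float)
        self.end_times_s = np.asarray(self.end_times_s, dtype=float)
        if self.intervals_ms.shape != self.end_times_s.shape:
            raise ParameterError("intervals and end times must align")

    def __len__(self) -> int:
        return len(self.intervals_ms)

    @property
    def duration(self) -> float:
        return float(self.end_times_s[-1]) if len(self) else 0.0


@dataclass
class QualityVector:
    """Quality labels on a fixed 0.5 s grid aligned to a record.

    ``scores`` lie in [0, 1]; 1 means clean.  ``labeled`` marks grid cells
    that actually received a label (a zero-padded model tail is unlabeled).
    """

    scores: np.ndarray
    resolution_s: float = 0.5
    offset_s: float = 0.0
    labeled: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        self.scores = np.asarray(self.scores, dtype=float)
        if self.labeled is None:
            self.labeled = np.ones(len(self.scores), dtype=bool)
        else:
            self.labeled = np.asarray(self.labeled, dtype=bool)
        if self.labeled.shape != self.scores.shape:
            raise ParameterError("labeled mask must align with scores")

    @property
    def binary(self) -> np.ndarray:
        """Boolean view: True = clean, using the 0.5 score threshold."""
        return self.scores >= 0.5

    def segment_times(self) -> np.ndarray:
        """Start time of each 0.5 s cell, in seconds."""
        return self.offset_s + np.arange(len(self.scores)) * self.resolution_s

    def __len__(self) -> int:
        return len(self.scores)


@dataclass
class WindowedMetricSeries:
    """Metric values on a sliding-window grid, with window provenance.

    ``values`` may contain NaN for windows where the metric was undefined
    (too few usable beats).  ``start_times_s`` are exact multiples of the
    step so two series computed with the same parameters share a grid.
    """

    values: np.ndarray
    start_times_s: np.ndarray
    window_s: float
    step_s: float
    metric: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.start_times_s = np.asarray(self.start_times_s, dtype=float)
        if self.values.shape != self.start_times_s.shape:
            raise ParameterError("values and start times must align")

    def __len__(self) -> int:
        return len(self.values)

    @property
    def valid(self) -> np.ndarray:
        return ~np.isnan(self.values)
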