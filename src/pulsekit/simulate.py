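"""Synthetic PPG generation with known ground truth.

The generator works in three stages that mirror how a pulse oximeter signal
arises physically:

1. a beat train — successive inter-beat intervals around a mean heart rate,
   with Gaussian interval jitter and occasional large excursions so that
   pulse-rate-variability indices such as pNN50 can be dialled in;
2. waveform rendering — each beat becomes a systolic Gaussian bump plus a
   smaller, delayed dicrotic bump.  The systolic peak sits at a *fixed time
   offset* after the beat onset, so peak-to-peak times reproduce the
   generated intervals exactly and the beat train is recoverable;
3. artifact injection — motion bursts, baseline wander, clipping and
   flatline events placed by a Poisson process, together with the binary
   ground-truth quality labels on a 0.5 s grid that the quality models train
   and evaluate against.

A four-condition study harness (:func:`simulate_study`) produces paired
"reference" (clean) and "device" (artifact-laden) recordings per simulated
subject, emulating a validation protocol in which conditions vary both
physiological state and movement level.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Optional, Sequence

import numpy as np

from .records import IBISeries, ParameterError, PPGRecord, QualityVector

__all__ = [
    "BeatTemplate",
    "ArtifactSpec",
    "SimulationSpec",
    "StudyProtocol",
    "StudyPair",
    "StudyDataset",
    "generate_ibi_series",
    "render_ppg",
    "inject_artifacts",
    "simulate_study",
    "default_study_protocol",
]

# physiologically plausible interval range, ms (also the default analysis
# validation range)
IBI_CLAMP_MS = (250.0, 2000.0)

ARTIFACT_KINDS = ("motion_burst", "baseline_wander", "clipping", "flatline")

# Systolic peak time after beat onset, seconds.  A constant (rather than a
# fraction of the interval) so that peak-to-peak times equal the interval
# series exactly.
SYSTOLIC_OFFSET_S = 0.15


@dataclass
class BeatTemplate:
    """Two-Gaussian pulse morphology.

    Widths and the dicrotic delay are fractions of the beat's own interval,
    so waveforms scale naturally with heart rate.  Amplitudes are arbitrary
    units; the dicrotic bump must stay smaller than the systolic one.
    """

    systolic_amp: float = 1.0
    systolic_width: float = 0.08
    dicrotic_amp: float = 0.25
    dicrotic_delay: float = 0.35
    dicrotic_width: float = 0.10
    dc_offset: float = 0.0

    def __post_init__(self) -> None:
        if self.systolic_amp <= 0:
            raise ParameterError("systolic_amp must be positive")
        if not 0 < self.dicrotic_delay < 1:
            raise ParameterError("dicrotic_delay must lie in (0, 1)")
        if self.dicrotic_amp >= self.systolic_amp:
            raise ParameterError("dicrotic bump must be smaller than systolic")


@dataclass
class ArtifactSpec:
    """One artifact process to superimpose on a clean recording.

    Events are placed by a Poisson process whose rate is chosen so the
    expected covered fraction of the recording equals ``duty_cycle``; event
    lengths are exponential with mean ``mean_event_s``.  ``events`` may be
    given explicitly (list of ``(start_s, duration_s)``) to bypass random
    placement, which tests use to construct exact label alignments.
    """

    kind: str
    duty_cycle: float = 0.1
    mean_event_s: float = 2.0
    amplitude: float = 1.0
    events: Optional[Sequence[tuple[float, float]]] = None

    def __post_init__(self) -> None:
        if self.kind not in ARTIFACT_KINDS:
            raise ParameterError(
                f"unknown artifact kind {self.kind!r}; expected one of {ARTIFACT_KINDS}"
            )
        if not 0.0 <= self.duty_cycle <= 1.0:
            raise ParameterError("duty_cycle must lie in [0, 1]")
        if self.mean_event_s <= 0:
            raise ParameterError("mean_event_s must be positive")


@dataclass
class SimulationSpec:
    """Full parameterization of one synthetic recording."""

    mean_hr: float = 70.0
    jitter_sd: float = 20.0
    jump_prob: float = 0.0
    jump_magnitude: float = 60.0
    duration: float = 180.0
    fs: float = 100.0
    template: BeatTemplate = field(default_factory=BeatTemplate)
    artifacts: list[ArtifactSpec] = field(default_factory=list)
    seed: int = 0

    def __post_init__(self) -> None:
        if not 30 <= self.mean_hr <= 220:
            raise ParameterError(f"mean_hr {self.mean_hr} outside [30, 220] bpm")
        if self.fs < 25:
            raise ParameterError("fs must be at least 25 Hz")
        if self.duration <= 0:
            raise ParameterError("duration must be positive")
        if self.jitter_sd < 0:
            raise ParameterError("jitter_sd must be non-negative")
        if not 0.0 <= self.jump_prob <= 1.0:
            raise ParameterError("jump_prob must lie in [0, 1]")


def generate_ibi_series(spec: SimulationSpec) -> IBISeries:
    """Draw an inter-beat-interval series from the generative model.

    Each interval is ``60000 / mean_hr`` plus Gaussian jitter, plus — with
    probability ``jump_prob`` — a large excursion of ``jump_magnitude`` ms
    whose sign alternates between successive excursions (so back-to-back
    jumps never cancel in the successive-difference sense that pNN50
    measures).  Intervals are clamped to the plausible range [250, 2000] ms.
    Generation continues until the cumulative beat time covers
    ``spec.duration``.
    """
    rng = np.random.default_rng(spec.seed)
    base = 60000.0 / spec.mean_hr
    # upper bound on beats needed, + slack
    n_max = int(math.ceil(spec.duration * 1000.0 / max(base - 4 * spec.jitter_sd, 250.0))) + 8
    jitter = rng.normal(0.0, spec.jitter_sd, size=n_max) if spec.jitter_sd > 0 else np.zeros(n_max)
    fires = rng.random(n_max) < spec.jump_prob
    jumps = np.zeros(n_max)
    sign = 1.0
    for i in np.flatnonzero(fires):
        jumps[i] = sign * spec.jump_magnitude
        sign = -sign
    intervals = np.clip(base + jitter + jumps, *IBI_CLAMP_MS)
    cum = np.cumsum(intervals)
    n = int(np.searchsorted(cum, spec.duration * 1000.0)) + 1
    n = min(n, n_max)
    intervals = intervals[:n]
    return IBISeries(intervals_ms=intervals, end_times_s=np.cumsum(intervals) / 1000.0)


def render_ppg(
    ibi: IBISeries,
    fs: float,
    template: BeatTemplate | None = None,
    channel: str = "ppg",
) -> PPGRecord:
    """Render an interval series into a continuous waveform.

    One systolic + one dicrotic Gaussian bump per interval.  The systolic
    centre is ``SYSTOLIC_OFFSET_S`` after the beat onset; the dicrotic
    centre trails it by ``dicrotic_delay`` of the interval.  Record length
    is ``round(total beat time * fs)`` samples.
    """
    if len(ibi) == 0:
        raise ParameterError("cannot render an empty IBI series")
    if fs < 25:
        raise ParameterError("fs must be at least 25 Hz")
    template = template or BeatTemplate()
    intervals_s = ibi.intervals_ms / 1000.0
    onsets = np.concatenate([[0.0], np.cumsum(intervals_s)[:-1]])
    total = float(np.sum(intervals_s))
    n = int(round(total * fs))
    x = np.full(n, template.dc_offset, dtype=float)

    def _add_bump(center: float, sigma: float, amp: float) -> None:
        if sigma <= 0:
            return
        lo = max(0, int(math.floor((center - 4 * sigma) * fs)))
        hi = min(n, int(math.ceil((center + 4 * sigma) * fs)) + 1)
        if hi <= lo:
            return
        t = np.arange(lo, hi) / fs
        x[lo:hi] += amp * np.exp(-0.5 * ((t - center) / sigma) ** 2)

    for onset, iv in zip(onsets, intervals_s):
        sys_c = onset + SYSTOLIC_OFFSET_S
        _add_bump(sys_c, template.systolic_width * iv, template.systolic_amp)
        if template.dicrotic_amp > 0:
            _add_bump(
                sys_c + template.dicrotic_delay * iv,
                template.dicrotic_width * iv,
                template.dicrotic_amp,
            )
    return PPGRecord(samples=x, fs=fs, channel=channel)


def systolic_peak_times(ibi: IBISeries) -> np.ndarray:
    """Ground-truth systolic peak times for a rendered series, in seconds."""
    intervals_s = ibi.intervals_ms / 1000.0
    onsets = np.concatenate([[0.0], np.cumsum(intervals_s)[:-1]])
    return onsets + SYSTOLIC_OFFSET_S


def _place_events(
    spec: ArtifactSpec, duration: float, rng: np.random.Generator
) -> list[tuple[float, float]]:
    if spec.events is not None:
        return [(float(s), float(d)) for s, d in spec.events]
    if spec.duty_cycle == 0:
        return []
    rate = spec.duty_cycle / spec.mean_event_s  # events per second
    events: list[tuple[float, float]] = []
    t = rng.exponential(1.0 / rate)
    while t < duration:
        d = rng.exponential(spec.mean_event_s)
        events.append((t, min(d, duration - t)))
        t += d + rng.exponential(1.0 / rate)
    return events


def _apply_event(
    x: np.ndarray, fs: float, kind: str, start: float, dur: float, amplitude: float,
    rng: np.random.Generator,
) -> None:
    lo = max(0, int(round(start * fs)))
    hi = min(len(x), int(round((start + dur) * fs)))
    if hi <= lo:
        return
    span = hi - lo
    if kind == "motion_burst":
        x[lo:hi] += amplitude * rng.standard_normal(span)
    elif kind == "baseline_wander":
        f = rng.uniform(0.05, 0.3)
        phase = rng.uniform(0, 2 * np.pi)
        t = np.arange(lo, hi) / fs
        x[lo:hi] += amplitude * np.sin(2 * np.pi * f * t + phase)
    elif kind == "clipping":
        np.clip(x[lo:hi], -amplitude, amplitude, out=x[lo:hi])
    elif kind == "flatline":
        x[lo:hi] = x[lo]


def inject_artifacts(
    rec: PPGRecord,
    specs: Iterable[ArtifactSpec],
    label_res: float = 0.5,
    seed: int = 0,
) -> tuple[PPGRecord, QualityVector]:
    """Corrupt a copy of ``rec`` and return it with ground-truth labels.

    Label rule: a ``label_res`` segment is *bad* when artifact events
    overlap more than half of it — except flatline and clipping events,
    where any overlap marks the segment bad (even a short saturation
    invalidates beat timing within the segment).  A trailing partial
    segment is dropped from the label vector.
    """
    rng = np.random.default_rng(seed)
    specs = list(specs)
    x = rec.samples.copy()
    duration = rec.duration
    n_seg = int(math.floor(duration / label_res))
    overlap = np.zeros(n_seg)          # seconds of soft-artifact overlap per segment
    hard_hit = np.zeros(n_seg, dtype=bool)

    # additive artifacts first, then saturating ones, so clipping acts on the
    # already-corrupted waveform
    order = {"motion_burst": 0, "baseline_wander": 0, "clipping": 1, "flatline": 2}
    placed: list[tuple[ArtifactSpec, list[tuple[float, float]]]] = [
        (s, _place_events(s, duration, rng)) for s in specs
    ]
    for spec, events in sorted(placed, key=lambda p: order[p[0].kind]):
        hard = spec.kind in ("clipping", "flatline")
        for start, dur in events:
            _apply_event(x, rec.fs, spec.kind, start, dur, spec.amplitude, rng)
            first = int(math.floor(start / label_res))
            last = int(math.floor((start + dur) / label_res))
            for k in range(max(first, 0), min(last + 1, n_seg)):
                seg_lo, seg_hi = k * label_res, (k + 1) * label_res
                ov = min(start + dur, seg_hi) - max(start, seg_lo)
                if ov <= 0:
                    continue
                if hard:
                    hard_hit[k] = True
                else:
                    overlap[k] += ov

    bad = hard_hit | (overlap > 0.5 * label_res)
    scores = np.where(bad, 0.0, 1.0)
    corrupted = PPGRecord(samples=x, fs=rec.fs, channel=rec.channel)
    quality = QualityVector(scores=scores, resolution_s=label_res)
    corrupted.quality = quality
    return corrupted, quality


# ---------------------------------------------------------------------------
# Study harness


@dataclass
class StudyProtocol:
    """An ordered multi-condition protocol applied to every simulated subject."""

    conditions: list[tuple[str, SimulationSpec]]
    condition_duration: float = 180.0
    rest_duration: float = 60.0
    n_subjects: int = 15
    seed: int = 0

    def __post_init__(self) -> None:
        names = [name for name, _ in self.conditions]
        if len(set(names)) != len(names):
            raise ParameterError("condition names must be unique")
        if self.condition_duration <= 0 or self.rest_duration < 0:
            raise ParameterError("durations must be positive")
        if self.n_subjects < 1:
            raise ParameterError("n_subjects must be at least 1")


@dataclass
class StudyPair:
    """One subject x condition cell: a clean reference and an artifact-laden
    device recording rendered from the same ground-truth beat train."""

    subject: int
    condition: str
    reference: PPGRecord
    device: PPGRecord
    ibi_truth: IBISeries
    quality_truth: QualityVector


@dataclass
class StudyDataset:
    protocol: StudyProtocol
    pairs: list[StudyPair]

    def for_condition(self, name: str) -> list[StudyPair]:
        return [p for p in self.pairs if p.condition == name]

    @property
    def conditions(self) -> list[str]:
        return [name for name, _ in self.protocol.conditions]


def default_study_protocol(
    n_subjects: int = 15,
    condition_duration: float = 180.0,
    seed: int = 0,
    fs: float = 100.0,
) -> StudyProtocol:
    """Four conditions with artifact severity ordered
    slow breathing < easy math < hard math < movement.

    Slow breathing maximizes respiratory-driven interval variability
    (large jitter); math tasks raise heart rate and damp variability;
    the movement condition adds heavy motion-burst, wander and clipping
    artifacts to the device channel.
    """

    def spec(hr: float, jit: float, arts: list[ArtifactSpec]) -> SimulationSpec:
        return SimulationSpec(
            mean_hr=hr, jitter_sd=jit, jump_prob=0.05, jump_magnitude=80.0,
            duration=condition_duration, fs=fs, artifacts=arts,
        )

    conditions = [
        ("baseline", spec(65, 45.0, [
            ArtifactSpec("motion_burst", duty_cycle=0.02, mean_event_s=1.0, amplitude=1.5),
        ])),
        ("easy_math", spec(72, 30.0, [
            ArtifactSpec("motion_burst", duty_cycle=0.06, mean_event_s=1.5, amplitude=2.0),
        ])),
        ("hard_math", spec(80, 22.0, [
            ArtifactSpec("motion_burst", duty_cycle=0.12, mean_event_s=2.0, amplitude=2.5),
            ArtifactSpec("baseline_wander", duty_cycle=0.10, mean_event_s=4.0, amplitude=1.0),
        ])),
        ("movement", spec(75, 30.0, [
            ArtifactSpec("motion_burst", duty_cycle=0.25, mean_event_s=2.5, amplitude=3.0),
            ArtifactSpec("baseline_wander", duty_cycle=0.15, mean_event_s=4.0, amplitude=1.5),
            ArtifactSpec("clipping", duty_cycle=0.06, mean_event_s=2.0, amplitude=0.8),
        ])),
    ]
    return StudyProtocol(
        conditions=conditions,
        condition_duration=condition_duration,
        n_subjects=n_subjects,
        seed=seed,
    )


def simulate_study(protocol: StudyProtocol) -> StudyDataset:
    """Run the protocol over all subjects.

    Per subject, a heart-rate offset and a variability scale are drawn once
    (stable across conditions, like a real participant's physiology); per
    (subject, condition) the beat train is generated and rendered, the
    reference record is kept clean, and the device record receives the
    condition's artifacts.  Everything derives deterministically from
    ``protocol.seed`` via independent seed streams.
    """
    pairs: list[StudyPair] = []
    for s in range(protocol.n_subjects):
        subj_rng = np.random.default_rng(np.random.SeedSequence((protocol.seed, s)))
        hr_offset = float(np.clip(subj_rng.normal(0.0, 8.0), -15.0, 25.0))
        jit_scale = float(subj_rng.uniform(0.75, 1.3))
        for c, (name, cond_spec) in enumerate(protocol.conditions):
            ss = np.random.SeedSequence((protocol.seed, s, c))
            gen_seed, art_seed = [int(x) for x in ss.generate_state(2) >> 1]
            spec = replace(
                cond_spec,
                mean_hr=float(np.clip(cond_spec.mean_hr + hr_offset, 40.0, 180.0)),
                jitter_sd=cond_spec.jitter_sd * jit_scale,
                duration=protocol.condition_duration,
                seed=gen_seed,
            )
            ibi = generate_ibi_series(spec)
            reference = render_ppg(ibi, spec.fs, spec.template, channel="reference")
            device_clean = render_ppg(ibi, spec.fs, spec.template, channel="device")
            device, quality = inject_artifacts(
                device_clean, spec.artifacts, seed=art_seed
            )
            pairs.append(StudyPair(
                subject=s, condition=name, reference=reference, device=device,
                ibi_truth=ibi, quality_truth=quality,
            ))
    return StudyDataset(protocol=protocol, pairs=pairs)
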