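# Methods

This note documents the models and procedures behind `pulsekit`, the
assumptions they make, the parameters that matter, and the numerical choices
that had to be pinned down for reproducible results.

## 1. The synthetic PPG generator

### Beat train

Inter-beat intervals are drawn as

    IBI_i = 60000 / HR_mean  +  N(0, σ_jitter)  +  J_i        [ms]

where `J_i` is, with probability `jump_prob` per beat, a large excursion of
`±jump_magnitude` ms. The excursion sign **alternates** between successive
firings (+m, −m, +m, …): with independent random signs, two adjacent
excursions of equal sign would cancel in the successive-difference sense,
and the degenerate case `jump_prob = 1` would no longer force every
successive difference above threshold. Alternation makes the excursion
channel a clean, monotone dial for pNN50: isolated excursions each create
two super-threshold differences, so pNN50 ≈ 1 − (1 − p)² for excursion
probability p. Intervals are clamped to 250–2000 ms, the same plausibility
range the analysis side uses for interval validation, and generation
continues until cumulative beat time covers the requested duration (so a
recording is at most one beat longer than asked).

### Waveform

Each interval is rendered as a systolic Gaussian bump plus a smaller,
delayed dicrotic bump. Widths and the dicrotic delay scale with the
interval (defaults: systolic width 8 % of IBI, dicrotic amplitude 0.25,
delay 35 %, width 10 %), but the **systolic peak sits at a fixed 150 ms
after beat onset** rather than at a fixed fraction. This is deliberate:
with a constant offset, peak-to-peak times reproduce the generated interval
series exactly, so the generator doubles as an exact oracle for beat
detection and interval recovery. A fractional placement would mix adjacent
intervals into every peak-to-peak time and destroy that property.

The two-Gaussian template is not a hemodynamic model; it reproduces the
features the analysis depends on (one dominant local maximum per beat, a
plausible harmonic envelope in the 0.7–4 Hz band) and nothing else.

### Artifacts and ground-truth labels

Four artifact processes can be superimposed: additive white **motion
bursts**, additive low-frequency (0.05–0.3 Hz) **baseline wander**,
amplitude **clipping**, and sample-hold **flatline**. Events are placed by
a Poisson process with rate `duty_cycle / mean_event_s` and exponential
durations, which makes coverage seedable and duty-cycle controllable;
explicit event lists can be supplied for exactly constructed cases.
Additive artifacts are applied before saturating ones, so clipping acts on
the already-corrupted waveform.

Ground-truth labels live on a 0.5 s grid (trailing partial cell dropped).
A cell is labelled bad when artifact events cover **more than half** of it —
except clipping and flatline, where **any** overlap marks the cell bad,
since even a brief saturation invalidates beat timing within the cell. The
half-overlap rule for soft artifacts is a design choice (a brief noise blip
in an otherwise clean cell usually leaves beats recoverable); no external
annotation standard was available to copy, and the rule is stated here
precisely so results are interpretable against it.

### Study harness

`default_study_protocol` emulates a four-condition validation session per
subject — slow breathing (high interval variability, minimal artifacts),
easy math, hard math (rising heart rate, falling variability, rising
artifact load), and guided movement (heavy motion bursts, wander and
clipping). Artifact severity is strictly ordered across the four
conditions. Each subject gets a per-subject heart-rate offset
(N(0, 8) bpm, clipped) and a variability scale (U(0.75, 1.3)) that persist
across conditions, like a real participant's physiology. Per
subject × condition, one ground-truth beat train is rendered twice: a clean
"reference" recording and a "device" recording that receives the
condition's artifacts — so disagreement between the two pipelines is caused
by artifacts alone, which is the question the agreement analysis isolates.
Every recording derives deterministically from the protocol seed through
independent `SeedSequence` streams.

What the simulator does **not** emulate: respiratory sinus arrhythmia as an
oscillatory process (jitter is white), sensor-specific noise spectra,
correlated artifacts across the two devices (reference recordings are
clean), blood-pressure-dependent waveform shape changes. Passing tests
therefore demonstrate pipeline correctness and artifact robustness under a
controlled, known generative model — not clinical validity on human data.

## 2. Preprocessing

The pulse band-pass is a **third-order Butterworth, 0.7–4.0 Hz**, applied
forward–backward (`sosfiltfilt`). Zero-phase filtering was chosen because
beat *timing* is the quantity of interest downstream; a causal pass would
shift peaks by the group delay. The effective magnitude response is the
square of the designed third-order response — the passband stays within a
few percent of unity while stopband attenuation doubles in dB, which only
strengthens the stated ≥20 dB contract at 0.1 and 8 Hz.

Windowing is half-open: window k covers `[k·step, k·step + window)` with
0-based time, and only complete windows are emitted — a T second recording
yields `floor((T − window)/step) + 1` windows (16 HR windows and 7 PRV
windows for a 180 s condition). Resampling is polyphase band-limited
(`resample_poly`), used to bring arbitrary-rate segments to the quality
model's fixed 64 Hz input rate.

## 3. Metrics

**Beat detection** picks local maxima whose prominence exceeds 30 % of the
local peak-to-peak signal range (2 s rolling neighbourhood — adaptive, so
amplitude drift and artifact bursts do not blind the detector), thinned
greedily by descending height under a 330 ms refractory period (180 bpm
cap); equal-height ties go to the earlier sample. Peak positions are
refined by parabolic interpolation, giving sub-sample timing — at 100 Hz
this reduces interval quantization from ±10 ms to ~1 ms, which matters for
pNN50's hard 50 ms threshold.

**Interval validation** discards intervals outside 250–2000 ms (missed or
spurious beats) while preserving each surviving interval's anchor time (its
second beat), so windowed statistics remain time-aligned after discards.

**Windowed HR** is `60000 / mean(IBI)` over intervals anchored in the
window, not beat-count/duration — robust to partial beats at window edges.
Windows with fewer than 2 intervals are NaN (missing), never zero.
**pNN50** counts `|ΔIBI| > 50 ms` strictly (a difference of exactly 50 ms
does not count) and is NaN below two successive differences. These
conventions are pinned because every downstream agreement number depends on
them.

## 4. Signal quality

**pSQI** is the mean-removed periodogram power ratio of the 0.7–4.0 Hz
pulse band to the 0–10 Hz total band, in percent. Band edges: the pulse
band matches the analysis filter passband; 10 Hz covers all harmonic
content a pulse waveform can carry at physiological rates while excluding
nothing that matters at typical sampling rates. Mean removal keeps DC
offsets from inflating the denominator. A constant segment is defined as
0 % quality (with a warning). The periodogram (rather than an averaged
Welch estimate) makes the index exactly equal to a direct FFT band-power
ratio, which the tests exploit as an oracle.

**Quality gating** drops windows whose *reference-device* pSQI falls below
40 % — from both series at once, on the assumption that motion corrupts
both simultaneous recordings. Each metric is gated on its own window grid
(30 s windows for HR, 120 s for pNN50); gating a 120 s metric on 30 s
sub-window quality would conflate grids and was rejected.

**Best-channel selection** takes, per window, the channel with the highest
mean quality (windowed pSQI or averaged 0.5 s scores); ties go to the first
channel in the configured order, making the choice deterministic.

## 5. The dense quality model

The SQA network maps an 8 s segment — resampled to 64 Hz (512 samples) and
z-scored per segment — to 16 clean-probabilities, one per 0.5 s cell.
Architecture: four encoder blocks (widths 16/32/64/64), each a stride-2
kernel-7 convolution followed by a stride-1 refinement convolution with
ReLU, taking 512 samples to a 32-step feature map; a decoder block of the
same shape lands on the 16-cell label grid, and a 1×1 convolution with
sigmoid produces the scores (~135 k parameters). The stack's receptive
field spans several beats, enough context to tell a flat diastolic run from
a flatline dropout. Per-segment z-scoring makes the model gain-invariant,
so it transfers across sensor scalings; the cost is that a *constant*
segment carries no amplitude cue, which is why whole-segment dropouts must
be represented in training data (see below).

Training minimizes mean per-cell binary cross-entropy with Adam
(batch 256, lr 1.5·10⁻³ stepped ×0.2 after 75 % of 60 epochs). The
train/validation split is **by subject**: no simulated subject contributes
segments to both sides, so validation accuracy measures generalization to
new subjects, not memorization. The single-conv-per-block variant of this
network plateaued near 0.84–0.92 held-out accuracy depending on the split;
the refinement convolutions and the late learning-rate step lift it to
0.91–0.94 across splits, which is why they are part of the default
configuration.

The training corpus simulates subjects with random physiology (HR
U(50, 110) bpm, jitter U(10, 50) ms) and random artifact mixtures of all
four kinds. Flatline event durations range up to whole-segment length
(mean U(2, 8) s): detached-sensor dropouts are a real failure mode, and a
z-scored all-constant input is otherwise out of distribution — without
such examples the model's response to a fully flat segment is an
untrained extrapolation.

Inference tiles a recording into consecutive 8 s segments; a shorter tail
is zero-padded for the forward pass and its padded cells are marked
*unlabeled* rather than guessed. Checkpoints store configuration,
parameters and a corpus fingerprint in a single `.npz` file.

The pSQI baseline the model is compared against classifies each whole 8 s
segment by thresholding its pSQI at 40 % and broadcasts that verdict to all
16 cells. On brief flatline/clipping events this baseline is near-blind —
a short dropout barely moves whole-segment spectral concentration, so the
gate rarely fires and its F1 on the bad class is near zero — which is
precisely the dense model's reason to exist.

## 6. Agreement evaluation

Errors are test − reference. RMSE, MAE, and SD of the error (sample, n−1),
with Pearson r (also n−1 convention); Bland–Altman bias is the mean
difference with limits of agreement bias ± 1.96·SD. Windows from all
subjects are **pooled within condition** before computing the statistics
(one value per condition, plus an all-conditions-combined row); a
per-subject breakdown is emitted alongside, since pooled and averaged
per-subject correlations answer different questions. No multiple-testing
correction is applied to the Wilcoxon comparisons; reports are descriptive.

The Wilcoxon signed-rank test drops zero differences, mid-ranks ties, and
computes exact p-values by enumerating all 2ⁿ sign assignments for n ≤ 15
(the enumeration is over the *observed* ranks, so ties are handled
exactly); above 15 it uses the normal approximation with tie-corrected
variance and a 0.5 continuity correction. `scipy.stats.wilcoxon` is used
in the tests as an independent oracle only.

The batch analyzer discovers sessions through a JSON manifest, isolates
per-file failures (logged, batch continues), and writes both a CSV
spreadsheet and a keyed `.npz` archive with fixed float formatting, so
reruns on identical input are byte-identical.

## 7. Session format, streaming and synchronization

Sessions are single rectangular CSVs: header of channel names, one row per
sample, an `event_code` column (0 = none, contiguous non-zero runs for
marked events), and per-channel quality columns in which each 0.5 s label
is repeated per sample — keeping signal, events and annotation in one
file at the cost of redundancy. Values are written with `repr` so float64
round-trips are exact. A JSON sidecar holds sampling rate, identifiers and
the UTC ISO-8601 start stamp; sample timing is implicit from the rate.

The streaming engine applies a metric to the trailing window on the same
half-open grid as offline windowing, emitting exactly one value per step
after the first full window — online and offline results are identical on
identical samples by construction, and a starved source ends the stream
rather than fabricating values.

The multi-node start-trigger protocol is line-delimited text over TCP:
HELLO/ACK handshake, broadcast START(session_id, utc_time), STOP, optional
MARK relay. The client state machine is a transport-free class (recording
strictly between START and STOP; duplicate START for the same session id is
idempotent; STOP without START is a protocol error and writes no file),
with a thin socket layer around it. HELLO/ACK and STOP extend the minimal
broadcast-trigger idea just far enough to make the state machine testable.

## 8. Problem sizes and known limitations

Default analysis sizes: 3 min conditions, 30 s/10 s HR windows, 120 s/10 s
PRV windows; SQA corpus of 20 subjects × 4 min (≈600 segments, 25 % of
subjects held out); study harness of 15 subjects × 4 conditions (60 paired
recordings). These sizes keep a full train-and-evaluate cycle at a few
minutes on one CPU while leaving every statistic with a meaningful n; they
are choices of this package, stated here so results can be scaled up.

Limitations worth keeping in mind: the jitter model is white (no
respiratory oscillation), so frequency-domain variability indices would be
meaningless on these simulations (only time-domain pNN50 is offered); the
reference device in the study harness is noiseless, so the 40 % gate is
exercised mainly by the device channel; accuracy figures for the quality
model are against simulator ground-truth labels whose bad/clean rule is
itself a design choice; and the exact Wilcoxon enumeration is O(2ⁿ), which
is why it hands over to the normal approximation above n = 15.
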