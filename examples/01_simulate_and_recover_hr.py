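"""Simulate a clean PPG recording and recover its heart rate.

Generates a 3 min beat train at 72 bpm, renders it into a pulse waveform,
then runs the full analysis pipeline (band-pass, beat detection, 30 s / 10 s
windowing) and compares the windowed HR estimates with the simulated truth.
"""

import numpy as np

from pulsekit.metrics import extract_ibi, hr_windowed
from pulsekit.simulate import SimulationSpec, generate_ibi_series, render_ppg

spec = SimulationSpec(mean_hr=72, jitter_sd=25, duration=180, fs=100, seed=1)
ibi = generate_ibi_series(spec)
rec = render_ppg(ibi, spec.fs)
print(f"simulated {len(ibi)} beats over {rec.duration:.1f} s "
      f"(mean interval {np.mean(ibi.intervals_ms):.0f} ms)")

est = extract_ibi(rec)
hr = hr_windowed(est, total_s=spec.duration)
print(f"{len(hr)} HR windows (30 s window, 10 s step):")
for start, value in zip(hr.start_times_s, hr.values):
    print(f"  t={start:5.0f} s  HR = {value:.2f} bpm")
print(f"worst deviation from the simulated 72 bpm: "
      f"{np.max(np.abs(hr.values - 72)):.2f} bpm")
# Each window averages the detected inter-beat intervals inside it, so the
# estimates hover around the simulated rate despite 25 ms interval jitter.
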