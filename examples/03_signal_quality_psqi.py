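"""Score signal quality with the spectral pSQI and gate bad windows.

pSQI is the fraction of spectral power inside the pulse band (0.7-4 Hz)
relative to the 0-10 Hz total, in percent.  Motion noise spreads power
across the spectrum and drags the index down; the 40% gate then discards
those windows from *both* devices of a paired comparison.
"""

import numpy as np

from pulsekit.preprocess import HR_WINDOW
from pulsekit.quality import psqi, psqi_windowed, quality_gate
from pulsekit.records import WindowedMetricSeries
from pulsekit.simulate import ArtifactSpec, SimulationSpec, generate_ibi_series, inject_artifacts, render_ppg

spec = SimulationSpec(mean_hr=70, jitter_sd=15, duration=180, fs=100, seed=3)
clean = render_ppg(generate_ibi_series(spec), spec.fs)
noisy, _truth = inject_artifacts(
    clean, [ArtifactSpec("motion_burst", duty_cycle=0.35, amplitude=3.0)], seed=3
)
print(f"whole-record pSQI: clean {psqi(clean):.1f}%, corrupted {psqi(noisy):.1f}%")

q = psqi_windowed(noisy, HR_WINDOW, total_s=180)
print("per-window pSQI (%):", np.round(q.values, 1))

hr_like = WindowedMetricSeries(np.full(len(q), 70.0), q.start_times_s,
                               q.window_s, q.step_s)
_t, _r, keep = quality_gate(hr_like, hr_like, q, threshold=40.0)
print(f"40% gate keeps {keep.sum()}/{len(keep)} windows "
      f"(dropped windows are removed from both paired series)")
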