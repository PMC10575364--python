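"""Stream a simulated sensor in real time and map HR to biofeedback.

A synthetic serial source replays integer ADC samples; the stream engine
maintains a trailing 30 s window and emits one HR value every 10 s, which
the biofeedback map converts to a [0, 1] scalar (driving, e.g., the size of
a shape on screen).  Online values are identical to offline windowing of
the same samples.
"""

import numpy as np

from pulsekit.io_stream import biofeedback_map, stream_engine, synthetic_serial_source
from pulsekit.metrics import extract_ibi
from pulsekit.records import PPGRecord
from pulsekit.simulate import SimulationSpec


def hr_metric(window: np.ndarray, fs: float) -> float:
    ibi = extract_ibi(PPGRecord(samples=window, fs=fs))
    return 60000.0 / float(np.mean(ibi.intervals_ms)) if len(ibi) >= 2 else float("nan")


spec = SimulationSpec(mean_hr=68, jitter_sd=20, duration=90, fs=100, seed=6)
source = synthetic_serial_source(spec)  # as-fast-as-possible replay
for t, hr in stream_engine(source, hr_metric, spec.fs, window_s=30, step_s=10):
    fb = biofeedback_map(hr, 40.0, 200.0)
    bar = "#" * int(40 * fb)
    print(f"t={t:5.0f} s  HR {hr:6.1f} bpm  biofeedback {fb:.2f}  {bar}")
# No value is emitted before the first full 30 s window; each subsequent
# step yields exactly one value, as an on-line protocol display would.
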