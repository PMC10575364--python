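import numpy as np
import pytest

from pulsekit.simulate import SimulationSpec, generate_ibi_series, render_ppg
from pulsekit.sqa import TrainConfig, build_corpus, build_sqa, train_sqa


@pytest.fixture(scope="session")
def clean_record_60bpm():
    """180 s clean recording at 60 bpm with moderate interval jitter."""
    spec = SimulationSpec(mean_hr=60, jitter_sd=20, duration=180, fs=100, seed=11)
    ibi = generate_ibi_series(spec)
    rec = render_ppg(ibi, spec.fs)
    return spec, ibi, rec


@pytest.fixture(scope="session")
def tiny_trained_sqa():
    """A small but genuinely trained quality model for cheap API contracts.

    8 subjects x 120 s keeps the fixture fast while still reaching
    clearly-better-than-chance held-out accuracy.
    """
    corpus = build_corpus(n_subjects=8, duration_s=120.0, seed=5)
    model = build_sqa(seed=5)
    history = train_sqa(model, corpus, TrainConfig(epochs=15, seed=5))
    return model, corpus, history


@pytest.fixture(scope="session")
def trained_sqa_full():
    """The study-grade quality model: 20 subjects, full training schedule.

    Trained once per test session; used wherever a test asserts *quality* of
    the model's decisions (accuracy, artifact localization) rather than just
    its API shape.
    """
    corpus = build_corpus(n_subjects=20, duration_s=240.0, seed=101)
    model = build_sqa(seed=101)
    history = train_sqa(model, corpus, TrainConfig(seed=101))
    return model, corpus, history
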