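"""Generator contracts: beat trains, rendering, artifacts, study harness."""

import numpy as np
import pytest
from scipy import signal as sps

from pulsekit.metrics import pnn50
from pulsekit.records import ParameterError
from pulsekit.simulate import (
    ArtifactSpec,
    BeatTemplate,
    SimulationSpec,
    StudyProtocol,
    default_study_protocol,
    generate_ibi_series,
    inject_artifacts,
    render_ppg,
    simulate_study,
)


class TestGenerateIBI:
    def test_zero_noise_gives_exact_intervals_and_zero_pnn50(self):
        spec = SimulationSpec(mean_hr=75, jitter_sd=0, jump_prob=0, duration=60, seed=0)
        ibi = generate_ibi_series(spec)
        assert np.allclose(ibi.intervals_ms, 800.0)
        assert pnn50(ibi) == 0.0

    def test_forced_excursions_give_full_pnn50(self):
        spec = SimulationSpec(mean_hr=75, jitter_sd=0, jump_prob=1.0,
                              jump_magnitude=60, duration=30, seed=1)
        ibi = generate_ibi_series(spec)
        assert len(ibi) >= 3
        assert np.all(np.abs(np.diff(ibi.intervals_ms)) >= 50.0)
        assert pnn50(ibi) == 100.0

    def test_mean_rate_recovered_from_jittered_series(self):
        # Monte-Carlo check against the stated generative model
        spec = SimulationSpec(mean_hr=60, jitter_sd=20, duration=300, seed=7)
        ibi = generate_ibi_series(spec)
        assert len(ibi) >= 290
        assert abs(np.mean(60000.0 / ibi.intervals_ms) - 60.0) < 2.0

    def test_intervals_clamped_to_plausible_range(self):
        spec = SimulationSpec(mean_hr=180, jitter_sd=200, duration=120, seed=3)
        ibi = generate_ibi_series(spec)
        assert np.all(ibi.intervals_ms >= 250.0)
        assert np.all(ibi.intervals_ms <= 2000.0)

    def test_covers_requested_duration(self):
        spec = SimulationSpec(mean_hr=50, jitter_sd=30, duration=45, seed=4)
        assert generate_ibi_series(spec).duration >= 45.0

    @pytest.mark.parametrize("kwargs", [
        {"mean_hr": 20}, {"mean_hr": 250}, {"fs": 10}, {"duration": 0},
        {"jitter_sd": -1}, {"jump_prob": 1.5},
    ])
    def test_invalid_spec_rejected(self, kwargs):
        with pytest.raises(ParameterError):
            SimulationSpec(**kwargs)

    def test_reproducible_given_seed(self):
        spec = SimulationSpec(mean_hr=70, jitter_sd=25, jump_prob=0.1, duration=60, seed=42)
        a, b = generate_ibi_series(spec), generate_ibi_series(spec)
        assert np.array_equal(a.intervals_ms, b.intervals_ms)


class TestRenderPPG:
    def test_peak_count_and_length(self):
        spec = SimulationSpec(mean_hr=75, jitter_sd=0, duration=8, seed=0)
        ibi = generate_ibi_series(spec)
        assert len(ibi) == 10
        rec = render_ppg(ibi, fs=100)
        assert len(rec) == 800
        peaks, _ = sps.find_peaks(rec.samples, prominence=0.5)
        assert len(peaks) == 10

    def test_dominant_frequency_matches_beat_rate(self):
        spec = SimulationSpec(mean_hr=80, jitter_sd=0, duration=60, seed=0)
        ibi = generate_ibi_series(spec)
        assert np.allclose(ibi.intervals_ms, 750.0)
        rec = render_ppg(ibi, fs=100)
        x = rec.samples - rec.samples.mean()
        f = np.fft.rfftfreq(len(x), 1 / rec.fs)
        amp = np.abs(np.fft.rfft(x))
        assert abs(f[np.argmax(amp)] - 1.3333) < 0.05

    def test_no_dicrotic_bump_means_one_maximum_per_beat(self):
        spec = SimulationSpec(mean_hr=60, jitter_sd=0, duration=10, seed=0)
        ibi = generate_ibi_series(spec)
        tpl = BeatTemplate(dicrotic_amp=0.0)
        rec = render_ppg(ibi, fs=100, template=tpl)
        peaks, _ = sps.find_peaks(rec.samples, prominence=1e-6)
        assert len(peaks) == len(ibi)

    def test_empty_series_rejected(self):
        from pulsekit.records import IBISeries
        with pytest.raises(ParameterError):
            render_ppg(IBISeries(np.array([]), np.array([])), fs=100)


class TestInjectArtifacts:
    def _clean(self, duration=30.0, fs=100.0, seed=0):
        spec = SimulationSpec(mean_hr=70, jitter_sd=10, duration=duration, fs=fs, seed=seed)
        return render_ppg(generate_ibi_series(spec), fs)

    def test_empty_artifact_list_is_identity(self):
        rec = self._clean()
        out, quality = inject_artifacts(rec, [], seed=0)
        assert np.array_equal(out.samples, rec.samples)
        assert np.all(quality.scores == 1.0)
        # one 0.5 s label per full segment; trailing partial segment dropped
        assert len(quality) == int(np.floor(rec.duration / 0.5))

    def test_flatline_labels_exactly_the_touched_segments(self):
        rec = self._clean()
        spec = ArtifactSpec("flatline", events=[(2.0, 2.0)])  # segments 4..7
        _out, quality = inject_artifacts(rec, [spec], seed=0)
        bad = np.flatnonzero(quality.scores == 0.0)
        assert bad.tolist() == [4, 5, 6, 7]

    def test_soft_artifact_needs_majority_overlap(self):
        rec = self._clean()
        # 0.2 s burst inside segment 2: below the 50% overlap rule -> clean
        short = ArtifactSpec("motion_burst", events=[(1.1, 0.2)], amplitude=3.0)
        _out, quality = inject_artifacts(rec, [short], seed=0)
        assert quality.scores[2] == 1.0
        # 0.4 s burst inside segment 2: above 50% -> bad
        longer = ArtifactSpec("motion_burst", events=[(1.05, 0.4)], amplitude=3.0)
        _out, quality = inject_artifacts(rec, [longer], seed=0)
        assert quality.scores[2] == 0.0

    def test_bad_fraction_tracks_duty_cycle(self):
        rec = self._clean(duration=300)
        art = ArtifactSpec("motion_burst", duty_cycle=0.3, mean_event_s=2.0, amplitude=2.0)
        _out, quality = inject_artifacts(rec, [art], seed=12)
        frac = float(np.mean(quality.scores == 0.0))
        assert abs(frac - 0.30) < 0.07

    def test_bad_fraction_monotone_in_duty_cycle(self):
        rec = self._clean(duration=120)
        duties = [0.05, 0.15, 0.3, 0.5]
        means = []
        for duty in duties:
            fracs = []
            for seed in range(20):
                art = ArtifactSpec("motion_burst", duty_cycle=duty,
                                   mean_event_s=2.0, amplitude=2.0)
                _o, q = inject_artifacts(rec, [art], seed=seed)
                fracs.append(float(np.mean(q.scores == 0.0)))
            means.append(np.mean(fracs))
        assert all(a < b for a, b in zip(means, means[1:]))

    def test_reproducible_given_seed(self):
        rec = self._clean()
        art = ArtifactSpec("motion_burst", duty_cycle=0.2, amplitude=2.0)
        o1, q1 = inject_artifacts(rec, [art], seed=9)
        o2, q2 = inject_artifacts(rec, [art], seed=9)
        assert np.array_equal(o1.samples, o2.samples)
        assert np.array_equal(q1.scores, q2.scores)

    def test_unknown_kind_rejected(self):
        with pytest.raises(ParameterError):
            ArtifactSpec("powerline")


class TestStudyHarness:
    def test_one_subject_yields_four_paired_conditions(self):
        study = simulate_study(default_study_protocol(n_subjects=1, seed=0))
        assert len(study.pairs) == 4
        for pair in study.pairs:
            # covers the full 3 min condition (plus at most one extra beat)
            assert 180.0 <= pair.reference.duration < 182.5
            assert len(pair.device) == len(pair.reference)

    def test_fifteen_subjects_yield_sixty_pairs(self):
        protocol = default_study_protocol(n_subjects=15, condition_duration=30, seed=0)
        study = simulate_study(protocol)
        assert len(study.pairs) == 60

    def test_artifact_free_protocol_gives_identical_pairs(self):
        from dataclasses import replace
        protocol = default_study_protocol(n_subjects=1, condition_duration=60, seed=1)
        stripped = StudyProtocol(
            conditions=[(n, replace(s, artifacts=[])) for n, s in protocol.conditions],
            condition_duration=60, n_subjects=1, seed=1,
        )
        study = simulate_study(stripped)
        for pair in study.pairs:
            assert np.array_equal(pair.device.samples, pair.reference.samples)

    def test_protocol_validation(self):
        spec = SimulationSpec()
        with pytest.raises(ParameterError):
            StudyProtocol(conditions=[("a", spec), ("a", spec)])
        with pytest.raises(ParameterError):
            StudyProtocol(conditions=[("a", spec)], n_subjects=0)

    def test_study_is_deterministic(self):
        p = default_study_protocol(n_subjects=2, condition_duration=30, seed=3)
        s1, s2 = simulate_study(p), simulate_study(p)
        for a, b in zip(s1.pairs, s2.pairs):
            assert np.array_equal(a.device.samples, b.device.samples)
            assert np.array_equal(a.quality_truth.scores, b.quality_truth.scores)
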