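"""Agreement statistics against independent naive-formula oracles."""

import itertools

import numpy as np
import pytest
from scipy import stats

from pulsekit.evaluate import (
    AgreementReport,
    agreement_stats,
    align_pairs,
    analyze_batch,
    bland_altman,
    condition_report,
    wilcoxon_signed_rank,
)
from pulsekit.quality import AlignmentError
from pulsekit.records import ParameterError, WindowedMetricSeries


def series(values, starts=None, window_s=30.0, step_s=10.0):
    values = np.asarray(values, dtype=float)
    if starts is None:
        starts = np.arange(len(values)) * step_s
    return WindowedMetricSeries(values, np.asarray(starts, float), window_s, step_s)


class TestAlignPairs:
    def test_identical_grids_pair_everything(self):
        t, r, starts = align_pairs(series([1, 2, 3]), series([4, 5, 6]))
        assert len(t) == 3 and np.array_equal(starts, [0.0, 10.0, 20.0])

    def test_missing_window_dropped(self):
        t, r, _ = align_pairs(series([1, np.nan, 3]), series([4, 5, 6]))
        assert t.tolist() == [1, 3] and r.tolist() == [4, 6]

    def test_time_keyed_not_order_keyed(self):
        a = series([1, 2, 3], starts=[0, 10, 20])
        b = series([6, 5, 4], starts=[20, 10, 0])
        t, r, starts = align_pairs(a, b)
        assert t.tolist() == [1, 2, 3] and r.tolist() == [4, 5, 6]

    def test_different_window_params_rejected(self):
        with pytest.raises(AlignmentError):
            align_pairs(series([1, 2]), series([1, 2], window_s=120.0))


class TestAgreementStats:
    def test_identity_pairs(self):
        rep = agreement_stats([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert rep.rmse == rep.mae == rep.sd_error == 0.0
        assert rep.pearson_r == pytest.approx(1.0)
        assert rep.loa_low == rep.loa_high == 0.0

    def test_hand_computed_example(self):
        rep = agreement_stats([1, 2, 4], [1, 2, 3])
        assert rep.rmse == pytest.approx(0.5774, abs=1e-4)
        assert rep.mae == pytest.approx(0.3333, abs=1e-4)
        assert rep.sd_error == pytest.approx(0.5774, abs=1e-4)
        assert rep.pearson_r == pytest.approx(0.9820, abs=1e-4)

    def test_matches_naive_recomputation_on_random_pairs(self):
        rng = np.random.default_rng(0)
        t, r = rng.normal(70, 10, 1000), rng.normal(70, 10, 1000)
        rep = agreement_stats(t, r)
        e = t - r
        assert rep.rmse == pytest.approx(np.sqrt(np.sum(e * e) / len(e)), abs=1e-9)
        assert rep.mae == pytest.approx(np.sum(np.abs(e)) / len(e), abs=1e-9)
        mean_e = np.sum(e) / len(e)
        sd = np.sqrt(np.sum((e - mean_e) ** 2) / (len(e) - 1))
        assert rep.sd_error == pytest.approx(sd, abs=1e-9)
        assert rep.pearson_r == pytest.approx(stats.pearsonr(t, r)[0], abs=1e-9)

    def test_invariants(self):
        rng = np.random.default_rng(5)
        t, r = rng.normal(0, 1, 200), rng.normal(0, 1, 200)
        rep = agreement_stats(t, r)
        assert rep.rmse >= rep.mae >= 0
        assert rep.loa_low <= rep.bias <= rep.loa_high
        assert abs(rep.pearson_r) <= 1

    def test_constant_reference_flags_undefined_r(self):
        rep = agreement_stats([1.0, 2.0, 3.0], [5.0, 5.0, 5.0])
        assert not rep.r_defined and np.isnan(rep.pearson_r)

    def test_too_few_pairs_rejected(self):
        with pytest.raises(ParameterError):
            agreement_stats([1.0, 2.0], [1.0, 2.0])


class TestBlandAltman:
    def test_identity(self):
        bias, (lo, hi), _ = bland_altman([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert bias == lo == hi == 0.0

    def test_constant_offset(self):
        bias, (lo, hi), table = bland_altman([6.0, 7.0, 8.0], [1.0, 2.0, 3.0])
        assert bias == 5.0 and lo == hi == 5.0
        assert table["difference"].tolist() == [5.0, 5.0, 5.0]

    def test_limits_match_formula_oracle(self):
        rng = np.random.default_rng(1)
        t, r = rng.normal(70, 5, 500), rng.normal(70, 5, 500)
        bias, (lo, hi), _ = bland_altman(t, r)
        d = t - r
        assert bias == pytest.approx(d.mean(), abs=1e-12)
        assert lo == pytest.approx(d.mean() - 1.96 * d.std(ddof=1), abs=1e-9)
        assert hi == pytest.approx(d.mean() + 1.96 * d.std(ddof=1), abs=1e-9)


def exact_wilcoxon_p(d, alternative):
    """Independent oracle: enumerate every sign assignment explicitly."""
    d = np.asarray(d, float)
    d = d[d != 0]
    ranks = stats.rankdata(np.abs(d))
    w_obs = ranks[d > 0].sum()
    ws = [np.sum(np.array(signs) * ranks)
          for signs in itertools.product([0, 1], repeat=len(d))]
    ws = np.array(ws)
    ge = np.mean(ws >= w_obs - 1e-12)
    le = np.mean(ws <= w_obs + 1e-12)
    if alternative == "greater":
        return ge
    if alternative == "less":
        return le
    return min(1.0, 2 * min(ge, le))


class TestWilcoxon:
    def test_five_positive_differences_one_sided(self):
        res = wilcoxon_signed_rank([1.0, 2.0, 0.5, 3.0, 1.5], alternative="greater")
        assert res.p_value == pytest.approx(0.03125)
        assert res.statistic == 15.0

    def test_symmetric_differences_two_sided(self):
        res = wilcoxon_signed_rank([2.0, -2.0, 1.0, -1.0, 3.0, -3.0])
        assert res.statistic == pytest.approx(10.5)  # midpoint of 0..21
        assert res.p_value == pytest.approx(1.0)

    @pytest.mark.parametrize("n", [6, 9, 12])
    @pytest.mark.parametrize("alternative", ["two-sided", "greater", "less"])
    def test_exact_p_matches_full_enumeration(self, n, alternative):
        rng = np.random.default_rng(n)
        d = rng.normal(0.3, 1.0, n)
        res = wilcoxon_signed_rank(d, alternative=alternative)
        assert res.p_value == pytest.approx(exact_wilcoxon_p(d, alternative), abs=1e-12)

    def test_matches_scipy_exact_for_tie_free_input(self):
        rng = np.random.default_rng(2)
        x, y = rng.normal(1, 1, 10), rng.normal(0, 1, 10)
        res = wilcoxon_signed_rank(x, y)
        ref = stats.wilcoxon(x, y, alternative="two-sided", method="exact")
        assert res.p_value == pytest.approx(ref.pvalue, abs=1e-12)

    def test_zero_differences_dropped(self):
        res = wilcoxon_signed_rank([0.0, 0.0, 1.0, 2.0, -0.5, 3.0])
        assert res.n_used == 4

    def test_all_zero_is_degenerate(self):
        res = wilcoxon_signed_rank([0.0, 0.0, 0.0])
        assert res.degenerate and res.p_value == 1.0

    def test_large_n_normal_approximation_is_sane(self):
        rng = np.random.default_rng(3)
        d = rng.normal(0.5, 1.0, 40)
        res = wilcoxon_signed_rank(d, alternative="greater")
        ref = stats.wilcoxon(d, alternative="greater", method="approx", correction=True)
        assert 0 < res.p_value < 0.05
        assert res.p_value == pytest.approx(ref.pvalue, rel=1e-6)


@pytest.fixture(scope="module")
def small_clean_study():
    from dataclasses import replace

    from pulsekit.simulate import StudyProtocol, default_study_protocol, simulate_study

    base = default_study_protocol(n_subjects=2, condition_duration=180, seed=7)
    clean = StudyProtocol(
        conditions=[(n, replace(s, artifacts=[])) for n, s in base.conditions],
        condition_duration=180, n_subjects=2, seed=7,
    )
    return simulate_study(clean)


@pytest.fixture(scope="module")
def session_dir(tmp_path_factory):
    from pulsekit.io_stream import write_study
    from pulsekit.simulate import SimulationSpec, StudyProtocol, simulate_study

    spec = SimulationSpec(mean_hr=70, jitter_sd=20, duration=130)
    protocol = StudyProtocol(
        conditions=[("rest", spec), ("task", spec)],
        condition_duration=130, n_subjects=2, seed=2,
    )
    study = simulate_study(protocol)
    out = tmp_path_factory.mktemp("sessions")
    write_study(study, out)
    return out


class TestConditionReport:
    def test_zero_artifacts_give_near_perfect_agreement(self, small_clean_study):
        report = condition_report(small_clean_study)
        hr = report.table[report.table.metric == "hr"]
        assert (hr.rmse < 0.1).all()
        assert (hr.pearson_r > 0.99).all()

    def test_report_has_per_condition_and_combined_rows(self, small_clean_study):
        report = condition_report(small_clean_study)
        hr = report.table[report.table.metric == "hr"]
        assert set(hr.condition) == {"baseline", "easy_math", "hard_math",
                                     "movement", "combined"}
        assert report.table.n_pairs.min() >= 3

    def test_json_summary_roundtrip(self, small_clean_study, tmp_path):
        import json

        report = condition_report(small_clean_study)
        out = tmp_path / "report.json"
        report.to_json(out)
        payload = json.loads(out.read_text())
        assert payload["gate_threshold"] == 40.0
        assert len(payload["table"]) == len(report.table)


class TestAnalyzeBatch:
    def test_row_count(self, session_dir):
        summary, errors = analyze_batch(session_dir)
        assert not errors
        hr_rows = summary[(summary.metric == "hr") & (summary.channel == "device")]
        assert len(hr_rows) == 4  # 2 subjects x 2 conditions

    def test_batch_equals_single_file_analysis(self, session_dir):
        import json

        from pulsekit.io_stream import read_session
        from pulsekit.metrics import extract_ibi, hr_windowed
        from pulsekit.records import PPGRecord

        summary, _ = analyze_batch(session_dir)
        manifest = json.loads((session_dir / "manifest.json").read_text())
        entry = manifest["sessions"][0]
        sess = read_session(session_dir / entry["file"])
        rec = PPGRecord(samples=sess.channels["reference"], fs=sess.fs)
        hr = hr_windowed(extract_ibi(rec), total_s=rec.duration)
        row = summary[(summary.participant == entry["participant"])
                      & (summary.condition == entry["condition"])
                      & (summary.channel == "reference")
                      & (summary.metric == "hr")].iloc[0]
        assert row["mean"] == pytest.approx(np.nanmean(hr.values))

    def test_rerun_is_byte_identical(self, session_dir):
        analyze_batch(session_dir)
        first = (session_dir / "summary.csv").read_bytes()
        analyze_batch(session_dir)
        assert (session_dir / "summary.csv").read_bytes() == first

    def test_bad_file_logged_batch_continues(self, session_dir, tmp_path):
        import json
        import shutil

        broken = tmp_path / "broken"
        shutil.copytree(session_dir, broken)
        manifest = json.loads((broken / "manifest.json").read_text())
        first_file = manifest["sessions"][0]["file"]
        text = (broken / first_file).read_text().splitlines()
        (broken / first_file).write_text("\n".join(text[:50]) + "\n1.0,2.0\n")
        summary, errors = analyze_batch(broken)
        assert first_file in errors
        assert len(summary) > 0
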