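"""Device-agreement statistics and study-level reports.

Agreement between a test device and a reference device is summarized per
metric and experimental condition by RMSE, MAE, the sample standard
deviation of the error, the Pearson correlation, and Bland-Altman bias with
1.96-SD limits of agreement.  Windows from all subjects within a condition
are pooled before computing the statistics (a per-subject breakdown is also
emitted), and poor-quality windows are discarded in a paired fashion via
the reference-device pSQI gate before any pooling.

Conventions: errors are test minus reference; SD and Pearson r use the
sample (n-1) normalization; limits of agreement are bias +/- 1.96 * SD of
the differences.
"""

from __future__ import annotations

import itertools
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .metrics import extract_ibi, hr_windowed, prv_windowed
from .preprocess import HR_WINDOW, PRV_WINDOW, WindowParams
from .quality import AlignmentError, psqi_windowed, quality_gate
from .records import ParameterError, WindowedMetricSeries
from .simulate import StudyDataset

__all__ = [
    "AgreementReport",
    "WilcoxonResult",
    "align_pairs",
    "agreement_stats",
    "bland_altman",
    "wilcoxon_signed_rank",
    "condition_report",
    "StudyReport",
    "analyze_batch",
]


@dataclass
class AgreementReport:
    rmse: float
    mae: float
    sd_error: float
    pearson_r: float
    bias: float
    loa_low: float
    loa_high: float
    n_pairs: int
    r_defined: bool = True


def align_pairs(
    test: WindowedMetricSeries, ref: WindowedMetricSeries
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Match two windowed series on window start time.

    Series must share window/step parameters.  Windows missing (NaN) in
    either series are dropped.  Returns (test_values, ref_values, starts).
    """
    if test.window_s != ref.window_s or test.step_s != ref.step_s:
        raise AlignmentError(
            f"window parameters differ: {test.window_s}/{test.step_s} "
            f"vs {ref.window_s}/{ref.step_s}"
        )
    # key on start times rounded to ms so float drift cannot split the grid
    t_key = np.round(test.start_times_s * 1000).astype(np.int64)
    r_key = np.round(ref.start_times_s * 1000).astype(np.int64)
    common, t_idx, r_idx = np.intersect1d(t_key, r_key, return_indices=True)
    tv, rv = test.values[t_idx], ref.values[r_idx]
    ok = ~(np.isnan(tv) | np.isnan(rv))
    return tv[ok], rv[ok], common[ok] / 1000.0


def agreement_stats(test: np.ndarray, ref: np.ndarray) -> AgreementReport:
    """Core agreement statistics on paired values."""
    test = np.asarray(test, dtype=float)
    ref = np.asarray(ref, dtype=float)
    if len(test) != len(ref):
        raise ParameterError("paired arrays must have equal length")
    n = len(test)
    if n < 3:
        raise ParameterError("need at least 3 pairs")
    e = test - ref
    rmse = float(np.sqrt(np.mean(e**2)))
    mae = float(np.mean(np.abs(e)))
    sd = float(np.std(e, ddof=1))
    r_defined = bool(np.std(ref) > 0 and np.std(test) > 0)
    if r_defined:
        tc, rc = test - test.mean(), ref - ref.mean()
        r = float(np.sum(tc * rc) / np.sqrt(np.sum(tc**2) * np.sum(rc**2)))
    else:
        r = float("nan")
    bias = float(np.mean(e))
    return AgreementReport(
        rmse=rmse, mae=mae, sd_error=sd, pearson_r=r, bias=bias,
        loa_low=bias - 1.96 * sd, loa_high=bias + 1.96 * sd,
        n_pairs=n, r_defined=r_defined,
    )


def bland_altman(test: np.ndarray, ref: np.ndarray):
    """Bias, limits of agreement and the per-pair (mean, difference) table."""
    test = np.asarray(test, dtype=float)
    ref = np.asarray(ref, dtype=float)
    d = test - ref
    bias = float(np.mean(d))
    sd = float(np.std(d, ddof=1)) if len(d) > 1 else 0.0
    table = pd.DataFrame({"mean": (test + ref) / 2.0, "difference": d})
    return bias, (bias - 1.96 * sd, bias + 1.96 * sd), table


# ---------------------------------------------------------------------------
# Wilcoxon signed-rank


@dataclass
class WilcoxonResult:
    statistic: float        # W+ = sum of ranks of positive differences
    p_value: float
    n_used: int             # non-zero differences
    degenerate: bool = False


def wilcoxon_signed_rank(
    x, y=None, alternative: str = "two-sided", exact_max_n: int = 15
) -> WilcoxonResult:
    """Wilcoxon signed-rank test on paired samples (or pre-computed
    differences when ``y`` is omitted).

    Zero differences are dropped; tied magnitudes receive mid-ranks.  For
    n <= ``exact_max_n`` the p-value is exact, by enumerating all 2^n sign
    assignments of the observed ranks; above that a normal approximation
    with tie correction and a 0.5 continuity correction is used.
    """
    from scipy.stats import rankdata

    if alternative not in ("two-sided", "greater", "less"):
        raise ParameterError(f"unknown alternative {alternative!r}")
    d = np.asarray(x, dtype=float) - (np.asarray(y, dtype=float) if y is not None else 0.0)
    d = d[d != 0]
    n = len(d)
    if n == 0:
        return WilcoxonResult(statistic=0.0, p_value=1.0, n_used=0, degenerate=True)
    ranks = rankdata(np.abs(d))
    w_pos = float(np.sum(ranks[d > 0]))

    if n <= exact_max_n:
        # distribution of W+ over all equally likely sign assignments
        totals = np.zeros(1)
        for r in ranks:
            totals = np.concatenate([totals, totals + r])
        ge = float(np.mean(totals >= w_pos - 1e-12))
        le = float(np.mean(totals <= w_pos + 1e-12))
        if alternative == "greater":
            p = ge
        elif alternative == "less":
            p = le
        else:
            p = min(1.0, 2.0 * min(ge, le))
    else:
        mu = n * (n + 1) / 4.0
        var = n * (n + 1) * (2 * n + 1) / 24.0
        _, counts = np.unique(ranks, return_counts=True)
        var -= float(np.sum(counts**3 - counts)) / 48.0
        sd = np.sqrt(var)
        from scipy.stats import norm

        if alternative == "greater":
            p = float(norm.sf((w_pos - mu - 0.5) / sd))
        elif alternative == "less":
            p = float(norm.cdf((w_pos - mu + 0.5) / sd))
        else:
            z = (w_pos - mu - np.sign(w_pos - mu) * 0.5) / sd
            p = float(min(1.0, 2.0 * norm.sf(abs(z))))
    return WilcoxonResult(statistic=w_pos, p_value=p, n_used=n)


# ---------------------------------------------------------------------------
# study-level report


@dataclass
class StudyReport:
    """Machine-readable agreement table plus per-condition quality summary."""

    table: pd.DataFrame                       # metric x condition rows
    per_subject: pd.DataFrame                 # per-subject breakdown
    psqi_by_condition: dict[str, float]       # mean device pSQI per condition
    gate_threshold: float

    def to_json(self, path=None) -> str:
        payload = {
            "gate_threshold": self.gate_threshold,
            "psqi_by_condition": self.psqi_by_condition,
            "table": self.table.to_dict(orient="records"),
        }
        text = json.dumps(payload, indent=2, default=float)
        if path is not None:
            Path(path).write_text(text)
        return text

    def summary(self) -> str:
        lines = ["Agreement by metric and condition (test vs reference):"]
        for _, row in self.table.iterrows():
            lines.append(
                f"  {row['metric']:>6} | {row['condition']:<10} | "
                f"RMSE {row['rmse']:6.2f}  MAE {row['mae']:6.2f}  "
                f"SD {row['sd_error']:6.2f}  r {row['pearson_r']:5.2f}  "
                f"(n={int(row['n_pairs'])})"
            )
        lines.append("Mean device pSQI by condition: " + ", ".join(
            f"{k}={v:.1f}%" for k, v in self.psqi_by_condition.items()))
        return "\n".join(lines)


def _pair_metric_windows(pair, window: WindowParams, metric: str, total_s: float):
    compute = hr_windowed if metric == "hr" else prv_windowed
    test = compute(extract_ibi(pair.device), window, total_s=total_s)
    ref = compute(extract_ibi(pair.reference), window, total_s=total_s)
    return test, ref


def condition_report(
    study: StudyDataset,
    gate_threshold: float = 40.0,
    metrics: tuple[str, ...] = ("hr", "pnn50"),
) -> StudyReport:
    """Full validation analysis of a simulated study.

    For each subject x condition pair, both recordings pass through the
    band-pass / beat-detection / windowing pipeline (30 s / 10 s windows for
    HR, 120 s / 10 s for pNN50).  Windows whose reference pSQI falls below
    ``gate_threshold`` percent are discarded from both series; survivors
    are pooled across subjects within each condition (and across everything
    for the combined row) before agreement statistics are computed.
    """
    total_s = study.protocol.condition_duration
    windows = {"hr": HR_WINDOW, "pnn50": PRV_WINDOW}
    pooled: dict[tuple[str, str], list[tuple[np.ndarray, np.ndarray]]] = {}
    per_subject_rows = []
    psqi_acc: dict[str, list[float]] = {c: [] for c in study.conditions}

    for pair in study.pairs:
        dev_psqi = psqi_windowed(pair.device, HR_WINDOW, total_s=total_s)
        psqi_acc[pair.condition].append(float(np.nanmean(dev_psqi.values)))
        for metric in metrics:
            w = windows[metric]
            test, ref = _pair_metric_windows(pair, w, metric, total_s)
            ref_q = psqi_windowed(pair.reference, w, total_s=total_s)
            test_g, ref_g, _ = quality_gate(test, ref, ref_q, gate_threshold)
            tv, rv, _ = align_pairs(test_g, ref_g)
            pooled.setdefault((metric, pair.condition), []).append((tv, rv))
            if len(tv) >= 3:
                rep = agreement_stats(tv, rv)
                per_subject_rows.append({
                    "subject": pair.subject, "condition": pair.condition,
                    "metric": metric, "rmse": rep.rmse, "mae": rep.mae,
                    "pearson_r": rep.pearson_r, "n_pairs": rep.n_pairs,
                })

    rows = []
    for metric in metrics:
        combined_t, combined_r = [], []
        for cond in study.conditions:
            chunks = pooled.get((metric, cond), [])
            tv = np.concatenate([c[0] for c in chunks]) if chunks else np.array([])
            rv = np.concatenate([c[1] for c in chunks]) if chunks else np.array([])
            combined_t.append(tv)
            combined_r.append(rv)
            if len(tv) >= 3:
                rows.append({"metric": metric, "condition": cond,
                             **agreement_stats(tv, rv).__dict__})
        tv, rv = np.concatenate(combined_t), np.concatenate(combined_r)
        if len(tv) >= 3:
            rows.append({"metric": metric, "condition": "combined",
                         **agreement_stats(tv, rv).__dict__})

    return StudyReport(
        table=pd.DataFrame(rows),
        per_subject=pd.DataFrame(per_subject_rows),
        psqi_by_condition={c: float(np.mean(v)) for c, v in psqi_acc.items() if v},
        gate_threshold=gate_threshold,
    )


# ---------------------------------------------------------------------------
# batch analysis of recorded sessions


def analyze_batch(session_dir, config: dict | None = None):
    """Analyze every session listed in a directory's manifest.

    ``manifest.json`` maps each session file to its participant and
    condition.  Each session runs through the preprocess -> metrics ->
    quality pipeline per channel; per-window values are summarized into one
    row per (participant, condition, channel, metric).  Output is written
    as ``summary.csv`` (spreadsheet) and ``summary.npz`` (keyed arrays);
    ill-formed sessions are logged and skipped, the batch continues.

    Returns ``(summary DataFrame, errors dict)``.
    """
    from .io_stream import read_session

    config = config or {}
    window_s = float(config.get("window_s", HR_WINDOW.window_s))
    step_s = float(config.get("step_s", HR_WINDOW.step_s))
    metric_names = list(config.get("metrics", ["hr", "pnn50"]))
    wp = WindowParams(window_s=window_s, step_s=step_s)

    session_dir = Path(session_dir)
    manifest = json.loads((session_dir / "manifest.json").read_text())
    rows, errors = [], {}
    arrays: dict[str, np.ndarray] = {}
    for entry in manifest["sessions"]:
        path = session_dir / entry["file"]
        try:
            session = read_session(path)
        except Exception as exc:  # per-file isolation: batch must continue
            errors[entry["file"]] = str(exc)
            continue
        for channel, samples in session.channels.items():
            from .records import PPGRecord

            rec = PPGRecord(samples=samples, fs=session.fs, channel=channel)
            ibi = extract_ibi(rec)
            for metric in metric_names:
                compute = hr_windowed if metric == "hr" else prv_windowed
                series = compute(ibi, wp if metric == "hr" else PRV_WINDOW,
                                 total_s=rec.duration)
                vals = series.values[series.valid]
                rows.append({
                    "participant": entry.get("participant", ""),
                    "condition": entry.get("condition", ""),
                    "channel": channel, "metric": metric,
                    "mean": float(np.mean(vals)) if len(vals) else float("nan"),
                    "sd": float(np.std(vals, ddof=1)) if len(vals) > 1 else float("nan"),
                    "n_windows": int(len(vals)),
                })
                key = f"{entry.get('participant','')}/{entry.get('condition','')}/{channel}/{metric}"
                arrays[key] = series.values

    summary = pd.DataFrame(rows)
    summary = summary.sort_values(
        ["participant", "condition", "channel", "metric"]
    ).reset_index(drop=True)
    out_csv = session_dir / "summary.csv"
    summary.to_csv(out_csv, index=False, float_format="%.6f", lineterminator="\n")
    np.savez(session_dir / "summary.npz", **arrays)
    return summary, errors
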