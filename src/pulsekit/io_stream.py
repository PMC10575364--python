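"""Session files, configuration, real-time streaming and multi-node sync.

Session format: one CSV per recording — a header row of channel names, one
row per sample, an ``event_code`` column (0 = no event; asynchronous events
are contiguous non-zero runs) and, per annotated channel, a
``quality_<channel>`` column in which each 0.5 s quality label is repeated
for every sample of its cell so the whole session stays in a single
rectangular file.  A JSON sidecar (``<file>.meta.json``) carries the
sampling rate, participant/condition identifiers and the UTC start time.

The streaming engine turns a sample iterator into a timed series of metric
values with the same half-open window convention as offline analysis, so
online and offline results agree exactly on identical samples.

The sync protocol is a line-delimited text protocol over TCP: clients greet
with HELLO and idle until the server broadcasts START with a shared session
id and timestamp; recording stops on STOP.  It is deliberately tiny — the
state machine is a plain class, so it can be tested without sockets.
"""

from __future__ import annotations

import csv
import json
import socket
import threading
import time
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Iterable, Iterator, Optional

import numpy as np

from .records import ParameterError, PPGRecord, QualityVector

__all__ = [
    "FormatError",
    "ValidationError",
    "ProtocolError",
    "SessionRecord",
    "ExperimentConfig",
    "SoftwareConfig",
    "write_session",
    "read_session",
    "write_study",
    "parse_experiment_config",
    "parse_software_config",
    "stream_engine",
    "windowed_apply",
    "biofeedback_map",
    "sync_serialize",
    "sync_parse",
    "SyncClientState",
    "run_sync_server",
    "run_sync_client",
    "synthetic_serial_source",
]


class FormatError(ValueError):
    """A session file violates the CSV layout."""


class ValidationError(ValueError):
    """A configuration file violates its schema; carries every violation."""

    def __init__(self, problems: list[str]):
        self.problems = problems
        super().__init__("; ".join(problems))


class ProtocolError(ValueError):
    """A sync-protocol message or transition was invalid."""


# ---------------------------------------------------------------------------
# session CSV


@dataclass
class SessionRecord:
    channels: dict[str, np.ndarray]
    fs: float
    event_code: np.ndarray
    quality: dict[str, QualityVector]
    meta: dict


def _events_to_codes(events, n: int, fs: float) -> np.ndarray:
    """(start_s, end_s, code) triples -> per-sample code column."""
    codes = np.zeros(n, dtype=int)
    for start, end, code in events or []:
        lo = max(0, int(round(start * fs)))
        hi = min(n, int(round(end * fs)))
        codes[lo:hi] = int(code)
    return codes


def write_session(
    records: dict[str, PPGRecord],
    path,
    events=None,
    quality: dict[str, QualityVector] | None = None,
    meta: dict | None = None,
) -> None:
    """Write channels + events + repeated quality labels to CSV + sidecar.

    ``events`` is either a per-sample integer code array or a list of
    ``(start_s, end_s, code)`` triples.  All channels must share length and
    sampling rate.
    """
    if not records:
        raise ParameterError("need at least one channel")
    names = list(records)
    fs = records[names[0]].fs
    n = len(records[names[0]])
    for name, rec in records.items():
        if rec.fs != fs or len(rec) != n:
            raise ParameterError(f"channel {name!r} does not match length/rate")
    if events is None:
        codes = np.zeros(n, dtype=int)
    elif isinstance(events, (list, tuple)):
        codes = _events_to_codes(events, n, fs)
    else:
        codes = np.asarray(events, dtype=int)
        if len(codes) != n:
            raise ParameterError("event code column must match sample count")

    quality = quality or {}
    q_cols: dict[str, np.ndarray] = {}
    for name, qv in quality.items():
        per_sample = np.repeat(qv.scores, int(round(qv.resolution_s * fs)))
        col = np.full(n, np.nan)
        col[:min(n, len(per_sample))] = per_sample[:n]
        q_cols[name] = col

    path = Path(path)
    with path.open("w", newline="") as fh:
        writer = csv.writer(fh, lineterminator="\n")
        writer.writerow(names + ["event_code"] + [f"quality_{c}" for c in q_cols])
        cols = [records[c].samples for c in names]
        for i in range(n):
            row = [repr(float(col[i])) for col in cols]
            row.append(str(int(codes[i])))
            row += ["" if np.isnan(q_cols[c][i]) else repr(float(q_cols[c][i]))
                    for c in q_cols]
            writer.writerow(row)
    sidecar = {"fs": fs, "n_samples": n, "channels": names, **(meta or {})}
    Path(str(path) + ".meta.json").write_text(json.dumps(sidecar, indent=2))


def read_session(path) -> SessionRecord:
    """Read a session CSV + sidecar back into arrays.

    Raises :class:`FormatError` naming the offending row for ragged or
    truncated files, and for non-numeric fields.
    """
    path = Path(path)
    sidecar_path = Path(str(path) + ".meta.json")
    if not sidecar_path.exists():
        raise FormatError(f"missing sidecar {sidecar_path.name}")
    meta = json.loads(sidecar_path.read_text())
    with path.open(newline="") as fh:
        reader = csv.reader(fh)
        try:
            header = next(reader)
        except StopIteration:
            raise FormatError("empty session file") from None
        if "event_code" not in header:
            raise FormatError("header lacks required event_code column")
        rows = []
        for lineno, row in enumerate(reader, start=2):
            if len(row) != len(header):
                raise FormatError(
                    f"row {lineno}: expected {len(header)} fields, got {len(row)}"
                )
            rows.append(row)
    ev_idx = header.index("event_code")
    ch_names = header[:ev_idx]
    q_names = [h[len("quality_"):] for h in header[ev_idx + 1:]]
    n = len(rows)
    if n != meta.get("n_samples", n):
        raise FormatError(
            f"file has {n} samples but sidecar declares {meta.get('n_samples')}"
        )
    data = np.empty((n, ev_idx))
    codes = np.empty(n, dtype=int)
    q_data = {name: np.full(n, np.nan) for name in q_names}
    for i, row in enumerate(rows):
        try:
            for j in range(ev_idx):
                data[i, j] = float(row[j])
            codes[i] = int(row[ev_idx])
            for k, name in enumerate(q_names):
                cell = row[ev_idx + 1 + k]
                if cell:
                    q_data[name][i] = float(cell)
        except ValueError as exc:
            raise FormatError(f"row {i + 2}: {exc}") from None
    fs = float(meta["fs"])
    cells = int(round(0.5 * fs))
    quality = {}
    for name, col in q_data.items():
        n_cells = int(np.floor(n / cells))
        scores = col[:n_cells * cells:cells]
        labeled = ~np.isnan(scores)
        scores = np.where(labeled, scores, 0.0)
        quality[name] = QualityVector(scores=scores, labeled=labeled)
    return SessionRecord(
        channels={name: data[:, j].copy() for j, name in enumerate(ch_names)},
        fs=fs, event_code=codes, quality=quality, meta=meta,
    )


def write_study(dataset, out_dir) -> Path:
    """Write a simulated study as session CSVs plus a JSON manifest."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    sessions = []
    for pair in dataset.pairs:
        fname = f"s{pair.subject:02d}_{pair.condition}.csv"
        write_session(
            {"reference": pair.reference, "device": pair.device},
            out_dir / fname,
            quality={"device": pair.quality_truth},
            meta={"participant": f"s{pair.subject:02d}", "condition": pair.condition},
        )
        sessions.append({
            "file": fname, "participant": f"s{pair.subject:02d}",
            "condition": pair.condition,
        })
    manifest = {"seed": dataset.protocol.seed, "sessions": sessions}
    (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return out_dir / "manifest.json"


# ---------------------------------------------------------------------------
# configuration files (JSON)


@dataclass
class ExperimentConfig:
    conditions: list[str]
    timed_acquisition: bool = True
    max_time_seconds: float = 180.0
    channels: list[tuple[str, str]] = field(default_factory=list)
    plot_channels: list[str] = field(default_factory=list)
    data_root: str = "."
    biofeedback: Optional[dict] = None


@dataclass
class SoftwareConfig:
    sampling_rate: float = 250.0
    baudrate: int = 115200
    role: str = "server"
    server_address: Optional[str] = None
    port: int = 5555


def parse_experiment_config(path) -> ExperimentConfig:
    raw = json.loads(Path(path).read_text())
    problems: list[str] = []
    conditions = raw.get("conditions", [])
    if not conditions:
        problems.append("at least one condition is required")
    timed = bool(raw.get("timed_acquisition", True))
    max_time = float(raw.get("max_time_seconds", 180.0))
    if timed and max_time <= 0:
        problems.append("timed_acquisition requires max_time_seconds > 0")
    channels = [tuple(c) for c in raw.get("channels", [])]
    plot_channels = list(raw.get("plot_channels", [c[0] for c in channels][:4]))
    if len(plot_channels) > 4:
        problems.append(
            f"{len(plot_channels)} channels marked for plotting; the maximum is 4"
        )
    known = {c[0] for c in channels}
    for p in plot_channels:
        if known and p not in known:
            problems.append(f"plot channel {p!r} is not a configured channel")
    bf = raw.get("biofeedback")
    if bf is not None:
        for key in ("metric", "window_s", "step_s", "metric_min", "metric_max"):
            if key not in bf:
                problems.append(f"biofeedback config missing {key!r}")
        if "metric_min" in bf and "metric_max" in bf and not bf["metric_min"] < bf["metric_max"]:
            problems.append("biofeedback metric_min must be below metric_max")
    if problems:
        raise ValidationError(problems)
    return ExperimentConfig(
        conditions=list(conditions), timed_acquisition=timed,
        max_time_seconds=max_time, channels=channels,
        plot_channels=plot_channels, data_root=raw.get("data_root", "."),
        biofeedback=bf,
    )


def parse_software_config(path) -> SoftwareConfig:
    raw = json.loads(Path(path).read_text())
    problems: list[str] = []
    fs = float(raw.get("sampling_rate", 250.0))
    if not 10 <= fs <= 10000:
        problems.append(f"sampling_rate {fs} outside the supported 10-10000 Hz range")
    role = raw.get("role", "server")
    if role not in ("server", "client"):
        problems.append(f"role must be 'server' or 'client', got {role!r}")
    server_address = raw.get("server_address")
    if role == "client" and not server_address:
        problems.append("client role requires server_address")
    port = int(raw.get("port", 5555))
    if not 0 < port < 65536:
        problems.append(f"port {port} out of range")
    if problems:
        raise ValidationError(problems)
    return SoftwareConfig(
        sampling_rate=fs, baudrate=int(raw.get("baudrate", 115200)),
        role=role, server_address=server_address, port=port,
    )


# ---------------------------------------------------------------------------
# real-time metric streaming


def stream_engine(
    source: Iterable[float],
    metric: Callable[[np.ndarray, float], float],
    fs: float,
    window_s: float,
    step_s: float,
) -> Iterator[tuple[float, float]]:
    """Turn a sample stream into a timed metric stream.

    Yields ``(window_start_s, value)`` once per step after the first full
    window; the trailing window passed to ``metric`` covers exactly
    ``[k*step, k*step + window)``, matching offline windowing, so online
    and offline values are identical on the same samples.  A starved source
    simply ends the stream — no value is fabricated.
    """
    if step_s > window_s:
        raise ParameterError("step_s must not exceed window_s")
    win_n = int(round(window_s * fs))
    step_n = int(round(step_s * fs))
    buf: list[float] = []
    k = 0
    for sample in source:
        buf.append(float(sample))
        needed = k * step_n + win_n
        if len(buf) >= needed:
            window = np.asarray(buf[k * step_n:needed])
            yield (k * step_s, float(metric(window, fs)))
            k += 1


def windowed_apply(
    samples: np.ndarray,
    fs: float,
    metric: Callable[[np.ndarray, float], float],
    window_s: float,
    step_s: float,
) -> list[tuple[float, float]]:
    """Offline counterpart of :func:`stream_engine` (same convention)."""
    samples = np.asarray(samples, dtype=float)
    win_n = int(round(window_s * fs))
    step_n = int(round(step_s * fs))
    out = []
    k = 0
    while k * step_n + win_n <= len(samples):
        window = samples[k * step_n:k * step_n + win_n]
        out.append((k * step_s, float(metric(window, fs))))
        k += 1
    return out


def biofeedback_map(value: float, metric_min: float, metric_max: float) -> float:
    """Linear map of a metric value onto [0, 1], clamped at both ends."""
    if not metric_min < metric_max:
        raise ParameterError("metric_min must be below metric_max")
    if np.isnan(value):
        return 0.0
    return float(np.clip((value - metric_min) / (metric_max - metric_min), 0.0, 1.0))


# ---------------------------------------------------------------------------
# sync protocol


_MSG_FIELDS = {
    "HELLO": ("client_id",),
    "ACK": (),
    "START": ("session_id", "utc_time"),
    "STOP": ("session_id",),
    "MARK": ("code", "state"),
    "ERROR": ("reason",),
}


def sync_serialize(msg: dict) -> str:
    """Message dict -> one protocol line (newline-terminated)."""
    kind = msg.get("type")
    if kind not in _MSG_FIELDS:
        raise ProtocolError(f"unknown message type {kind!r}")
    parts = [kind] + [str(msg[f]) for f in _MSG_FIELDS[kind]]
    for p in parts:
        if " " in p[1:] and kind != "ERROR":
            raise ProtocolError(f"field value {p!r} may not contain spaces")
    if kind == "ERROR":
        return f"ERROR {msg['reason']}\n"
    return " ".join(parts) + "\n"


def sync_parse(line: str | bytes) -> dict:
    """One protocol line -> message dict; malformed lines raise."""
    if isinstance(line, bytes):
        line = line.decode("utf-8", errors="replace")
    parts = line.strip().split(" ")
    if not parts or parts[0] not in _MSG_FIELDS:
        raise ProtocolError(f"unknown message type in line {line!r}")
    kind = parts[0]
    fields = _MSG_FIELDS[kind]
    if kind == "ERROR":
        return {"type": "ERROR", "reason": " ".join(parts[1:])}
    if len(parts) - 1 != len(fields):
        raise ProtocolError(
            f"{kind} expects {len(fields)} fields, got {len(parts) - 1}"
        )
    msg = {"type": kind}
    msg.update(zip(fields, parts[1:]))
    if kind == "MARK" and msg["state"] not in ("on", "off"):
        raise ProtocolError("MARK state must be 'on' or 'off'")
    return msg


class SyncClientState:
    """Client-side protocol state machine, transport-agnostic.

    Feed it parsed messages with :meth:`handle`; it returns the action the
    transport layer should take.  Recording happens strictly between START
    and STOP; a STOP without a START, or a START for a second session while
    one is active, is a protocol error.  Duplicate START for the *same*
    session id is idempotent.
    """

    def __init__(self, client_id: str):
        self.client_id = client_id
        self.greeted = False
        self.session_id: Optional[str] = None
        self.start_time: Optional[str] = None
        self.marks: list[tuple[str, str]] = []

    def hello_line(self) -> str:
        return sync_serialize({"type": "HELLO", "client_id": self.client_id})

    def handle(self, msg: dict) -> str:
        kind = msg["type"]
        if kind == "ACK":
            self.greeted = True
            return "greeted"
        if kind == "START":
            if not self.greeted:
                raise ProtocolError("START before HELLO/ACK handshake")
            if self.session_id == msg["session_id"]:
                return "recording"  # idempotent duplicate
            if self.session_id is not None:
                raise ProtocolError("START while another session is active")
            self.session_id = msg["session_id"]
            self.start_time = msg["utc_time"]
            return "recording"
        if kind == "STOP":
            if self.session_id is None:
                raise ProtocolError("STOP without an active session")
            if msg["session_id"] != self.session_id:
                raise ProtocolError("STOP for an unknown session")
            return "stopped"
        if kind == "MARK":
            if self.session_id is None:
                raise ProtocolError("MARK outside a session")
            self.marks.append((msg["code"], msg["state"]))
            return "marked"
        raise ProtocolError(f"client cannot handle {kind}")

    @property
    def recording(self) -> bool:
        return self.session_id is not None


def run_sync_server(
    host: str,
    port: int,
    n_clients: int,
    session_id: str,
    record_s: float = 0.2,
    utc_time: str | None = None,
) -> dict:
    """Accept ``n_clients``, handshake, broadcast START, wait, broadcast STOP.

    Returns the session metadata it broadcast.  Binds ``port`` (0 picks a
    free port; the chosen one is returned in the result).
    """
    utc_time = utc_time or time.strftime("%Y-%m-%dT%H:%M:%SZ", time.gmtime())
    srv = socket.create_server((host, port))
    srv.settimeout(10.0)
    conns = []
    try:
        actual_port = srv.getsockname()[1]
        for _ in range(n_clients):
            conn, _addr = srv.accept()
            conn.settimeout(10.0)
            fh = conn.makefile("rw")
            msg = sync_parse(fh.readline())
            if msg["type"] != "HELLO":
                fh.write(sync_serialize({"type": "ERROR", "reason": "expected HELLO"}))
                fh.flush()
                conn.close()
                continue
            fh.write(sync_serialize({"type": "ACK"}))
            fh.flush()
            conns.append((conn, fh))
        start = sync_serialize({"type": "START", "session_id": session_id,
                                "utc_time": utc_time})
        for _conn, fh in conns:
            fh.write(start)
            fh.flush()
        time.sleep(record_s)
        stop = sync_serialize({"type": "STOP", "session_id": session_id})
        for _conn, fh in conns:
            fh.write(stop)
            fh.flush()
        return {"session_id": session_id, "utc_time": utc_time,
                "port": actual_port, "n_clients": len(conns)}
    finally:
        for conn, fh in conns:
            fh.close()
            conn.close()
        srv.close()


def run_sync_client(
    host: str,
    port: int,
    client_id: str,
    source: Iterable[float],
    fs: float,
    out_path,
) -> dict:
    """Connect, handshake, idle until START, record until STOP, write session.

    Samples are drawn from ``source`` only while recording.  Returns the
    session metadata; no file is written unless a session actually ran.
    """
    state = SyncClientState(client_id)
    with socket.create_connection((host, port), timeout=10.0) as sock:
        fh = sock.makefile("rw")
        fh.write(state.hello_line())
        fh.flush()
        it = iter(source)
        samples: list[float] = []
        while True:
            line = fh.readline()
            if not line:
                break
            action = state.handle(sync_parse(line))
            if action == "recording" and not samples:
                # drain the (simulated) source for this session
                samples = [float(s) for s in it]
            elif action == "stopped":
                break
    if state.session_id is None:
        raise ProtocolError("server closed before starting a session")
    rec = PPGRecord(samples=np.asarray(samples, dtype=float), fs=fs, channel="ppg")
    write_session({"ppg": rec}, out_path, meta={
        "session_id": state.session_id, "start_time": state.start_time,
        "client_id": client_id,
    })
    return {"session_id": state.session_id, "start_time": state.start_time,
            "n_samples": len(samples), "file": str(out_path)}


# ---------------------------------------------------------------------------
# synthetic serial source


def synthetic_serial_source(
    spec_or_path,
    fs: float | None = None,
    channel: str | None = None,
    adc_bits: int = 12,
    realtime: bool = False,
) -> Iterator[int]:
    """Emulate a device sample stream.

    Given a :class:`~pulsekit.simulate.SimulationSpec`, renders the signal
    and emits integer ADC counts (full-scale over ``adc_bits``); given a
    session file path, replays the stored channel.  ``realtime`` paces the
    stream at the nominal rate; the default replays as fast as possible
    (test mode).  Warns when ``fs`` disagrees with the source's own rate.
    """
    from .simulate import SimulationSpec, generate_ibi_series, render_ppg

    if isinstance(spec_or_path, SimulationSpec):
        spec = spec_or_path
        if fs is not None and fs != spec.fs:
            warnings.warn(
                f"requested fs {fs} Hz != simulation fs {spec.fs} Hz; using {spec.fs}",
                stacklevel=2,
            )
        rec = render_ppg(generate_ibi_series(spec), spec.fs, spec.template)
        x = rec.samples
        src_fs = spec.fs
        lo, hi = float(np.min(x)), float(np.max(x))
        span = (hi - lo) or 1.0
        values = np.round((x - lo) / span * (2**adc_bits - 1)).astype(int)
    else:
        session = read_session(spec_or_path)
        name = channel or next(iter(session.channels))
        if fs is not None and fs != session.fs:
            warnings.warn(
                f"requested fs {fs} Hz != session fs {session.fs} Hz; using {session.fs}",
                stacklevel=2,
            )
        values = session.channels[name]
        src_fs = session.fs
    period = 1.0 / src_fs
    for v in values:
        if realtime:
            time.sleep(period)
        yield int(v) if float(v).is_integer() else float(v)
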