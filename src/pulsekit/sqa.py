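"""Dense signal-quality assessment with a 1D-CNN encoder-decoder.

The model maps an 8 s PPG segment (resampled to a fixed internal rate of
64 Hz, i.e. 512 samples, and z-scored) to 16 clean-probability scores, one
per 0.5 s cell — dense inference rather than a single per-segment label, so
short artifacts are localized instead of condemning a whole segment.

Architecture: four convolutional encoder blocks (widths 16/32/64/64, kernel
7, ReLU), each a stride-2 downsampling convolution followed by a stride-1
refinement convolution, shrink 512 samples to a 32-step feature map (two
steps per 0.5 s cell); the decoder head is one more such block onto the
16-cell label grid followed by a 1x1 convolution and a sigmoid squash.
Training minimizes per-cell binary cross-entropy with Adam under a step
learning-rate schedule, with the train/validation split made on subject
identity so no simulated subject leaks across the split.

The network, backpropagation and Adam are implemented directly on numpy
(im2col convolutions via ``sliding_window_view``); the model is small enough
that CPU training takes a couple of minutes.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field

import numpy as np

from .preprocess import resample
from .records import ParameterError, PPGRecord, QualityVector

__all__ = [
    "SQAConfig",
    "TrainConfig",
    "SQAModel",
    "SegmentCorpus",
    "build_sqa",
    "train_sqa",
    "sqa_infer",
    "annotate_recording",
    "build_corpus",
    "save_checkpoint",
    "load_checkpoint",
]


@dataclass
class SQAConfig:
    input_s: float = 8.0
    label_res: float = 0.5
    input_fs: float = 64.0
    encoder_widths: tuple[int, ...] = (16, 32, 64, 64)
    kernel: int = 7

    def __post_init__(self) -> None:
        if abs(self.input_s / self.label_res - round(self.input_s / self.label_res)) > 1e-9:
            raise ParameterError("input_s must be an integer multiple of label_res")
        n = self.input_samples
        # encoder blocks + the decoder stage each halve the length; the
        # result must land exactly on the label grid
        stages = len(self.encoder_widths) + 1
        if n / (2 ** stages) != self.n_labels:
            raise ParameterError(
                f"{n} input samples cannot reach {self.n_labels} outputs "
                f"through {stages} stride-2 stages"
            )

    @property
    def input_samples(self) -> int:
        return int(round(self.input_s * self.input_fs))

    @property
    def n_labels(self) -> int:
        return int(round(self.input_s / self.label_res))


@dataclass
class TrainConfig:
    batch_size: int = 256
    learning_rate: float = 1.5e-3
    epochs: int = 60
    lr_decay_factor: float = 0.2        # step decay near the end of training
    lr_decay_epoch_frac: float = 0.75   # fraction of epochs before the step
    val_fraction: float = 0.25          # fraction of *subjects* held out
    seed: int = 0

    def __post_init__(self) -> None:
        if self.batch_size < 1:
            raise ParameterError("batch_size must be >= 1")
        if not 0 < self.val_fraction < 1:
            raise ParameterError("val_fraction must lie in (0, 1)")


# ---------------------------------------------------------------------------
# numpy conv layers


def _conv1d_forward(x: np.ndarray, w: np.ndarray, b: np.ndarray, stride: int,
                    pad: int) -> tuple[np.ndarray, tuple]:
    """x: (B, C_in, L) -> y: (B, C_out, L_out); returns cache for backward."""
    xp = np.pad(x, ((0, 0), (0, 0), (pad, pad)))
    k = w.shape[2]
    win = np.lib.stride_tricks.sliding_window_view(xp, k, axis=2)[:, :, ::stride, :]
    y = np.einsum("bclk,ock->bol", win, w, optimize=True) + b[None, :, None]
    return y, (win, xp.shape, x.shape, w, stride, pad)


def _conv1d_backward(dy: np.ndarray, cache: tuple):
    win, xp_shape, x_shape, w, stride, pad = cache
    k = w.shape[2]
    dw = np.einsum("bol,bclk->ock", dy, win, optimize=True)
    db = dy.sum(axis=(0, 2))
    dxp = np.zeros(xp_shape)
    l_out = dy.shape[2]
    for kk in range(k):
        contrib = np.einsum("bol,oc->bcl", dy, w[:, :, kk], optimize=True)
        dxp[:, :, kk:kk + stride * l_out:stride] += contrib
    dx = dxp[:, :, pad:pad + x_shape[2]] if pad else dxp
    return dx, dw, db


def _sigmoid(z: np.ndarray) -> np.ndarray:
    out = np.empty_like(z)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


def _bce_with_logits(z: np.ndarray, y: np.ndarray) -> tuple[float, np.ndarray]:
    """Stable mean binary cross-entropy and its gradient wrt logits."""
    loss = np.mean(np.maximum(z, 0) - z * y + np.log1p(np.exp(-np.abs(z))))
    grad = (_sigmoid(z) - y) / z.size
    return float(loss), grad


class SQAModel:
    """The encoder-decoder network: parameter store plus forward/backward."""

    def __init__(self, cfg: SQAConfig, seed: int = 0):
        self.cfg = cfg
        rng = np.random.default_rng(seed)
        self.weights: list[np.ndarray] = []
        self.biases: list[np.ndarray] = []
        self.strides: list[int] = []
        c_in = 1
        k = cfg.kernel
        # encoder blocks + decoder stage: stride-2 downsampling conv, then a
        # stride-1 refinement conv, all kernel-7
        widths = list(cfg.encoder_widths) + [cfg.encoder_widths[-1] // 2]
        for c_out in widths:
            for stride in (2, 1):
                scale = np.sqrt(2.0 / (c_in * k))  # He init for ReLU stacks
                self.weights.append(rng.normal(0.0, scale, size=(c_out, c_in, k)))
                self.biases.append(np.zeros(c_out))
                self.strides.append(stride)
                c_in = c_out
        # 1x1 conv head onto a single clean-logit channel
        scale = np.sqrt(1.0 / c_in)
        self.weights.append(rng.normal(0.0, scale, size=(1, c_in, 1)))
        self.biases.append(np.zeros(1))
        self.strides.append(1)
        self._caches: list = []

    @property
    def n_parameters(self) -> int:
        return sum(w.size for w in self.weights) + sum(b.size for b in self.biases)

    def forward(self, x: np.ndarray, keep_cache: bool = False) -> np.ndarray:
        """x: (B, input_samples) -> logits (B, n_labels)."""
        if x.ndim != 2 or x.shape[1] != self.cfg.input_samples:
            raise ParameterError(
                f"expected (batch, {self.cfg.input_samples}) input, got {x.shape}"
            )
        h = x[:, None, :]
        caches = []
        pad = self.cfg.kernel // 2
        for i in range(len(self.weights) - 1):
            z, cache = _conv1d_forward(h, self.weights[i], self.biases[i],
                                       stride=self.strides[i], pad=pad)
            mask = z > 0
            h = z * mask
            caches.append((cache, mask))
        z, cache = _conv1d_forward(h, self.weights[-1], self.biases[-1], stride=1, pad=0)
        caches.append((cache, None))
        if keep_cache:
            self._caches = caches
        return z[:, 0, :]

    def backward(self, dlogits: np.ndarray) -> tuple[list[np.ndarray], list[np.ndarray]]:
        """Gradient of the loss wrt every parameter, given d(loss)/d(logits)."""
        grads_w: list[np.ndarray] = [None] * len(self.weights)
        grads_b: list[np.ndarray] = [None] * len(self.biases)
        dy = dlogits[:, None, :]
        cache, _ = self._caches[-1]
        dy, grads_w[-1], grads_b[-1] = _conv1d_backward(dy, cache)
        for i in range(len(self.weights) - 2, -1, -1):
            cache, mask = self._caches[i]
            dy = dy * mask
            dy, grads_w[i], grads_b[i] = _conv1d_backward(dy, cache)
        return grads_w, grads_b

    def predict_scores(self, x: np.ndarray) -> np.ndarray:
        """Clean-probability scores in [0, 1], shape (B, n_labels)."""
        return _sigmoid(self.forward(x))


def build_sqa(cfg: SQAConfig | None = None, seed: int = 0) -> SQAModel:
    """Deterministically initialized model for the given configuration."""
    return SQAModel(cfg or SQAConfig(), seed=seed)


# ---------------------------------------------------------------------------
# training corpus


@dataclass
class SegmentCorpus:
    """Labelled 8 s segments grouped by (synthetic) subject.

    ``segments``: (N, input_samples) z-scored; ``labels``: (N, n_labels)
    with 1 = clean; ``subjects``: (N,) integer subject ids.
    """

    segments: np.ndarray
    labels: np.ndarray
    subjects: np.ndarray

    def __post_init__(self) -> None:
        if not (len(self.segments) == len(self.labels) == len(self.subjects)):
            raise ParameterError("corpus arrays must align")

    @property
    def n_subjects(self) -> int:
        return len(np.unique(self.subjects))


def normalize_segment(x: np.ndarray) -> np.ndarray:
    """Per-segment z-score; a constant segment maps to zeros (gain-invariant
    input is what makes the model transferable across sensor scalings)."""
    x = np.asarray(x, dtype=float)
    sd = x.std()
    return (x - x.mean()) / sd if sd > 0 else np.zeros_like(x)


def build_corpus(
    n_subjects: int = 20,
    duration_s: float = 240.0,
    cfg: SQAConfig | None = None,
    seed: int = 0,
    kinds: tuple[str, ...] = ("motion_burst", "baseline_wander", "clipping", "flatline"),
) -> SegmentCorpus:
    """Simulate a labelled training corpus with mixed artifacts.

    Each subject gets one recording at the model's internal rate with a
    random physiology (heart rate, interval jitter) and a random mixture of
    the artifact ``kinds``, then is cut into non-overlapping 8 s segments
    with their 0.5 s ground-truth labels.
    """
    from .simulate import ArtifactSpec, SimulationSpec, generate_ibi_series, inject_artifacts, render_ppg

    cfg = cfg or SQAConfig()
    rng = np.random.default_rng(seed)
    xs, ys, subj = [], [], []
    seg_len = cfg.input_samples
    n_lab = cfg.n_labels
    for s in range(n_subjects):
        spec = SimulationSpec(
            mean_hr=float(rng.uniform(50, 110)),
            jitter_sd=float(rng.uniform(10, 50)),
            duration=duration_s,
            fs=cfg.input_fs,
            seed=int(rng.integers(2**31 - 1)),
        )
        pool = {
            "motion_burst": ArtifactSpec(
                "motion_burst", duty_cycle=float(rng.uniform(0.05, 0.2)),
                mean_event_s=float(rng.uniform(1.0, 3.0)),
                amplitude=float(rng.uniform(1.5, 3.0))),
            "baseline_wander": ArtifactSpec(
                "baseline_wander", duty_cycle=float(rng.uniform(0.0, 0.15)),
                mean_event_s=4.0, amplitude=float(rng.uniform(0.8, 2.0))),
            "clipping": ArtifactSpec(
                "clipping", duty_cycle=float(rng.uniform(0.02, 0.1)),
                mean_event_s=2.0, amplitude=float(rng.uniform(0.5, 0.9))),
            # flatline events span short glitches up to whole-segment dropouts
            # (a detached sensor), so fully flat inputs are in-distribution
            "flatline": ArtifactSpec(
                "flatline", duty_cycle=float(rng.uniform(0.02, 0.12)),
                mean_event_s=float(rng.uniform(2.0, 8.0))),
        }
        arts = [pool[k] for k in kinds]
        ibi = generate_ibi_series(spec)
        clean = render_ppg(ibi, spec.fs, spec.template)
        corrupted, quality = inject_artifacts(clean, arts, seed=int(rng.integers(2**31 - 1)))
        n_seg = min(len(corrupted.samples) // seg_len, len(quality.scores) // n_lab)
        for i in range(n_seg):
            xs.append(normalize_segment(corrupted.samples[i * seg_len:(i + 1) * seg_len]))
            ys.append(quality.scores[i * n_lab:(i + 1) * n_lab])
            subj.append(s)
    return SegmentCorpus(
        segments=np.asarray(xs), labels=np.asarray(ys), subjects=np.asarray(subj)
    )


# ---------------------------------------------------------------------------
# training


def subject_split(corpus: SegmentCorpus, val_fraction: float, seed: int):
    """Boolean (train_mask, val_mask) with no subject on both sides."""
    subjects = np.unique(corpus.subjects)
    if len(subjects) < 2:
        raise ParameterError("subject-wise split needs at least 2 subjects")
    rng = np.random.default_rng(seed)
    shuffled = rng.permutation(subjects)
    n_val = max(1, int(round(val_fraction * len(subjects))))
    val_subjects = set(shuffled[:n_val].tolist())
    val_mask = np.isin(corpus.subjects, list(val_subjects))
    return ~val_mask, val_mask


def train_sqa(
    model: SQAModel,
    corpus: SegmentCorpus,
    tcfg: TrainConfig | None = None,
) -> dict:
    """Adam / binary-cross-entropy training with a subject-wise split.

    Returns a history dict with per-epoch train loss, validation loss and
    validation 0.5 s-resolution accuracy (score >= 0.5 counted clean).
    """
    tcfg = tcfg or TrainConfig()
    train_mask, val_mask = subject_split(corpus, tcfg.val_fraction, tcfg.seed)
    x_tr, y_tr = corpus.segments[train_mask], corpus.labels[train_mask]
    x_va, y_va = corpus.segments[val_mask], corpus.labels[val_mask]
    rng = np.random.default_rng(tcfg.seed + 1)

    params = model.weights + model.biases
    m = [np.zeros_like(p) for p in params]
    v = [np.zeros_like(p) for p in params]
    beta1, beta2, eps = 0.9, 0.999, 1e-8
    t = 0
    history = {"train_loss": [], "val_loss": [], "val_acc": []}

    decay_after = int(tcfg.lr_decay_epoch_frac * tcfg.epochs)
    for epoch in range(tcfg.epochs):
        base_lr = tcfg.learning_rate * (tcfg.lr_decay_factor if epoch >= decay_after else 1.0)
        order = rng.permutation(len(x_tr))
        epoch_loss, n_batches = 0.0, 0
        for lo in range(0, len(order), tcfg.batch_size):
            idx = order[lo:lo + tcfg.batch_size]
            z = model.forward(x_tr[idx], keep_cache=True)
            loss, dz = _bce_with_logits(z, y_tr[idx])
            gw, gb = model.backward(dz)
            grads = gw + gb
            t += 1
            lr_t = base_lr * np.sqrt(1 - beta2**t) / (1 - beta1**t)
            for p, g, mi, vi in zip(params, grads, m, v):
                mi *= beta1
                mi += (1 - beta1) * g
                vi *= beta2
                vi += (1 - beta2) * g * g
                p -= lr_t * mi / (np.sqrt(vi) + eps)
            epoch_loss += loss
            n_batches += 1
        zv = model.forward(x_va)
        val_loss, _ = _bce_with_logits(zv, y_va)
        val_acc = float(np.mean((_sigmoid(zv) >= 0.5) == (y_va >= 0.5)))
        history["train_loss"].append(epoch_loss / max(n_batches, 1))
        history["val_loss"].append(val_loss)
        history["val_acc"].append(val_acc)
    history["val_mask"] = val_mask
    return history


# ---------------------------------------------------------------------------
# inference


def sqa_infer(model: SQAModel, segment: PPGRecord | np.ndarray) -> QualityVector:
    """Quality scores for one 8 s segment.

    A :class:`PPGRecord` is resampled to the model's internal rate first; a
    bare array must already be at that rate.  Scores are clean
    probabilities; the binary view thresholds at 0.5.
    """
    cfg = model.cfg
    if isinstance(segment, PPGRecord):
        if segment.fs != cfg.input_fs:
            segment = resample(segment, cfg.input_fs)
        x = segment.samples
    else:
        x = np.asarray(segment, dtype=float)
    if len(x) != cfg.input_samples:
        raise ParameterError(
            f"segment must have {cfg.input_samples} samples at {cfg.input_fs} Hz, got {len(x)}"
        )
    scores = model.predict_scores(normalize_segment(x)[None, :])[0]
    return QualityVector(scores=scores, resolution_s=cfg.label_res)


def annotate_recording(model: SQAModel, rec: PPGRecord) -> QualityVector:
    """Dense quality annotation of a whole record.

    The record is tiled into consecutive 8 s segments; a shorter tail is
    zero-padded for the forward pass and its padded cells are marked
    unlabeled.  The concatenated labels align to record time from zero.
    """
    cfg = model.cfg
    work = rec if rec.fs == cfg.input_fs else resample(rec, cfg.input_fs)
    seg_len, n_lab = cfg.input_samples, cfg.n_labels
    n_cells = int(np.floor(rec.duration / cfg.label_res))
    scores = np.zeros(n_cells)
    labeled = np.zeros(n_cells, dtype=bool)
    x = work.samples
    n_full = len(x) // seg_len
    batches = [x[i * seg_len:(i + 1) * seg_len] for i in range(n_full)]
    tail = x[n_full * seg_len:]
    if len(tail):
        batches.append(np.pad(tail, (0, seg_len - len(tail))))
    if not batches:
        return QualityVector(scores=scores, resolution_s=cfg.label_res, labeled=labeled)
    segs = np.stack([normalize_segment(b) for b in batches])
    flat = model.predict_scores(segs).reshape(-1)
    n_fill = min(len(scores), len(flat))
    scores[:n_fill] = flat[:n_fill]
    # only cells fully covered by real (non-padded) samples count as labeled
    real_cells = int(np.floor(len(x) / (cfg.input_fs * cfg.label_res)))
    labeled[:min(n_fill, real_cells)] = True
    return QualityVector(scores=scores, resolution_s=cfg.label_res, labeled=labeled)


# ---------------------------------------------------------------------------
# checkpointing


def save_checkpoint(model: SQAModel, path, corpus_fingerprint: str = "") -> None:
    """Single-file checkpoint: config, parameters and corpus fingerprint."""
    meta = {"config": asdict(model.cfg), "fingerprint": corpus_fingerprint}
    arrays = {f"w{i}": w for i, w in enumerate(model.weights)}
    arrays.update({f"b{i}": b for i, b in enumerate(model.biases)})
    np.savez(path, meta=np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8), **arrays)


def load_checkpoint(path) -> SQAModel:
    with np.load(path) as data:
        meta = json.loads(bytes(data["meta"]).decode())
        cfg_d = meta["config"]
        cfg_d["encoder_widths"] = tuple(cfg_d["encoder_widths"])
        model = SQAModel(SQAConfig(**cfg_d), seed=0)
        model.weights = [data[f"w{i}"] for i in range(len(model.weights))]
        model.biases = [data[f"b{i}"] for i in range(len(model.biases))]
    return model
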