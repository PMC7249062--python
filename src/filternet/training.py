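"""Training loop with the smoothed checkpoint metric and patience stopping.

Training windows of ``window_len`` input samples are drawn from the training
series with a step of ``train_window_step`` *output* samples, shuffled each
epoch, and batched so one batch holds roughly ``samples_per_batch`` input
samples.  The loss is cross-entropy over every output sample of every window
(the null class is a regular class); the optimizer is Adam (or RMSProp) with
L2 weight decay, and the learning rate is multiplied by ``lr_decay`` each
epoch.

Early stopping uses a robust checkpoint metric designed for noisy validation
curves: the per-epoch raw value is validation loss divided by validation
weighted F1 (decreases when either improves); it is smoothed with an
exponentially weighted moving average of half-life 3 epochs, and an
instability penalty (standard deviation of the last <=5 raw values) is added.
The model is checkpointed whenever this metric reaches a new minimum, and
training stops after ``patience`` epochs without a checkpoint; the weights
from the last checkpoint are restored.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats as _sps

from .architectures import ArchitectureSpec, Network
from .data import LabeledSeries
from .metrics import sample_f1_scores
from .nn import cross_entropy, make_optimizer

__all__ = [
    "TrainConfig",
    "TrainHistory",
    "checkpoint_metric",
    "checkpoint_metric_series",
    "should_stop",
    "labels_at_output_rate",
    "train",
]

#: EWMA decay for a half-life of 3 epochs: alpha = 1 - 0.5**(1/3).
EWMA_ALPHA = 1.0 - 0.5 ** (1.0 / 3.0)
_F1_FLOOR = 1e-6  # keeps loss/F1 finite at chance-level F1


@dataclass(frozen=True)
class TrainConfig:
    """Training schedule settings (defaults are the study conditions)."""

    max_epochs: int = 100
    initial_lr: float = 0.001
    samples_per_batch: int = 5000
    train_window_step: int = 16  # output samples
    optimizer: str = "adam"
    weight_decay: float = 0.0001
    patience: int = 10
    lr_decay: float = 0.95
    window_len: int = 512

    @property
    def windows_per_batch(self) -> int:
        return max(1, round(self.samples_per_batch / self.window_len))

    def lr_at_epoch(self, epoch: int) -> float:
        """Learning rate for 1-based ``epoch``: initial_lr * lr_decay**(epoch-1)."""
        return self.initial_lr * self.lr_decay ** (epoch - 1)


@dataclass
class TrainHistory:
    """Per-epoch validation diagnostics (epochs are 1-based)."""

    val_loss: list[float] = field(default_factory=list)
    val_f1w: list[float] = field(default_factory=list)
    raw: list[float] = field(default_factory=list)
    smoothed: list[float] = field(default_factory=list)
    instability: list[float] = field(default_factory=list)
    metric: list[float] = field(default_factory=list)
    checkpoint_epochs: list[int] = field(default_factory=list)

    @property
    def n_epochs(self) -> int:
        return len(self.raw)

    @property
    def last_checkpoint_epoch(self) -> int:
        return self.checkpoint_epochs[-1] if self.checkpoint_epochs else 0

    @property
    def best_epoch(self) -> int:
        return self.last_checkpoint_epoch

    def record_epoch(self, val_loss: float, val_f1w: float) -> bool:
        """Append one epoch; returns True if this epoch sets a checkpoint."""
        raw = val_loss / max(val_f1w, _F1_FLOOR)
        self.val_loss.append(val_loss)
        self.val_f1w.append(val_f1w)
        self.raw.append(raw)
        s, i, m = checkpoint_metric(self.raw)
        self.smoothed.append(s)
        self.instability.append(i)
        self.metric.append(m)
        best = min(self.metric[:-1], default=np.inf)
        if m < best:
            self.checkpoint_epochs.append(self.n_epochs)
            return True
        return False


def checkpoint_metric(raw_history) -> tuple[float, float, float]:
    """(smoothed, instability, metric) after the last epoch of ``raw_history``.

    smoothed_e = (1-a)*smoothed_{e-1} + a*raw_e with a = 1 - 0.5**(1/3) and
    smoothed_1 = raw_1; instability is the population standard deviation of
    the most recent min(5, e) raw values (0 with a single epoch); the metric
    is their sum.
    """
    raw = np.asarray(raw_history, dtype=np.float64)
    if raw.size == 0:
        raise ValueError("raw history must be nonempty")
    if np.any(raw <= 0):
        raise ValueError("raw checkpoint values must be positive (loss / F1)")
    smoothed = raw[0]
    for r in raw[1:]:
        smoothed = (1.0 - EWMA_ALPHA) * smoothed + EWMA_ALPHA * r
    window = raw[-5:]
    instability = float(np.std(window))  # population sd over <=5 values
    return float(smoothed), instability, float(smoothed + instability)


def checkpoint_metric_series(raw_history) -> np.ndarray:
    """Checkpoint metric at every epoch of a raw history."""
    return np.array(
        [checkpoint_metric(raw_history[: e + 1])[2] for e in range(len(raw_history))]
    )


def should_stop(history: TrainHistory, patience: int) -> bool:
    """True once ``patience`` epochs have passed without a checkpoint."""
    if history.n_epochs < 1:
        raise ValueError("need at least one recorded epoch")
    return (history.n_epochs - history.last_checkpoint_epoch) >= patience


def labels_at_output_rate(labels: np.ndarray, stride_ratio: int) -> np.ndarray:
    """Down-label to the output rate: mode of each stride_ratio-wide bin.

    The mode preserves short events better than plain subsampling; ties break
    toward the smallest label.
    """
    labels = np.asarray(labels)
    if stride_ratio == 1:
        return labels.copy()
    n = len(labels) // stride_ratio
    if n * stride_ratio != len(labels):
        labels = labels[: n * stride_ratio]
    binned = labels.reshape(n, stride_ratio)
    return _sps.mode(binned, axis=1).mode.astype(np.int64)


def _window_starts(n_samples: int, window_len: int, step_in: int) -> np.ndarray:
    if n_samples < window_len:
        raise ValueError(f"series of {n_samples} samples is shorter than one window")
    return np.arange(0, n_samples - window_len + 1, step_in)


def evaluate_loss_f1(net: Network, series: LabeledSeries, window_len: int):
    """Validation loss and weighted F1 over non-overlapping windows."""
    sr = net.spec.output_stride_ratio
    L = series.n_samples
    starts = list(range(0, L - window_len + 1, window_len))
    last = L - window_len
    if not starts:
        raise ValueError("validation series shorter than one window")
    if starts[-1] != last:
        starts.append(last)
    losses = []
    y_true = []
    y_pred = []
    for a in starts:
        x = series.data[:, a : a + window_len][None]
        labels = labels_at_output_rate(series.labels[a : a + window_len], sr)[None]
        logits = net.forward(x, train=False)
        loss, _ = cross_entropy(logits, labels)
        losses.append(loss)
        y_true.append(labels[0])
        y_pred.append(logits[0].argmax(axis=0))
    f1 = sample_f1_scores(np.concatenate(y_true), np.concatenate(y_pred))
    return float(np.mean(losses)), f1.f1w


def train(
    spec: ArchitectureSpec | Network,
    train_series: LabeledSeries,
    val_series: LabeledSeries,
    cfg: TrainConfig | None = None,
    seed: int = 0,
    log=None,
) -> tuple[Network, TrainHistory]:
    """Train a network; deterministic given ``seed`` (single-threaded CPU).

    Returns the network with the restored-best weights and the history.
    ``log``, if given, receives one tab-separated line per epoch.
    """
    cfg = cfg or TrainConfig()
    net = spec if isinstance(spec, Network) else Network(spec, seed=seed)
    sr = net.spec.output_stride_ratio
    if cfg.window_len % sr:
        raise ValueError(
            f"window_len {cfg.window_len} must be divisible by the output stride ratio {sr}"
        )
    rng = np.random.default_rng(seed + 1)
    step_in = cfg.train_window_step * sr
    starts = _window_starts(train_series.n_samples, cfg.window_len, step_in)
    out_labels_full = labels_at_output_rate(train_series.labels, sr)
    lw = cfg.window_len // sr

    optimizer = make_optimizer(
        cfg.optimizer, net.parameters(), cfg.initial_lr, cfg.weight_decay
    )
    history = TrainHistory()
    best_state = net.get_state()
    for epoch in range(1, cfg.max_epochs + 1):
        optimizer.lr = cfg.lr_at_epoch(epoch)
        order = rng.permutation(starts)
        for i in range(0, len(order), cfg.windows_per_batch):
            batch_starts = order[i : i + cfg.windows_per_batch]
            x = np.stack(
                [train_series.data[:, a : a + cfg.window_len] for a in batch_starts]
            )
            y = np.stack([out_labels_full[a // sr : a // sr + lw] for a in batch_starts])
            net.zero_grad()
            logits = net.forward(x, train=True, rng=rng)
            _loss, dlogits = cross_entropy(logits, y)
            net.backward(dlogits)
            optimizer.step()
        val_loss, val_f1w = evaluate_loss_f1(net, val_series, cfg.window_len)
        checkpointed = history.record_epoch(val_loss, val_f1w)
        if checkpointed:
            best_state = net.get_state()
        if log is not None:
            log(
                f"{epoch}\t{val_loss:.5f}\t{val_f1w:.4f}\t"
                f"{history.metric[-1]:.5f}\t{'checkpoint' if checkpointed else ''}"
            )
        if should_stop(history, cfg.patience):
            break
    net.set_state(best_state)
    return net, history
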