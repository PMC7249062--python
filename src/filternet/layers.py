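"""The FilterNet layer module (FLM) and its shape/parameter/ROI calculus.

An FLM is the unit of composition of every FilterNet architecture: a channel
dropout, then either a same-padded 1-D CNN with ReLU or a bidirectional LSTM,
then average pooling with kernel = stride = s, then (optionally) batch
normalization.  The module is *coverage preserving*: the output covers exactly
the time span of the input at 1/s the sampling rate.

Two notions of temporal extent are provided:

``roi_after_stack``
    The region-of-influence metric conventionally reported for these
    architectures, ROI_i = ROI_{i-1} + (k_i - 1) * prod_{j<=i} s_j.  It is the
    number used when quoting an architecture's ROI (61 for a 4-layer pooled
    stack, 765 for the 8-layer multi-scale stack at reference settings).

``exact_receptive_field``
    The exact maximal number of input samples that can influence one output
    sample of a conv->avg-pool stack, obtained by composing pre-images:
    R -> R*s + (k - 1) from the last layer to the first.  For unstrided stacks
    the two coincide; for strided stacks the ROI metric is an upper bound.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

from .nn import AvgPool1d, BatchNorm1d, BiLSTM, ChannelDropout, Conv1d, Module, ReLU

__all__ = [
    "FLMConfig",
    "SeriesShape",
    "FLM",
    "ROI_ENTIRE_INPUT",
    "flm_output_length",
    "flm_param_count",
    "roi_after_stack",
    "exact_receptive_field",
    "apply_flm",
]

#: Distinguished ROI value for stacks containing a bidirectional recurrent
#: layer, whose region of influence is the entire input.
ROI_ENTIRE_INPUT = math.inf


@dataclass(frozen=True)
class FLMConfig:
    """Hyperparameters of one FilterNet layer module.

    Parameters
    ----------
    layer_type : {'cnn', 'lstm'}
    w_out : int
        Output channels.  For ``lstm`` this is the total width of the
        concatenated bidirectional hidden state and must be even.
    s : int
        Stride ratio of the average-pooling step (default 1 = no pooling).
    k : int
        Kernel length, CNN only; positive odd (default 5).  Ignored for lstm.
    p_drop : float
        Probability of dropping an input channel during training.
    use_bn : bool
        Whether a batch-norm closes the module (default True).
    use_bias : bool or None
        Convolution bias.  ``None`` (default) resolves to ``not use_bn``:
        a bias is redundant in front of batch-norm's shift, and omitting it
        there is the convention that reproduces the published parameter
        counts of the reference architectures.
    """

    layer_type: str
    w_out: int
    s: int = 1
    k: int = 5
    p_drop: float = 0.1
    use_bn: bool = True
    use_bias: bool | None = None

    def __post_init__(self):
        if self.layer_type not in ("cnn", "lstm"):
            raise ValueError(f"layer_type must be 'cnn' or 'lstm', got {self.layer_type!r}")
        if self.w_out < 1:
            raise ValueError(f"w_out must be positive, got {self.w_out}")
        if self.s < 1:
            raise ValueError(f"stride ratio must be >= 1, got {self.s}")
        if self.layer_type == "cnn" and (self.k < 1 or self.k % 2 == 0):
            raise ValueError(f"kernel length must be positive odd, got {self.k}")
        if not 0.0 <= self.p_drop < 1.0:
            raise ValueError(f"p_drop must be in [0, 1), got {self.p_drop}")
        if self.layer_type == "lstm" and self.w_out % 2:
            raise ValueError(
                f"lstm w_out must be even (split across two directions), got {self.w_out}"
            )

    @property
    def bias(self) -> bool:
        """Resolved convolution-bias flag."""
        return (not self.use_bn) if self.use_bias is None else self.use_bias

    def to_dict(self) -> dict:
        return {
            "type": self.layer_type,
            "w_out": int(self.w_out),
            "s": int(self.s),
            "k": int(self.k),
            "p_drop": float(self.p_drop),
            "bn": bool(self.use_bn),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "FLMConfig":
        return cls(
            layer_type=d["type"],
            w_out=int(d["w_out"]),
            s=int(d.get("s", 1)),
            k=int(d.get("k", 5)),
            p_drop=float(d.get("p_drop", 0.1)),
            use_bn=bool(d.get("bn", True)),
            use_bias=d.get("bias"),
        )

    def scaled(self, factor: float) -> "FLMConfig":
        """Return a copy with ``w_out`` scaled (rounded, floor 1; even for lstm)."""
        if self.layer_type == "lstm":
            w = max(2, 2 * round(self.w_out * factor / 2))
        else:
            w = max(1, round(self.w_out * factor))
        return replace(self, w_out=w)


@dataclass(frozen=True)
class SeriesShape:
    """Channel count and sample count of a channel-major series."""

    w: int
    L: int

    def __post_init__(self):
        if self.w < 1 or self.L < 1:
            raise ValueError(f"shape must be positive, got ({self.w}, {self.L})")


def flm_output_length(L_in: int, s: int) -> int:
    """Output sample count of an FLM: ceil(L_in / s).

    Equals L_in / s exactly when s divides L_in; the training path always
    chooses window lengths divisible by the network stride ratio, and eval
    inputs are right-padded with zeros before pooling otherwise.
    """
    if L_in < 1 or s < 1:
        raise ValueError(f"L_in and s must be positive, got ({L_in}, {s})")
    return -(-L_in // s)


def flm_param_count(cfg: FLMConfig, w_in: int) -> int:
    """Trainable parameters of an FLM with ``w_in`` input channels.

    CNN: w_in*w_out*k weights, plus w_out if biased, plus 2*w_out for
    batch-norm scale and shift.  LSTM: the implementation's true count
    (two directions of 4 gates with input/recurrent weights and two bias
    vectors each) plus batch-norm.
    """
    if w_in < 1:
        raise ValueError(f"w_in must be positive, got {w_in}")
    bn = 2 * cfg.w_out if cfg.use_bn else 0
    if cfg.layer_type == "cnn":
        n = w_in * cfg.w_out * cfg.k
        if cfg.bias:
            n += cfg.w_out
        return n + bn
    hidden = cfg.w_out // 2
    per_dir = 4 * hidden * (w_in + hidden) + 8 * hidden
    return 2 * per_dir + bn


def _stack_tuples(layers) -> list[tuple[int, int]]:
    out = []
    for layer in layers:
        if isinstance(layer, FLMConfig):
            if layer.layer_type != "cnn":
                return None
            out.append((layer.s, layer.k))
        else:
            s, k = layer
            out.append((int(s), int(k)))
    return out


def roi_after_stack(layers) -> float:
    """Region of influence after an ordered stack of CNN layers.

    ``layers`` is a list of (s, k) pairs or FLMConfigs.  Uses the
    stride-cumulative-product recurrence ROI_i = ROI_{i-1} + (k_i-1)*prod s_j,
    the form that reproduces the reference architectures' published ROI
    column.  A recurrent layer anywhere makes the ROI the entire input;
    ``ROI_ENTIRE_INPUT`` is returned.
    """
    if not len(layers):
        raise ValueError("layer stack must be nonempty")
    tuples = _stack_tuples(layers)
    if tuples is None:
        return ROI_ENTIRE_INPUT
    roi = 1
    jump = 1
    for s, k in tuples:
        if s < 1 or k < 1:
            raise ValueError(f"invalid (s, k) = ({s}, {k})")
        jump *= s
        roi += (k - 1) * jump
    return roi


def exact_receptive_field(layers) -> float:
    """Exact maximal input extent of one output sample of a conv->pool stack.

    Composes pre-images back-to-front: a run of R output samples of a layer
    requires R*s conv outputs, hence R*s + (k-1) inputs.  Coincides with
    ``roi_after_stack`` when every stride is 1 and lower-bounds it otherwise.
    """
    if not len(layers):
        raise ValueError("layer stack must be nonempty")
    tuples = _stack_tuples(layers)
    if tuples is None:
        return ROI_ENTIRE_INPUT
    r = 1
    for s, k in reversed(tuples):
        r = r * s + (k - 1)
    return r


class FLM(Module):
    """An instantiated FilterNet layer module.

    Sub-layer order: channel dropout -> (CNN+ReLU | biLSTM) -> average pool
    (kernel = stride = s) -> batch norm.  CNN inputs are zero-padded so the
    pre-pool length equals the input length; hence output length is
    ceil(L_in / s).
    """

    def __init__(self, cfg: FLMConfig, w_in: int, rng: np.random.Generator):
        self.cfg = cfg
        self.w_in = int(w_in)
        self.dropout = ChannelDropout(cfg.p_drop) if cfg.p_drop > 0 else None
        if cfg.layer_type == "cnn":
            self.core = Conv1d(w_in, cfg.w_out, cfg.k, bias=cfg.bias, rng=rng)
            self.act = ReLU()
        else:
            self.core = BiLSTM(w_in, cfg.w_out // 2, rng=rng)
            self.act = None
        self.pool = AvgPool1d(cfg.s) if cfg.s > 1 else None
        self.bn = BatchNorm1d(cfg.w_out) if cfg.use_bn else None

    def _sublayers(self):
        return [m for m in (self.dropout, self.core, self.act, self.pool, self.bn) if m is not None]

    def parameters(self):
        out = []
        for m in self._sublayers():
            out.extend(m.parameters())
        return out

    def buffers(self):
        return self.bn.buffers() if self.bn is not None else {}

    def forward(self, x, train=False, rng=None):
        if x.ndim != 3:
            raise ValueError(f"expected (N, C, L) input, got shape {x.shape}")
        if x.shape[1] != self.w_in:
            raise ValueError(f"expected {self.w_in} input channels, got {x.shape[1]}")
        if x.shape[2] < 1:
            raise ValueError("input length must be >= 1")
        if not np.all(np.isfinite(x)):
            raise ValueError("non-finite values in FLM input")
        for m in self._sublayers():
            x = m.forward(x, train=train, rng=rng)
        return x

    def backward(self, grad):
        for m in reversed(self._sublayers()):
            grad = m.backward(grad)
        return grad

    @property
    def param_count(self) -> int:
        return self.num_params()


def apply_flm(
    x: np.ndarray,
    cfg: FLMConfig,
    mode: str = "eval",
    seed: int = 0,
    flm: FLM | None = None,
) -> np.ndarray:
    """Apply a (freshly initialized or given) FLM to a single (w, L) series."""
    if mode not in ("train", "eval"):
        raise ValueError(f"mode must be 'train' or 'eval', got {mode!r}")
    x = np.asarray(x, dtype=np.float64)
    if x.ndim != 2:
        raise ValueError(f"expected a (channels, length) series, got shape {x.shape}")
    rng = np.random.default_rng(seed)
    if flm is None:
        flm = FLM(cfg, w_in=x.shape[0], rng=rng)
    y = flm.forward(x[None], train=(mode == "train"), rng=rng)
    return y[0]
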