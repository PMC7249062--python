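"""Reference FilterNet architectures and the component-graph network.

The prototypical component architecture chains up to seven components:

- **A** full-resolution CNN (s=1) at the input sampling rate;
- **B** pooling stack 1: ``n_p1`` strided CNN modules that set the network
  output stride ratio ``s**n_p1``;
- **C** pooling stack 2: further strided CNN modules whose widths halve
  layer to layer, capturing slower dynamics;
- **D** resampling step: every C output is linearly interpolated back to the
  network output length and concatenated with the last B output;
- **E** bottleneck: a k=1 CNN reducing the concatenated width;
- **F** recurrent stack: bidirectional LSTM module(s);
- **G** output module: a k=1 CNN (bias, no batch-norm) emitting one logit
  vector per output sample; probabilities are a softmax over classes.

Five named variants cover the useful subsets: ``b_lstm`` (F, G only; output
stride 1), ``p_cnn`` (A, B, G), ``p_cl`` (A, B, F, G), ``ms_cnn``
(A, B, C, D, E, G) and ``ms_cl`` (all components).
"""

from __future__ import annotations

import io
import json
import math
from dataclasses import dataclass, field

import numpy as np
import yaml

from .layers import (
    FLM,
    ROI_ENTIRE_INPUT,
    FLMConfig,
    exact_receptive_field,
    flm_param_count,
    roi_after_stack,
)
from .nn import Module, softmax_probs

__all__ = [
    "ArchitectureSpec",
    "NetworkOutput",
    "Network",
    "VARIANTS",
    "build_reference",
    "resample_concat",
    "total_param_count",
]

VARIANTS = ("b_lstm", "p_cnn", "p_cl", "ms_cnn", "ms_cl")

_COMPONENT_ORDER = "ABCEFG"  # D is the (parameter-free) resampling step


@dataclass(frozen=True)
class NetworkOutput:
    """Dense per-sample network output: logits and softmax probabilities (K, L)."""

    logits: np.ndarray

    @property
    def probabilities(self) -> np.ndarray:
        return softmax_probs(self.logits, axis=0)

    @property
    def n_classes(self) -> int:
        return self.logits.shape[0]

    @property
    def length(self) -> int:
        return self.logits.shape[1]


@dataclass
class ArchitectureSpec:
    """Ordered component graph of FLM configs for one variant."""

    variant_name: str
    components: dict[str, list[FLMConfig]]
    input_channels: int
    n_classes: int
    width_scale: float = 1.0
    s: int = 2
    n_p1: int = 0
    n_p2: int = 0
    n_l: int = 0

    @property
    def output_stride_ratio(self) -> int:
        return self.s**self.n_p1 if self.n_p1 else 1

    def ordered_layers(self) -> list[tuple[str, FLMConfig, int]]:
        """(component, config, w_in) triples in forward order."""
        rows = []
        w = self.input_channels
        w_ps1 = self.input_channels
        for comp in _COMPONENT_ORDER:
            for cfg in self.components.get(comp, []):
                if comp == "E" and "C" in self.components:
                    # bottleneck input is the D concatenation
                    w = w_ps1 + sum(c.w_out for c in self.components["C"])
                rows.append((comp, cfg, w))
                w = cfg.w_out
            if comp == "B" or (comp == "A" and "B" not in self.components):
                w_ps1 = w
        return rows

    def cnn_stack(self) -> list[tuple[int, int]]:
        """(s, k) pairs of the A+B+C convolutional front end."""
        return [
            (cfg.s, cfg.k)
            for comp in "ABC"
            for cfg in self.components.get(comp, [])
        ]

    @property
    def cnn_stack_roi(self) -> float:
        stack = self.cnn_stack()
        return roi_after_stack(stack) if stack else 1

    @property
    def roi(self) -> float:
        """ROI of the whole network (entire input if any LSTM is present)."""
        if self.components.get("F"):
            return ROI_ENTIRE_INPUT
        return self.cnn_stack_roi

    def layer_table(self) -> list[dict]:
        """Per-layer description: widths, stride, kernel, params, stride ratio, ROI."""
        rows = []
        stride_ratio = 1
        roi_stack: list[tuple[int, int]] = []
        unbounded = False
        for comp, cfg, w_in in self.ordered_layers():
            if cfg.layer_type == "cnn" and not unbounded:
                roi_stack.append((cfg.s, cfg.k))
                roi = roi_after_stack(roi_stack)
            else:
                unbounded = True
                roi = ROI_ENTIRE_INPUT
            stride_ratio *= cfg.s
            rows.append(
                {
                    "component": comp,
                    "type": cfg.layer_type,
                    "w_in": w_in,
                    "w_out": cfg.w_out,
                    "s": cfg.s,
                    "k": cfg.k if cfg.layer_type == "cnn" else None,
                    "params": flm_param_count(cfg, w_in),
                    "stride_ratio": stride_ratio if comp in "ABC" else self.output_stride_ratio,
                    "roi": roi,
                }
            )
        return rows

    # -- plain-text round trip ------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "variant": self.variant_name,
            "input_channels": int(self.input_channels),
            "n_classes": int(self.n_classes),
            "width_scale": float(self.width_scale),
            "stride": int(self.s),
            "n_p1": int(self.n_p1),
            "n_p2": int(self.n_p2),
            "n_l": int(self.n_l),
            "components": {
                comp: [cfg.to_dict() for cfg in cfgs]
                for comp, cfgs in self.components.items()
            },
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ArchitectureSpec":
        return cls(
            variant_name=d["variant"],
            components={
                comp: [FLMConfig.from_dict(c) for c in cfgs]
                for comp, cfgs in d["components"].items()
            },
            input_channels=int(d["input_channels"]),
            n_classes=int(d["n_classes"]),
            width_scale=float(d.get("width_scale", 1.0)),
            s=int(d.get("stride", 2)),
            n_p1=int(d.get("n_p1", 0)),
            n_p2=int(d.get("n_p2", 0)),
            n_l=int(d.get("n_l", 0)),
        )

    def to_yaml(self) -> str:
        return yaml.safe_dump(self.to_dict(), sort_keys=False)

    @classmethod
    def from_yaml(cls, text: str) -> "ArchitectureSpec":
        return cls.from_dict(yaml.safe_load(text))


def build_reference(
    variant_name: str,
    input_channels: int,
    n_classes: int,
    width_scale: float = 1.0,
    n_p1: int = 3,
    n_p2: int = 4,
    n_l: int = 1,
    s: int = 2,
) -> ArchitectureSpec:
    """Build one of the five reference architectures.

    At ``width_scale=1`` the CNN widths are 100 throughout A/B/E, the pooling
    stack 2 widths halve (rounded up) 50, 25, 13, 7 with the final layer
    unstrided, the LSTM width is 100, and the output module has ``n_classes``
    channels with bias and no batch-norm.  Widths scale by ``width_scale``
    (rounded to nearest, floor 1; LSTM widths kept even).
    """
    if variant_name not in VARIANTS:
        raise ValueError(f"unknown variant {variant_name!r}; expected one of {VARIANTS}")
    w = max(1, round(100 * width_scale))
    w_lstm = max(2, 2 * round(50 * width_scale))

    comp: dict[str, list[FLMConfig]] = {}
    has = {
        "b_lstm": "FG",
        "p_cnn": "ABG",
        "p_cl": "ABFG",
        "ms_cnn": "ABCDEG",
        "ms_cl": "ABCDEFG",
    }[variant_name]

    if "A" in has:
        comp["A"] = [FLMConfig("cnn", w, s=1, k=5)]
    if "B" in has:
        comp["B"] = [FLMConfig("cnn", w, s=s, k=5) for _ in range(n_p1)]
    if "C" in has:
        cs = []
        prev = w
        for i in range(n_p2):
            width = -(-prev // s)  # halve, rounded up
            stride = s if i < n_p2 - 1 else 1  # last layer keeps full depth scale
            cs.append(FLMConfig("cnn", width, s=stride, k=5))
            prev = width
        comp["C"] = cs
    if "E" in has:
        comp["E"] = [FLMConfig("cnn", w, s=1, k=1)]
    if "F" in has:
        comp["F"] = [FLMConfig("lstm", w_lstm, s=1) for _ in range(n_l)]
    comp["G"] = [FLMConfig("cnn", n_classes, s=1, k=1, p_drop=0.0, use_bn=False, use_bias=True)]

    return ArchitectureSpec(
        variant_name=variant_name,
        components=comp,
        input_channels=input_channels,
        n_classes=n_classes,
        width_scale=width_scale,
        s=s,
        n_p1=n_p1 if "B" in has else 0,
        n_p2=n_p2 if "C" in has else 0,
        n_l=n_l if "F" in has else 0,
    )


def total_param_count(spec: ArchitectureSpec) -> int:
    """Sum of per-layer trainable counts over the whole architecture."""
    if not spec.components:
        return 0
    return sum(flm_param_count(cfg, w_in) for _, cfg, w_in in spec.ordered_layers())


# ---------------------------------------------------------------------------
# Linear-interpolation resampling (align-ends) with a backward pass
# ---------------------------------------------------------------------------


def _resample_plan(m: int, M: int):
    """Indices/fractions mapping a length-m series onto M align-ends positions."""
    if m == 1:
        i0 = np.zeros(M, dtype=np.intp)
        frac = np.zeros(M)
        return i0, frac
    pos = np.linspace(0.0, m - 1.0, M) if M > 1 else np.array([0.0])
    i0 = np.minimum(pos.astype(np.intp), m - 2)
    frac = pos - i0
    return i0, frac


def _resample_forward(x: np.ndarray, M: int):
    m = x.shape[-1]
    i0, frac = _resample_plan(m, M)
    if m == 1:
        return np.repeat(x, M, axis=-1), (i0, frac, m)
    y = x[..., i0] * (1.0 - frac) + x[..., i0 + 1] * frac
    return y, (i0, frac, m)


def _resample_backward(dy: np.ndarray, plan) -> np.ndarray:
    i0, frac, m = plan
    dx = np.zeros(dy.shape[:-1] + (m,))
    if m == 1:
        dx[..., 0] = dy.sum(axis=-1)
        return dx
    np.add.at(dx, (..., i0), dy * (1.0 - frac))
    np.add.at(dx, (..., i0 + 1), dy * frac)
    return dx


def resample_concat(final_ps1_output: np.ndarray, c_stack_outputs) -> np.ndarray:
    """Resample each pooling-stack-2 output to the network output length and
    concatenate with the pooling-stack-1 output along channels.

    Operates on single (channels, length) series.  Linear interpolation uses
    the align-ends convention, so constant series stay constant.  With the
    reference widths (100 and 50, 25, 13, 7) the result has 195 channels.
    """
    base = np.asarray(final_ps1_output, dtype=np.float64)
    if base.ndim != 2:
        raise ValueError(f"expected (channels, length), got shape {base.shape}")
    if not c_stack_outputs:
        return base
    M = base.shape[-1]
    pieces = [base]
    for c in c_stack_outputs:
        c = np.asarray(c, dtype=np.float64)
        y, _ = _resample_forward(c, M)
        pieces.append(y)
    return np.concatenate(pieces, axis=0)


# ---------------------------------------------------------------------------
# The network
# ---------------------------------------------------------------------------


class Network(Module):
    """An instantiated FilterNet: an ArchitectureSpec's component graph with weights.

    ``forward`` takes a batch ``(N, C, L)`` and returns logits
    ``(N, n_classes, L / stride_ratio)``; ``predict_logits`` is the
    single-series convenience wrapper.  The backward pass mirrors the
    forward wiring, including the split of the concatenation gradient back
    into the pooling stacks.
    """

    def __init__(self, spec: ArchitectureSpec, seed: int = 0):
        self.spec = spec
        rng = np.random.default_rng(seed)
        self.flms: dict[str, list[FLM]] = {}
        for comp, cfg, w_in in spec.ordered_layers():
            self.flms.setdefault(comp, []).append(FLM(cfg, w_in, rng))
        self._w_ps1 = None
        for comp in ("B", "A"):
            if comp in self.flms:
                self._w_ps1 = self.flms[comp][-1].cfg.w_out
                break
        if self._w_ps1 is None:
            self._w_ps1 = spec.input_channels

    # -- parameter plumbing --------------------------------------------------

    def _all_flms(self) -> list[FLM]:
        return [f for comp in _COMPONENT_ORDER for f in self.flms.get(comp, [])]

    def parameters(self):
        out = []
        for f in self._all_flms():
            out.extend(f.parameters())
        return out

    def total_param_count(self) -> int:
        return sum(p.size for p in self.parameters())

    def get_state(self) -> dict[str, np.ndarray]:
        state = {}
        for i, p in enumerate(self.parameters()):
            state[f"param_{i}"] = p.value.copy()
        for j, f in enumerate(self._all_flms()):
            if f.bn is not None:
                state[f"bn_{j}_mean"] = f.bn.running_mean.copy()
                state[f"bn_{j}_var"] = f.bn.running_var.copy()
        return state

    def set_state(self, state: dict) -> None:
        for i, p in enumerate(self.parameters()):
            p.value[...] = state[f"param_{i}"]
        for j, f in enumerate(self._all_flms()):
            if f.bn is not None:
                f.bn.running_mean[...] = state[f"bn_{j}_mean"]
                f.bn.running_var[...] = state[f"bn_{j}_var"]

    # -- forward / backward ---------------------------------------------------

    def forward(self, x, train=False, rng=None):
        if x.ndim != 3:
            raise ValueError(f"expected (N, C, L), got shape {x.shape}")
        if x.shape[1] != self.spec.input_channels:
            raise ValueError(
                f"expected {self.spec.input_channels} input channels, got {x.shape[1]}"
            )
        sr = self.spec.output_stride_ratio
        if train and x.shape[2] % sr:
            raise ValueError(f"train-mode input length must be a multiple of {sr}")
        h = x
        for f in self.flms.get("A", []) + self.flms.get("B", []):
            h = f.forward(h, train=train, rng=rng)
        self._has_c = "C" in self.flms
        if self._has_c:
            ps1 = h
            c_outs = []
            for f in self.flms["C"]:
                h = f.forward(h, train=train, rng=rng)
                c_outs.append(h)
            M = ps1.shape[-1]
            pieces = [ps1]
            plans = []
            for c in c_outs:
                y, plan = _resample_forward(c, M)
                pieces.append(y)
                plans.append(plan)
            self._c_widths = [c.shape[1] for c in c_outs]
            self._plans = plans
            h = np.concatenate(pieces, axis=1)
        for f in self.flms.get("E", []) + self.flms.get("F", []) + self.flms.get("G", []):
            h = f.forward(h, train=train, rng=rng)
        return h

    def backward(self, grad):
        for f in reversed(self.flms.get("E", []) + self.flms.get("F", []) + self.flms.get("G", [])):
            grad = f.backward(grad)
        if self._has_c:
            w0 = self._w_ps1
            grad_ps1 = grad[:, :w0]
            chunks = []
            at = w0
            for w in self._c_widths:
                chunks.append(grad[:, at : at + w])
                at += w
            g = None
            c_layers = self.flms["C"]
            for i in range(len(c_layers) - 1, -1, -1):
                gi = _resample_backward(chunks[i], self._plans[i])
                g = gi if g is None else g + gi
                g = c_layers[i].backward(g)
            grad = grad_ps1 + g
        for f in reversed(self.flms.get("A", []) + self.flms.get("B", [])):
            grad = f.backward(grad)
        return grad

    # -- inference convenience -----------------------------------------------

    def predict_logits(self, x: np.ndarray) -> np.ndarray:
        """Eval-mode logits for a single (channels, length) series."""
        x = np.asarray(x, dtype=np.float64)
        if x.ndim != 2:
            raise ValueError(f"expected (channels, length), got shape {x.shape}")
        return self.forward(x[None], train=False)[0]

    def predict(self, x: np.ndarray) -> NetworkOutput:
        return NetworkOutput(self.predict_logits(x))

    # -- serialization --------------------------------------------------------

    def save(self, path) -> None:
        """Single-file checkpoint: weights + embedded architecture config."""
        state = self.get_state()
        state["__config__"] = np.frombuffer(
            json.dumps(self.spec.to_dict()).encode(), dtype=np.uint8
        )
        np.savez(path, **state)

    @classmethod
    def load(cls, path) -> "Network":
        with np.load(path) as data:
            cfg = json.loads(bytes(data["__config__"].tobytes()).decode())
            net = cls(ArchitectureSpec.from_dict(cfg))
            net.set_state({k: data[k] for k in data.files if k != "__config__"})
        return net
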