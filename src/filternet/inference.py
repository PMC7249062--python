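"""Windowed inference: split, run per-window, reassemble.

Long inputs are cut into overlapping fixed-length windows, the network is run
per window (in batches), and a single output series is reconstructed either by

- weighted overlap-add on the output-sample axis with a Hanning taper
  de-emphasizing window edges (works for every architecture), or
- ROI-trim concatenation, valid only for finite-ROI (CNN-only) networks:
  windows overlap by at least the ROI and half of each overlapped region is
  discarded, which reproduces the unsegmented forward pass exactly outside
  the global edges.

Weighted averaging is applied to *logits*; probabilities are recomputed after
reconstruction (consistent with how fold ensembles average logits before the
softmax).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .architectures import Network, NetworkOutput
from .layers import ROI_ENTIRE_INPUT

__all__ = [
    "WindowPlan",
    "plan_windows",
    "run_windows",
    "reconstruct",
    "roi_trim_reconstruct",
    "predict_windowed",
]

#: Hanning weights are floored at this value so samples covered by a single
#: window (where the zero-endpoint taper would zero-divide) reduce to the raw
#: window output.
WEIGHT_FLOOR = 1e-6

DEFAULT_WINDOW_LEN = 512
DEFAULT_OVERLAP = 0.5
#: Default windows per forward batch: ~50k input samples per batch.
BATCH_INPUT_SAMPLES = 50_000


@dataclass(frozen=True)
class WindowPlan:
    """Sliding-window segmentation of an input of length ``L``.

    Segments are half-open input intervals on the (possibly right-padded)
    input axis; the padded region is discarded from the reconstruction.
    """

    L: int
    window_len: int
    overlap_fraction: float
    weighting: str
    batch_windows: int
    segments: tuple[tuple[int, int], ...]

    @property
    def padded_len(self) -> int:
        return max(self.L, self.window_len)

    @property
    def step(self) -> int:
        return self.window_len - round(self.window_len * self.overlap_fraction)


def plan_windows(
    L: int,
    window_len: int = DEFAULT_WINDOW_LEN,
    overlap_fraction: float = DEFAULT_OVERLAP,
    weighting: str = "hanning",
    batch_windows: int | None = None,
) -> WindowPlan:
    """Plan sliding windows over an input of length ``L``.

    Windows start at multiples of ``step = window_len - round(window_len *
    overlap_fraction)``; a final window is right-aligned so the union covers
    the whole input.  Inputs shorter than one window are planned on the
    zero-padded length.
    """
    if not 0.0 <= overlap_fraction < 1.0:
        raise ValueError(f"overlap_fraction must be in [0, 1), got {overlap_fraction}")
    if window_len < 1 or L < 1:
        raise ValueError("window_len and L must be positive")
    if weighting not in ("hanning", "rectangular"):
        raise ValueError(f"weighting must be 'hanning' or 'rectangular', got {weighting!r}")
    step = window_len - round(window_len * overlap_fraction)
    if step < 1:
        raise ValueError("window step must be >= 1; lower the overlap fraction")
    padded = max(L, window_len)
    starts = list(range(0, max(padded - window_len, 0) + 1, step))
    last = padded - window_len
    if starts[-1] != last:
        starts.append(last)
    if batch_windows is None:
        batch_windows = max(1, round(BATCH_INPUT_SAMPLES / window_len))
    segments = tuple((s, s + window_len) for s in starts)
    return WindowPlan(
        L=L,
        window_len=window_len,
        overlap_fraction=overlap_fraction,
        weighting=weighting,
        batch_windows=batch_windows,
        segments=segments,
    )


def run_windows(network: Network, x: np.ndarray, plan: WindowPlan) -> list[np.ndarray]:
    """Eval-mode logits for every planned window, batched."""
    x = np.asarray(x, dtype=np.float64)
    if x.shape[-1] != plan.L:
        raise ValueError(f"series length {x.shape[-1]} does not match plan L={plan.L}")
    if plan.padded_len > plan.L:
        x = np.pad(x, ((0, 0), (0, plan.padded_len - plan.L)))
    outs: list[np.ndarray] = []
    segs = plan.segments
    for i in range(0, len(segs), plan.batch_windows):
        batch = np.stack([x[:, a:b] for a, b in segs[i : i + plan.batch_windows]])
        logits = network.forward(batch, train=False)
        outs.extend(logits)
    return outs


def _out_len(L: int, stride_ratio: int) -> int:
    return -(-L // stride_ratio)


def reconstruct(
    window_outputs: list[np.ndarray],
    plan: WindowPlan,
    stride_ratio: int = 1,
) -> np.ndarray:
    """Weighted overlap-add of per-window logit series.

    Each output sample is the weight-normalized average of the windows
    covering it, with Hanning (or rectangular) weights computed on the
    output-sample axis.  The result has length ``ceil(L / stride_ratio)``.
    """
    if len(window_outputs) != len(plan.segments):
        raise ValueError("one output series per planned window is required")
    lw = plan.window_len // stride_ratio
    for out in window_outputs:
        if out.shape[-1] != lw:
            raise ValueError(
                f"window output length {out.shape[-1]} != window_len/stride_ratio = {lw}"
            )
    if plan.weighting == "hanning":
        w = np.hanning(lw) if lw > 1 else np.ones(1)
        w = np.maximum(w, WEIGHT_FLOOR)
    else:
        w = np.ones(lw)
    n_classes = window_outputs[0].shape[0]
    total = _out_len(plan.padded_len, stride_ratio)
    num = np.zeros((n_classes, total))
    den = np.zeros(total)
    for (start, _end), out in zip(plan.segments, window_outputs):
        g0 = int(round(start / stride_ratio))
        num[:, g0 : g0 + lw] += out * w
        den[g0 : g0 + lw] += w
    keep = _out_len(plan.L, stride_ratio)
    if np.any(den[:keep] == 0):
        raise ValueError("window plan leaves gaps in output coverage")
    return num[:, :keep] / den[:keep]


def roi_trim_reconstruct(
    window_outputs: list[np.ndarray],
    plan: WindowPlan,
    roi: float,
    stride_ratio: int = 1,
) -> np.ndarray:
    """Concatenate window outputs after discarding half of each overlap.

    Valid only for finite-ROI (CNN-only) networks and overlaps of at least
    the ROI; then the reconstruction equals the unsegmented forward pass
    except within ROI/2 of the global ends.
    """
    if math.isinf(roi) or roi == ROI_ENTIRE_INPUT:
        raise ValueError("ROI-trim reconstruction requires a finite-ROI (CNN-only) network")
    if len(window_outputs) != len(plan.segments):
        raise ValueError("one output series per planned window is required")
    segs = plan.segments
    if len(segs) > 1:
        overlap = min(
            segs[i][1] - segs[i + 1][0] for i in range(len(segs) - 1)
        )
        if overlap < roi:
            raise ValueError(
                f"window overlap ({overlap} input samples) is smaller than the ROI ({roi})"
            )
    lw = plan.window_len // stride_ratio
    n_classes = window_outputs[0].shape[0]
    total = _out_len(plan.padded_len, stride_ratio)
    out = np.empty((n_classes, total))
    prev_cut = 0  # global output index where the previous window stopped
    for i, ((start, end), wout) in enumerate(zip(segs, window_outputs)):
        g0 = int(round(start / stride_ratio))
        if i + 1 < len(segs):
            mid_in = (segs[i + 1][0] + end) // 2  # midpoint of the overlap
            cut = int(round(mid_in / stride_ratio))
        else:
            cut = total
        out[:, prev_cut:cut] = wout[:, prev_cut - g0 : cut - g0]
        prev_cut = cut
    keep = _out_len(plan.L, stride_ratio)
    return out[:, :keep]


def predict_windowed(
    network: Network,
    x: np.ndarray,
    window_len: int = DEFAULT_WINDOW_LEN,
    overlap_fraction: float = DEFAULT_OVERLAP,
    weighting: str = "hanning",
    batch_windows: int | None = None,
    method: str = "overlap",
) -> NetworkOutput:
    """Full windowed inference for one (channels, length) series."""
    x = np.asarray(x, dtype=np.float64)
    sr = network.spec.output_stride_ratio
    if window_len % sr:
        raise ValueError(f"window_len must be divisible by the output stride ratio {sr}")
    plan = plan_windows(
        x.shape[-1], window_len, overlap_fraction, weighting, batch_windows
    )
    outs = run_windows(network, x, plan)
    if method == "overlap":
        logits = reconstruct(outs, plan, sr)
    elif method == "roi_trim":
        logits = roi_trim_reconstruct(outs, plan, network.spec.roi, sr)
    else:
        raise ValueError(f"method must be 'overlap' or 'roi_trim', got {method!r}")
    return NetworkOutput(logits)
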