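"""Labeled multichannel series: synthetic generation, preprocessing, I/O.

The synthetic generator emulates the statistical structure of sporadic-gesture
wearable-sensor recordings: a handful to ~100 z-scale continuous channels, a
dominant null class, sporadic labeled events of heterogeneous durations, and
occasional bursts of missing samples.  Each non-null class injects a fixed
band-limited sinusoid plus DC offset into a fixed random channel subset during
its events, which makes the classes spectrally separable by small CNNs while
remaining far simpler than real biomechanics (see the methods note for what
this does and does not exercise).

Preprocessing mirrors the standard pipeline for such data: linear
interpolation of missing samples (edges held constant) followed by per-channel
standardization using the training split's mean and standard deviation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import NamedTuple

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "LabeledSeries",
    "SynthConfig",
    "ChannelStats",
    "generate",
    "preprocess",
    "split_series",
    "write_series",
    "read_series",
    "load_opportunity",
]


@dataclass
class LabeledSeries:
    """Channel-major real-valued series with aligned per-sample integer labels.

    ``mask`` (optional, same shape as ``data``) marks missing samples that
    preprocessing should interpolate.
    """

    data: np.ndarray  # (n_channels, L)
    labels: np.ndarray  # (L,) integer, null class = 0
    sampling_rate: float = 30.0
    mask: np.ndarray | None = None

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=np.float64)
        self.labels = np.asarray(self.labels, dtype=np.int64)
        if self.data.ndim != 2:
            raise ValueError(f"data must be (n_channels, L), got shape {self.data.shape}")
        if self.labels.shape != (self.data.shape[1],):
            raise ValueError("labels must align with the sample axis of data")
        if self.mask is not None:
            self.mask = np.asarray(self.mask, dtype=bool)
            if self.mask.shape != self.data.shape:
                raise ValueError("mask must have the same shape as data")

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    def slice(self, start: int, end: int) -> "LabeledSeries":
        return LabeledSeries(
            self.data[:, start:end],
            self.labels[start:end],
            self.sampling_rate,
            None if self.mask is None else self.mask[:, start:end],
        )

    @staticmethod
    def concatenate(parts: list["LabeledSeries"]) -> "LabeledSeries":
        if not parts:
            raise ValueError("nothing to concatenate")
        masks = [p.mask for p in parts]
        if any(m is not None for m in masks):
            masks = [
                p.mask if p.mask is not None else np.zeros_like(p.data, dtype=bool)
                for p in parts
            ]
            mask = np.concatenate(masks, axis=1)
        else:
            mask = None
        return LabeledSeries(
            np.concatenate([p.data for p in parts], axis=1),
            np.concatenate([p.labels for p in parts]),
            parts[0].sampling_rate,
            mask,
        )


@dataclass(frozen=True)
class SynthConfig:
    """Synthetic-data generator settings.

    ``event_rate`` is the expected number of events per 1000 samples per
    non-null class; with the defaults the null class occupies roughly 80% of
    the samples.  Durations are uniform over ``duration_range`` (samples) and
    must stay resolvable by the coarsest model stride (>= ~2x the largest
    stride ratio).  Missing samples occur in contiguous bursts (geometric
    lengths, mean 5) totalling ``missing_fraction`` of each channel.
    """

    n_channels: int = 12
    n_classes: int = 6  # including the null class 0
    n_samples: int = 30_000
    sampling_rate: float = 30.0
    event_rate: float = 0.6
    duration_range: tuple[int, int] = (20, 100)
    amplitude_range: tuple[float, float] = (1.0, 2.0)
    noise_sd: float = 1.0
    missing_fraction: float = 0.02
    seed: int = 0


def generate(cfg: SynthConfig) -> LabeledSeries:
    """Generate a labeled series; deterministic given ``cfg.seed``.

    Background is white noise on every channel.  Each non-null class has a
    fixed random channel subset and a signature sinusoid (distinct frequency,
    random phase per event) plus a DC offset, injected during its events.
    Events never overlap (labels are single-valued per sample).
    """
    if cfg.n_classes < 2 or cfg.n_channels < 1 or cfg.n_samples < 1:
        raise ValueError("need at least one channel, one sample and two classes")
    lo, hi = cfg.duration_range
    if lo < 1 or hi < lo:
        raise ValueError(f"bad duration_range {cfg.duration_range}")
    rng = np.random.default_rng(cfg.seed)
    n_events_per_class = {
        k: rng.poisson(cfg.event_rate * cfg.n_samples / 1000.0)
        for k in range(1, cfg.n_classes)
    }
    mean_dur = (lo + hi) / 2.0
    expected_occupancy = sum(n_events_per_class.values()) * mean_dur
    if expected_occupancy > 0.8 * cfg.n_samples:
        raise ValueError(
            "infeasible event packing: expected labeled occupancy "
            f"{expected_occupancy:.0f} of {cfg.n_samples} samples"
        )

    data = rng.normal(0.0, cfg.noise_sd, size=(cfg.n_channels, cfg.n_samples))
    labels = np.zeros(cfg.n_samples, dtype=np.int64)
    occupied = np.zeros(cfg.n_samples, dtype=bool)
    fs = cfg.sampling_rate

    n_sub = max(2, cfg.n_channels // 3)
    for k in range(1, cfg.n_classes):
        subset = rng.choice(cfg.n_channels, size=n_sub, replace=False)
        # distinct signature frequencies spread over ~(0.05..0.33) * fs
        frac = 0.05 + 0.28 * (k - 1) / max(1, cfg.n_classes - 2)
        freq = frac * fs
        amp = rng.uniform(*cfg.amplitude_range)
        offset = rng.uniform(*cfg.amplitude_range)
        placed = 0
        attempts = 0
        target = n_events_per_class[k]
        while placed < target and attempts < 50 * max(1, target):
            attempts += 1
            dur = int(rng.integers(lo, hi + 1))
            if dur + 2 >= cfg.n_samples:
                continue
            start = int(rng.integers(0, cfg.n_samples - dur))
            # one-sample margin keeps events of any class from touching
            a = max(0, start - 1)
            b = min(cfg.n_samples, start + dur + 1)
            if occupied[a:b].any():
                continue
            occupied[a:b] = True
            labels[start : start + dur] = k
            t = np.arange(dur) / fs
            phase = rng.uniform(0, 2 * np.pi)
            sig = offset + amp * np.sin(2 * np.pi * freq * t + phase)
            data[subset, start : start + dur] += sig
            placed += 1
        if placed < target:
            raise ValueError(
                f"infeasible event packing for class {k}: placed {placed} of {target}"
            )

    mask = np.zeros_like(data, dtype=bool)
    if cfg.missing_fraction > 0:
        mean_burst = 5.0
        n_bursts = int(round(cfg.missing_fraction * cfg.n_samples / mean_burst))
        for ch in range(cfg.n_channels):
            for _ in range(n_bursts):
                start = int(rng.integers(0, cfg.n_samples))
                length = int(rng.geometric(1.0 / mean_burst))
                mask[ch, start : start + length] = True

    return LabeledSeries(data, labels, fs, mask)


class ChannelStats(NamedTuple):
    """Per-channel mean and standard deviation used for standardization."""

    mean: np.ndarray
    sd: np.ndarray


def preprocess(
    series: LabeledSeries, train_stats: ChannelStats | None = None
) -> tuple[LabeledSeries, ChannelStats]:
    """Interpolate missing samples, then standardize per channel.

    Missing samples (per ``series.mask``) are filled by linear interpolation
    with edges held constant.  Standardization uses ``train_stats`` when
    given (apply training-set statistics to validation/test data) and the
    series' own post-interpolation statistics otherwise.  Zero-variance
    channels have their sd floored at 1e-8 with a warning.

    Returns the preprocessed series (mask cleared) and the stats used.
    """
    data = series.data.copy()
    if series.mask is not None and series.mask.any():
        idx = np.arange(series.n_samples)
        for ch in range(series.n_channels):
            miss = series.mask[ch]
            if not miss.any():
                continue
            if miss.all():
                raise ValueError(f"channel {ch} has no observed values to interpolate from")
            data[ch, miss] = np.interp(idx[miss], idx[~miss], data[ch, ~miss])
    if train_stats is None:
        mean = data.mean(axis=1)
        sd = data.std(axis=1)
        if np.any(sd < 1e-8):
            warnings.warn("zero-variance channel(s); sd floored at 1e-8")
            sd = np.maximum(sd, 1e-8)
        train_stats = ChannelStats(mean, sd)
    data = (data - train_stats.mean[:, None]) / train_stats.sd[:, None]
    out = LabeledSeries(data, series.labels.copy(), series.sampling_rate, None)
    return out, train_stats


def split_series(series: LabeledSeries, fractions=(0.6, 0.2, 0.2)) -> list[LabeledSeries]:
    """Split into contiguous chunks by fraction (train/val/test style)."""
    if not np.isclose(sum(fractions), 1.0):
        raise ValueError("fractions must sum to 1")
    edges = np.cumsum([0.0, *fractions])
    idx = (edges * series.n_samples).round().astype(int)
    return [series.slice(a, b) for a, b in zip(idx[:-1], idx[1:])]


# ---------------------------------------------------------------------------
# Columnar text I/O (one row per sample: channels then label)
# ---------------------------------------------------------------------------


def write_series(series: LabeledSeries, path, config: SynthConfig | None = None) -> None:
    path = Path(path)
    df = pd.DataFrame(series.data.T, columns=[f"ch{i}" for i in range(series.n_channels)])
    df["label"] = series.labels
    df.to_csv(path, sep="\t", index=False, float_format="%.6g")
    if config is not None:
        sidecar = path.with_suffix(path.suffix + ".yaml")
        sidecar.write_text(yaml.safe_dump({**config.__dict__}, sort_keys=False))


def read_series(path, sampling_rate: float = 30.0) -> LabeledSeries:
    df = pd.read_csv(path, sep="\t")
    if "label" not in df.columns:
        raise ValueError(f"{path}: expected a 'label' column")
    labels = df.pop("label").to_numpy(dtype=np.int64)
    return LabeledSeries(df.to_numpy(dtype=np.float64).T, labels, sampling_rate)


# ---------------------------------------------------------------------------
# Optional adapter for the Opportunity benchmark's whitespace-delimited .dat
# session files (not exercised by the test suite; requires the externally
# downloaded dataset).
# ---------------------------------------------------------------------------

#: Gesture label values of the 18-class task, mapped to 0..17 (0 = null).
_GESTURE_LABELS = [
    0, 406516, 406517, 404516, 404517, 406520, 404520, 406505, 404505,
    406519, 404519, 406511, 404511, 406508, 404508, 408512, 407521, 405506,
]

#: Sensor subsets by channel position after challenge-column selection: the
#: first 45 columns are five body IMUs, each acc(3)+gyro(3)+mag(3).
_SUBSETS = {
    "Gyros": [i for b in range(5) for i in range(9 * b + 3, 9 * b + 6)],
    "Accels": [i for b in range(5) for i in range(9 * b, 9 * b + 3)],
    "Accels+Gyros": [i for b in range(5) for i in range(9 * b, 9 * b + 6)],
    "Accels+Gyros+Magnetic": list(range(45)),
    "All": list(range(113)),
}

_TRAIN_SESSIONS = {
    1: ["ADL1", "ADL2", "ADL3", "ADL4", "ADL5", "Drill"],
    2: ["ADL1", "ADL2", "Drill"],
    3: ["ADL1", "ADL2", "Drill"],
}
_VAL_SESSIONS = {2: ["ADL3"], 3: ["ADL3"]}
_TEST_SESSIONS = {2: ["ADL4", "ADL5"], 3: ["ADL4", "ADL5"]}


def _challenge_columns() -> np.ndarray:
    """0-based columns of a 250-column .dat row kept for the 113-channel task."""
    drop = np.concatenate(
        [
            np.arange(46, 50),
            np.arange(59, 63),
            np.arange(72, 76),
            np.arange(85, 89),
            np.arange(98, 102),
        ]
    )
    cols = np.setdiff1d(np.arange(1, 134), drop)  # col 0 is the timestamp
    assert cols.size == 113
    return cols


def _load_session(path: Path) -> tuple[np.ndarray, np.ndarray]:
    raw = np.loadtxt(path)
    sensors = raw[:, _challenge_columns()]
    gestures = raw[:, 249].astype(np.int64)
    label_map = {v: i for i, v in enumerate(_GESTURE_LABELS)}
    labels = np.array([label_map.get(v, 0) for v in gestures], dtype=np.int64)
    return sensors.T, labels


def load_opportunity(path, sensor_subset: str = "All"):
    """Load and compose the gesture-task splits from .dat session files.

    Returns (train, validation, test) preprocessed ``LabeledSeries`` with the
    requested sensor subset; standardization statistics come from the
    training split.
    """
    if sensor_subset not in _SUBSETS:
        raise ValueError(
            f"unknown sensor subset {sensor_subset!r}; expected one of {sorted(_SUBSETS)}"
        )
    root = Path(path)

    def compose(session_map):
        parts = []
        for subject, sessions in session_map.items():
            for sess in sessions:
                f = root / f"S{subject}-{sess}.dat"
                if not f.exists():
                    raise FileNotFoundError(
                        f"missing session file {f.name}; expected files like "
                        "S1-ADL1.dat ... S3-Drill.dat under the dataset directory"
                    )
                sensors, labels = _load_session(f)
                sel = _SUBSETS[sensor_subset]
                mask = np.isnan(sensors[sel])
                parts.append(
                    LabeledSeries(np.nan_to_num(sensors[sel]), labels, 30.0, mask)
                )
        return LabeledSeries.concatenate(parts)

    train, stats = preprocess(compose(_TRAIN_SESSIONS))
    val, _ = preprocess(compose(_VAL_SESSIONS), stats)
    test, _ = preprocess(compose(_TEST_SESSIONS), stats)
    return train, val, test
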