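"""n-fold contiguous cross-validation ensembles with logit averaging.

The combined train+validation series is divided into ``n`` disjoint
contiguous folds; sub-model *i* validates on fold *i* and trains on the
concatenation of the others (sub-models share the architecture and training
configuration and differ only in fold assignment and a seed offset).  At
inference the sub-models' logit series are averaged elementwise and the
softmax is applied once to the mean.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .architectures import ArchitectureSpec, Network, NetworkOutput
from .data import LabeledSeries
from .training import TrainConfig, TrainHistory, train

__all__ = [
    "FoldPlan",
    "make_folds",
    "ensemble_logits",
    "train_ensemble",
    "predict_ensemble",
]


@dataclass(frozen=True)
class FoldPlan:
    """Disjoint contiguous sample intervals covering [0, L)."""

    n_folds: int
    folds: tuple[tuple[int, int], ...]

    @property
    def L(self) -> int:
        return self.folds[-1][1]


def make_folds(L: int, n: int) -> FoldPlan:
    """Split [0, L) into n contiguous folds whose lengths differ by <= 1.

    The remainder goes to the leftmost folds.
    """
    if n < 2:
        raise ValueError(f"need at least 2 folds, got {n}")
    if n > L:
        raise ValueError(f"cannot make {n} folds from {L} samples")
    base, rem = divmod(L, n)
    folds = []
    at = 0
    for i in range(n):
        length = base + (1 if i < rem else 0)
        folds.append((at, at + length))
        at += length
    return FoldPlan(n_folds=n, folds=tuple(folds))


def ensemble_logits(logit_series_list) -> NetworkOutput:
    """Elementwise mean of sub-model logits; softmax applied once to the mean."""
    if not logit_series_list:
        raise ValueError("need at least one logit series to ensemble")
    arrs = [np.asarray(a, dtype=np.float64) for a in logit_series_list]
    shape = arrs[0].shape
    for a in arrs[1:]:
        if a.shape != shape:
            raise ValueError(f"logit shape mismatch: {a.shape} vs {shape}")
    return NetworkOutput(np.mean(arrs, axis=0))


@dataclass
class EnsembleResult:
    """Trained sub-models plus the fold plan that produced them."""

    networks: list[Network]
    histories: list[TrainHistory]
    fold_plan: FoldPlan

    def save(self, path) -> None:
        import json

        state = {"__n__": np.array(len(self.networks))}
        state["__folds__"] = np.array(self.fold_plan.folds)
        for i, net in enumerate(self.networks):
            for k, v in net.get_state().items():
                state[f"m{i}/{k}"] = v
            state[f"m{i}/__config__"] = np.frombuffer(
                json.dumps(net.spec.to_dict()).encode(), dtype=np.uint8
            )
        np.savez(path, **state)

    @classmethod
    def load(cls, path) -> "EnsembleResult":
        import json

        with np.load(path) as data:
            n = int(data["__n__"])
            folds = tuple(map(tuple, data["__folds__"].tolist()))
            nets = []
            for i in range(n):
                cfg = json.loads(bytes(data[f"m{i}/__config__"].tobytes()).decode())
                net = Network(ArchitectureSpec.from_dict(cfg))
                prefix = f"m{i}/"
                net.set_state(
                    {
                        k[len(prefix):]: data[k]
                        for k in data.files
                        if k.startswith(prefix) and not k.endswith("__config__")
                    }
                )
                nets.append(net)
        return cls(nets, [], FoldPlan(n_folds=n, folds=folds))


def train_ensemble(
    spec: ArchitectureSpec,
    combined: LabeledSeries,
    n_folds: int,
    cfg: TrainConfig | None = None,
    seed: int = 0,
    log=None,
) -> EnsembleResult:
    """Train one sub-model per fold (validation = the fold, train = the rest)."""
    plan = make_folds(combined.n_samples, n_folds)
    networks = []
    histories = []
    for i, (a, b) in enumerate(plan.folds):
        val = combined.slice(a, b)
        parts = []
        if a > 0:
            parts.append(combined.slice(0, a))
        if b < combined.n_samples:
            parts.append(combined.slice(b, combined.n_samples))
        train_part = LabeledSeries.concatenate(parts)
        if log is not None:
            log(f"# fold {i}: val [{a}, {b})")
        net, hist = train(spec, train_part, val, cfg, seed=seed + i, log=log)
        networks.append(net)
        histories.append(hist)
    return EnsembleResult(networks, histories, plan)


def predict_ensemble(result: EnsembleResult, x: np.ndarray, **window_kwargs) -> NetworkOutput:
    """Windowed inference per sub-model, then logit averaging."""
    from .inference import predict_windowed

    outs = [predict_windowed(net, x, **window_kwargs).logits for net in result.networks]
    return ensemble_logits(outs)
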